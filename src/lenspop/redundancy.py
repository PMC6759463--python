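"""Identity-by-state similarity, replicate-calibrated redundancy threshold,
and collapsing of redundant accessions.

Per locus the IBS score between two calls is the shared-allele fraction
1 - |a - b| / 2 (identical genotypes 1, het vs hom 0.5, opposite
homozygotes 0); the pair value is the mean over loci where both calls are
present.  The redundancy threshold is calibrated as mean - 3 x SD of the
pairwise IBS values among designated biological replicates, and redundancy
groups are the connected components (size >= 2) of the graph linking pairs
at or above the threshold.  Within a group the accession with the highest
call rate is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Symmetric sample x sample IBS similarity in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray          # (n, n); NaN where no shared loci
    n_shared: np.ndarray        # per-pair count of loci compared

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9:
                raise ValueError("IBS values must lie in [0, 1]")

    def undefined_pairs(self) -> list[tuple[str, str]]:
        i, j = np.where(np.isnan(np.triu(self.values, 1)))
        mask = i < j
        return [(self.sample_ids[a], self.sample_ids[b])
                for a, b in zip(i[mask], j[mask])]

    def pair(self, a: str, b: str) -> float:
        ia, ib = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[ia, ib])


@dataclass
class RedundancyResult:
    threshold: float
    groups: list[list[str]]
    representatives: list[str]
    replicate_mean: float | None = None
    replicate_sd: float | None = None


def ibs_matrix(g: GenotypeMatrix) -> SimilarityMatrix:
    """All-pairs IBS similarity over pairwise-complete loci.

    Pairs sharing zero non-missing loci are NaN (reported, never zeroed).
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    calls = g.calls_float()
    n = g.n_samples
    values = np.ones((n, n))
    shared = np.zeros((n, n), dtype=int)
    present = ~np.isnan(calls)
    shared[np.diag_indices(n)] = present.sum(axis=1)
    for i in range(n):
        both = present[i] & present[i + 1:]
        diff = np.abs(calls[i] - calls[i + 1:])
        score = np.where(both, 1.0 - diff / 2.0, 0.0)
        cnt = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            sim = np.where(cnt > 0, score.sum(axis=1) / np.maximum(cnt, 1), np.nan)
        values[i, i + 1:] = values[i + 1:, i] = sim
        shared[i, i + 1:] = shared[i + 1:, i] = cnt
    out = SimilarityMatrix(list(g.sample_ids), values, shared)
    undef = out.undefined_pairs()
    if undef:
        logger.warning("ibs_matrix: %d pairs share zero loci: %s", len(undef), undef[:5])
    return out


def calibrate_threshold(
    sim: SimilarityMatrix, replicate_ids: list[str]
) -> tuple[float, float, float]:
    """Redundancy threshold = mean - 3 x SD over replicate-pair IBS values.

    Returns ``(threshold, mean, sd)``.  With a single replicate pair the SD
    is zero and the threshold equals that pair's IBS (logged warning).
    """
    if len(replicate_ids) < 2:
        raise ValueError("need at least two replicate samples")
    idx = [sim.sample_ids.index(r) for r in replicate_ids]
    vals = np.array(
        [sim.values[a, b] for i, a in enumerate(idx) for b in idx[i + 1:]]
    )
    if np.isnan(vals).any():
        raise ValueError("replicate pair with undefined IBS")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    if len(vals) == 1:
        logger.warning("calibrate_threshold: single replicate pair, SD taken as 0")
    return mean - 3.0 * sd, mean, sd


def collapse_redundant(
    g: GenotypeMatrix, sim: SimilarityMatrix, threshold: float
) -> tuple[GenotypeMatrix, RedundancyResult]:
    """Group samples with IBS >= threshold by connected components and keep
    one representative per group (highest call rate; ties by matrix order)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    n = len(sim.sample_ids)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, 1)
    with np.errstate(invalid="ignore"):
        hits = sim.values[iu, ju] >= threshold
    graph.add_edges_from(zip(iu[hits], ju[hits]))

    call_rate = g.sample_call_rate()
    order = {s: i for i, s in enumerate(g.sample_ids)}
    groups: list[list[str]] = []
    reps: list[str] = []
    drop: set[str] = set()
    for comp in sorted(nx.connected_components(graph), key=min):
        if len(comp) < 2:
            continue
        members = sorted((sim.sample_ids[i] for i in comp), key=order.get)
        rep = max(members, key=lambda s: (call_rate[order[s]], -order[s]))
        groups.append(members)
        reps.append(rep)
        drop.update(m for m in members if m != rep)
    keep_idx = [i for i, s in enumerate(g.sample_ids) if s not in drop]
    result = RedundancyResult(threshold=threshold, groups=groups, representatives=reps)
    return g.take_samples(keep_idx), result
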