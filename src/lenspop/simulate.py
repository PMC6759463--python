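"""Synthetic genotype and phenotype generator.

Genotypes follow the Balding-Nichols island model: each locus has an
ancestral allele frequency p ~ Uniform(0.05, 0.95) and each subpopulation
k draws its own frequency from Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k), so
the differentiation parameter F_k is the expected F_ST of population k
against the ancestral pool.  Within individuals a selfing inbreeding
coefficient F_IS controls the excess of homozygotes: with probability
F_IS a single allele is drawn and doubled, otherwise two alleles are
drawn independently.

On top of the island model the generator plants the nuisance structure a
germplasm panel shows in practice: admixed individuals (ancestry from a
flat Dirichlet, truncated so the largest component is at most 0.6, which
by construction fails the q > 0.6 assignment rule), groups of
near-duplicate accessions (copies of a source genotype with a per-locus
error rate), and uniformly random missing calls.

Phenotypes follow a randomized-block model: trait value = cluster mean +
block effect + additive causal-marker effect x allele count + Gaussian
residual, with two blocks by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PhenoTable

_TRANSITIONS = [("A", "G"), ("C", "T")]
_TRANSVERSIONS = [("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]


@dataclass(frozen=True)
class TraitModel:
    """Per-cluster means plus residual and block-effect standard deviations."""

    cluster_means: tuple[float, ...]
    residual_sd: float
    block_sd: float = 0.0


@dataclass(frozen=True)
class CausalMarker:
    """A planted additive QTL: per-allele effect(s) at one locus.

    ``effects`` maps trait name to the additive effect of one alternate
    allele; traits not listed are unaffected.
    """

    locus: int
    effects: Mapping[str, float]


@dataclass(frozen=True)
class DuplicateGroup:
    """Copies of a source accession with a per-call error rate."""

    source: str
    copies: int
    error_rate: float


@dataclass(frozen=True)
class SimSpec:
    """Full description of one synthetic dataset.

    The defaults emulate a Mediterranean inbred-lentil germplasm panel:
    five subpopulations of 33 accessions, 3,000 biallelic GBS SNPs,
    pairwise differentiation in the low-0.2 to mid-0.3 range, near-complete
    selfing (F_IS = 0.95), 19 admixed accessions, a four-way replicate set
    of one reference line plus several duplicate pairs/triples, 5% missing
    calls, and six agronomic/seed traits with cluster-level effects and one
    shared large-effect seed-size marker.
    """

    n_pops: int = 5
    samples_per_pop: tuple[int, ...] = (33, 33, 33, 33, 33)
    n_loci: int = 3000
    differentiation: tuple[float, ...] = (0.25, 0.25, 0.30, 0.30, 0.35)
    selfing_inbreeding: float = 0.95
    n_admixed: int = 19
    max_admixed_q: float = 0.6
    duplicate_groups: tuple[DuplicateGroup, ...] = (
        DuplicateGroup("P1_000", 3, 0.01),   # four-way replicate set
        DuplicateGroup("P2_001", 1, 0.01),
        DuplicateGroup("P3_001", 2, 0.01),
        DuplicateGroup("P4_001", 1, 0.01),
        DuplicateGroup("P5_001", 1, 0.01),
    )
    missing_rate: float = 0.05
    transition_prob: float = 0.64
    trait_model: Mapping[str, TraitModel] = field(
        default_factory=lambda: {
            "flowering_time": TraitModel((134, 132, 143, 146, 144), 5.0, 1.5),
            "plant_height": TraitModel((31, 36, 41, 44, 37), 4.5, 1.0),
            "first_node_height": TraitModel((13, 13, 18, 20, 17), 3.5, 0.5),
            "seed_area": TraitModel((11.9, 16.2, 25.6, 18.4, 17.2), 4.0, 0.5),
            "seed_perimeter": TraitModel((13.0, 15.7, 19.1, 16.2, 15.7), 1.8, 0.3),
            "seed_diameter": TraitModel((3.8, 4.5, 5.6, 4.7, 4.6), 0.55, 0.1),
        }
    )
    # locus -1 = "middle of the panel", resolved against n_loci
    causal_marker: CausalMarker | None = CausalMarker(
        -1, {"seed_area": 4.0, "seed_perimeter": 1.8, "seed_diameter": 0.55}
    )
    n_blocks: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_loci < 1:
            raise ValueError("counts must be positive")
        if len(self.samples_per_pop) != self.n_pops:
            raise ValueError("samples_per_pop length must equal n_pops")
        if len(self.differentiation) != self.n_pops:
            raise ValueError("differentiation length must equal n_pops")
        for f in self.differentiation:
            if not 0.0 < f < 1.0:
                raise ValueError("differentiation F must lie in (0,1)")
        for rate in (self.selfing_inbreeding, self.missing_rate, self.transition_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0,1]")
        for grp in self.duplicate_groups:
            if grp.copies < 1 or not 0.0 <= grp.error_rate <= 1.0:
                raise ValueError(f"bad duplicate group {grp}")
        if self.causal_marker is not None and self.causal_marker.locus < 0:
            object.__setattr__(
                self, "causal_marker",
                CausalMarker(self.n_loci // 2, dict(self.causal_marker.effects)),
            )

    def with_(self, **kw) -> "SimSpec":
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated panel."""

    labels: list[str]                 # population name or "admixed"
    ancestry: np.ndarray              # (n_samples, n_pops), rows sum to 1
    pop_names: list[str]
    duplicates: dict[str, str]        # copy id -> source id
    replicate_ids: list[str]          # source + copies of the first duplicate group
    causal_locus: str | None
    pop_freqs: np.ndarray             # (n_pops, n_loci)


def two_pop_spec(
    fst: float, n_per_pop: int, n_loci: int, f_is: float = 0.95, seed: int = 0
) -> SimSpec:
    """Convenience spec: two clean populations, no admixture/duplicates/missing."""
    return SimSpec(
        n_pops=2,
        samples_per_pop=(n_per_pop, n_per_pop),
        n_loci=n_loci,
        differentiation=(fst, fst),
        selfing_inbreeding=f_is,
        n_admixed=0,
        duplicate_groups=(),
        missing_rate=0.0,
        causal_marker=None,
        seed=seed,
    )


def island_spec(
    n_pops: int,
    n_per_pop: int,
    n_loci: int,
    fst: float,
    f_is: float = 0.95,
    seed: int = 0,
    **kw,
) -> SimSpec:
    """Convenience spec: K equal clean populations at a common differentiation."""
    return SimSpec(
        n_pops=n_pops,
        samples_per_pop=(n_per_pop,) * n_pops,
        n_loci=n_loci,
        differentiation=(fst,) * n_pops,
        selfing_inbreeding=f_is,
        n_admixed=0,
        duplicate_groups=(),
        missing_rate=0.0,
        causal_marker=None,
        seed=seed,
        **kw,
    )


def _draw_genotypes(rng, p: np.ndarray, f_is: float) -> np.ndarray:
    """One individual's calls given its per-locus allele frequencies."""
    selfed = rng.random(p.shape) < f_is
    g_self = 2 * (rng.random(p.shape) < p)
    g_out = rng.binomial(2, p)
    return np.where(selfed, g_self, g_out).astype(np.int8)


def simulate_genotypes(spec: SimSpec) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate a genotype panel under ``spec`` (deterministic given seed)."""
    rng = np.random.default_rng(spec.seed)
    L, K = spec.n_loci, spec.n_pops
    pop_names = [f"P{k + 1}" for k in range(K)]

    p_anc = rng.uniform(0.05, 0.95, size=L)
    pop_freqs = np.empty((K, L))
    for k, f in enumerate(spec.differentiation):
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        pop_freqs[k] = rng.beta(a, b)

    sample_ids: list[str] = []
    labels: list[str] = []
    ancestry_rows: list[np.ndarray] = []
    rows: list[np.ndarray] = []

    for k, n_k in enumerate(spec.samples_per_pop):
        for i in range(n_k):
            sample_ids.append(f"{pop_names[k]}_{i:03d}")
            labels.append(pop_names[k])
            onehot = np.zeros(K)
            onehot[k] = 1.0
            ancestry_rows.append(onehot)
            rows.append(_draw_genotypes(rng, pop_freqs[k], spec.selfing_inbreeding))

    for i in range(spec.n_admixed):
        while True:
            q = rng.dirichlet(np.ones(K))
            if q.max() <= spec.max_admixed_q:
                break
        origin = (rng.random(L)[:, None] > np.cumsum(q)[None, :-1]).sum(axis=1)
        p_ind = pop_freqs[origin, np.arange(L)]
        sample_ids.append(f"ADM_{i:03d}")
        labels.append("admixed")
        ancestry_rows.append(q)
        rows.append(_draw_genotypes(rng, p_ind, spec.selfing_inbreeding))

    duplicates: dict[str, str] = {}
    replicate_ids: list[str] = []
    for gi, grp in enumerate(spec.duplicate_groups):
        try:
            src = sample_ids.index(grp.source)
        except ValueError:
            raise ValueError(f"duplicate source {grp.source!r} not among samples") from None
        for c in range(grp.copies):
            g = rows[src].copy()
            flip = rng.random(L) < grp.error_rate
            shift = 1 + (rng.random(L) < 0.5)
            g[flip] = (g[flip] + shift[flip]) % 3
            cid = f"{grp.source}_rep{c + 1}"
            sample_ids.append(cid)
            labels.append(labels[src])
            ancestry_rows.append(ancestry_rows[src])
            rows.append(g)
            duplicates[cid] = grp.source
            if gi == 0:
                replicate_ids.append(cid)
        if gi == 0 and grp.copies:
            replicate_ids.insert(0, grp.source)

    calls = np.vstack(rows)
    if spec.missing_rate > 0:
        calls[rng.random(calls.shape) < spec.missing_rate] = MISSING

    alleles: list[tuple[str, str]] = []
    for _ in range(L):
        pool = _TRANSITIONS if rng.random() < spec.transition_prob else _TRANSVERSIONS
        pair = pool[rng.integers(len(pool))]
        alleles.append(pair if rng.random() < 0.5 else (pair[1], pair[0]))

    locus_ids = [f"TP{j + 1}" for j in range(L)]
    gmat = GenotypeMatrix(sample_ids, locus_ids, calls, alleles)
    if spec.causal_marker is not None and not 0 <= spec.causal_marker.locus < L:
        raise ValueError("causal marker locus index out of range")
    truth = SimTruth(
        labels=labels,
        ancestry=np.vstack(ancestry_rows),
        pop_names=pop_names,
        duplicates=duplicates,
        replicate_ids=replicate_ids,
        causal_locus=None if spec.causal_marker is None
        else locus_ids[spec.causal_marker.locus],
        pop_freqs=pop_freqs,
    )
    return gmat, truth


def simulate_phenotypes(
    labels: Sequence[str],
    genotypes: GenotypeMatrix,
    spec: SimSpec,
    ancestry: np.ndarray | None = None,
) -> PhenoTable:
    """Randomized-block phenotypes for every sample in ``genotypes``.

    ``labels`` gives each sample's cluster (admixed samples may carry any
    non-cluster label); admixed samples receive ancestry-weighted cluster
    means when ``ancestry`` is supplied, otherwise the grand mean.
    """
    if len(labels) != genotypes.n_samples:
        raise ValueError("labels length must match sample count")
    rng = np.random.default_rng([spec.seed, 7])
    pop_names = [f"P{k + 1}" for k in range(spec.n_pops)]
    n = genotypes.n_samples

    causal_calls = np.zeros(n)
    if spec.causal_marker is not None:
        j = spec.causal_marker.locus
        if not 0 <= j < genotypes.n_loci:
            raise ValueError("causal marker locus index out of range")
        col = genotypes.calls_float()[:, j]
        col[np.isnan(col)] = np.nanmean(col)
        causal_calls = col

    records: dict[str, list] = {"genotype": [], "block": []}
    trait_names = list(spec.trait_model)
    for t in trait_names:
        records[t] = []

    # block effects are shared by every genotype within a block
    block_effects = {
        t: rng.normal(0.0, tm.block_sd, size=spec.n_blocks)
        for t, tm in spec.trait_model.items()
    }
    for i, sid in enumerate(genotypes.sample_ids):
        lab = labels[i]
        for b in range(spec.n_blocks):
            records["genotype"].append(sid)
            records["block"].append(str(b + 1))
            for t, tm in spec.trait_model.items():
                means = np.asarray(tm.cluster_means, dtype=float)
                if lab in pop_names:
                    mu = means[pop_names.index(lab)]
                elif ancestry is not None:
                    mu = float(ancestry[i] @ means)
                else:
                    mu = float(means.mean())
                beta = 0.0
                if spec.causal_marker is not None:
                    beta = spec.causal_marker.effects.get(t, 0.0)
                val = (
                    mu
                    + block_effects[t][b]
                    + beta * causal_calls[i]
                    + rng.normal(0.0, tm.residual_sd)
                )
                records[t].append(val)
    return PhenoTable(pd.DataFrame(records))


def write_truth_tsv(truth: SimTruth, sample_ids: Sequence[str], path) -> None:
    """Persist the ground truth (labels, ancestry, duplicate sources)."""
    df = pd.DataFrame(
        truth.ancestry, index=list(sample_ids),
        columns=[f"q_{p}" for p in truth.pop_names],
    )
    df.insert(0, "label", truth.labels)
    df["duplicate_of"] = [truth.duplicates.get(s, "") for s in sample_ids]
    df["is_replicate"] = [s in truth.replicate_ids for s in sample_ids]
    df.to_csv(path, sep="\t", float_format="%.4f")
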