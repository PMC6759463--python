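"""Between-cluster differentiation and trees.

Weir-Cockerham variance components are computed per locus from group
sizes, allele frequencies and *observed* heterozygote frequencies (no
Hardy-Weinberg assumption -- appropriate for a selfing crop):

    a : among-population variance component
    b : between-individuals-within-population component
    c : within-individual component

The multi-locus estimate is the ratio of sums theta = sum(a) / sum(a+b+c),
never the mean of per-locus ratios.  Per-locus one-vs-rest theta screens
for distinctive alleles (flags at 0.8 and 0.95), reported unclamped so
the null behaviour of the screen stays unbiased.

Cluster trees use Nei's (1972) standard distance with neighbor joining
and a locus bootstrap for branch support; individual relationships use
the allele-sharing distance (1 - IBS) with Ward linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io import GenotypeMatrix
from .redundancy import ibs_matrix

logger = logging.getLogger(__name__)


# -- Weir-Cockerham ------------------------------------------------------


def _group_locus_summaries(g: GenotypeMatrix, labels, groups):
    """Per group x locus: non-missing count, alt-allele freq, het freq."""
    calls = g.calls_float()
    labels = np.asarray(labels)
    n_i, p_i, h_i = [], [], []
    for grp in groups:
        sub = calls[labels == grp]
        obs = ~np.isnan(sub)
        cnt = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p = np.nansum(sub, axis=0) / (2.0 * np.maximum(cnt, 1))
            h = (sub == 1).sum(axis=0) / np.maximum(cnt, 1)
        n_i.append(cnt)
        p_i.append(p)
        h_i.append(h)
    return np.array(n_i), np.array(p_i), np.array(h_i)


def wc_components(
    g: GenotypeMatrix, labels, groups=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham components (a, b, c) plus a validity mask.

    Loci where any group has zero non-missing calls, or where the mean
    sample size does not exceed 1, are marked invalid.
    """
    labels = np.asarray(labels)
    if groups is None:
        groups = sorted(set(labels))
    r = len(groups)
    if r < 2:
        raise ValueError("need at least two groups")
    for grp in groups:
        sub = g.calls_float()[labels == grp]
        if sub.shape[0] == 0 or (~np.isnan(sub)).sum() < 2:
            raise ValueError(f"group {grp!r} has fewer than two non-missing calls")
    n_i, p_i, h_i = _group_locus_summaries(g, labels, groups)

    valid = (n_i >= 1).all(axis=0)
    nbar = n_i.sum(axis=0) / r
    valid &= nbar > 1
    nbar_safe = np.where(valid, nbar, 2.0)
    nc = (r * nbar_safe - (n_i ** 2).sum(axis=0) / (r * nbar_safe)) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / (r * nbar_safe)
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar_safe)
    hbar = (n_i * h_i).sum(axis=0) / (r * nbar_safe)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar_safe / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar_safe - 1)
        )
        b = (nbar_safe / (nbar_safe - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar_safe - 1) / (4 * nbar_safe) * hbar
        )
    c = hbar / 2.0
    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (nc > 0)
    return a, b, c, valid


def multilocus_theta(g: GenotypeMatrix, labels, groups=None) -> tuple[float, int]:
    """Ratio-of-sums multi-locus theta and the count of loci used."""
    a, b, c, valid = wc_components(g, labels, groups)
    denom = (a + b + c)[valid].sum()
    if denom == 0:
        return float("nan"), int(valid.sum())
    return float(a[valid].sum() / denom), int(valid.sum())


@dataclass
class FstMatrix:
    group_names: list[str]
    values: np.ndarray          # symmetric, zero diagonal
    n_loci: np.ndarray          # per-pair locus count used

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.group_names,
                            columns=self.group_names)


def wc_fst_pairwise(g: GenotypeMatrix, labels) -> FstMatrix:
    """Pairwise multi-locus Weir-Cockerham theta between labelled clusters."""
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    r = len(groups)
    if r < 2:
        raise ValueError("need at least two groups")
    values = np.zeros((r, r))
    counts = np.zeros((r, r), dtype=int)
    for i in range(r):
        for j in range(i + 1, r):
            keep = np.isin(labels, [groups[i], groups[j]])
            sub = g.take_samples(np.flatnonzero(keep))
            theta, nl = multilocus_theta(sub, labels[keep], [groups[i], groups[j]])
            values[i, j] = values[j, i] = theta
            counts[i, j] = counts[j, i] = nl
    return FstMatrix([str(x) for x in groups], values, counts)


def wc_fst_one_vs_rest(
    g: GenotypeMatrix, labels, flag_thresholds: tuple[float, float] = (0.8, 0.95)
) -> pd.DataFrame:
    """Per-locus theta comparing each cluster against the pooled rest.

    Theta is reported unclamped (negative values possible); flag columns
    mark loci above the two screen thresholds, with the allele enriched in
    the focal cluster.  Loci monomorphic across both groups are NaN and
    never flagged.
    """
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    lo, hi = flag_thresholds
    frames = []
    for grp in groups:
        two = np.where(labels == grp, "focal", "rest")
        a, b, c, valid = wc_components(g, two, ["focal", "rest"])
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(valid & ((a + b + c) != 0), a / (a + b + c), np.nan)
        n_i, p_i, _ = _group_locus_summaries(g, two, ["focal", "rest"])
        enriched = np.where(p_i[0] > p_i[1], "alt", "ref")
        ok = np.isfinite(theta)
        frames.append(pd.DataFrame({
            "locus_id": g.locus_ids,
            "cluster": str(grp),
            "theta": theta,
            f"above_{lo}": ok & (theta > lo),
            f"above_{hi}": ok & (theta > hi),
            "enriched_allele": enriched,
        }))
    return pd.concat(frames, ignore_index=True)


# -- Nei distance and trees ----------------------------------------------


def _group_freqs(g: GenotypeMatrix, labels, groups):
    calls = g.calls_float()
    labels = np.asarray(labels)
    p, have = [], []
    for grp in groups:
        sub = calls[labels == grp]
        cnt = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p.append(np.nansum(sub, axis=0) / (2.0 * np.maximum(cnt, 1)))
        have.append(cnt > 0)
    return np.array(p), np.array(have)


def nei_distance(g: GenotypeMatrix, labels) -> FstMatrix:
    """Nei's (1972) standard genetic distance between labelled clusters.

    D = -ln( J_XY / sqrt(J_X * J_Y) ) with the J terms averaged over loci
    present in both groups; disjoint allele sets give infinite distance
    (flagged in the log).
    """
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    p, have = _group_freqs(g, labels, groups)
    r = len(groups)
    values = np.zeros((r, r))
    counts = np.zeros((r, r), dtype=int)
    for i in range(r):
        for j in range(i + 1, r):
            both = have[i] & have[j]
            x, y = p[i][both], p[j][both]
            jx = float(np.mean(x ** 2 + (1 - x) ** 2))
            jy = float(np.mean(y ** 2 + (1 - y) ** 2))
            jxy = float(np.mean(x * y + (1 - x) * (1 - y)))
            if jxy == 0:
                logger.warning("nei_distance: disjoint alleles between %s and %s",
                               groups[i], groups[j])
                d = np.inf
            else:
                d = -np.log(jxy / np.sqrt(jx * jy))
            values[i, j] = values[j, i] = d
            counts[i, j] = counts[j, i] = int(both.sum())
    return FstMatrix([str(x) for x in groups], values, counts)


def nj_tree(values: np.ndarray, labels: list[str]) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths are clamped."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(labels) < 3:
        raise ValueError("need at least three taxa")
    return nj(DistanceMatrix(values, labels), neg_as_zero=True)


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Internal-edge bipartitions as unordered pairs of leaf-name sets."""
    all_leaves = frozenset(l.name for l in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        if 2 <= len(side) <= len(all_leaves) - 2:
            parts.add(frozenset({side, all_leaves - side}))
    return parts


def bootstrap_support(
    g: GenotypeMatrix, labels, n_boot: int = 100, seed: int = 0
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree on Nei distances with locus-bootstrap branch support.

    Loci are resampled with replacement; support is the percentage of
    replicates whose NJ tree contains each internal bipartition of the
    full-data tree.  Supports are written onto the tree's internal node
    names as integers.
    """
    full = nei_distance(g, labels)
    tree = nj_tree(full.values, full.group_names)
    target = {p: 0 for p in _bipartitions(tree)}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        idx = rng.integers(0, g.n_loci, size=g.n_loci)
        sub = g.take_loci(idx) if len(set(idx)) == g.n_loci else _resample_loci(g, idx)
        d = nei_distance(sub, labels)
        reps = _bipartitions(nj_tree(d.values, d.group_names))
        for p in target:
            if p in reps:
                target[p] += 1
    support = {p: 100.0 * c / n_boot for p, c in target.items()}
    all_leaves = frozenset(l.name for l in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        key = frozenset({side, all_leaves - side})
        if key in support:
            node.name = str(int(round(support[key])))
    return tree, support


def _resample_loci(g: GenotypeMatrix, idx: np.ndarray) -> GenotypeMatrix:
    """take_loci with duplicate indices (bootstrap): rename repeated loci."""
    ids = []
    seen: dict[str, int] = {}
    for j in idx:
        base = g.locus_ids[j]
        seen[base] = seen.get(base, 0) + 1
        ids.append(base if seen[base] == 1 else f"{base}.b{seen[base]}")
    return GenotypeMatrix(
        list(g.sample_ids), ids, g.calls[:, idx],
        None if g.alleles is None else [g.alleles[j] for j in idx],
    )


# -- individual dendrogram -----------------------------------------------


def allele_sharing_ward(g: GenotypeMatrix) -> tuple[TreeNode, np.ndarray]:
    """Ward dendrogram of individuals on the allele-sharing distance 1 - IBS.

    Returns the dendrogram (as a rooted tree with merge-height branch
    lengths) and the distance matrix used.  Ward linkage follows the
    Ward.D2 convention (variance criterion on squared distances).
    """
    sim = ibs_matrix(g)
    if np.isnan(sim.values).any():
        raise ValueError("undefined IBS pairs; filter loci/samples upstream first")
    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    root = to_tree(z)

    def build(node) -> TreeNode:
        if node.is_leaf():
            return TreeNode(name=sim.sample_ids[node.id], length=None)
        left, right = build(node.left), build(node.right)
        for child, sub in ((node.left, left), (node.right, right)):
            h = 0.0 if child.is_leaf() else child.dist
            sub.length = node.dist - h
        return TreeNode(children=[left, right])

    return build(root), dist
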