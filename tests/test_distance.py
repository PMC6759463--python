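import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from conftest import fixed_difference_matrix
from lenspop.distance import (
    _bipartitions,
    allele_sharing_ward,
    bootstrap_support,
    multilocus_theta,
    nei_distance,
    nj_tree,
    wc_components,
    wc_fst_one_vs_rest,
    wc_fst_pairwise,
)
from lenspop.io import GenotypeMatrix
from lenspop.redundancy import ibs_matrix
from lenspop.simulate import island_spec, simulate_genotypes


# -- Weir-Cockerham ------------------------------------------------------


def test_fixed_difference_components_and_theta_one():
    """Two equal groups fixed for alternative alleles: a = 0.5, b = c = 0,
    hence theta = 1 at every locus."""
    g, labels = fixed_difference_matrix(20, 5)
    a, b, c, valid = wc_components(g, labels)
    assert valid.all()
    assert np.allclose(a, 0.5)
    assert np.allclose(b, 0.0)
    assert np.allclose(c, 0.0)
    theta, _ = multilocus_theta(g, labels)
    assert theta == 1.0


def test_identical_groups_theta_vanishes_with_sample_size():
    """Copied groups have zero among-group variance; the estimator's
    finite-sample correction leaves a small negative theta of order
    -1/(n-1) that vanishes as n grows."""
    rng = np.random.default_rng(0)
    for n in (25, 200):
        block = rng.binomial(2, 0.4, size=(n, 30)).astype(np.int8)
        calls = np.vstack([block, block])
        g = GenotypeMatrix([f"s{i}" for i in range(2 * n)],
                           [f"L{j}" for j in range(30)], calls)
        labels = ["X"] * n + ["Y"] * n
        theta, _ = multilocus_theta(g, labels)
        assert theta <= 0
        assert abs(theta) < 2.0 / (n - 1)


def test_null_theta_near_zero():
    """Two groups cut from a single panmictic population."""
    g, _ = simulate_genotypes(island_spec(1, 200, 2000, 0.2, seed=13))
    labels = ["A"] * 100 + ["B"] * 100
    theta, n_used = multilocus_theta(g, labels)
    assert abs(theta) < 0.02
    assert n_used > 1500


def test_pairwise_matrix_symmetric_zero_diagonal():
    g, truth = simulate_genotypes(island_spec(3, 25, 400, 0.25, seed=14))
    m = wc_fst_pairwise(g, truth.labels)
    assert np.allclose(m.values, m.values.T)
    assert np.all(np.diag(m.values) == 0)
    off = m.values[~np.eye(3, dtype=bool)]
    assert (off > 0.1).all()  # strongly differentiated populations


def test_one_vs_rest_flags_planted_private_allele():
    """A locus nearly fixed in the focal cluster and absent elsewhere is
    flagged above 0.8; equal frequencies are never flagged."""
    rng = np.random.default_rng(7)
    n_focal, n_rest, L = 40, 160, 50
    calls = rng.binomial(2, 0.5, size=(n_focal + n_rest, L)).astype(np.int8)
    # locus 0: p = 0.98 focal vs 0.02 rest (selfing homozygotes)
    calls[:n_focal, 0] = 2 * (rng.random(n_focal) < 0.98)
    calls[n_focal:, 0] = 2 * (rng.random(n_rest) < 0.02)
    g = GenotypeMatrix([f"s{i}" for i in range(n_focal + n_rest)],
                       [f"L{j}" for j in range(L)], calls)
    labels = ["F"] * n_focal + ["R"] * n_rest
    rep = wc_fst_one_vs_rest(g, labels)
    focal_rows = rep[rep.cluster == "F"].set_index("locus_id")
    assert bool(focal_rows.loc["L0", "above_0.8"])
    assert focal_rows.loc["L0", "enriched_allele"] == "alt"
    # remaining loci share frequencies across groups: never flagged
    assert not focal_rows.drop("L0")["above_0.8"].any()


def test_one_vs_rest_theta_bounded_by_one():
    g, labels = fixed_difference_matrix(10, 3)
    rep = wc_fst_one_vs_rest(g, labels)
    assert (rep.theta.dropna() <= 1.0).all()
    assert (rep[rep.cluster == "A"].theta == 1.0).all()


# -- Nei distance --------------------------------------------------------


def test_nei_identical_frequencies_zero():
    rng = np.random.default_rng(11)
    block = rng.binomial(2, 0.3, size=(12, 40)).astype(np.int8)
    g = GenotypeMatrix([f"s{i}" for i in range(24)],
                       [f"L{j}" for j in range(40)], np.vstack([block, block]))
    d = nei_distance(g, ["X"] * 12 + ["Y"] * 12)
    assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_nei_hand_value():
    """x = (0.9, 0.1) vs y = (0.1, 0.9): D = -ln(0.18/0.82) ~ 1.5163."""
    calls = np.zeros((20, 1), dtype=np.int8)
    calls[:9, 0] = 2   # group X: p_alt = 0.9
    calls[10, 0] = 2   # group Y: p_alt = 0.1
    g = GenotypeMatrix([f"s{i}" for i in range(20)], ["L1"], calls)
    labels = ["X"] * 10 + ["Y"] * 10
    d = nei_distance(g, labels)
    assert d.values[0, 1] == pytest.approx(-np.log(0.18 / 0.82), abs=1e-9)


def test_nei_disjoint_alleles_infinite():
    g, labels = fixed_difference_matrix(10, 2)
    d = nei_distance(g, labels)
    assert np.isinf(d.values[0, 1])


def test_nei_nonnegative_on_random_panels():
    for seed in range(3):
        g, truth = simulate_genotypes(island_spec(3, 15, 200, 0.3, seed=seed))
        d = nei_distance(g, truth.labels)
        assert (d.values >= 0).all()


# -- neighbor joining ----------------------------------------------------


def _tree_distances(tree, taxa):
    return {
        (a, b): tree.find(a).distance(tree.find(b))
        for a, b in itertools.combinations(taxa, 2)
    }


def _random_additive_matrix(rng, taxa):
    """Distances from a random binary tree with positive branch lengths."""
    graph = nx.Graph()
    nodes = list(taxa[:3])
    center = "I0"
    for t in nodes:
        graph.add_edge(t, center, w=rng.uniform(0.5, 2.0))
    next_internal = 1
    for t in taxa[3:]:
        u, v = list(graph.edges)[rng.integers(graph.number_of_edges())]
        w = graph.edges[u, v]["w"]
        graph.remove_edge(u, v)
        mid = f"I{next_internal}"
        next_internal += 1
        cut = rng.uniform(0.2, 0.8) * w
        graph.add_edge(u, mid, w=cut)
        graph.add_edge(mid, v, w=w - cut)
        graph.add_edge(mid, t, w=rng.uniform(0.5, 2.0))
    n = len(taxa)
    m = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                d = nx.shortest_path_length(graph, a, b, weight="w")
                m[i, j] = m[j, i] = d
    true_parts = set()
    leaves = frozenset(taxa)
    for u, v in graph.edges:
        g2 = graph.copy()
        g2.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(g2, u) if x in leaves)
        if 2 <= len(side) <= n - 2:
            true_parts.add(frozenset({side, frozenset(leaves - side)}))
    return m, true_parts


def _exhaustive_topologies(taxa):
    """All unrooted binary topologies as edge graphs (3 for 4 taxa, 15 for 5...)."""
    base = nx.Graph()
    for t in taxa[:3]:
        base.add_edge(t, "X0")
    trees = [base]
    for k, t in enumerate(taxa[3:], start=1):
        grown = []
        for tr in trees:
            for u, v in list(tr.edges):
                g2 = tr.copy()
                g2.remove_edge(u, v)
                mid = f"X{k}"
                g2.add_edge(u, mid)
                g2.add_edge(mid, v)
                g2.add_edge(mid, t)
                grown.append(g2)
        trees = grown
    return trees


def _topology_fit(graph, taxa, dmat):
    """Least-squares branch lengths for one topology; returns residual and
    bipartitions."""
    edges = list(graph.edges)
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        path = nx.shortest_path(graph, taxa[i], taxa[j])
        for u, v in zip(path, path[1:]):
            e = edges.index((u, v)) if (u, v) in edges else edges.index((v, u))
            A[row, e] = 1.0
        y[row] = dmat[i, j]
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(((A @ sol - y) ** 2).sum())
    leaves = frozenset(taxa)
    parts = set()
    for u, v in edges:
        g2 = graph.copy()
        g2.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(g2, u) if x in leaves)
        if 2 <= len(side) <= len(taxa) - 2:
            parts.add(frozenset({side, frozenset(leaves - side)}))
    return resid, parts


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = nj_tree(d, ["a", "b", "c"])
    got = _tree_distances(tree, ["a", "b", "c"])
    assert got[("a", "b")] == pytest.approx(3)
    assert got[("a", "c")] == pytest.approx(4)
    assert got[("b", "c")] == pytest.approx(5)


@pytest.mark.parametrize("n_taxa", [4, 5, 6])
def test_nj_recovers_additive_trees_vs_exhaustive_oracle(n_taxa):
    """On additive matrices NJ reproduces both the path distances and the
    topology that an exhaustive least-squares topology search selects."""
    rng = np.random.default_rng(n_taxa)
    taxa = [f"t{i}" for i in range(n_taxa)]
    for _ in range(3):
        dmat, true_parts = _random_additive_matrix(rng, taxa)
        tree = nj_tree(dmat, taxa)
        got = _tree_distances(tree, taxa)
        for (a, b), val in got.items():
            assert val == pytest.approx(dmat[taxa.index(a), taxa.index(b)], abs=1e-8)
        assert _bipartitions(tree) == true_parts
        fits = [_topology_fit(t, taxa, dmat) for t in _exhaustive_topologies(taxa)]
        best = min(fits, key=lambda rp: rp[0])
        assert best[0] == pytest.approx(0.0, abs=1e-12)
        assert best[1] == _bipartitions(tree)


def test_nj_rejects_asymmetric():
    with pytest.raises(ValueError):
        nj_tree(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]]), list("abc"))


# -- bootstrap -----------------------------------------------------------


def _hierarchical_panel(seed=0, n_per=20, L=1000):
    """Four populations with nested differentiation: ((A1,A2),(B1,B2))."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, L)

    def bn(base, f):
        return rng.beta(base * (1 - f) / f, (1 - base) * (1 - f) / f)

    pa, pb = bn(p, 0.25), bn(p, 0.25)
    freqs = {"A1": bn(pa, 0.08), "A2": bn(pa, 0.08),
             "B1": bn(pb, 0.08), "B2": bn(pb, 0.08)}
    rows, ids, labels = [], [], []
    for pop, fr in freqs.items():
        for i in range(n_per):
            rows.append((2 * (rng.random(L) < fr)).astype(np.int8))
            ids.append(f"{pop}_{i}")
            labels.append(pop)
    g = GenotypeMatrix(ids, [f"L{j}" for j in range(L)], np.vstack(rows))
    return g, labels


def test_bootstrap_supports_bounded_and_high_for_real_splits():
    g, labels = _hierarchical_panel(seed=3)
    tree, support = bootstrap_support(g, labels, n_boot=50, seed=1)
    assert support  # 4 taxa -> one internal bipartition
    for val in support.values():
        assert 0.0 <= val <= 100.0
        assert val >= 95.0  # the planted split is strongly supported
    part = next(iter(support))
    assert frozenset({frozenset({"A1", "A2"}), frozenset({"B1", "B2"})}) == part


def test_bootstrap_single_replicate_support_in_0_or_100():
    g, labels = _hierarchical_panel(seed=4, n_per=10, L=200)
    _, support = bootstrap_support(g, labels, n_boot=1, seed=0)
    assert set(support.values()) <= {0.0, 100.0}


# -- allele-sharing / Ward ----------------------------------------------


def test_ward_distance_is_one_minus_ibs_and_identical_samples_merge_at_zero():
    rng = np.random.default_rng(5)
    calls = rng.binomial(2, 0.4, size=(10, 60)).astype(np.int8)
    calls[1] = calls[0]  # identical pair
    g = GenotypeMatrix([f"s{i}" for i in range(10)],
                       [f"L{j}" for j in range(60)], calls)
    tree, dist = allele_sharing_ward(g)
    sim = ibs_matrix(g)
    assert np.allclose(dist, 1.0 - sim.values + np.diag(np.diag(sim.values) - 1.0))
    assert tree.find("s0").distance(tree.find("s1")) == pytest.approx(0.0)


def test_ward_recovers_planted_populations():
    g, truth = simulate_genotypes(island_spec(5, 20, 500, 0.3, seed=21))
    _, dist = allele_sharing_ward(g)
    z = linkage(squareform(dist, checks=False), method="ward")
    cut = fcluster(z, t=5, criterion="maxclust")
    assert adjusted_rand_score(truth.labels, cut) >= 0.95
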