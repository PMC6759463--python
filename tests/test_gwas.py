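import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from lenspop.gwas import bh_fdr, mixed_model_scan, mlmm_forward
from lenspop.redundancy import ibs_matrix
from lenspop.simulate import island_spec, simulate_genotypes


def _brute_force_bh(p):
    """Literal step-up definition of Benjamini-Hochberg adjusted values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * m / rank_from_top)
        q[idx] = val
        prev = val
    return q


def test_bh_hand_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
    assert np.allclose(q, 0.05)


@pytest.mark.parametrize("p", [[0.2], [1.0, 1.0, 1.0], []])
def test_bh_degenerate_inputs(p):
    q = bh_fdr(p)
    assert np.allclose(q, p)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_matches_brute_force_oracle(p):
    assert np.allclose(bh_fdr(p), _brute_force_bh(p), atol=1e-12)


def _mean_imputed(g):
    x = g.calls_float()
    mu = np.nanmean(x, axis=0)
    i, j = np.where(np.isnan(x))
    x[i, j] = mu[j]
    return x


def test_identity_kinship_equals_ols():
    """With K = I the mixed model degenerates to OLS (p-values to 1e-8)."""
    rng = np.random.default_rng(0)
    g, _ = simulate_genotypes(island_spec(2, 30, 80, 0.2, seed=5))
    y = rng.normal(0, 1, g.n_samples)
    tab, _ = mixed_model_scan(g, y, np.eye(g.n_samples))
    x = _mean_imputed(g)
    for m in range(g.n_loci):
        if x[:, m].std() == 0 or not np.isfinite(tab.p_value[m]):
            continue
        ols = sm.OLS(y, sm.add_constant(x[:, m])).fit()
        assert abs(ols.pvalues[1] - tab.p_value[m]) < 1e-8
        assert abs(ols.params[1] - tab.beta[m]) < 1e-8


def test_structured_null_type_one_error():
    """Type-I error at alpha = 0.05 under a kinship-structured null trait."""
    hits = tot = 0
    for seed in range(8):
        g, _ = simulate_genotypes(island_spec(3, 30, 400, 0.25, seed=100 + seed))
        kin = ibs_matrix(g)
        rng = np.random.default_rng(200 + seed)
        chol = np.linalg.cholesky(kin.values + 1e-6 * np.eye(g.n_samples))
        y = chol @ rng.normal(0, 1, g.n_samples) + rng.normal(0, 1, g.n_samples)
        tab, _ = mixed_model_scan(g, y, kin)
        hits += int((tab.p_value < 0.05).sum())
        tot += int(tab.p_value.notna().sum())
    assert 0.03 <= hits / tot <= 0.07


def test_planted_causal_marker_is_top_hit():
    found = 0
    for seed in range(5):
        g, _ = simulate_genotypes(island_spec(2, 90, 400, 0.2, seed=300 + seed))
        kin = ibs_matrix(g)
        rng = np.random.default_rng(seed)
        causal = 200
        x = _mean_imputed(g)[:, causal]
        chol = np.linalg.cholesky(kin.values + 1e-6 * np.eye(g.n_samples))
        y = x + chol @ rng.normal(0, 0.5, g.n_samples) + rng.normal(0, 1, g.n_samples)
        tab, _ = mixed_model_scan(g, y, kin)
        if int(tab.p_value.idxmin()) == causal:
            found += 1
    assert found >= 4


def test_reml_recovers_variance_ratio():
    """sigma2_g / sigma2_e within +/-25 percent of the simulated ratio."""
    ratios = []
    for seed in range(8):
        g, _ = simulate_genotypes(island_spec(2, 100, 500, 0.25, seed=400 + seed))
        kin = ibs_matrix(g)
        rng = np.random.default_rng(seed)
        chol = np.linalg.cholesky(kin.values + 1e-6 * np.eye(g.n_samples))
        y = chol @ rng.normal(0, 1.0, g.n_samples) + rng.normal(0, 1.0, g.n_samples)
        _, vc = mixed_model_scan(g, y, kin)
        ratios.append(vc.sigma2_g / vc.sigma2_e)
    assert abs(np.mean(ratios) - 1.0) < 0.25


def test_mlmm_pure_noise_selects_nothing():
    empty = 0
    for seed in range(6):
        g, _ = simulate_genotypes(island_spec(2, 40, 200, 0.2, seed=500 + seed))
        kin = ibs_matrix(g)
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, g.n_samples)
        res = mlmm_forward(g, y, kin, max_steps=5)
        if not res.cofactors:
            empty += 1
    assert empty >= 5


def test_mlmm_selects_two_independent_causal_markers():
    g, _ = simulate_genotypes(island_spec(2, 100, 300, 0.2, seed=600))
    kin = ibs_matrix(g)
    rng = np.random.default_rng(7)
    x = _mean_imputed(g)
    c1, c2 = 50, 250
    y = 1.2 * x[:, c1] + 1.2 * x[:, c2] + rng.normal(0, 1, g.n_samples)
    res = mlmm_forward(g, y, kin, max_steps=6)
    assert {g.locus_ids[c1], g.locus_ids[c2]} <= set(res.cofactors)


def test_correlated_traits_share_top_marker():
    """Three seed-size traits driven by one latent variable plus one causal
    marker give the same top association in all three scans."""
    g, _ = simulate_genotypes(island_spec(2, 90, 300, 0.2, seed=700))
    kin = ibs_matrix(g)
    rng = np.random.default_rng(8)
    causal = 150
    x = _mean_imputed(g)[:, causal]
    latent = 1.5 * x + rng.normal(0, 1, g.n_samples)
    tops = []
    for scale, noise in ((1.0, 0.4), (0.5, 0.2), (0.2, 0.1)):
        y = scale * latent + rng.normal(0, noise, g.n_samples)
        tab, _ = mixed_model_scan(g, y, kin)
        tops.append(int(tab.p_value.idxmin()))
    assert tops == [causal] * 3


def test_mlmm_validation_and_q_monotonicity():
    g, _ = simulate_genotypes(island_spec(2, 30, 100, 0.2, seed=800))
    kin = ibs_matrix(g)
    y = np.random.default_rng(0).normal(0, 1, g.n_samples)
    with pytest.raises(ValueError):
        mlmm_forward(g, y, kin, max_steps=0)
    tab, _ = mixed_model_scan(g, y, kin)
    sub = tab.dropna().sort_values("p_value")
    assert (np.diff(sub.q_value.to_numpy()) >= -1e-12).all()


def test_series_trait_aligned_by_sample_id():
    g, _ = simulate_genotypes(island_spec(2, 20, 60, 0.2, seed=900))
    kin = ibs_matrix(g)
    rng = np.random.default_rng(1)
    y = pd.Series(rng.normal(0, 1, g.n_samples), index=g.sample_ids)
    shuffled = y.sample(frac=1.0, random_state=2)
    t1, _ = mixed_model_scan(g, y, kin)
    t2, _ = mixed_model_scan(g, shuffled, kin)
    assert np.allclose(t1.p_value.dropna(), t2.p_value.dropna())
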