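import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lenspop.io import PhenoTable
from lenspop.pheno import (
    AnovaTable,
    cluster_tukey,
    heritability,
    rcbd_anova,
)


def _rcbd_frame(n_geno, r, geno_sd, block_effects, resid_sd, rng, mu=10.0):
    rows = []
    geno_eff = rng.normal(0, geno_sd, n_geno)
    for i in range(n_geno):
        for b in range(r):
            rows.append({
                "genotype": f"g{i}", "block": str(b + 1),
                "y": mu + geno_eff[i] + block_effects[b] + rng.normal(0, resid_sd),
            })
    return PhenoTable(pd.DataFrame(rows))


def test_balanced_anova_decomposition_exact():
    rng = np.random.default_rng(0)
    p = _rcbd_frame(30, 2, 1.0, [0.5, -0.5], 0.7, rng)
    a = rcbd_anova(p, "y")
    y = p.data["y"].to_numpy()
    ss_total = float(((y - y.mean()) ** 2).sum())
    assert a.ss_genotype + a.ss_block + a.ss_residual == pytest.approx(
        ss_total, rel=1e-9
    )
    assert a.df_genotype + a.df_block + a.df_residual == len(y) - 1


def test_anova_detects_genotype_effect_and_null_is_calibrated():
    rng = np.random.default_rng(1)
    strong = _rcbd_frame(40, 2, 2.0, [0.3, -0.3], 0.5, rng)
    assert rcbd_anova(strong, "y").p_value < 1e-6
    # null: p-values approximately uniform across seeds
    pvals = []
    for seed in range(60):
        r = np.random.default_rng(100 + seed)
        null = _rcbd_frame(25, 2, 0.0, [0.3, -0.3], 1.0, r)
        pvals.append(rcbd_anova(null, "y").p_value)
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_anova_constant_response_flagged():
    rows = [{"genotype": f"g{i}", "block": str(b), "y": 5.0}
            for i in range(3) for b in (1, 2)]
    a = rcbd_anova(PhenoTable(pd.DataFrame(rows)), "y")
    assert np.isnan(a.f_statistic)


@pytest.mark.parametrize(
    "ms_g,ms_e,r,expected",
    [
        (10.0, 2.0, 2, 0.8),   # sigma2_g = 4, H2 = 4/(4+1)
        (2.0, 2.0, 2, 0.0),    # MS_G == MS_E
        (1.0, 2.0, 2, 0.0),    # negative variance clamped
    ],
)
def test_heritability_plug_in(ms_g, ms_e, r, expected):
    a = AnovaTable("y", ms_g * 9, ms_e, ms_e * 10, 9, 1, 10,
                   np.nan, np.nan)
    h = heritability(a, r)
    assert h.h2 == pytest.approx(expected)
    assert h.clamped == (ms_g < ms_e)


def test_heritability_degenerate_ms_e_zero():
    a = AnovaTable("y", 10.0, 0.0, 0.0, 5, 1, 6, np.nan, np.nan)
    h = heritability(a, 2)
    assert h.h2 == 1.0 and h.degenerate


def _cluster_pheno(means, sd, n_per, rng):
    rows, labels = [], {}
    for c, mu in enumerate(means):
        for i in range(n_per):
            gid = f"c{c}g{i}"
            labels[gid] = f"K{c}"
            for b in (1, 2):
                rows.append({"genotype": gid, "block": str(b),
                             "y": mu + rng.normal(0, sd)})
    return PhenoTable(pd.DataFrame(rows)), labels


def test_tukey_zero_noise_all_share_one_letter():
    rng = np.random.default_rng(2)
    p, labels = _cluster_pheno([5.0, 5.0, 5.0], 1e-9, 5, rng)
    res = cluster_tukey(p, labels, "y")
    assert not res.pairwise["significant"].any()
    assert len(set(res.summary["letters"])) == 1


def test_tukey_separated_means_distinct_letters():
    """Cluster means 3.8 vs 5.6 at SD 0.3 (seed-diameter-like contrast)."""
    rng = np.random.default_rng(3)
    p, labels = _cluster_pheno([3.8, 5.6], 0.3, 20, rng)
    res = cluster_tukey(p, labels, "y")
    assert res.pairwise["significant"].all()
    letters = dict(zip(res.summary.cluster, res.summary.letters))
    assert set(letters["K0"]).isdisjoint(set(letters["K1"]))


def test_tukey_letters_consistent_with_pairwise_table():
    rng = np.random.default_rng(4)
    p, labels = _cluster_pheno([3.8, 4.5, 5.6, 4.7, 4.6], 0.5, 15, rng)
    res = cluster_tukey(p, labels, "y")
    letters = dict(zip(res.summary.cluster, res.summary.letters))
    for _, row in res.pairwise.iterrows():
        shared = set(letters[row.group1]) & set(letters[row.group2])
        if row.significant:
            assert not shared
        else:
            assert shared


def test_tukey_singleton_cluster_excluded():
    rng = np.random.default_rng(5)
    p, labels = _cluster_pheno([4.0, 5.0], 0.3, 10, rng)
    labels["lonely"] = "K9"
    extra = pd.DataFrame([{"genotype": "lonely", "block": "1", "y": 4.5},
                          {"genotype": "lonely", "block": "2", "y": 4.6}])
    p = PhenoTable(pd.concat([p.data, extra], ignore_index=True))
    res = cluster_tukey(p, labels, "y")
    assert res.excluded == ["K9"]
    assert "K9" not in set(res.summary.cluster)


def test_tukey_pvalues_match_permutation_oracle():
    """Tukey-Kramer adjusted p-values agree with a label-permutation oracle
    of the studentized-range family-wise test on a 3-group toy set."""
    rng = np.random.default_rng(6)
    groups = {"A": rng.normal(0.0, 1.0, 8), "B": rng.normal(0.8, 1.0, 8),
              "C": rng.normal(1.6, 1.0, 8)}
    rows, labels = [], {}
    for gname, vals in groups.items():
        for i, v in enumerate(vals):
            gid = f"{gname}{i}"
            labels[gid] = gname
            rows.append({"genotype": gid, "block": "1", "y": v})
            rows.append({"genotype": gid, "block": "2", "y": v})
    p = PhenoTable(pd.DataFrame(rows))
    res = cluster_tukey(p, labels, "y")

    # permutation oracle on genotype means
    means = p.genotype_means("y")
    lab = np.array([labels[g] for g in means.index])
    vals = means.to_numpy()

    def pair_stats(values, lab_arr):
        out = {}
        gs = sorted(set(lab_arr))
        ni = {g: (lab_arr == g).sum() for g in gs}
        mse = np.mean([values[lab_arr == g].var(ddof=1) for g in gs])
        for a, b in itertools.combinations(gs, 2):
            diff = abs(values[lab_arr == a].mean() - values[lab_arr == b].mean())
            se = np.sqrt(mse / 2 * (1 / ni[a] + 1 / ni[b]))
            out[(a, b)] = diff / se
        return out

    obs = pair_stats(vals, lab)
    n_perm = 4000
    exceed = {k: 0 for k in obs}
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        stats_p = pair_stats(vals, perm)
        qmax = max(stats_p.values())
        for k in obs:
            if qmax >= obs[k]:
                exceed[k] += 1
    for _, row in res.pairwise.iterrows():
        key = tuple(sorted((row.group1, row.group2)))
        p_perm = exceed[key] / n_perm
        assert abs(row.p_adj - p_perm) < 0.06  # within Monte-Carlo error
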