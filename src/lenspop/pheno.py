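"""Phenotype statistics for a randomized complete block design.

Genotypic effects per trait are tested by two-way additive ANOVA
(genotype + block, Type-II sums of squares so mildly unbalanced data are
handled), broad-sense heritability is computed on an entry-mean basis

    H^2 = sigma2_g / (sigma2_g + sigma2_e / r),  sigma2_g = (MS_G - MS_E)/r

with r replicate blocks, and cluster-level trait differences are assessed
by one-way ANOVA plus Tukey-Kramer HSD on genotype means (the analysis
unit, since cluster summaries report mean +/- SD across accessions), with
a compact letter display assembled from the nonsignificant-pair graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import PhenoTable

logger = logging.getLogger(__name__)


@dataclass
class AnovaTable:
    trait: str
    ss_genotype: float
    ss_block: float
    ss_residual: float
    df_genotype: int
    df_block: int
    df_residual: int
    f_statistic: float
    p_value: float

    @property
    def ms_genotype(self) -> float:
        return self.ss_genotype / self.df_genotype

    @property
    def ms_error(self) -> float:
        return self.ss_residual / self.df_residual if self.df_residual else np.nan


@dataclass
class HeritabilityResult:
    trait: str
    sigma2_g: float
    sigma2_e: float
    h2: float
    clamped: bool = False
    degenerate: bool = False


@dataclass
class TukeyResult:
    trait: str
    summary: pd.DataFrame        # per cluster: n, mean, sd, letters
    pairwise: pd.DataFrame       # per pair: meandiff, p_adj, significant
    excluded: list[str]


def rcbd_anova(p: PhenoTable, trait: str) -> AnovaTable:
    """Two-way additive ANOVA (genotype + block) for one trait.

    Balanced designs decompose exactly (SS_total = SS_G + SS_B + SS_E);
    unbalanced data fall back on Type-II sums of squares.  A constant
    response yields an undefined (NaN) F, flagged by a warning.
    """
    if trait not in p.traits:
        raise KeyError(f"unknown trait {trait!r}")
    df = p.data[["genotype", "block", trait]].dropna().rename(columns={trait: "y"})
    if df["genotype"].nunique() < 2 or df["block"].nunique() < 2:
        raise ValueError("need >= 2 genotypes and >= 2 blocks")
    counts = df.groupby("genotype")["block"].nunique()
    lonely = counts[counts < 2]
    if len(lonely):
        logger.warning("rcbd_anova: %d genotypes observed in a single block", len(lonely))
    model = smf.ols("y ~ C(genotype) + C(block)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    ss_g = float(tab.loc["C(genotype)", "sum_sq"])
    ss_b = float(tab.loc["C(block)", "sum_sq"])
    ss_e = float(tab.loc["Residual", "sum_sq"])
    out = AnovaTable(
        trait=trait,
        ss_genotype=ss_g,
        ss_block=ss_b,
        ss_residual=ss_e,
        df_genotype=int(tab.loc["C(genotype)", "df"]),
        df_block=int(tab.loc["C(block)", "df"]),
        df_residual=int(tab.loc["Residual", "df"]),
        f_statistic=float(tab.loc["C(genotype)", "F"]),
        p_value=float(tab.loc["C(genotype)", "PR(>F)"]),
    )
    scale = max(1.0, float(np.mean(df["y"]) ** 2)) * len(df)
    if ss_g + ss_b + ss_e < 1e-12 * scale:
        logger.warning("rcbd_anova: constant response for %s, F undefined", trait)
        out.f_statistic = np.nan
        out.p_value = np.nan
    return out


def heritability(a: AnovaTable, r: int) -> HeritabilityResult:
    """Entry-mean broad-sense heritability from the RCBD mean squares."""
    if r < 2:
        raise ValueError("need at least two replicates")
    ms_g, ms_e = a.ms_genotype, a.ms_error
    sigma2_g = (ms_g - ms_e) / r
    clamped = False
    if sigma2_g < 0:
        logger.warning("heritability: negative genotypic variance for %s clamped to 0",
                       a.trait)
        sigma2_g, clamped = 0.0, True
    if ms_e == 0:
        logger.warning("heritability: MS_E = 0 for %s, H2 degenerate at 1", a.trait)
        return HeritabilityResult(a.trait, sigma2_g, 0.0, 1.0, clamped, degenerate=True)
    h2 = sigma2_g / (sigma2_g + ms_e / r)
    return HeritabilityResult(a.trait, sigma2_g, ms_e, h2, clamped)


def _letter_display(groups: list[str], nonsig: set[frozenset]) -> dict[str, str]:
    """Greedy compact letter display: groups sharing a letter do not differ.

    Letters are built by the insert-and-absorb method on the
    nonsignificant-pair graph, so the display is independent of label
    order up to letter naming.
    """
    # maximal sets of mutually nonsignificant groups, seeded per group
    sets: list[set[str]] = []
    for grp in sorted(groups):
        block = {grp}
        for other in sorted(groups):
            if other == grp:
                continue
            if all(frozenset({other, m}) in nonsig for m in block):
                block.add(other)
        if not any(block <= s for s in sets):
            sets = [s for s in sets if not s <= block] + [block]
    # guarantee: every nonsignificant pair shares at least one set
    for pair in sorted(nonsig, key=sorted):
        if not any(pair <= s for s in sets):
            sets.append(set(pair))
    sets.sort(key=lambda s: sorted(s)[0])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, str] = {g: "" for g in groups}
    for i, s in enumerate(sets):
        for grp in sorted(s):
            letters[grp] += alphabet[i % len(alphabet)]
    return letters


def cluster_tukey(
    p: PhenoTable,
    cluster_labels: dict[str, str],
    trait: str,
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey-Kramer HSD across clusters on genotype trait means.

    ``cluster_labels`` maps genotype id to cluster; genotypes without a
    label and singleton clusters are excluded (with a warning).  Returns
    per-cluster mean +/- SD with a compact letter display plus the full
    pairwise table.
    """
    means = p.genotype_means(trait)
    labels = pd.Series({gid: cluster_labels.get(gid) for gid in means.index})
    keep = labels.notna()
    means, labels = means[keep], labels[keep]
    sizes = labels.value_counts()
    excluded = sorted(sizes[sizes < 2].index)
    if excluded:
        logger.warning("cluster_tukey: excluding singleton clusters %s", excluded)
        ok = ~labels.isin(excluded)
        means, labels = means[ok], labels[ok]
    if labels.nunique() < 2:
        raise ValueError("need at least two clusters with >= 2 genotypes")

    res = pairwise_tukeyhsd(means.to_numpy(), labels.to_numpy(), alpha=alpha)
    pair_df = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    pair_df = pair_df.rename(columns={"p-adj": "p_adj", "meandiff": "mean_diff"})
    pair_df["significant"] = res.reject

    nonsig = {
        frozenset({str(a), str(b)})
        for (a, b), rej in zip(
            zip(pair_df["group1"], pair_df["group2"]), res.reject
        )
        if not rej
    }
    groups = sorted(labels.unique())
    letters = _letter_display(groups, nonsig)
    summary = pd.DataFrame({
        "cluster": groups,
        "n": [int((labels == g).sum()) for g in groups],
        "mean": [float(means[labels == g].mean()) for g in groups],
        "sd": [float(means[labels == g].std(ddof=1)) for g in groups],
        "letters": [letters[g] for g in groups],
    })
    return TukeyResult(trait, summary, pair_df, excluded)
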