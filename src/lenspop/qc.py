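"""SNP and sample quality control, Ts/Tv summary, and LD pruning.

The filter cascade follows standard GBS practice for a selfing crop:
per-locus minor allele frequency (> 0.05), call rate (> 0.80) and
inbreeding coefficient F = 1 - H_obs/H_exp (> 0.8), all strict
inequalities, then removal of samples with call rate < 0.80.  LD pruning
is a greedy sequential scan on the squared Pearson correlation of 0/1/2
call vectors (composite genotypic r^2) with no positional window --
UNEAK-style loci carry no genomic coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    """Attrition bookkeeping for one filtering run."""

    n_loci_in: int = 0
    dropped_by_filter: dict[str, int] = field(default_factory=dict)
    n_loci_kept: int = 0
    samples_dropped: list[str] = field(default_factory=list)
    transitions: int | None = None
    transversions: int | None = None
    ts_tv_ratio: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [("input_loci", self.n_loci_in)]
        rows += [(f"dropped_{k}", v) for k, v in self.dropped_by_filter.items()]
        rows += [("kept_loci", self.n_loci_kept),
                 ("dropped_samples", len(self.samples_dropped))]
        if self.transitions is not None:
            rows += [("transitions", self.transitions),
                     ("transversions", self.transversions),
                     ("ts_tv_ratio", self.ts_tv_ratio)]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def locus_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus MAF, call rate, inbreeding coefficient and transition flag.

    MAF and heterozygosity are computed over non-missing calls only.  The
    inbreeding coefficient is F = 1 - H_obs/H_exp with H_exp = 2p(1-p);
    it is NaN (undefined) for monomorphic loci or loci with no calls.
    """
    calls = g.calls_float()
    n_obs = np.sum(~np.isnan(calls), axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(calls, axis=0) / 2.0
    # (calls == 1) is False at NaN, so divide by the non-missing count
    h_obs = np.where(n_obs > 0, (calls == 1).sum(axis=0) / np.maximum(n_obs, 1), np.nan)
    h_exp = 2.0 * p * (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(h_exp > 0, 1.0 - h_obs / h_exp, np.nan)
    maf = np.minimum(p, 1.0 - p)
    df = pd.DataFrame(
        {
            "locus_id": g.locus_ids,
            "maf": maf,
            "call_rate": n_obs / g.n_samples,
            "inbreeding_f": f,
        }
    )
    if g.alleles is not None:
        df["is_transition"] = [frozenset(a) in ({"A", "G"}, {"C", "T"}) for a in g.alleles]
    return df


def filter_loci(
    g: GenotypeMatrix,
    min_maf: float = 0.05,
    min_call_rate: float = 0.80,
    min_inbreeding: float = 0.8,
) -> tuple[GenotypeMatrix, QCReport]:
    """Keep loci with MAF, call rate and inbreeding F strictly above the
    thresholds; record per-filter attrition in application order
    (MAF, call rate, inbreeding)."""
    stats = locus_stats(g)
    report = QCReport(n_loci_in=g.n_loci)
    alive = np.ones(g.n_loci, dtype=bool)
    for name, passed in (
        ("maf", stats["maf"].to_numpy() > min_maf),
        ("call_rate", stats["call_rate"].to_numpy() > min_call_rate),
        # NaN F (monomorphic / no calls) fails the filter
        ("inbreeding_f", np.nan_to_num(stats["inbreeding_f"].to_numpy(), nan=-np.inf)
         > min_inbreeding),
    ):
        dropped = alive & ~passed
        report.dropped_by_filter[name] = int(dropped.sum())
        alive &= passed
    report.n_loci_kept = int(alive.sum())
    if report.n_loci_kept == 0:
        raise QCError("all loci removed by the filter cascade")
    return g.take_loci(np.flatnonzero(alive)), report


def filter_samples(
    g: GenotypeMatrix, min_call_rate: float = 0.80
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples with call rate below ``min_call_rate`` (strict <)."""
    rate = g.sample_call_rate()
    keep = rate >= min_call_rate
    dropped = [s for s, k in zip(g.sample_ids, keep) if not k]
    if not keep.any():
        raise QCError("all samples removed by the call-rate filter")
    if dropped:
        logger.info("filter_samples: dropped %d samples: %s", len(dropped), dropped)
    return g.take_samples(np.flatnonzero(keep)), dropped


def ts_tv(g: GenotypeMatrix) -> tuple[int, int, float | None]:
    """Transition / transversion counts and their ratio (None if no
    transversions).  Transitions are the allele pairs {A,G} and {C,T}."""
    if g.alleles is None:
        raise QCError("allele letters unavailable; cannot classify substitutions")
    ts = sum(frozenset(a) in ({"A", "G"}, {"C", "T"}) for a in g.alleles)
    tv = g.n_loci - ts
    ratio = round(ts / tv, 2) if tv else None
    if ratio is None:
        logger.warning("ts_tv: zero transversions, ratio undefined")
    return ts, tv, ratio


def qc_cascade(
    g: GenotypeMatrix,
    min_maf: float = 0.05,
    min_call_rate: float = 0.80,
    min_inbreeding: float = 0.8,
    sample_call_rate: float = 0.80,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC: locus filters, then sample call-rate exclusion, then Ts/Tv."""
    g2, report = filter_loci(g, min_maf, min_call_rate, min_inbreeding)
    g3, dropped = filter_samples(g2, sample_call_rate)
    report.samples_dropped = dropped
    if g3.alleles is not None:
        report.transitions, report.transversions, report.ts_tv_ratio = ts_tv(g3)
    return g3, report


def _r2_against(x: np.ndarray, kept: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared Pearson r of one locus against many.

    ``x`` is (n,), ``kept`` is (n, m); NaN marks missing.  Loci with zero
    variance over the complete pairs contribute r^2 = 0.
    """
    vx = ~np.isnan(x)
    vk = ~np.isnan(kept)
    both = vx[:, None] & vk
    n = both.sum(axis=0)
    xs = np.where(both, x[:, None], 0.0)
    ks = np.where(both, kept, 0.0)
    sx, sk = xs.sum(axis=0), ks.sum(axis=0)
    sxx = (xs * xs).sum(axis=0)
    skk = (ks * ks).sum(axis=0)
    sxk = (xs * ks).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxk - sx * sk / np.maximum(n, 1)
        vxx = sxx - sx * sx / np.maximum(n, 1)
        vkk = skk - sk * sk / np.maximum(n, 1)
        r2 = np.where((n > 1) & (vxx > 1e-12) & (vkk > 1e-12),
                      cov * cov / (vxx * vkk), 0.0)
    return r2


def ld_prune(
    g: GenotypeMatrix, r2_max: float = 0.5
) -> tuple[GenotypeMatrix, dict]:
    """Greedy sequential LD pruning in locus (file) order.

    A locus is dropped when its r^2 with any previously kept locus is
    >= ``r2_max`` (so the kept set satisfies r^2 < r2_max pairwise against
    the scan order).  Ties resolve by keeping the earlier locus.
    """
    if g.n_loci < 2:
        raise QCError("ld_prune needs at least two loci")
    calls = g.calls_float()
    kept_idx: list[int] = [0]
    n_pairs = 0
    for j in range(1, g.n_loci):
        kept_block = calls[:, kept_idx]
        r2 = _r2_against(calls[:, j], kept_block)
        n_pairs += len(kept_idx)
        if not (r2 >= r2_max).any():
            kept_idx.append(j)
    report = {
        "n_in": g.n_loci,
        "n_kept": len(kept_idx),
        "n_dropped": g.n_loci - len(kept_idx),
        "pairs_evaluated": n_pairs,
        "r2_max": r2_max,
    }
    return g.take_loci(kept_idx), report
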