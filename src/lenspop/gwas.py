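"""Kinship mixed-model genome-wide association with multi-locus forward
selection.

The model is y = X b + u + e with u ~ N(0, sigma2_g K) for a sample x
sample IBS kinship matrix K and e ~ N(0, sigma2_e I).  Variance
components are estimated once per cofactor set by REML on the spectral
decomposition of K (a one-dimensional profile search over the variance
ratio delta = sigma2_e / sigma2_g); every marker is then tested by
generalized least squares with the fitted covariance (Wald t test).
Forward selection adds the best marker as a fixed cofactor while its
Benjamini-Hochberg q-value stays below the FDR level, re-estimating the
variance components at each step.

With K = I the scan reduces exactly to ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .io import GenotypeMatrix
from .redundancy import SimilarityMatrix

logger = logging.getLogger(__name__)


def bh_fdr(p: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonized)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float

    @property
    def delta(self) -> float:
        return self.sigma2_e / self.sigma2_g if self.sigma2_g > 0 else np.inf


@dataclass
class GwasResult:
    scan: pd.DataFrame                     # final scan: beta, se, p, q per marker
    cofactors: list[str] = field(default_factory=list)
    steps: list[pd.DataFrame] = field(default_factory=list)
    variance_components: list[VarianceComponents] = field(default_factory=list)
    kinship_id: str = "ibs"


def _prepare_kinship(k: np.ndarray) -> np.ndarray:
    """Symmetrize and, if needed, jitter the kinship to positive semidefinite."""
    k = np.asarray(k, dtype=float)
    k = (k + k.T) / 2.0
    w = np.linalg.eigvalsh(k)
    if w.min() < -1e-8:
        jitter = -w.min() + 1e-8
        logger.warning("kinship not PSD (min eig %.3g); adding %.3g to diagonal",
                       w.min(), jitter)
        k = k + jitter * np.eye(k.shape[0])
    return k


def _reml_delta(y_r: np.ndarray, x_r: np.ndarray, lam: np.ndarray) -> tuple[float, VarianceComponents]:
    """Profile-REML over the variance ratio delta on rotated data.

    ``y_r``/``x_r`` are U' y and U' X for the kinship eigenvectors U and
    eigenvalues ``lam``.  Returns (delta, variance components).
    """
    n, q = x_r.shape

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = lam + delta
        xw = x_r / w[:, None]
        xtx = x_r.T @ xw
        try:
            beta = np.linalg.solve(xtx, xw.T @ y_r)
        except np.linalg.LinAlgError:
            return np.inf
        resid = y_r - x_r @ beta
        rss = float(resid @ (resid / w))
        if rss <= 0:
            return np.inf
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf
        ll = -0.5 * ((n - q) * np.log(rss) + np.log(w).sum() + logdet_xtx)
        return -ll

    grid = np.linspace(-10.0, 10.0, 41)
    vals = [neg_reml(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    delta = float(np.exp(res.x))
    w = lam + delta
    xw = x_r / w[:, None]
    beta = np.linalg.solve(x_r.T @ xw, xw.T @ y_r)
    resid = y_r - x_r @ beta
    sigma2_g = float(resid @ (resid / w)) / (n - q)
    return delta, VarianceComponents(sigma2_g=sigma2_g, sigma2_e=sigma2_g * delta)


def _marker_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Markers as mean-imputed allele-count columns."""
    x = g.calls_float()
    mu = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(mu, idx[1])
    return x


def mixed_model_scan(
    g: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    kinship: SimilarityMatrix | np.ndarray,
    cofactors: list[str] | None = None,
) -> tuple[pd.DataFrame, VarianceComponents]:
    """Single-marker mixed-model scan (EMMAX-style).

    ``y`` holds one value per genotype (indexable by sample id when a
    Series).  Markers collinear with the intercept or cofactors are
    skipped (NaN statistics, logged).  Returns the per-marker table and
    the variance components of the null (cofactor-only) model.
    """
    if isinstance(kinship, SimilarityMatrix):
        k_ids = kinship.sample_ids
        k_vals = kinship.values
    else:
        k_ids = list(g.sample_ids)
        k_vals = np.asarray(kinship, dtype=float)

    if isinstance(y, pd.Series):
        sample_ids = [s for s in g.sample_ids if s in y.index and np.isfinite(y[s])]
        y_vec = y.loc[sample_ids].to_numpy(dtype=float)
    else:
        y_vec = np.asarray(y, dtype=float)
        if len(y_vec) != g.n_samples:
            raise ValueError("y length must match the genotype matrix")
        sample_ids = list(g.sample_ids)

    g_idx = [g.sample_ids.index(s) for s in sample_ids]
    k_idx = [k_ids.index(s) for s in sample_ids]
    gsub = g.take_samples(g_idx)
    k = _prepare_kinship(k_vals[np.ix_(k_idx, k_idx)])

    lam, u = np.linalg.eigh(k)
    lam = np.clip(lam, 0.0, None)
    markers = _marker_matrix(gsub)
    n = len(sample_ids)

    cofactors = list(cofactors or [])
    x_cols = [np.ones(n)]
    for c in cofactors:
        x_cols.append(markers[:, gsub.locus_ids.index(c)])
    x0 = np.column_stack(x_cols)

    y_r = u.T @ y_vec
    x0_r = u.T @ x0
    delta, vc = _reml_delta(y_r, x0_r, lam)
    w = lam + delta
    m_r = u.T @ markers

    q0 = x0.shape[1]
    beta_out = np.full(gsub.n_loci, np.nan)
    se_out = np.full(gsub.n_loci, np.nan)
    p_out = np.full(gsub.n_loci, np.nan)
    for j in range(gsub.n_loci):
        if gsub.locus_ids[j] in cofactors:
            continue
        xj = np.column_stack([x0_r, m_r[:, j]])
        xw = xj / w[:, None]
        xtx = xj.T @ xw
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            logger.info("marker %s collinear with cofactors; skipped", gsub.locus_ids[j])
            continue
        if np.linalg.cond(xtx) > 1e10:
            logger.info("marker %s collinear with cofactors; skipped", gsub.locus_ids[j])
            continue
        beta = xtx_inv @ (xw.T @ y_r)
        resid = y_r - xj @ beta
        dof = n - (q0 + 1)
        sigma2 = float(resid @ (resid / w)) / dof
        se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
        t = beta[-1] / se
        beta_out[j] = beta[-1]
        se_out[j] = se
        p_out[j] = 2.0 * stats.t.sf(abs(t), dof)
    table = pd.DataFrame({
        "locus_id": gsub.locus_ids,
        "beta": beta_out,
        "se": se_out,
        "p_value": p_out,
        "q_value": bh_fdr(p_out),
    })
    return table, vc


def mlmm_forward(
    g: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    kinship: SimilarityMatrix | np.ndarray,
    max_steps: int = 10,
    fdr: float = 0.05,
) -> GwasResult:
    """Multi-locus mixed model: forward inclusion of significant markers.

    At each step the scan is BH-adjusted; if the best marker's q-value is
    below ``fdr`` it joins the fixed cofactors and the variance components
    are re-estimated.  Stops when nothing passes or ``max_steps`` is hit.
    The reported scan is the last one (markers tested given the final
    cofactor set).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    cofactors: list[str] = []
    result = GwasResult(scan=pd.DataFrame(), cofactors=cofactors)
    for _ in range(max_steps):
        table, vc = mixed_model_scan(g, y, kinship, cofactors)
        result.steps.append(table)
        result.variance_components.append(vc)
        result.scan = table
        valid = table.dropna(subset=["q_value"])
        if valid.empty:
            break
        best = valid.loc[valid["p_value"].idxmin()]
        if best["q_value"] < fdr:
            cofactors.append(str(best["locus_id"]))
        else:
            break
    result.cofactors = cofactors
    return result
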