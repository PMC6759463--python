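"""Population-structure inference.

Three complementary routes:

* nonparametric -- per-locus mean imputation, centre-and-scale, PCA, then
  k-means over a k range with model selection by the k-means BIC
  ``n ln(WSS/n) + k ln(n)`` on the retained PC scores;
* DAPC -- linear discriminant axes fitted on PCA scores, with the number
  of retained PCs chosen by stratified cross-validated assignment error;
* parametric -- the admixture model: each individual i has ancestry
  proportions q_i over K clusters with per-cluster allele frequencies
  f_k, and the binomial log-likelihood

      l(Q, F) = sum_il [ g_il ln(sum_k q_ik f_kl)
                         + (2 - g_il) ln(sum_k q_ik (1 - f_kl)) ]

  is maximized by EM with multiplicative updates over non-missing calls,
  best of several random restarts.  Run-to-run log-likelihood spread over
  a K range feeds the Evanno ΔK cluster-number diagnostic, and samples
  are assigned to the argmax cluster only when max q exceeds a membership
  floor (default 0.6), otherwise labelled admixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

ADMIXED = "admixed"


def impute_scaled_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Calls with per-locus mean imputation, then centred and scaled.

    Only the multivariate stages (PCA, k-means, DAPC) use this; likelihood
    methods handle missing calls exactly.
    """
    x = g.calls_float()
    mu = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(mu, idx[1])
    x -= mu
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _pca_scores(x: np.ndarray, pc_variance: float, max_pcs: int | None = None):
    pca = PCA(n_components=min(x.shape) - 1, svd_solver="full")
    scores = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_pc = int(np.searchsorted(cum, pc_variance) + 1)
    if max_pcs is not None:
        n_pc = min(n_pc, max_pcs)
    return scores[:, :n_pc], pca, n_pc


@dataclass
class ClusterScan:
    """k-means sweep with BIC model selection."""

    k_values: list[int]
    bic: list[float]
    wss: list[float]
    assignments: dict[int, np.ndarray]
    n_pcs: int
    k_selected: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "wss": self.wss, "bic": self.bic})


def find_clusters(
    g: GenotypeMatrix,
    k_max: int = 40,
    pc_variance: float = 0.95,
    n_starts: int = 10,
    seed: int = 0,
) -> ClusterScan:
    """k-means over k = 1..k_max on PCA scores; selects the BIC minimum."""
    x = impute_scaled_matrix(g)
    n = x.shape[0]
    if k_max >= n:
        logger.warning("find_clusters: k_max %d >= n samples %d, truncating", k_max, n)
        k_max = n - 1
    scores, _, n_pc = _pca_scores(x, pc_variance)
    k_values, bic, wss, assignments = [], [], [], {}
    for k in range(1, k_max + 1):
        if k == 1:
            labels = np.zeros(n, dtype=int)
            w = float(((scores - scores.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
            labels = km.fit_predict(scores)
            w = float(km.inertia_)
        k_values.append(k)
        wss.append(w)
        bic.append(n * np.log(w / n) + k * np.log(n))
        assignments[k] = labels + 1
    k_selected = int(np.array(k_values)[int(np.argmin(bic))])
    return ClusterScan(k_values, bic, wss, assignments, n_pc, k_selected)


@dataclass
class DapcModel:
    n_pcs: int
    xval_pc_grid: list[int]
    xval_error: list[float]
    scores: np.ndarray             # per-sample discriminant scores
    centroids: np.ndarray          # per-group centroids in discriminant space
    group_names: list[str]
    locus_loadings: np.ndarray     # discriminant axes composed back onto loci


def dapc(
    g: GenotypeMatrix,
    groups: np.ndarray | list,
    xval_folds: int = 5,
    pc_grid: list[int] | None = None,
    seed: int = 0,
) -> DapcModel:
    """Discriminant analysis of principal components.

    The retained PC count is chosen by stratified cross-validation: for
    each candidate, LDA axes are trained on the training folds and the
    held-out assignment error recorded; the candidate with the lowest mean
    error wins (ties to fewer PCs).  The final model is refitted on all
    data.
    """
    groups = np.asarray(groups)
    names, y = np.unique(groups, return_inverse=True)
    if len(names) < 2:
        raise ValueError("DAPC needs at least two groups")
    x = impute_scaled_matrix(g)
    full_scores, pca, _ = _pca_scores(x, 1.0)
    max_pc = full_scores.shape[1]
    if pc_grid is None:
        # candidates start at K-1 so the final model can carry K-1 axes
        lo = max(2, len(names) - 1)
        pc_grid = sorted({max(lo, round(p))
                          for p in np.linspace(lo, max_pc * 0.9, 8)})
    pc_grid = [p for p in pc_grid if 1 <= p <= max_pc]

    min_group = np.bincount(y).min()
    folds = min(xval_folds, min_group)
    if folds < xval_folds:
        logger.warning("dapc: smallest group has %d samples, reducing folds to %d",
                       min_group, folds)
    if folds < 2:
        raise ValueError("smallest group too small for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = []
    for n_pc in pc_grid:
        errs = []
        for tr, te in skf.split(full_scores, y):
            lda = LinearDiscriminantAnalysis()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lda.fit(full_scores[tr, :n_pc], y[tr])
            errs.append(1.0 - float(np.mean(lda.predict(full_scores[te, :n_pc]) == y[te])))
        errors.append(float(np.mean(errs)))
    best_pc = pc_grid[int(np.argmin(errors))]

    lda = LinearDiscriminantAnalysis()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda.fit(full_scores[:, :best_pc], y)
    disc = full_scores[:, :best_pc] @ lda.scalings_
    centroids = np.vstack([disc[y == k].mean(axis=0) for k in range(len(names))])
    locus_loadings = pca.components_[:best_pc].T @ lda.scalings_
    return DapcModel(
        n_pcs=best_pc,
        xval_pc_grid=list(pc_grid),
        xval_error=errors,
        scores=disc,
        centroids=centroids,
        group_names=[str(n) for n in names],
        locus_loadings=locus_loadings,
    )


@dataclass
class AdmixtureFit:
    K: int
    q: np.ndarray               # (n, K), rows sum to 1
    f: np.ndarray               # (K, L) alternate-allele frequencies
    log_likelihood: float
    n_iter: int
    run: int
    ll_path: list[float] = field(default_factory=list, repr=False)


_F_EPS = 1e-6


def _admixture_loglik(gcalls, mask, q, f) -> float:
    a1 = q @ f
    a0 = q @ (1.0 - f)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = gcalls * np.log(a1) + (2.0 - gcalls) * np.log(a0)
    return float(ll[mask].sum())


def admixture_em(
    g: GenotypeMatrix,
    K: int,
    n_runs: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-4,
    seed: int = 0,
) -> tuple[AdmixtureFit, list[AdmixtureFit]]:
    """Maximum-likelihood admixture fit by EM, best of ``n_runs`` restarts.

    Missing calls are skipped exactly.  The log-likelihood is checked to be
    non-decreasing at every iteration; convergence when the improvement
    drops below ``tol``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > g.n_samples:
        raise ValueError("K exceeds the number of samples")
    calls = g.calls_float()
    mask = ~np.isnan(calls)
    gc = np.nan_to_num(calls)
    n, L = gc.shape
    n_obs = mask.sum(axis=1).astype(float)  # loci observed per sample

    if K == 1:
        with np.errstate(invalid="ignore"):
            f = (np.nansum(calls, axis=0) / (2.0 * mask.sum(axis=0)))[None, :]
        f = np.clip(np.nan_to_num(f, nan=0.5), _F_EPS, 1 - _F_EPS)
        q = np.ones((n, 1))
        fit = AdmixtureFit(1, q, f, _admixture_loglik(gc, mask, q, f), 0, 0)
        # every restart converges to the same closed form at K = 1
        return fit, [fit] * n_runs

    rng = np.random.default_rng(seed)
    obs_freq = np.clip(
        np.nan_to_num(np.nansum(calls, axis=0) / (2.0 * np.maximum(mask.sum(axis=0), 1)),
                      nan=0.5),
        0.05, 0.95,
    )
    runs: list[AdmixtureFit] = []
    for run in range(n_runs):
        q = rng.dirichlet(np.ones(K), size=n)
        f = np.clip(obs_freq[None, :] + rng.normal(0, 0.1, size=(K, L)),
                    _F_EPS, 1 - _F_EPS)
        ll_prev = -np.inf
        ll_path = []
        for it in range(1, max_iter + 1):
            a1 = q @ f
            a0 = q @ (1.0 - f)
            with np.errstate(divide="ignore", invalid="ignore"):
                r1 = np.where(mask, gc / a1, 0.0)
                r0 = np.where(mask, (2.0 - gc) / a0, 0.0)
            f_num = f * (q.T @ r1)
            f_den = f_num + (1.0 - f) * (q.T @ r0)
            q_new = q * (r1 @ f.T + r0 @ (1.0 - f).T)
            q = q_new / (2.0 * n_obs[:, None])
            q /= q.sum(axis=1, keepdims=True)  # guard tiny numeric drift
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.clip(np.where(f_den > 0, f_num / f_den, 0.5),
                            _F_EPS, 1 - _F_EPS)
            ll = _admixture_loglik(gc, mask, q, f)
            if ll < ll_prev - 1e-6 * max(1.0, abs(ll_prev)):
                raise AssertionError(
                    f"EM log-likelihood decreased: {ll_prev} -> {ll}"
                )
            ll_path.append(ll)
            if ll - ll_prev < tol:
                break
            ll_prev = ll
        runs.append(AdmixtureFit(K, q, f, ll_path[-1], len(ll_path), run, ll_path))
    best = max(runs, key=lambda r: r.log_likelihood)
    return best, runs


@dataclass
class DeltaKTable:
    k_values: list[int]
    mean_ll: list[float]
    sd_ll: list[float]
    delta_k: list[float]        # NaN at boundary / undefined K
    k_best: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.k_values, "mean_LL": self.mean_ll,
                             "sd_LL": self.sd_ll, "delta_K": self.delta_k})


def evanno_delta_k(run_ll: dict[int, list[float]]) -> DeltaKTable:
    """Evanno ΔK from per-K, per-run log-likelihoods.

    ΔK(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd_runs(L(K)), with L the mean
    over runs; defined only for interior K of a contiguous range.
    """
    ks = sorted(run_ll)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need a contiguous K range of length >= 3")
    for k in ks:
        if len(run_ll[k]) < 2:
            raise ValueError(f"need >= 2 runs per K (K={k})")
    mean_ll = [float(np.mean(run_ll[k])) for k in ks]
    sd_ll = [float(np.std(run_ll[k], ddof=1)) for k in ks]
    delta = [np.nan] * len(ks)
    for i in range(1, len(ks) - 1):
        second = abs(mean_ll[i + 1] - 2 * mean_ll[i] + mean_ll[i - 1])
        if sd_ll[i] == 0:
            logger.warning("evanno_delta_k: sd=0 at K=%d, ΔK undefined", ks[i])
            continue
        delta[i] = second / sd_ll[i]
    finite = [(d, k) for d, k in zip(delta, ks) if np.isfinite(d)]
    k_best = max(finite)[1] if finite else None
    return DeltaKTable(ks, mean_ll, sd_ll, delta, k_best)


def assign_membership(fit: AdmixtureFit, q_min: float = 0.6) -> list[str]:
    """Cluster label per sample: argmax_k q_ik when max q > q_min (strict),
    otherwise "admixed"."""
    labels = []
    for row in fit.q:
        k = int(np.argmax(row))
        labels.append(f"C{k + 1}" if row[k] > q_min else ADMIXED)
    return labels
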