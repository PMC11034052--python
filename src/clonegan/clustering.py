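"""Gaussian-mixture clustering of latent embeddings with BIC model selection.

Full-covariance GMMs are fitted by EM (k-means initialization, 5 restarts,
1e-4 tolerance on the mean log-likelihood) for K = 1, 2, 3, ...; each fit is
scored by BIC = p * ln(n) - 2 * logL.  The scan stops once the running
minimum BIC has gone unimproved for more than ``patience`` consecutive K,
and any solution whose hard assignment contains a cluster of fewer than
``min_cluster_size`` cells is flagged invalid and excluded from the argmin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .model import LatentEmbedding

REG_COVAR = 1e-6


@dataclass
class GMMFit:
    K: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    n_params: int
    converged: bool
    seed: int
    ll_trace: list[float] = field(default_factory=list)

    def responsibilities(self, Z: np.ndarray) -> np.ndarray:
        log_r = _log_weighted_densities(
            Z, self.weights, self.means, self.covariances
        )
        return np.exp(log_r - logsumexp(log_r, axis=1, keepdims=True))

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return np.argmax(
            _log_weighted_densities(Z, self.weights, self.means, self.covariances),
            axis=1,
        )


@dataclass
class ClusterResult:
    labels: np.ndarray
    K_selected: int
    bic_trace: list[tuple[int, float, bool]]
    min_cluster_size: int
    cell_ids: list[str] = field(default_factory=list)
    fit: GMMFit | None = None


def _log_weighted_densities(Z, weights, means, covs) -> np.ndarray:
    """n x K matrix of log(w_k) + log N(z | mu_k, Sigma_k), batched over K."""
    n, d = Z.shape
    covs = np.asarray(covs).reshape(-1, d, d)
    chol = np.linalg.cholesky(covs)                      # (K, d, d)
    diff = Z[None, :, :] - np.asarray(means)[:, None, :]  # (K, n, d)
    sol = np.linalg.solve(chol, diff.transpose(0, 2, 1))  # (K, d, n)
    maha = np.einsum("kdn,kdn->kn", sol, sol)
    log_det = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
    log_pdf = -0.5 * (d * np.log(2.0 * np.pi) + log_det[:, None] + maha)
    return (np.log(np.maximum(weights, 1e-300))[:, None] + log_pdf).T


def _em_once(
    Z: np.ndarray,
    K: int,
    seed: int,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> GMMFit | None:
    n, d = Z.shape
    if K == 1:
        means = Z.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(Z)
        means = km.cluster_centers_
    weights = np.full(K, 1.0 / K)
    base_cov = np.cov(Z.T, ddof=0).reshape(d, d) + REG_COVAR * np.eye(d)
    covs = np.stack([base_cov.copy() for _ in range(K)])

    ll_trace: list[float] = []
    prev_mean_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # E-step
        try:
            log_r = _log_weighted_densities(Z, weights, means, covs)
        except np.linalg.LinAlgError:
            return None
        m = log_r.max(axis=1, keepdims=True)
        log_norm = m + np.log(np.exp(log_r - m).sum(axis=1, keepdims=True))
        resp = np.exp(log_r - log_norm)
        ll = float(log_norm.sum())
        ll_trace.append(ll)
        # M-step
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp.T @ Z) / nk[:, None]
        diff = Z[None, :, :] - means[:, None, :]          # (K, n, d)
        wdiff = resp.T[:, :, None] * diff
        covs = np.einsum("knd,kne->kde", wdiff, diff) / nk[:, None, None]
        covs += REG_COVAR * np.eye(d)
        mean_ll = ll / n
        if abs(mean_ll - prev_mean_ll) < tol:
            converged = True
            break
        prev_mean_ll = mean_ll

    try:
        final_ll = float(
            logsumexp(_log_weighted_densities(Z, weights, means, covs), axis=1).sum()
        )
    except np.linalg.LinAlgError:
        return None
    n_params = K * d + K * d * (d + 1) // 2 + (K - 1)
    return GMMFit(
        K=K,
        weights=weights,
        means=means,
        covariances=covs,
        log_likelihood=final_ll,
        n_params=n_params,
        converged=converged,
        seed=seed,
        ll_trace=ll_trace,
    )


def fit_gmm(
    Z: LatentEmbedding | np.ndarray,
    K: int,
    seed: int,
    n_restarts: int = 5,
) -> GMMFit:
    """Fit a full-covariance K-component GMM by EM, keeping the best of
    ``n_restarts`` differently-initialized runs."""
    Zm = Z.z_matrix if isinstance(Z, LatentEmbedding) else np.asarray(Z, float)
    if Zm.ndim != 2:
        raise ValueError("embedding must be 2-dimensional")
    n = Zm.shape[0]
    if not (1 <= K <= n):
        raise ValueError(f"need 1 <= K <= n, got K={K}, n={n}")
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31 - 1)
    best: GMMFit | None = None
    for s in sub_seeds:
        fit = _em_once(Zm, K, int(s))
        if fit is None:
            continue
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if best is None:
        raise np.linalg.LinAlgError(
            f"all EM restarts failed with singular covariances at K={K}"
        )
    return best


def bic_score(fit: GMMFit, n: int) -> float:
    """BIC = p * ln(n) - 2 * logL; smaller is better."""
    if n < 1:
        raise ValueError("n must be positive")
    return float(fit.n_params * np.log(n) - 2.0 * fit.log_likelihood)


def select_clusters(
    Z: LatentEmbedding | np.ndarray,
    min_cluster_size: int = 3,
    patience: int = 10,
    seed: int = 0,
    max_K: int | None = None,
    n_restarts: int = 5,
) -> ClusterResult:
    """Scan K upward, score by BIC, and return the best valid clustering.

    K starts at 1 and increases by one while the running minimum BIC keeps
    improving; the scan stops once it has gone unimproved for more than
    ``patience`` consecutive values of K (or at the hard cap).  A solution
    is valid only if every hard-assigned cluster has at least
    ``min_cluster_size`` cells; invalid solutions stay in the trace but are
    excluded from the argmin.  If no valid solution exists the K=1 fit is
    returned with a warning.
    """
    Zm = Z.z_matrix if isinstance(Z, LatentEmbedding) else np.asarray(Z, float)
    cell_ids = Z.cell_ids if isinstance(Z, LatentEmbedding) else [
        str(i) for i in range(Zm.shape[0])
    ]
    n = Zm.shape[0]
    if n < min_cluster_size:
        raise ValueError(f"need at least {min_cluster_size} cells, got {n}")
    cap = max_K if max_K is not None else min(50, n // max(min_cluster_size, 1))
    cap = max(cap, 1)

    scan_seeds = np.random.SeedSequence(seed).generate_state(cap) % (2**31 - 1)
    trace: list[tuple[int, float, bool]] = []
    fits: dict[int, GMMFit] = {}
    best_bic = np.inf
    best_valid_bic = np.inf
    best_valid_K: int | None = None
    stall = 0
    for K in range(1, cap + 1):
        try:
            fit = fit_gmm(Zm, K, int(scan_seeds[K - 1]), n_restarts=n_restarts)
        except np.linalg.LinAlgError:
            trace.append((K, float("inf"), False))
            stall += 1
            if stall > patience:
                break
            continue
        bic = bic_score(fit, n)
        labels = fit.predict(Zm)
        sizes = np.bincount(labels, minlength=K)
        valid = bool(np.all(sizes >= min_cluster_size))
        trace.append((K, bic, valid))
        fits[K] = fit
        if valid and bic < best_valid_bic:
            best_valid_bic = bic
            best_valid_K = K
        if bic < best_bic:
            best_bic = bic
            stall = 0
        else:
            stall += 1
        if stall > patience:
            break

    if best_valid_K is None:
        warnings.warn(
            "no valid clustering found at any K; falling back to K=1",
            stacklevel=2,
        )
        best_valid_K = 1
        if 1 not in fits:
            fits[1] = fit_gmm(Zm, 1, int(scan_seeds[0]), n_restarts=1)
    fit = fits[best_valid_K]
    return ClusterResult(
        labels=fit.predict(Zm),
        K_selected=best_valid_K,
        bic_trace=trace,
        min_cluster_size=min_cluster_size,
        cell_ids=list(cell_ids),
        fit=fit,
    )
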