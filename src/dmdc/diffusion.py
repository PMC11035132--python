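"""Diffusion operator on the delay-embedded point cloud and its spectrum.

The construction follows the self-tuning diffusion-map recipe:

1. k-nearest-neighbor distances (k = 32 by default) give each point a local
   bandwidth ``sigma_i`` -- the distance to its k-th neighbor, floored at the
   first *distinct* neighbor so exactly periodic trajectories (whose embedded
   points repeat to machine precision) keep a well-defined scale.
2. Gaussian affinities ``w_ij = exp(-||x_i - x_j||^2 / (sigma_i sigma_j))``
   are kept out to ``2 sqrt(sigma_i sigma_j)`` (where the kernel has fallen
   to e^-4) so the truncated kernel's diffusion time stays close to the
   nominal ``sigma^2 / 4``; the symmetrized kNN edges are always kept.
3. Density normalization with exponent ``alpha = 1`` (the Laplace-Beltrami
   limit) removes sampling-density bias, then row-stochastic normalization
   yields the Markov operator.
4. The top eigenpairs come from the symmetric conjugate form (real spectrum
   guaranteed); heat-semigroup inversion ``lambda = -log(mu) / epsilon`` with
   ``epsilon = median(sigma^2) / 4`` maps diffusion eigenvalues onto
   Laplacian eigenvalues in squared embedding units.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spl
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "DiffusionConfig",
    "DiffusionSpectrum",
    "DiffusionMap",
    "build_diffusion_operator",
    "eigendecompose",
    "GraphConnectivityError",
]

#: hard cap on the per-point neighbor search when extending kernel support
K_SEARCH_MAX = 512


class GraphConnectivityError(RuntimeError):
    """The affinity graph splits into several components."""


@dataclasses.dataclass(frozen=True)
class DiffusionConfig:
    """Tunables of the diffusion operator."""

    k_neighbors: int = 32
    n_eigenpairs: int = 101
    density_alpha: float = 1.0
    eig_tol: float = 1e-10

    def validate(self, n_points: int) -> None:
        if self.k_neighbors < 1:
            raise ValueError(f"k_neighbors must be >= 1, got {self.k_neighbors}")
        if self.k_neighbors >= n_points:
            raise ValueError(
                f"k_neighbors={self.k_neighbors} must be < n_points={n_points}"
            )
        if self.n_eigenpairs > n_points:
            raise ValueError(
                f"n_eigenpairs={self.n_eigenpairs} exceeds n_points={n_points}"
            )


@dataclasses.dataclass
class DiffusionSpectrum:
    """Ordered eigenpairs of the diffusion operator plus kernel bookkeeping.

    ``eigenvalues`` are the Markov-operator eigenvalues in descending order
    (the leading one equals 1 with a constant eigenvector);
    ``laplacian_eigenvalues`` are the nontrivial eigenvalues mapped through
    ``-log(mu)/epsilon``, nondecreasing, with the trivial pair removed.
    ``epsilon`` is the kernel's heat time, ``median(sigma_i^2)/4``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    epsilon: float

    @property
    def laplacian_eigenvalues(self) -> np.ndarray:
        mu = self.eigenvalues[1:]
        mu = mu[mu > 1e-15]
        lam = -np.log(mu) / self.epsilon
        return lam[lam > 0]

    @property
    def spectral_gap_decay(self) -> float:
        """-log(mu_1): decay of the slowest nontrivial mode per kernel time."""
        if len(self.eigenvalues) < 2 or self.eigenvalues[1] <= 0:
            return np.inf
        return float(-np.log(self.eigenvalues[1]))


def _local_bandwidths(
    dist: np.ndarray, k: int, tol: float
) -> tuple[np.ndarray, bool]:
    """sigma_i = max(distance to k-th neighbor, first distinct distance).

    Returns (sigma, complete); ``complete`` is False when some point saw only
    duplicates within the searched neighbor budget.
    """
    n, K = dist.shape
    kth = dist[:, min(k, K - 1)]
    distinct_mask = dist > tol
    has_distinct = distinct_mask.any(axis=1)
    first_distinct = np.where(
        has_distinct,
        np.take_along_axis(
            dist, np.argmax(distinct_mask, axis=1)[:, None], axis=1
        ).ravel(),
        np.inf,
    )
    sigma = np.maximum(kth, np.where(np.isfinite(first_distinct), first_distinct, 0.0))
    return sigma, bool(has_distinct.all())


def build_diffusion_operator(
    points: np.ndarray, cfg: DiffusionConfig = DiffusionConfig()
) -> tuple[sp.csr_matrix, np.ndarray, float]:
    """Build the (pre-row-normalization) operator for a point cloud.

    Returns ``(W, rowsum, epsilon)`` where ``W`` is the density-normalized
    symmetric affinity matrix, ``rowsum`` its row sums (so the Markov
    operator is ``diag(rowsum)^-1 W``) and ``epsilon`` the kernel heat time.
    Raises :class:`GraphConnectivityError` on a disconnected graph.
    """
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    k = cfg.k_neighbors
    cfg.validate(n)
    scale = float(np.sqrt(np.mean(np.var(X, axis=0))))
    tol = 1e-8 * max(scale, 1e-300)

    K = min(n, max(4 * k, 64))
    while True:
        nn = NearestNeighbors(n_neighbors=K).fit(X)
        dist, ind = nn.kneighbors(X)
        sigma, complete = _local_bandwidths(dist[:, 1:], k - 1, tol)
        if complete or K >= min(n, K_SEARCH_MAX):
            if complete:
                # widen until the searched radius covers the 2-sigma support
                covered = (dist[:, -1] >= 2.0 * sigma) | (K >= min(n, K_SEARCH_MAX))
                if covered.all():
                    break
            if K >= min(n, K_SEARCH_MAX):
                break
        K = min(min(n, K_SEARCH_MAX), 2 * K)

    rows = np.repeat(np.arange(n), K - 1)
    cols = ind[:, 1:].ravel()
    d = dist[:, 1:].ravel()
    ss = sigma[rows] * sigma[cols]
    ss = np.maximum(ss, tol**2)
    within_support = d <= 2.0 * np.sqrt(ss)
    is_knn = np.tile(np.arange(1, K), n) <= k
    keep = within_support | is_knn
    w = np.exp(-(d[keep] ** 2) / ss[keep])
    W = sp.coo_matrix((w, (rows[keep], cols[keep])), shape=(n, n)).tocsr()
    W = W.maximum(W.T)  # symmetrized kNN graph
    W = W + sp.eye(n, format="csr")  # self-affinity exp(0) = 1

    n_comp, _ = connected_components(W, directed=False)
    if n_comp > 1:
        raise GraphConnectivityError(
            f"affinity graph has {n_comp} connected components"
        )

    q = np.asarray(W.sum(axis=1)).ravel()
    if cfg.density_alpha != 0:
        dq = sp.diags(q ** (-cfg.density_alpha))
        W = dq @ W @ dq
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    epsilon = float(np.median(sigma**2)) / 4.0
    return W, rowsum, epsilon


def eigendecompose(
    W: sp.csr_matrix,
    rowsum: np.ndarray,
    epsilon: float,
    cfg: DiffusionConfig = DiffusionConfig(),
) -> DiffusionSpectrum:
    """Top eigenpairs of the Markov operator via its symmetric conjugate.

    ``S = D^-1/2 W D^-1/2`` shares eigenvalues with ``D^-1 W``; eigenvectors
    are recovered by ``D^-1/2``-scaling.  The starting vector is fixed so the
    decomposition is deterministic.
    """
    n = W.shape[0]
    dm = sp.diags(rowsum**-0.5)
    S = dm @ W @ dm
    S = (S + S.T) * 0.5  # enforce exact symmetry against rounding
    k = min(cfg.n_eigenpairs, n - 2)
    v0 = np.full(n, 1.0 / np.sqrt(n))
    vals, vecs = spl.eigsh(S, k=k, which="LA", tol=cfg.eig_tol, v0=v0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vecs = dm @ vecs  # conjugate back to Markov-operator eigenvectors
    vecs /= np.linalg.norm(vecs, axis=0, keepdims=True)
    return DiffusionSpectrum(eigenvalues=vals, eigenvectors=vecs, epsilon=epsilon)


class DiffusionMap(BaseEstimator):
    """Diffusion-map spectral embedding as a scikit-learn estimator.

    After ``fit(X)`` on an ``(n_points, n_dims)`` cloud the instance carries
    ``eigenvalues_``, ``eigenvectors_``, ``epsilon_``,
    ``laplacian_eigenvalues_`` and ``spectrum_``.
    """

    def __init__(
        self,
        k_neighbors: int = 32,
        n_eigenpairs: int = 101,
        density_alpha: float = 1.0,
        eig_tol: float = 1e-10,
    ):
        self.k_neighbors = k_neighbors
        self.n_eigenpairs = n_eigenpairs
        self.density_alpha = density_alpha
        self.eig_tol = eig_tol

    def _config(self) -> DiffusionConfig:
        return DiffusionConfig(
            k_neighbors=self.k_neighbors,
            n_eigenpairs=self.n_eigenpairs,
            density_alpha=self.density_alpha,
            eig_tol=self.eig_tol,
        )

    def fit(self, X, y=None):
        cfg = self._config()
        W, rowsum, epsilon = build_diffusion_operator(np.asarray(X, float), cfg)
        spectrum = eigendecompose(W, rowsum, epsilon, cfg)
        self.spectrum_ = spectrum
        self.eigenvalues_ = spectrum.eigenvalues
        self.eigenvectors_ = spectrum.eigenvectors
        self.epsilon_ = spectrum.epsilon
        self.laplacian_eigenvalues_ = spectrum.laplacian_eigenvalues
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X=None) -> np.ndarray:
        """Diffusion coordinates of the fitted cloud (nontrivial modes)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "eigenvectors_")
        return self.eigenvectors_[:, 1:] * self.eigenvalues_[1:]

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X).transform()
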