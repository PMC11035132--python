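"""End-to-end attractor Dimension and Volume estimation.

:class:`ManifoldEstimator` chains delay embedding, the self-tuning diffusion
operator, eigendecomposition, and the Weyl counting fit.  Two rules sit on
top of the chain:

* **Resolution rule** -- if even the slowest nontrivial diffusion mode
  decays at the kernel's own time scale (``mu_1 < 0.98``), the point cloud
  has no extended structure the kernel can resolve: the epoch is classified
  as a point attractor with dimension 0 and volume 0.  This is what makes a
  tightly jittered fixed point read as dimension 0 rather than as a
  noise ball filling the embedding space.
* **Volume calibration** -- the raw Weyl volume is in embedding-space units;
  dividing by the median per-step trajectory displacement raised to the
  power d converts it to timesteps, so a period-P orbit reads Vol ~ P.  The
  median matches the median used for the kernel's heat time; the two must
  agree for the units to cancel.

Per the quality-control convention, any volume strictly greater than 250
timesteps is flagged ``discarded`` (a tenth of the 2500-sample window is the
longest quasi-period the window can measure reliably); failures at any stage
yield a flagged row, never an exception across a batch boundary.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator

from .diffusion import (
    DiffusionConfig,
    DiffusionMap,
    GraphConnectivityError,
)
from .embedding import DelayEmbedding, EmbeddingError
from .store import Epoch
from .weyl import R2_CONVERGENCE, WeylFitError, weyl_fit

__all__ = [
    "ManifoldEstimate",
    "ManifoldEstimator",
    "estimate_manifold",
    "discard_flag",
    "VOLUME_DISCARD",
    "GAP_MU_MIN",
]

#: volumes above this many timesteps cannot be measured within the window
VOLUME_DISCARD = 250.0

#: resolution rule: mu_1 below this means no resolvable extended structure
GAP_MU_MIN = 0.98


def discard_flag(volume: float) -> bool:
    """Strict QC inequality: volumes above (not at) 250 timesteps are out."""
    return bool(np.isfinite(volume) and volume > VOLUME_DISCARD)


@dataclasses.dataclass
class ManifoldEstimate:
    """One epoch x filter condition worth of attractor geometry."""

    dimension: float
    volume: float
    fit_r2: float
    converged: bool
    discarded: bool
    filter_name: str = "no_filter"
    error: str = ""
    fit_window: tuple[int, int] = (0, 0)
    labels: dict[str, Any] = dataclasses.field(default_factory=dict)


class ManifoldEstimator(BaseEstimator):
    """Dimension/Volume estimator with the scikit-learn fit API.

    Parameters mirror the fixed analysis settings: 8 delay coordinates at
    lag 1, 32 nearest neighbors, 101 eigenpairs.  ``fit(X)`` accepts an
    :class:`~dmdc.store.Epoch`, a pair of epochs (the composite two-stream
    condition), or a plain 1-D array; fitted attributes are ``dimension_``,
    ``volume_``, ``fit_r2_``, ``converged_``, ``discarded_``, ``spectrum_``
    and ``error_``.
    """

    def __init__(
        self,
        n_delays: int = 8,
        lag: int = 1,
        k_neighbors: int = 32,
        n_eigenpairs: int = 101,
        density_alpha: float = 1.0,
        eig_tol: float = 1e-10,
        min_window: int = 20,
    ):
        self.n_delays = n_delays
        self.lag = lag
        self.k_neighbors = k_neighbors
        self.n_eigenpairs = n_eigenpairs
        self.density_alpha = density_alpha
        self.eig_tol = eig_tol
        self.min_window = min_window

    def fit(self, X, y=None):
        self.error_ = ""
        self.spectrum_ = None
        self.fit_window_ = (0, 0)
        try:
            self._fit(X)
        except (
            EmbeddingError,
            GraphConnectivityError,
            WeylFitError,
            ValueError,
        ) as exc:
            self.dimension_ = np.nan
            self.volume_ = np.nan
            self.fit_r2_ = 0.0
            self.converged_ = False
            self.error_ = f"{type(exc).__name__}: {exc}"
        self.discarded_ = discard_flag(getattr(self, "volume_", np.nan))
        return self

    def _fit(self, X) -> None:
        emb = DelayEmbedding(n_delays=self.n_delays, lag=self.lag)
        points = emb.fit_transform(X)
        self.n_points_ = points.shape[0]

        span = float(np.max(np.ptp(points, axis=0), initial=0.0))
        if span <= 1e-12 * max(1.0, float(np.abs(points).max(initial=0.0))):
            # strictly constant signal: a point attractor by definition
            self.dimension_, self.volume_ = 0.0, 0.0
            self.fit_r2_, self.converged_ = 1.0, True
            self.resolution_limited_ = True
            return

        dmap = DiffusionMap(
            k_neighbors=self.k_neighbors,
            n_eigenpairs=self.n_eigenpairs,
            density_alpha=self.density_alpha,
            eig_tol=self.eig_tol,
        ).fit(points)
        self.spectrum_ = dmap.spectrum_

        mu = dmap.eigenvalues_
        if len(mu) > 1 and mu[1] < GAP_MU_MIN:
            # resolution rule: no structure survives one kernel time
            self.dimension_, self.volume_ = 0.0, 0.0
            self.fit_r2_, self.converged_ = 1.0, True
            self.resolution_limited_ = True
            return
        self.resolution_limited_ = False

        fit = weyl_fit(dmap.spectrum_, min_window=self.min_window)
        steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
        median_step = float(np.median(steps))
        volume = fit.volume
        if median_step > 0 and np.isfinite(fit.dimension):
            volume = fit.volume / median_step**fit.dimension
        self.dimension_ = fit.dimension
        self.volume_ = float(volume)
        self.fit_r2_ = fit.fit_r2
        self.fit_window_ = fit.fit_window
        self.converged_ = fit.fit_r2 >= R2_CONVERGENCE

    def estimate(self, X, filter_name: str = "no_filter") -> ManifoldEstimate:
        """Fit and package the result as a :class:`ManifoldEstimate` row."""
        self.fit(X)
        labels: dict[str, Any] = {}
        ref = X[0] if isinstance(X, (tuple, list)) else X
        if isinstance(ref, Epoch):
            labels = {
                **ref.labels,
                "location": ref.location,
                "alternation": ref.alternation,
                "epoch_start_s": ref.start,
            }
            if ref.ground_truth:
                labels["ground_truth_kind"] = ref.ground_truth.get("kind", "")
        return ManifoldEstimate(
            dimension=float(self.dimension_),
            volume=float(self.volume_),
            fit_r2=float(self.fit_r2_),
            converged=bool(self.converged_),
            discarded=bool(self.discarded_),
            filter_name=filter_name,
            error=self.error_,
            fit_window=self.fit_window_,
            labels=labels,
        )


def estimate_manifold(
    epoch_or_pair,
    filter_name: str = "no_filter",
    n_delays: int = 8,
    lag: int = 1,
    diffusion: DiffusionConfig = DiffusionConfig(),
    min_window: int = 20,
) -> ManifoldEstimate:
    """Functional wrapper over :class:`ManifoldEstimator`."""
    est = ManifoldEstimator(
        n_delays=n_delays,
        lag=lag,
        k_neighbors=diffusion.k_neighbors,
        n_eigenpairs=diffusion.n_eigenpairs,
        density_alpha=diffusion.density_alpha,
        eig_tol=diffusion.eig_tol,
        min_window=min_window,
    )
    return est.estimate(epoch_or_pair, filter_name=filter_name)
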