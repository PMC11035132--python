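"""Weyl's-law extraction of manifold dimension and volume.

Weyl's counting law for the Laplacian on a compact d-manifold of volume V,

    N(lambda) ~ omega_d * V * lambda^(d/2) / (2 pi)^d,
    omega_d = pi^(d/2) / Gamma(d/2 + 1),

is a power law, so ``log N`` against ``log lambda`` is fit by least squares
over the contiguous eigenvalue window maximizing R^2 (window length >= 20,
starting past the first nontrivial eigenvalue; ties broken by the longer
window, then the lower start).  The slope gives ``d = 2 * slope``; the
intercept gives the raw volume ``V = exp(intercept) * (2 pi)^d / omega_d``
in embedding-space units.

When the fit input is a full diffusion spectrum, only modes still in the
heat-semigroup regime (``-log mu <= 0.5``) are trusted: deeper modes carry
visible discretization bias in the ``-log(mu)/epsilon`` inversion.  If fewer
than a window's worth qualify, the shallowest window's worth is used so
noisy epochs still yield a (flagged) estimate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import gammaln

from .diffusion import DiffusionSpectrum

__all__ = ["WeylFit", "weyl_fit", "WeylFitError", "MODE_DECAY_CUT"]

#: modes with -log(mu) beyond this are outside the trusted semigroup regime
MODE_DECAY_CUT = 0.5

#: least-squares fit quality below which an estimate is flagged unconverged
R2_CONVERGENCE = 0.8


class WeylFitError(ValueError):
    """Too few usable Laplacian eigenvalues for a counting fit."""


@dataclasses.dataclass(frozen=True)
class WeylFit:
    dimension: float
    volume: float
    fit_r2: float
    fit_window: tuple[int, int]

    @property
    def converged(self) -> bool:
        return self.fit_r2 >= R2_CONVERGENCE


def _fit_set(spectrum: DiffusionSpectrum, min_window: int) -> np.ndarray:
    mu = spectrum.eigenvalues[1:]
    mu = mu[mu > 1e-15]
    decay = -np.log(mu)
    n_shallow = int(np.sum(decay <= MODE_DECAY_CUT))
    n_keep = max(n_shallow, min(min_window + 1, len(decay)))
    lam = decay[:n_keep] / spectrum.epsilon
    return lam[lam > 0]


def weyl_fit(
    spectrum: DiffusionSpectrum | np.ndarray, min_window: int = 20
) -> WeylFit:
    """Fit the eigenvalue counting law; accepts a spectrum or a raw
    array of Laplacian eigenvalues (the analytic-oracle path)."""
    if isinstance(spectrum, DiffusionSpectrum):
        lam = _fit_set(spectrum, min_window)
    else:
        lam = np.asarray(spectrum, dtype=float)
        lam = lam[lam > 0]
    lam = np.sort(lam)
    if len(lam) < min_window + 1:
        raise WeylFitError(
            f"need more than {min_window} positive Laplacian eigenvalues, "
            f"got {len(lam)}"
        )

    x = np.log(lam)
    y = np.log(np.arange(1, len(lam) + 1, dtype=float))
    # prefix sums make every window's regression O(1)
    z = np.zeros(1)
    cx = np.concatenate([z, np.cumsum(x)])
    cy = np.concatenate([z, np.cumsum(y)])
    cxx = np.concatenate([z, np.cumsum(x * x)])
    cxy = np.concatenate([z, np.cumsum(x * y)])
    cyy = np.concatenate([z, np.cumsum(y * y)])

    best_key: tuple[float, int, int] | None = None
    best_coef = (0.0, 0.0)
    n = len(lam)
    for i in range(1, n - min_window + 1):  # skip the first nontrivial eigenvalue
        for j in range(i + min_window, n + 1):
            w = j - i
            sx, sy = cx[j] - cx[i], cy[j] - cy[i]
            vxx = cxx[j] - cxx[i] - sx * sx / w
            if vxx < 1e-12:
                continue
            vxy = cxy[j] - cxy[i] - sx * sy / w
            vyy = cyy[j] - cyy[i] - sy * sy / w
            r2 = 0.0 if vyy <= 0 else (vxy * vxy) / (vxx * vyy)
            key = (round(r2, 12), w, -i)
            if best_key is None or key > best_key:
                slope = vxy / vxx
                best_key = key
                best_coef = (slope, (sy - slope * sx) / w)
    if best_key is None:
        raise WeylFitError("degenerate eigenvalue set: no window has spread")

    r2, w, neg_i = best_key
    slope, intercept = best_coef
    dim = 2.0 * slope
    log_omega = (dim / 2.0) * np.log(np.pi) - gammaln(dim / 2.0 + 1.0)
    volume = float(np.exp(intercept - log_omega + dim * np.log(2.0 * np.pi)))
    return WeylFit(
        dimension=float(dim),
        volume=volume,
        fit_r2=float(r2),
        fit_window=(-neg_i, -neg_i + w),
    )
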