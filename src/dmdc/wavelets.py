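"""Morlet-wavelet power, within-trial z-scoring, band summaries, events.

The comparator to attractor geometry: complex Morlet wavelets (Gaussian
envelope with time sd ``n_cycles / (2 pi f)``) at 1 Hz steps from 1 to
101 Hz, squared-magnitude power, per-frequency z-scoring across the trial
(flattening the 1/f power spectrum), band-average power over the integer-Hz
rows of a band, and event counting: one event is one maximal contiguous run
of the band-mean z series with ``|z| > 1.95`` (the two-sided 5% point of a
standard normal).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .filters import FilterSpec
from .store import Epoch

__all__ = [
    "WaveletConfig",
    "PowerMap",
    "BandSummary",
    "MorletPower",
    "morlet_transform",
    "zscore_power",
    "band_average",
    "count_events",
    "EVENT_THRESHOLD",
]

EVENT_THRESHOLD = 1.95  # |z| above this marks a supra-threshold excursion


@dataclasses.dataclass(frozen=True)
class WaveletConfig:
    """Frequency grid and cycle count of the Morlet filter bank."""

    freqs: tuple[float, ...] = tuple(float(f) for f in range(1, 102))
    n_cycles: int = 7

    def validate(self, fs: float) -> None:
        if self.n_cycles < 3:
            raise ValueError(f"n_cycles must be >= 3, got {self.n_cycles}")
        if max(self.freqs) >= fs / 2:
            raise ValueError(
                f"max wavelet frequency {max(self.freqs)} must be < fs/2 = {fs / 2}"
            )


@dataclasses.dataclass
class PowerMap:
    """time x frequency power (raw or z-scored)."""

    values: np.ndarray  # (n_times, n_freqs)
    fs: float
    freqs: tuple[float, ...]
    zscored: bool = False

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    def freq_index(self, f: float) -> int:
        idx = int(np.argmin(np.abs(np.asarray(self.freqs) - f)))
        if abs(self.freqs[idx] - f) > 0.5:
            raise ValueError(f"frequency {f} Hz not on the wavelet grid")
        return idx


@dataclasses.dataclass
class BandSummary:
    """Average z-power and event statistics for one band in one window."""

    band: str
    avg_power: float
    event_count: int
    event_rate: float  # events per second
    labels: dict = dataclasses.field(default_factory=dict)


def _morlet_kernel(f: float, fs: float, n_cycles: int) -> np.ndarray:
    sd_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(4.0 * sd_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2.0 * sd_t**2))
    # unit total envelope: power scale then set purely by the signal
    return kernel / np.sum(np.abs(kernel))


def morlet_transform(
    trial_or_epoch, cfg: WaveletConfig = WaveletConfig()
) -> PowerMap:
    """Squared magnitude of the complex Morlet convolution per frequency.

    The signal is reflect-padded by each wavelet's half-support.  Wavelets
    whose support exceeds the signal are dropped with a warning rather than
    failing the whole transform.
    """
    if isinstance(trial_or_epoch, Epoch):
        x, fs = trial_or_epoch.samples, trial_or_epoch.fs
    elif hasattr(trial_or_epoch, "samples"):
        x, fs = trial_or_epoch.samples, trial_or_epoch.fs
    else:
        raise TypeError("morlet_transform needs a Trial or Epoch")
    cfg.validate(fs)
    n = len(x)
    usable = []
    for f in cfg.freqs:
        half = int(np.ceil(4.0 * cfg.n_cycles / (2.0 * np.pi * f) * fs))
        if 2 * half + 1 > 2 * n:
            warnings.warn(
                f"dropping {f} Hz wavelet: support exceeds signal length",
                stacklevel=2,
            )
            continue
        usable.append(f)
    power = np.empty((n, len(usable)))
    for j, f in enumerate(usable):
        kernel = _morlet_kernel(f, fs, cfg.n_cycles)
        half = (len(kernel) - 1) // 2
        pad = min(half, n - 1)
        padded = np.pad(x, pad, mode="reflect")
        conv = sps.fftconvolve(padded, kernel, mode="same")[pad : pad + n]
        power[:, j] = np.abs(conv) ** 2
    return PowerMap(values=power, fs=fs, freqs=tuple(usable), zscored=False)


def zscore_power(pm: PowerMap) -> PowerMap:
    """Per-frequency standardization over the trial extent.

    Zero-variance columns (e.g. a zero signal) are set to 0 with a warning.
    """
    if pm.zscored:
        raise ValueError("power map is already z-scored")
    mean = pm.values.mean(axis=0)
    sd = pm.values.std(axis=0)
    flat = sd <= 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance frequency column(s) set to 0",
            stacklevel=2,
        )
    sd_safe = np.where(flat, 1.0, sd)
    z = (pm.values - mean) / sd_safe
    z[:, flat] = 0.0
    return PowerMap(values=z, fs=pm.fs, freqs=pm.freqs, zscored=True)


def _band_rows(pm: PowerMap, band: FilterSpec | tuple[float, float]) -> np.ndarray:
    lo, hi = band.edges if isinstance(band, FilterSpec) else band
    freqs = np.asarray(pm.freqs)
    rows = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if rows.size == 0:
        raise ValueError(f"band ({lo}, {hi}) Hz outside wavelet grid")
    return rows


def _window_slice(pm: PowerMap, window: tuple[float, float] | None) -> slice:
    if window is None:
        return slice(None)
    i0 = int(round(window[0] * pm.fs))
    i1 = int(round(window[1] * pm.fs))
    if not 0 <= i0 < i1 <= pm.n_times:
        raise ValueError(f"window {window} s outside the power map extent")
    return slice(i0, i1)


def band_average(
    pm: PowerMap,
    band: FilterSpec | tuple[float, float],
    window: tuple[float, float] | None = None,
) -> float:
    """Mean z-scored power over a band's integer-Hz rows and a time window."""
    if not pm.zscored:
        raise ValueError("band_average needs a z-scored power map")
    rows = _band_rows(pm, band)
    return float(pm.values[_window_slice(pm, window)][:, rows].mean())


def count_events(
    pm: PowerMap,
    band: FilterSpec | tuple[float, float],
    threshold: float = EVENT_THRESHOLD,
    window: tuple[float, float] | None = None,
    band_name: str = "",
    event_mode: str = "runs",
) -> BandSummary:
    """Count supra-threshold excursions of the band-mean z series.

    ``event_mode="runs"`` counts each maximal contiguous run with
    ``|z| > threshold`` as one event; ``"samples"`` counts supra-threshold
    samples instead (the alternative reading of "number of times power
    surpassed" the threshold).
    """
    if not pm.zscored:
        raise ValueError("count_events needs a z-scored power map")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if event_mode not in ("runs", "samples"):
        raise ValueError(f"unknown event_mode {event_mode!r}")
    rows = _band_rows(pm, band)
    sl = _window_slice(pm, window)
    series = pm.values[sl][:, rows].mean(axis=1)
    above = np.abs(series) > threshold
    if event_mode == "samples":
        count = int(above.sum())
    else:
        starts = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
        count = int(starts.size)
    seconds = len(series) / pm.fs
    name = band_name or (band.name if isinstance(band, FilterSpec) else f"{band}")
    return BandSummary(
        band=name,
        avg_power=float(series.mean()),
        event_count=count,
        event_rate=count / seconds,
    )


class MorletPower(TransformerMixin, BaseEstimator):
    """Morlet power map as a transformer: Epoch/Trial in, z-scored map out."""

    def __init__(
        self,
        freqs: Sequence[float] = tuple(float(f) for f in range(1, 102)),
        n_cycles: int = 7,
        zscore: bool = True,
    ):
        self.freqs = tuple(freqs)
        self.n_cycles = n_cycles
        self.zscore = zscore

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> PowerMap:
        cfg = WaveletConfig(freqs=tuple(self.freqs), n_cycles=self.n_cycles)
        pm = morlet_transform(X, cfg)
        return zscore_power(pm) if self.zscore else pm
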