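"""The ten filter conditions applied before attractor estimation.

Biologically motivated bands: theta 4-12 Hz, slow gamma 25-55 Hz, fast gamma
65-100 Hz, sharp-wave ripple (SWR) 140-200 Hz; control conditions: 20 Hz
high-pass, 100 Hz low-pass, 100 Hz high-pass, 100-135 Hz band-pass, and a
composite that runs the 4-100 Hz and SWR streams concurrently.  Filters are
4th-order Butterworth sections applied forward-backward (zero phase,
effective 8th order): phase distortion would warp delay-embedding geometry,
so zero-phase filtering is a requirement, not a convenience.  Stated edges
are -3 dB corners.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .store import Epoch

__all__ = ["FilterSpec", "FilterDesignError", "registry", "apply_filter", "BAND_NAMES"]

#: bands available for wavelet summaries (SWR excluded: the wavelet grid
#: tops out near 100 Hz)
BAND_NAMES = ("theta", "slow_gamma", "fast_gamma")


class FilterDesignError(ValueError):
    """Filter edges are invalid for the sampling rate (or design unstable)."""


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Declarative description of one filter condition."""

    name: str
    kind: str  # none | bandpass | highpass | lowpass | composite
    edges: tuple[float, ...] = ()
    components: tuple["FilterSpec", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "bandpass":
            if len(self.edges) != 2 or not self.edges[0] < self.edges[1]:
                raise FilterDesignError(f"{self.name}: bandpass needs 2 increasing edges")
        elif self.kind in ("highpass", "lowpass"):
            if len(self.edges) != 1:
                raise FilterDesignError(f"{self.name}: {self.kind} needs exactly 1 edge")
        elif self.kind == "composite":
            if len(self.components) < 2 or any(
                c.kind == "composite" for c in self.components
            ):
                raise FilterDesignError(
                    f"{self.name}: composite needs >=2 non-composite components"
                )
        elif self.kind != "none":
            raise FilterDesignError(f"{self.name}: unknown kind {self.kind!r}")
        if any(e <= 0 for e in self.edges):
            raise FilterDesignError(f"{self.name}: edges must be positive")

    def effective_edges(self, fs: float) -> tuple[float, float]:
        """(low, high) with unbounded sides replaced by 0 / Nyquist."""
        if self.kind == "bandpass":
            return self.edges  # type: ignore[return-value]
        if self.kind == "highpass":
            return (self.edges[0], fs / 2.0)
        if self.kind == "lowpass":
            return (0.0, self.edges[0])
        if self.kind == "composite":
            spans = [c.effective_edges(fs) for c in self.components]
            return (min(s[0] for s in spans), max(s[1] for s in spans))
        return (0.0, fs / 2.0)


def registry() -> dict[str, FilterSpec]:
    """The ten named filter conditions, keyed by name."""
    bp4_100 = FilterSpec("bp4_100", "bandpass", (4.0, 100.0))
    swr = FilterSpec("swr", "bandpass", (140.0, 200.0))
    specs = [
        FilterSpec("no_filter", "none"),
        FilterSpec("theta", "bandpass", (4.0, 12.0)),
        FilterSpec("slow_gamma", "bandpass", (25.0, 55.0)),
        FilterSpec("fast_gamma", "bandpass", (65.0, 100.0)),
        swr,
        FilterSpec("hp20", "highpass", (20.0,)),
        FilterSpec("lp100", "lowpass", (100.0,)),
        FilterSpec("hp100", "highpass", (100.0,)),
        FilterSpec("bp100_135", "bandpass", (100.0, 135.0)),
        FilterSpec("composite_4_100_swr", "composite", components=(bp4_100, swr)),
    ]
    return {s.name: s for s in specs}


def _design(spec: FilterSpec, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if any(e >= nyq for e in spec.edges):
        raise FilterDesignError(
            f"{spec.name}: edge at or above Nyquist ({nyq} Hz) for fs={fs}"
        )
    if spec.kind == "bandpass":
        sos = sps.butter(4, spec.edges, btype="bandpass", fs=fs, output="sos")
    elif spec.kind == "highpass":
        sos = sps.butter(4, spec.edges[0], btype="highpass", fs=fs, output="sos")
    elif spec.kind == "lowpass":
        sos = sps.butter(4, spec.edges[0], btype="lowpass", fs=fs, output="sos")
    else:  # pragma: no cover - guarded by apply_filter
        raise FilterDesignError(f"{spec.name}: cannot design kind {spec.kind!r}")
    # pole magnitudes: |p| >= 1 would make forward-backward filtering blow up
    _, poles, _ = sps.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise FilterDesignError(f"{spec.name}: unstable design (pole on/outside unit circle)")
    return sos


def _impulse_length(sos: np.ndarray) -> int:
    """Effective impulse-response length: where the response decays to 1e-3."""
    resp = sps.sosfilt(sos, np.eye(1, 4096, 0).ravel())
    mag = np.abs(resp)
    above = np.flatnonzero(mag > 1e-3 * mag.max())
    return int(above[-1]) + 1 if above.size else 1


def apply_filter(epoch: Epoch, spec: FilterSpec) -> Epoch | tuple[Epoch, Epoch]:
    """Zero-phase filter an epoch; composite specs return one epoch per stream.

    The epoch is reflect-padded by one impulse-response length on each side
    before forward-backward filtering, then trimmed, to keep edge ringing off
    the short analysis windows.
    """
    if spec.kind == "none":
        return epoch.with_samples(epoch.samples.copy())
    if spec.kind == "composite":
        parts = tuple(apply_filter(epoch, c) for c in spec.components)
        return parts  # type: ignore[return-value]
    sos = _design(spec, epoch.fs)
    pad = min(_impulse_length(sos), len(epoch.samples) - 1)
    filtered = sps.sosfiltfilt(sos, epoch.samples, padtype="even", padlen=pad)
    return epoch.with_samples(filtered)
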