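"""Synthetic signals of known dynamical geometry and oscillatory content.

These generators exist so every downstream stage can be validated without
in-vivo recordings: signals lying on manifolds of known dimension (a jittered
fixed point -> 0, a sinusoidal limit cycle -> 1, a two-tone torus -> 2), a
chaotic Lorenz flow (non-integer dimension near 2.06 in the literature), and
an LFP-like composite of 1/f background plus band-limited oscillatory bursts
with a known event schedule.

All generators are deterministic in (parameters, seed): the same call twice
returns bit-identical samples.  Ground-truth labels (true dimension, true
period, scheduled burst times) travel in ``Epoch.ground_truth`` so they
round-trip into every result row.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np

from .store import Epoch

__all__ = [
    "gen_fixed_point",
    "gen_limit_cycle",
    "gen_torus",
    "gen_lorenz",
    "gen_lfp_composite",
    "InvalidSpecError",
    "AliasingError",
    "IntegrationError",
]

DEFAULT_FS = 1000.0  # Hz; makes samples and milliseconds interchangeable


class InvalidSpecError(ValueError):
    """Generator parameters are out of their documented domain."""


class AliasingError(InvalidSpecError):
    """A requested tone is at or above the Nyquist frequency."""


class IntegrationError(RuntimeError):
    """Numerical integration diverged (time step too large)."""


def _check_n_fs(n: int, fs: float) -> None:
    if n < 64:
        raise InvalidSpecError(f"n must be >= 64, got {n}")
    if fs <= 0:
        raise InvalidSpecError(f"fs must be positive, got {fs}")


def gen_fixed_point(
    n: int = 2500,
    fs: float = DEFAULT_FS,
    jitter_sd: float = 1e-3,
    level: float = 1.0,
    seed: int = 0,
) -> Epoch:
    """Constant level plus i.i.d. Gaussian jitter: a dimension-0 attractor."""
    _check_n_fs(n, fs)
    if jitter_sd < 0:
        raise InvalidSpecError(f"jitter_sd must be >= 0, got {jitter_sd}")
    rng = np.random.default_rng(seed)
    x = level + jitter_sd * rng.standard_normal(n)
    return Epoch(
        samples=x,
        fs=fs,
        ground_truth={"kind": "fixed_point", "dimension": 0, "jitter_sd": jitter_sd,
                      "seed": seed},
    )


def gen_limit_cycle(
    n: int = 2500,
    fs: float = DEFAULT_FS,
    freq: float = 10.0,
    amp: float = 1.0,
    noise_sd: float = 0.0,
    phase: float | None = None,
    seed: int = 0,
) -> Epoch:
    """Sinusoidal periodic orbit: dimension 1, period ``fs/freq`` samples.

    ``phase=None`` draws a uniform random initial phase from the seed;
    pass an explicit phase for a fully specified waveform.
    """
    _check_n_fs(n, fs)
    if not 0 < freq < fs / 2:
        raise AliasingError(f"freq must lie in (0, fs/2)=(0, {fs / 2}), got {freq}")
    if noise_sd < 0:
        raise InvalidSpecError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0, 2 * np.pi) if phase is None else float(phase)
    t = np.arange(n) / fs
    x = amp * np.sin(2 * np.pi * freq * t + phi)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return Epoch(
        samples=x,
        fs=fs,
        ground_truth={"kind": "limit_cycle", "dimension": 1,
                      "period_samples": fs / freq, "freq": freq, "phase": phi,
                      "noise_sd": noise_sd, "seed": seed},
    )


def _commensurate(f1: float, f2: float, tol: float = 1e-9, max_den: int = 64) -> bool:
    ratio = f1 / f2
    frac = Fraction(ratio).limit_denominator(max_den)
    return abs(ratio - float(frac)) <= tol


def gen_torus(
    n: int = 10000,
    fs: float = DEFAULT_FS,
    f1: float = 7.0,
    f2: float = 7.0 * np.sqrt(2.0),
    phases: tuple[float, float] | None = None,
    seed: int = 0,
) -> Epoch:
    """Sum of two unit sinusoids: a 2-torus when f1/f2 is irrational.

    A commensurate pair (ratio equal to a small-integer fraction within
    1e-9) degenerates to a closed curve; the epoch is returned with a
    warning flag rather than rejected.
    """
    _check_n_fs(n, fs)
    for f in (f1, f2):
        if not 0 < f < fs / 2:
            raise AliasingError(f"tone {f} Hz outside (0, fs/2)=(0, {fs / 2})")
    rng = np.random.default_rng(seed)
    if phases is None:
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    else:
        ph1, ph2 = phases
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * f1 * t + ph1) + np.sin(2 * np.pi * f2 * t + ph2)
    epoch = Epoch(
        samples=x,
        fs=fs,
        ground_truth={"kind": "torus", "dimension": 2, "f1": f1, "f2": f2,
                      "phases": (ph1, ph2), "seed": seed},
    )
    if _commensurate(f1, f2):
        epoch.warnings.append(
            f"commensurate tones f1={f1}, f2={f2}: trajectory closes, "
            "ground-truth dimension degenerates from 2 to 1"
        )
    return epoch


def gen_lorenz(
    n: int = 2500,
    fs: float = DEFAULT_FS,
    sigma: float = 10.0,
    rho: float = 28.0,
    beta: float = 8.0 / 3.0,
    dt: float = 0.01,
    discard: int = 2000,
    seed: int = 0,
) -> Epoch:
    """x-coordinate of a fixed-step RK4 Lorenz integration, transient removed.

    The scalar observable mirrors a single-electrode measurement; the
    attractor's fractal dimension is ~2.06 in the chaotic regime, so a
    downstream estimate is only held to a loose non-integer band.
    """
    _check_n_fs(n, fs)
    if dt <= 0:
        raise InvalidSpecError(f"dt must be positive, got {dt}")
    if discard < 1000:
        raise InvalidSpecError("transient discard must span at least 1000 steps")
    rng = np.random.default_rng(seed)
    y = np.array([1.0, 1.0, 1.0]) + 0.1 * rng.standard_normal(3)

    def deriv(y: np.ndarray) -> np.ndarray:
        return np.array(
            [
                sigma * (y[1] - y[0]),
                y[0] * (rho - y[2]) - y[1],
                y[0] * y[1] - beta * y[2],
            ]
        )

    out = np.empty(n)
    for i in range(n + discard):
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > 1e6:
            raise IntegrationError(f"Lorenz integration diverged at step {i} (dt={dt})")
        if i >= discard:
            out[i - discard] = y[0]
    return Epoch(
        samples=out,
        fs=fs,
        ground_truth={"kind": "lorenz", "dimension": 2.06, "dt": dt,
                      "discard": discard, "seed": seed},
    )


def _band_unit_z_amplitude(
    x: np.ndarray, fs: float, lo: float, hi: float, f0: float
) -> float:
    """Tone amplitude whose added Morlet power averages one background
    power-sd across the band's integer-Hz rows.

    A tone of amplitude A at f0 drives the complex Morlet at frequency f to
    power ``(A/2)^2 |K_f(f0)|^2`` (K_f is the kernel's frequency response);
    dividing by each row's background power-sd and averaging over rows gives
    the burst's height in band-mean z units.
    """
    from .wavelets import WaveletConfig, _morlet_kernel, morlet_transform

    band_freqs = tuple(float(f) for f in range(int(np.ceil(lo)), int(hi) + 1))
    pm = morlet_transform(
        Epoch(samples=x, fs=fs), WaveletConfig(freqs=band_freqs)
    )
    sigma = pm.values.std(axis=0)
    sigma = np.maximum(sigma, 1e-300)
    n_fft = 1 << 16
    f_axis = np.fft.fftfreq(n_fft, 1.0 / fs)
    gain2 = np.empty(len(pm.freqs))
    for j, f in enumerate(pm.freqs):
        spec = np.abs(np.fft.fft(_morlet_kernel(f, fs, 7), n_fft))
        gain2[j] = spec[np.argmin(np.abs(f_axis - f0))] ** 2
    # mean_f [ (A/2)^2 gain2_f / sigma_f ] = 1  =>  A = 2 / sqrt(mean(...))
    return 2.0 / float(np.sqrt(np.mean(gain2 / sigma)))


def _calibrate_to_zscored_scale(
    background: np.ndarray,
    waves: list[np.ndarray],
    amps: list[float],
    events: list[dict],
    fs: float,
    reg: dict,
    n_iter: int = 3,
) -> list[float]:
    """Scale burst amplitudes so each peaks near its z_amp after z-scoring.

    Dense schedules cannot reach arbitrarily high z (the bursts dominate the
    normalization), so per-iteration growth is clamped; the achieved peak
    then settles at the schedule's self-limit.
    """
    from .store import Epoch as _Epoch
    from .wavelets import WaveletConfig, morlet_transform, zscore_power

    amps = list(amps)
    for _ in range(n_iter):
        x = background + sum(a * w for a, w in zip(amps, waves))
        for j, ev in enumerate(events):
            if ev["z_amp"] <= 0 or amps[j] == 0:
                continue
            lo, hi = reg[ev["band"]].edges
            band_freqs = tuple(
                float(f) for f in range(int(np.ceil(lo)), int(hi) + 1)
            )
            pm = zscore_power(
                morlet_transform(
                    _Epoch(samples=x, fs=fs), WaveletConfig(freqs=band_freqs)
                )
            )
            i0 = int(round(ev["onset"] * fs))
            i1 = int(round((ev["onset"] + ev["duration"]) * fs))
            achieved = float(pm.values[i0:i1].mean(axis=1).max())
            ratio = np.sqrt(ev["z_amp"] / max(achieved, 0.05))
            amps[j] *= float(np.clip(ratio, 1.0 / 3.0, 3.0))
    return amps


def gen_lfp_composite(
    n: int = 2500,
    fs: float = DEFAULT_FS,
    burst_spec: Sequence[tuple[str, float, float, float]] = (),
    noise_exponent: float = 1.0,
    seed: int = 0,
) -> Epoch:
    """1/f^exponent background plus scheduled band-limited bursts.

    ``burst_spec`` rows are ``(band, onset_s, duration_s, z_amp)`` with band
    names drawn from the filter registry.  Each burst is a tone at the band's
    center frequency under a raised-cosine (Hann) envelope.  ``z_amp`` is on
    the band-mean *power z-score* scale the event detector thresholds: the
    tone amplitude is calibrated through the Morlet filterbank response so
    the burst's added power averages ``z_amp`` background standard
    deviations across the band's frequency rows, making a ``z_amp=4`` burst
    an unambiguous ground-truth event at the usual 1.95 threshold.
    Overlapping bursts in the same band are rejected to keep the ground
    truth unambiguous.
    """
    from .filters import registry  # local import: avoid a cycle at import time

    _check_n_fs(n, fs)
    reg = registry()
    duration = n / fs
    by_band: dict[str, list[tuple[float, float]]] = {}
    for band, onset, dur, z_amp in burst_spec:
        if band not in reg or reg[band].kind != "bandpass":
            raise InvalidSpecError(f"unknown or non-bandpass burst band {band!r}")
        if onset < 0 or onset + dur > duration:
            raise InvalidSpecError(
                f"burst ({band}, {onset}, {dur}) outside [0, {duration}] s"
            )
        for o2, d2 in by_band.get(band, []):
            if onset < o2 + d2 and o2 < onset + dur:
                raise InvalidSpecError(f"overlapping bursts in band {band!r}")
        by_band.setdefault(band, []).append((onset, dur))

    rng = np.random.default_rng(seed)
    # colored background: white noise shaped to 1/f^exponent in amplitude
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-noise_exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    x /= max(np.std(x), 1e-300)

    t = np.arange(n) / fs
    background = x.copy()
    events: list[dict] = []
    waves: list[np.ndarray] = []
    amps: list[float] = []
    for band, onset, dur, z_amp in burst_spec:
        lo, hi = reg[band].edges
        f0 = 0.5 * (lo + hi)
        i0, i1 = int(round(onset * fs)), int(round((onset + dur) * fs))
        env = np.zeros(n)
        seg = np.hanning(max(i1 - i0, 2))
        env[i0:i1] = seg[: i1 - i0]
        waves.append(env * np.sin(2 * np.pi * f0 * t))
        amps.append(z_amp * _band_unit_z_amplitude(background, fs, lo, hi, f0))
        events.append({"band": band, "onset": onset, "duration": dur,
                       "z_amp": z_amp, "center_freq": f0})
    if events:
        # z-scoring power over the trial is self-normalizing: a burst's own
        # power inflates its column's sd.  Calibrate the amplitudes to the
        # post-z-scoring scale by fixed-point iteration so z_amp means what
        # the event detector thresholds.
        amps = _calibrate_to_zscored_scale(
            background, waves, amps, events, fs, reg
        )
        x = background + sum(a * w for a, w in zip(amps, waves))

    return Epoch(
        samples=x,
        fs=fs,
        ground_truth={"kind": "lfp_composite", "events": events,
                      "noise_exponent": noise_exponent, "seed": seed},
    )
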