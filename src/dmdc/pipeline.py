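"""One-config orchestration: simulate/load -> filter -> estimate -> stats.

A :class:`RunConfig` fully determines a run: inputs (file paths or synthetic
epoch specs), the filter list, embedding/diffusion/wavelet settings, and a
single seed fanned out to per-stage seeds by stable hashing.  ``run()``
writes ``results.csv`` (one row per epoch x filter), ``band_summaries.csv``,
ANOVA tables, a QC log with discarded/non-converged counts, and a manifest
with the config hash, so a persisted config re-executes to identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .filters import BAND_NAMES, apply_filter, registry
from .manifold import ManifoldEstimator
from .stats import one_way_filter_anova, tukey_hsd
from .store import Epoch, extract_epochs, read_trial
from .wavelets import MorletPower, band_average, count_events

__all__ = ["RunConfig", "ConfigError", "run", "demo_config", "stage_seed"]

_GENERATORS = {
    "fixed_point": synthetic.gen_fixed_point,
    "limit_cycle": synthetic.gen_limit_cycle,
    "torus": synthetic.gen_torus,
    "lorenz": synthetic.gen_lorenz,
    "lfp_composite": synthetic.gen_lfp_composite,
}


class ConfigError(ValueError):
    """The run configuration fails validation before any compute."""


@dataclasses.dataclass
class RunConfig:
    """Fully serializable description of one reproducible run."""

    out_dir: str
    seed: int = 0
    # synthetic inputs: list of {"kind": ..., "n": ..., "params": {...}}
    synthetic_epochs: list[dict] = dataclasses.field(default_factory=list)
    # or file inputs
    signal_path: str | None = None
    meta_path: str | None = None
    epoch_table_path: str | None = None
    filters: Sequence[str] = ("all",)
    n_delays: int = 8
    lag: int = 1
    k_neighbors: int = 32
    n_eigenpairs: int = 101
    wavelet_bands: Sequence[str] = BAND_NAMES
    event_threshold: float = 1.95
    run_wavelets: bool = True

    def resolved_filters(self) -> list[str]:
        reg = registry()
        names: list[str] = []
        for f in self.filters:
            if f == "all":
                names.extend(reg.keys())
            elif f in reg:
                names.append(f)
            else:
                raise ConfigError(f"unknown filter name in 'filters': {f!r}")
        return list(dict.fromkeys(names))

    def validate(self) -> None:
        if not self.synthetic_epochs and not (
            self.signal_path and self.meta_path and self.epoch_table_path
        ):
            raise ConfigError(
                "config needs either 'synthetic_epochs' or all of "
                "'signal_path', 'meta_path', 'epoch_table_path'"
            )
        for spec in self.synthetic_epochs:
            if spec.get("kind") not in _GENERATORS:
                raise ConfigError(f"unknown synthetic kind: {spec.get('kind')!r}")
        self.resolved_filters()
        for b in self.wavelet_bands:
            if b not in BAND_NAMES:
                raise ConfigError(f"unknown wavelet band: {b!r}")
        if self.event_threshold <= 0:
            raise ConfigError("event_threshold must be positive")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["filters"] = list(self.filters)
        d["wavelet_bands"] = list(self.wavelet_bands)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        for key in ("filters", "wavelet_bands"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Stable per-stage sub-seed below 2^31."""
    h = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _build_epochs(config: RunConfig) -> list[tuple[str, Epoch]]:
    out: list[tuple[str, Epoch]] = []
    if config.synthetic_epochs:
        for i, spec in enumerate(config.synthetic_epochs):
            gen = _GENERATORS[spec["kind"]]
            params = dict(spec.get("params", {}))
            params.setdefault("seed", stage_seed(config.seed, "simulate", i))
            epoch = gen(**params)
            epoch.labels.setdefault("trial_id", f"synthetic_{i}")
            out.append((f"synthetic_{i}", epoch))
    else:
        trial = read_trial(config.signal_path, config.meta_path)
        qc: list = []
        for j, epoch in enumerate(
            extract_epochs(trial, config.epoch_table_path, qc_log=qc)
        ):
            out.append((f"{trial.trial_id}:{j}", epoch))
    return out


def run(config: RunConfig) -> dict[str, Any]:
    """Execute a config; returns the manifest (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reg = registry()
    filter_names = config.resolved_filters()
    epochs = _build_epochs(config)

    est = ManifoldEstimator(
        n_delays=config.n_delays,
        lag=config.lag,
        k_neighbors=config.k_neighbors,
        n_eigenpairs=config.n_eigenpairs,
    )
    rows = []
    qc = {"n_epochs": len(epochs), "n_estimates": 0, "n_discarded": 0,
          "n_nonconverged": 0}
    for epoch_id, epoch in epochs:
        for fname in filter_names:
            filtered = apply_filter(epoch, reg[fname])
            result = est.estimate(filtered, filter_name=fname)
            row = {
                "epoch_id": epoch_id,
                "filter_name": fname,
                "dimension": result.dimension,
                "volume": result.volume,
                "fit_r2": result.fit_r2,
                "converged": result.converged,
                "discarded": result.discarded,
                "error": result.error,
                **result.labels,
            }
            rows.append(row)
            qc["n_estimates"] += 1
            qc["n_discarded"] += int(result.discarded)
            qc["n_nonconverged"] += int(not result.converged)
    results = pd.DataFrame(rows)
    results_path = out_dir / "results.csv"
    results.to_csv(results_path, index=False, float_format="%.17g")

    artifacts = {"results": str(results_path)}

    if config.run_wavelets:
        brows = []
        mp = MorletPower()
        for epoch_id, epoch in epochs:
            pm = mp.fit(epoch).transform(epoch)
            for bname in config.wavelet_bands:
                summ = count_events(
                    pm, reg[bname], threshold=config.event_threshold,
                    band_name=bname,
                )
                brows.append(
                    {"epoch_id": epoch_id, "band": bname,
                     "avg_power": band_average(pm, reg[bname]),
                     "event_count": summ.event_count,
                     "event_rate": summ.event_rate}
                )
        band_path = out_dir / "band_summaries.csv"
        pd.DataFrame(brows).to_csv(band_path, index=False, float_format="%.17g")
        artifacts["band_summaries"] = str(band_path)

    # collapsed one-way comparisons across filter conditions
    for response in ("dimension", "volume"):
        usable = results[results["converged"] & ~results["discarded"]]
        if usable["filter_name"].nunique() >= 2 and len(usable) > usable[
            "filter_name"
        ].nunique():
            aov = one_way_filter_anova(usable, response)
            aov_path = out_dir / f"anova_{response}.csv"
            aov.table.to_csv(aov_path, index=False)
            artifacts[f"anova_{response}"] = str(aov_path)
            counts = usable.groupby("filter_name").size()
            if (counts >= 2).sum() >= 2:
                hsd = tukey_hsd(usable, response, "filter_name")
                hsd_path = out_dir / f"tukey_{response}.csv"
                hsd.table.to_csv(hsd_path, index=False)
                artifacts[f"tukey_{response}"] = str(hsd_path)

    qc_path = out_dir / "qc.json"
    qc_path.write_text(json.dumps(qc, indent=2, sort_keys=True))
    artifacts["qc"] = str(qc_path)

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out_dir / "config.json").write_text(config.to_json())
    return manifest


def demo_config(out_dir: str, seed: int = 0) -> RunConfig:
    """The bundled synthetic study: one epoch per canonical geometry plus an
    LFP-like composite, across all ten filter conditions."""
    return RunConfig(
        out_dir=out_dir,
        seed=seed,
        synthetic_epochs=[
            {"kind": "fixed_point", "params": {"n": 2500, "jitter_sd": 1e-3}},
            {"kind": "limit_cycle", "params": {"n": 2500, "freq": 10.0}},
            {"kind": "torus", "params": {"n": 2500}},
            {
                "kind": "lfp_composite",
                "params": {
                    "n": 2500,
                    "burst_spec": [
                        ["theta", 0.4, 0.5, 4.0],
                        ["slow_gamma", 1.4, 0.3, 4.0],
                    ],
                },
            },
        ],
        filters=("all",),
    )
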