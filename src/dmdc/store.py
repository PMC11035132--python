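"""Signal containers and on-disk formats.

A :class:`Trial` is one continuous recording (e.g. an eight-minute maze
exploration) with its factor labels; an :class:`Epoch` is the fixed-duration
analysis window cut from it (2500 ms at 1000 Hz by default, mirroring the
immobility windows used for attractor estimation).

Signals travel as one-column delimited text or raw little-endian float64
binary, with a JSON sidecar carrying at least the sampling rate.  Epoch
tables are delimited text with columns ``trial_id,start_ms,location,
alternation``.  All indexing is 0-based with half-open sample windows.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "Epoch",
    "MetadataError",
    "DataError",
    "read_trial",
    "extract_epochs",
    "write_results",
    "read_results",
    "DEFAULT_EPOCH_MS",
]

DEFAULT_EPOCH_MS = 2500.0

LOCATIONS = ("center", "outer")
ALTERNATIONS = ("alternation", "non_alternation", "n/a")


class MetadataError(ValueError):
    """Sidecar or epoch-table metadata is missing or inconsistent."""


class DataError(ValueError):
    """Signal samples are unusable (non-finite, wrong shape, ...)."""


@dataclasses.dataclass
class Trial:
    """A continuous single-channel recording with factor labels."""

    samples: np.ndarray
    fs: float
    trial_id: str = "trial"
    subject_id: str = ""
    age_group: str = ""
    drug: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise MetadataError(f"fs must be positive, got {self.fs}")
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise DataError(
                f"trial {self.trial_id!r}: non-finite sample at index {bad[0]}"
            )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def labels(self) -> dict[str, Any]:
        return {
            "trial_id": self.trial_id,
            "subject_id": self.subject_id,
            "age_group": self.age_group,
            "drug": self.drug,
        }


@dataclasses.dataclass
class Epoch:
    """A fixed-duration window of samples, the unit of attractor analysis.

    ``location="outer"`` forces ``alternation="n/a"`` (no arm choice is
    pending away from the maze center).  ``ground_truth`` carries synthetic
    generator metadata (true dimension, scheduled events, ...) so that known
    labels round-trip into every downstream result row.
    """

    samples: np.ndarray
    fs: float
    start: float = 0.0
    location: str = "center"
    alternation: str = "n/a"
    labels: dict[str, Any] = dataclasses.field(default_factory=dict)
    ground_truth: dict[str, Any] = dataclasses.field(default_factory=dict)
    warnings: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise MetadataError(f"fs must be positive, got {self.fs}")
        if self.location not in LOCATIONS:
            raise MetadataError(f"unknown location {self.location!r}")
        if self.location == "outer":
            self.alternation = "n/a"
        if self.alternation not in ALTERNATIONS:
            raise MetadataError(f"unknown alternation {self.alternation!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Epoch":
        """Copy of this epoch with new samples and identical labels."""
        return dataclasses.replace(self, samples=np.asarray(samples, float))


def read_trial(signal_path: str | Path, meta_path: str | Path) -> Trial:
    """Load a trial from a signal file plus JSON sidecar.

    The signal file is either one-column delimited text or raw little-endian
    float64 binary; the two are told apart by extension (``.bin``/``.raw``/
    ``.f64`` are binary, everything else text).  The sidecar must contain at
    least ``fs``.
    """
    signal_path, meta_path = Path(signal_path), Path(meta_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    if "fs" not in meta:
        raise MetadataError(f"{meta_path}: sidecar lacks required key 'fs'")
    fs = float(meta["fs"])
    if signal_path.suffix.lower() in (".bin", ".raw", ".f64"):
        samples = np.fromfile(signal_path, dtype="<f8")
    else:
        samples = np.loadtxt(signal_path, dtype=float, ndmin=1)
        if samples.ndim != 1:
            raise DataError(f"{signal_path}: expected one column")
    return Trial(
        samples=samples,
        fs=fs,
        trial_id=str(meta.get("trial_id", signal_path.stem)),
        subject_id=str(meta.get("subject_id", "")),
        age_group=str(meta.get("age_group", "")),
        drug=str(meta.get("drug", "")),
    )


def extract_epochs(
    trial: Trial,
    epoch_table: pd.DataFrame | Sequence[dict] | str | Path,
    duration_ms: float = DEFAULT_EPOCH_MS,
    qc_log: list | None = None,
) -> list[Epoch]:
    """Cut one epoch per table row; out-of-bounds rows are logged, not fatal.

    ``epoch_table`` needs columns ``start_ms``, ``location``, ``alternation``
    (a path to delimited text with a header also works).  Start times are
    milliseconds; conversion to samples rounds to the nearest sample, which
    is lossless at fs = 1000 Hz.  Windows are 0-based and half-open, so
    adjacent epochs re-concatenate to the original trial segment exactly.
    """
    if isinstance(epoch_table, (str, Path)):
        # keep_default_na: "n/a" is a legitimate alternation level, not NaN
        epoch_table = pd.read_csv(epoch_table, keep_default_na=False)
    elif not isinstance(epoch_table, pd.DataFrame):
        epoch_table = pd.DataFrame(list(epoch_table))
    n_window = int(round(duration_ms * trial.fs / 1000.0))
    epochs: list[Epoch] = []
    for row in epoch_table.itertuples(index=True):
        if "trial_id" in epoch_table.columns and str(row.trial_id) != trial.trial_id:
            continue
        start = int(round(float(row.start_ms) * trial.fs / 1000.0))
        stop = start + n_window
        if start < 0 or stop > len(trial.samples):
            if qc_log is not None:
                qc_log.append(
                    {
                        "trial_id": trial.trial_id,
                        "row": row.Index,
                        "start_ms": float(row.start_ms),
                        "reason": "window outside trial bounds",
                    }
                )
            continue
        epochs.append(
            Epoch(
                samples=trial.samples[start:stop],
                fs=trial.fs,
                start=start / trial.fs,
                location=str(getattr(row, "location", "center")),
                alternation=str(getattr(row, "alternation", "n/a")) or "n/a",
                labels=trial.labels(),
            )
        )
    return epochs


def _row_to_dict(row: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(row) and not isinstance(row, type):
        d = dataclasses.asdict(row)
        labels = d.pop("labels", {}) or {}
        d.pop("fit_window", None)
        d.update(labels)
        return d
    if isinstance(row, dict):
        return dict(row)
    raise TypeError(f"unsupported result row type {type(row)!r}")


def write_results(rows: Iterable[Any], out_path: str | Path) -> Path:
    """Write homogeneous result rows as delimited text with a header.

    Floats are written with 17 significant digits so a re-read reproduces
    values to at least 12 significant digits.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to write")
    kinds = {type(r) for r in rows}
    if len(kinds) > 1:
        raise TypeError(f"mixed result row types: {sorted(k.__name__ for k in kinds)}")
    frame = pd.DataFrame([_row_to_dict(r) for r in rows])
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_path, index=False, float_format="%.17g")
    return out_path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
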