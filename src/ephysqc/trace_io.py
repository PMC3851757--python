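"""Plain-text I/O for recordings, label tables, feature tables and model files.

Trace files are CSV with ``#``-prefixed metadata header lines followed by
either a single ``voltage`` column (requires a ``sampling_rate`` header) or
two columns ``time_s,voltage`` from which the sampling rate is inferred.
Voltages are stored in mV after gain correction; time is in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "LabelTable",
    "TraceFormatError",
    "SamplingError",
    "LabelError",
    "LABEL_TO_CODE",
    "CODE_TO_LABEL",
    "read_trace",
    "write_trace",
    "read_labels",
    "write_labels",
    "read_features",
    "write_features",
    "save_json",
    "load_json",
]

LABEL_TO_CODE: dict[str, int] = {"bad": -1, "intermediate": 0, "good": 1}
CODE_TO_LABEL: dict[int, str] = {v: k for k, v in LABEL_TO_CODE.items()}


class TraceFormatError(ValueError):
    """Malformed trace file."""


class SamplingError(TraceFormatError):
    """Non-uniform time column (sample interval varies by more than 1%)."""


class LabelError(ValueError):
    """Unknown label vocabulary or duplicated recording id."""


@dataclass
class Trace:
    """One recording: gain-corrected membrane potential samples in mV.

    Parameters
    ----------
    id : str
        Recording identifier.
    samples : ndarray
        Membrane potential in mV, already multiplied by ``gain``.
    sampling_rate : float
        Samples per second; must be positive.
    gain : float
        Multiplier that was applied at load time to reach the mV scale.
    stim_onset, stim_duration : float, optional
        Stimulus metadata in seconds; not used by the detector.
    """

    id: str
    samples: np.ndarray
    sampling_rate: float
    gain: float = 1.0
    stim_onset: float | None = None
    stim_duration: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"trace {self.id!r} contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n_samples / sampling_rate)."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class LabelTable:
    """Mapping recording id -> quality label ('bad'/'intermediate'/'good')."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, lab in self.labels.items():
            if lab not in LABEL_TO_CODE:
                raise LabelError(f"unknown label {lab!r} for id {rid!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, rid: str) -> str:
        return self.labels[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.labels

    @property
    def ids(self) -> list[str]:
        return list(self.labels)

    def code(self, rid: str) -> int:
        """Numeric encoding: bad = -1, intermediate = 0, good = +1."""
        return LABEL_TO_CODE[self.labels[rid]]

    def codes(self, ids: Iterable[str] | None = None) -> np.ndarray:
        ids = self.ids if ids is None else list(ids)
        return np.array([LABEL_TO_CODE[self.labels[i]] for i in ids], dtype=int)

    def counts(self) -> dict[str, int]:
        out = {"bad": 0, "intermediate": 0, "good": 0}
        for lab in self.labels.values():
            out[lab] += 1
        return out


def _parse_header(lines: list[str]) -> tuple[dict[str, str], int]:
    """Split '#'-prefixed `key: value` metadata lines off the top of a file."""
    meta: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if not stripped.startswith("#"):
            break
        body = stripped.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    else:
        i = len(lines)
    return meta, i


def read_trace(path: str | Path, gain: float | None = None) -> Trace:
    """Read a trace file and apply the gain factor.

    If ``gain`` is None the header's ``gain`` entry is used (default 1).
    One-column files require a ``sampling_rate`` header; two-column files
    infer the rate from the median time step and reject time columns whose
    step varies by more than 1%.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, start = _parse_header(lines)
    if gain is None:
        gain = float(meta.get("gain", 1.0))

    body = lines[start:]
    # optional non-numeric column-name line
    data_start = start
    if body and not _is_numeric_row(body[0]):
        data_start += 1
        body = body[1:]

    rows: list[list[float]] = []
    ncol: int | None = None
    for offset, line in enumerate(body):
        if not line.strip():
            continue
        parts = [p for p in line.replace("\t", ",").split(",")]
        try:
            values = [float(p) for p in parts]
        except ValueError as exc:
            raise TraceFormatError(
                f"{path}: cannot parse line {data_start + offset + 1}: {line!r}"
            ) from exc
        if ncol is None:
            ncol = len(values)
            if ncol not in (1, 2):
                raise TraceFormatError(
                    f"{path}: expected 1 or 2 columns, got {ncol} "
                    f"on line {data_start + offset + 1}"
                )
        elif len(values) != ncol:
            raise TraceFormatError(
                f"{path}: inconsistent column count on line {data_start + offset + 1}"
            )
        rows.append(values)

    if len(rows) < 2:
        raise TraceFormatError(f"{path}: need at least 2 samples")

    arr = np.asarray(rows, dtype=float)
    if ncol == 2:
        t, v = arr[:, 0], arr[:, 1]
        dt = np.diff(t)
        med = float(np.median(dt))
        if med <= 0:
            raise SamplingError(f"{path}: time column is not increasing")
        if np.any(np.abs(dt - med) > 0.01 * med):
            raise SamplingError(f"{path}: time step varies by more than 1%")
        rate = 1.0 / med
    else:
        v = arr[:, 0]
        if "sampling_rate" not in meta:
            raise TraceFormatError(
                f"{path}: one-column trace requires a '# sampling_rate:' header"
            )
        rate = float(meta["sampling_rate"])

    return Trace(
        id=meta.get("id", path.stem),
        samples=v * gain,
        sampling_rate=rate,
        gain=gain,
        stim_onset=float(meta["stim_onset"]) if "stim_onset" in meta else None,
        stim_duration=float(meta["stim_duration"]) if "stim_duration" in meta else None,
    )


def _is_numeric_row(line: str) -> bool:
    parts = line.replace("\t", ",").split(",")
    try:
        [float(p) for p in parts]
        return True
    except ValueError:
        return False


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as a one-column file; samples are already gain-corrected,
    so the stored gain is 1 and a read round-trips exactly."""
    path = Path(path)
    lines = [f"# id: {trace.id}", f"# sampling_rate: {trace.sampling_rate!r}", "# gain: 1.0"]
    if trace.stim_onset is not None:
        lines.append(f"# stim_onset: {trace.stim_onset!r}")
    if trace.stim_duration is not None:
        lines.append(f"# stim_duration: {trace.stim_duration!r}")
    lines.append("voltage")
    lines.extend(repr(float(v)) for v in trace.samples)
    path.write_text("\n".join(lines) + "\n")


def read_labels(path: str | Path) -> LabelTable:
    """Read an ``id,label`` CSV; labels are case-insensitive, duplicates error."""
    path = Path(path)
    labels: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if lineno == 1 and stripped.lower().replace(" ", "") in ("id,label",):
            continue
        parts = [p.strip() for p in stripped.split(",")]
        if len(parts) != 2:
            raise LabelError(f"{path}: expected 'id,label' on line {lineno}")
        rid, lab = parts[0], parts[1].lower()
        if lab not in LABEL_TO_CODE:
            raise LabelError(f"{path}: unknown label {parts[1]!r} on line {lineno}")
        if rid in labels:
            raise LabelError(f"{path}: duplicate id {rid!r} on line {lineno}")
        labels[rid] = lab
    return LabelTable(labels)


def write_labels(table: LabelTable, path: str | Path) -> None:
    lines = ["id,label"] + [f"{rid},{lab}" for rid, lab in table.labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV into a DataFrame indexed by recording id."""
    df = pd.read_csv(path)
    return df.set_index("id")


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (index = id, 16 named columns) as CSV."""
    table.to_csv(path, index_label="id")


def save_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
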