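"""File I/O and run configuration.

Formats (all plain text):

* **Trace CSV** — two columns ``time_s,voltage_v``, optional single
  header line, decimal point, no thousands separators.
* **Pulse-table CSV/JSON** — records with ``amplitude`` (signed,
  normalised volts) and ``duration_s`` fields; JSON is a list of objects.
* **Config YAML** — flat schema, SI units (Hz, s, V); see
  :class:`RunConfig`.

Writes use 15 significant digits so a write/read round-trip is lossless
at double precision for all practical purposes.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coil_model import PulseSegment, PulseTrain, Trace

__all__ = [
    "TraceFormatError",
    "TrainFormatError",
    "read_trace",
    "write_trace",
    "read_train",
    "write_train",
    "RunConfig",
]

_FLOAT_FMT = "%.15g"


class TraceFormatError(ValueError):
    """Malformed trace file."""


class TrainFormatError(ValueError):
    """Malformed pulse-table file."""


def _first_bad_line(path: Path, n_cols: int) -> int | None:
    """1-based line number of the first row that does not parse as floats."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1:
                # a header line is allowed
                try:
                    [float(p) for p in parts]
                except ValueError:
                    continue
            if len(parts) != n_cols:
                return lineno
            try:
                [float(p) for p in parts]
            except ValueError:
                return lineno
    return None


def _read_two_column_csv(path: str | Path, what: str, err):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # header sniff: does the first line parse as numbers?
    with open(path) as fh:
        first = fh.readline()
    try:
        [float(p) for p in first.strip().split(",")]
        header = None
    except ValueError:
        header = 0
    try:
        df = pd.read_csv(path, header=header, dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        bad = _first_bad_line(path, 2)
        where = f" (line {bad})" if bad else ""
        raise err(f"malformed {what} file {path}{where}: {exc}") from exc
    if df.shape[1] != 2:
        raise err(f"{what} file {path} must have exactly 2 columns, found {df.shape[1]}")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 1 + (1 if header == 0 else 0)
        raise err(f"malformed {what} file {path} (line {bad}): non-numeric or missing value")
    return df


def read_trace(path: str | Path) -> Trace:
    """Read a two-column ``time_s,voltage_v`` CSV into a :class:`Trace`.

    Raises
    ------
    TraceFormatError
        On malformed rows (with the line number) or a non-uniform /
        non-monotonic time grid.
    """
    df = _read_two_column_csv(path, "trace", TraceFormatError)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if len(t) < 2:
        raise TraceFormatError(f"trace file {path} needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        k = int(np.argmax(dt <= 0))
        raise TraceFormatError(
            f"trace file {path}: time column not strictly increasing near row {k + 1}"
        )
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > 1e-6 * step):
        raise TraceFormatError(f"trace file {path}: time grid is not uniform")
    return Trace(t=t, v=v, rate=1.0 / step, meta={"source": str(path)})


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a :class:`Trace` as ``time_s,voltage_v`` CSV (15 significant digits)."""
    df = pd.DataFrame({"time_s": trace.t, "voltage_v": trace.v})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_train(path: str | Path) -> PulseTrain:
    """Read a pulse table (CSV with ``amplitude,duration_s`` columns, or JSON).

    Zero or negative segment durations are rejected: they cannot
    represent a physical drive interval in a stored pulse table.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            records = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise TrainFormatError(f"malformed JSON pulse table {path}: {exc}") from exc
        if not isinstance(records, list):
            raise TrainFormatError(f"pulse table {path} must be a JSON list of objects")
        try:
            segs = [(float(r["amplitude"]), float(r["duration_s"])) for r in records]
        except (KeyError, TypeError, ValueError) as exc:
            raise TrainFormatError(
                f"pulse table {path}: each record needs numeric "
                f"'amplitude' and 'duration_s' fields ({exc})"
            ) from exc
    else:
        df = _read_two_column_csv(path, "pulse table", TrainFormatError)
        segs = list(zip(df.iloc[:, 0].astype(float), df.iloc[:, 1].astype(float)))
    for k, (amp, dur) in enumerate(segs):
        if not math.isfinite(amp):
            raise TrainFormatError(f"pulse table {path}: segment {k + 1} amplitude not finite")
        if not dur > 0:
            raise TrainFormatError(
                f"pulse table {path}: segment {k + 1} has non-positive duration {dur:g}"
            )
    return PulseTrain(tuple(PulseSegment(a, d) for a, d in segs))


def write_train(train: PulseTrain, path: str | Path) -> None:
    """Write a pulse table as CSV or JSON, chosen by the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(train.to_records(), indent=2) + "\n")
    else:
        df = pd.DataFrame(train.to_records())[["amplitude", "duration_s"]]
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass
class RunConfig:
    """Flat run configuration (SI units: Hz, s, V).

    Attributes
    ----------
    f_r, q : float
        Coil resonance frequency and quality factor.
    rate : float
        Trace sample rate, samples/s.
    pad_factor : int
        FFT zero-padding multiple for spectra.
    overdrive : float
        Square-pulse pre-emphasis/damping amplitude ratio V0/V1.
    max_amplitude : float or None
        Amplifier ceiling for compensation trains (warning only).
    seed : int
        Seed for every stochastic generator in a run.
    log_level : str
        Python logging level name.
    """

    f_r: float = 1e6
    q: float = 49.83
    rate: float = 50e6
    pad_factor: int = 16
    overdrive: float = 3.0
    max_amplitude: float | None = None
    seed: int = 0
    log_level: str = "INFO"
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (for run logging)."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
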