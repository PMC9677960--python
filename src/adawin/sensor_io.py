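"""Reading, writing and validating inertial sensor logs and behavior label tracks.

Sensor logs are delimited text (comma separator, header row, ``.`` decimal),
one record per sample: timestamp, hardware counter, three acceleration axes
(m/s^2) and three angular-velocity axes (deg/s).  Missing cells are empty
fields and become NaN in memory.  Label tracks are CSV rows of
``start_s,end_s,label`` half-open intervals drawn from the ethogram
vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Behavior vocabulary of the ethogram (four analysed classes plus the
#: minor classes excluded from modelling and the out-of-sight marker).
BEHAVIOR_VOCABULARY = (
    "eating",
    "lying",
    "walking",
    "standing",
    "playing",
    "drinking",
    "sitting",
    "unknown",
)

#: Classes retained for classification by default; the minor classes and
#: "unknown" are excluded from the analysis.
DEFAULT_CLASSES = ("eating", "lying", "walking", "standing")

#: Default column layout of a sensor log.
DEFAULT_SCHEMA = {
    "ts": "ts",
    "counter": "counter",
    "ax": "ax",
    "ay": "ay",
    "az": "az",
    "gx": "gx",
    "gy": "gy",
    "gz": "gz",
}

_CHANNEL_KEYS = ("ax", "ay", "az", "gx", "gy", "gz")


class SchemaError(ValueError):
    """A required column is missing from a sensor log."""


class EmptyInputError(ValueError):
    """The input file contains no data rows."""


class IntervalOverlapError(ValueError):
    """Two label intervals overlap."""


class VocabularyError(ValueError):
    """A label is not in the behavior vocabulary."""


class InsufficientDataError(ValueError):
    """Too few samples/finite values for the requested operation."""


@dataclass
class SensorStream:
    """A time-ordered 6-channel inertial record for one animal/session.

    ``acc`` and ``gyro`` are ``(n, 3)`` float arrays (x, y, z columns);
    missing values are NaN.  After preprocessing the sample index, not the
    timestamp, is the canonical time axis.
    """

    timestamps: np.ndarray
    counters: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    sample_rate: float = 10.0
    animal_id: str = "animal0"
    session_id: str = "session0"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.counters = np.asarray(self.counters, dtype=np.int64)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.timestamps)
        if not (len(self.counters) == n and self.acc.shape == (n, 3) and self.gyro.shape == (n, 3)):
            raise ValueError("per-sample arrays must share length n and be n x 3")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        finite = self.timestamps[np.isfinite(self.timestamps)]
        if finite.size and np.any(np.diff(finite) < -1e-12):
            # tolerated at construction; validate_stream reports regressions
            pass

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    def channels(self) -> dict[str, np.ndarray]:
        """Views of the six raw channels keyed by name."""
        return {
            "ax": self.acc[:, 0],
            "ay": self.acc[:, 1],
            "az": self.acc[:, 2],
            "gx": self.gyro[:, 0],
            "gy": self.gyro[:, 1],
            "gz": self.gyro[:, 2],
        }

    def copy(self) -> "SensorStream":
        return replace(
            self,
            timestamps=self.timestamps.copy(),
            counters=self.counters.copy(),
            acc=self.acc.copy(),
            gyro=self.gyro.copy(),
        )


@dataclass
class LabelTrack:
    """Non-overlapping behavior intervals ``[start_s, end_s)`` over a stream."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda t: (t[0], t[1]))
        for start, end, label in ivs:
            if label not in BEHAVIOR_VOCABULARY:
                raise VocabularyError(
                    f"unknown behavior label {label!r}; expected one of {BEHAVIOR_VOCABULARY}"
                )
            if not start < end:
                raise ValueError(f"interval ({start}, {end}) must satisfy start < end")
        for (s0, e0, l0), (s1, e1, l1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise IntervalOverlapError(
                    f"intervals ({s0}, {e0}, {l0!r}) and ({s1}, {e1}, {l1!r}) overlap"
                )
        self.intervals = [(float(s), float(e), l) for s, e, l in ivs]

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def end_s(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0

    def labels_per_sample(self, n: int, rate: float) -> np.ndarray:
        """Label of each sample index (sample i covers time i/rate), '' if uncovered."""
        out = np.full(n, "", dtype=object)
        for start, end, label in self.intervals:
            i0 = max(0, int(np.ceil(start * rate - 1e-9)))
            i1 = min(n, int(np.ceil(end * rate - 1e-9)))
            if i1 > i0:
                out[i0:i1] = label
        return out


@dataclass
class ValidityReport:
    """Counts and locations of counter/timestamp anomalies in a stream."""

    n_counter_gaps: int
    n_timestamp_regressions: int
    n_duplicate_counters: int
    gap_locations: list[int]
    regression_locations: list[int]
    duplicate_locations: list[int]

    @property
    def is_clean(self) -> bool:
        return (
            self.n_counter_gaps == 0
            and self.n_timestamp_regressions == 0
            and self.n_duplicate_counters == 0
        )


def read_sensor_stream(
    path: str | Path,
    schema: dict[str, str] | None = None,
    sample_rate: float = 10.0,
    animal_id: str = "animal0",
    session_id: str = "session0",
) -> SensorStream:
    """Read a delimited sensor log into a :class:`SensorStream`.

    Unparseable numeric cells become NaN; rows keep file order.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    missing = [k for k in DEFAULT_SCHEMA if k not in schema]
    if missing:
        raise SchemaError(f"schema is missing required keys: {missing}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} contains no data") from exc
    if frame.empty:
        raise EmptyInputError(f"{path} contains no data rows")
    absent = [schema[k] for k in DEFAULT_SCHEMA if schema[k] not in frame.columns]
    if absent:
        raise SchemaError(f"required columns not found in {path}: {absent}")

    def col(key: str) -> np.ndarray:
        return pd.to_numeric(frame[schema[key]], errors="coerce").to_numpy(dtype=float)

    counters = pd.to_numeric(frame[schema["counter"]], errors="coerce")
    if counters.isna().any():
        raise SchemaError("counter column contains non-integer cells")
    acc = np.column_stack([col("ax"), col("ay"), col("az")])
    gyro = np.column_stack([col("gx"), col("gy"), col("gz")])
    if "animal_id" in frame.columns:
        animal_id = str(frame["animal_id"].iloc[0])
    if "session_id" in frame.columns:
        session_id = str(frame["session_id"].iloc[0])
    return SensorStream(
        timestamps=col("ts"),
        counters=counters.to_numpy(dtype=np.int64),
        acc=acc,
        gyro=gyro,
        sample_rate=sample_rate,
        animal_id=animal_id,
        session_id=session_id,
    )


def write_sensor_stream(stream: SensorStream, path: str | Path) -> None:
    """Write a stream as CSV (missing cells as empty fields); round-trips read."""
    frame = pd.DataFrame(
        {
            "ts": stream.timestamps,
            "counter": stream.counters,
            "ax": stream.acc[:, 0],
            "ay": stream.acc[:, 1],
            "az": stream.acc[:, 2],
            "gx": stream.gyro[:, 0],
            "gy": stream.gyro[:, 1],
            "gz": stream.gyro[:, 2],
            "animal_id": stream.animal_id,
            "session_id": stream.session_id,
        }
    )
    frame.to_csv(path, index=False, float_format="%.12g", na_rep="")


def read_label_track(path: str | Path) -> LabelTrack:
    """Read a ``start_s,end_s,label`` CSV into a validated :class:`LabelTrack`."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} contains no data") from exc
    needed = {"start_s", "end_s", "label"}
    if not needed.issubset(frame.columns):
        raise SchemaError(f"label track must have columns {sorted(needed)}")
    intervals = [
        (float(r.start_s), float(r.end_s), str(r.label)) for r in frame.itertuples(index=False)
    ]
    return LabelTrack(intervals=intervals)


def write_label_track(track: LabelTrack, path: str | Path) -> None:
    frame = pd.DataFrame(track.intervals, columns=["start_s", "end_s", "label"])
    frame.to_csv(path, index=False, float_format="%.12g")


def validate_stream(stream: SensorStream, counter_bits: int = 16) -> ValidityReport:
    """Check stream integrity via the hardware counter and the timestamp.

    A counter gap is an adjacent pair whose increment differs from 1 modulo
    ``2**counter_bits`` (so wraparound is not a gap); an increment of 0 is a
    duplicate.  A timestamp regression is an adjacent pair with decreasing
    timestamp.  Locations index the second element of the offending pair.
    """
    if len(stream) < 2:
        raise InsufficientDataError("stream validation needs at least 2 samples")
    modulus = 1 << counter_bits
    inc = np.mod(np.diff(stream.counters), modulus)
    dup_idx = np.flatnonzero(inc == 0) + 1
    gap_idx = np.flatnonzero((inc != 1) & (inc != 0)) + 1
    dts = np.diff(stream.timestamps)
    reg_idx = np.flatnonzero(dts < 0) + 1
    return ValidityReport(
        n_counter_gaps=int(gap_idx.size),
        n_timestamp_regressions=int(reg_idx.size),
        n_duplicate_counters=int(dup_idx.size),
        gap_locations=gap_idx.tolist(),
        regression_locations=reg_idx.tolist(),
        duplicate_locations=dup_idx.tolist(),
    )
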