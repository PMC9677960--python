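"""Sensor-stream cleaning: IQR-fence outlier censoring, gap filling, min-max scaling.

A sample is treated as an outlier when it lies outside the Tukey fences of
its channel *and* beyond the sensor's physical measurement range (the
accelerometer saturates at 16 g = 156.96 m/s^2, the gyroscope at
+/-2000 deg/s).  Censored samples become NaN, NaN runs are filled by linear
interpolation, and each animal's channels are finally scaled to [0, 1] so
data from different animals and sessions can be pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .sensor_io import InsufficientDataError, SensorStream

GRAVITY = 9.81


@dataclass(frozen=True)
class PhysicalRanges:
    """Hard measurement bounds of the IMU (absolute values)."""

    acc_abs_max: float = 16 * GRAVITY  # 156.96 m/s^2
    gyro_abs_max: float = 2000.0  # deg/s

    def __post_init__(self) -> None:
        if self.acc_abs_max <= 0 or self.gyro_abs_max <= 0:
            raise ValueError("physical ranges must be positive")


@dataclass(frozen=True)
class Fences:
    """Tukey fences of one channel: [q1 - k*IQR, q3 + k*IQR]."""

    lower: float
    upper: float
    q1: float
    q3: float
    multiplier: float = 1.5

    def __post_init__(self) -> None:
        if not (self.lower <= self.q1 <= self.q3 <= self.upper):
            raise ValueError("fences must satisfy lower <= q1 <= q3 <= upper")


def _finite(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def iqr_fences(x: np.ndarray, multiplier: float = 1.5) -> Fences:
    """Tukey fences of a vector, ignoring missing values.

    Quantiles use linear interpolation between closest order statistics at
    position ``(m - 1) * q`` over the ``m`` finite values (numpy's default),
    pinned here for reproducibility.
    """
    vals = _finite(x)
    if vals.size < 4:
        raise InsufficientDataError(
            f"IQR fences need at least 4 finite values, got {vals.size}"
        )
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    iqr = q3 - q1
    return Fences(
        lower=float(q1 - multiplier * iqr),
        upper=float(q3 + multiplier * iqr),
        q1=float(q1),
        q3=float(q3),
        multiplier=multiplier,
    )


def censor_outliers(
    stream: SensorStream,
    ranges: PhysicalRanges | None = None,
    multiplier: float = 1.5,
    rule: str = "and",
) -> SensorStream:
    """Replace outlier samples with NaN, channel by channel.

    ``rule='and'`` (default) censors a sample only when it is outside the
    channel's IQR fence *and* beyond the physical range — the physical range
    is the sensor's saturation bound, so in practice this flags corrupted
    records while never touching plausible motion.  ``rule='or'`` censors on
    either condition (fence-only violations included), for sensitivity
    analysis.  Fences are computed per channel over the session.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    if ranges is None:
        ranges = PhysicalRanges()
    out = stream.copy()
    for name, x in out.channels().items():
        finite = np.isfinite(x)
        if finite.sum() < 4:
            continue
        fences = iqr_fences(x, multiplier)
        abs_max = ranges.acc_abs_max if name.startswith("a") else ranges.gyro_abs_max
        outside_fence = finite & ((x < fences.lower) | (x > fences.upper))
        beyond_range = finite & (np.abs(x) > abs_max)
        flag = (outside_fence & beyond_range) if rule == "and" else (outside_fence | beyond_range)
        x[flag] = np.nan  # channels() returns views into out
    return out


def fill_missing(x: np.ndarray) -> np.ndarray:
    """Fill NaN runs by linear interpolation; hold the nearest value at the edges."""
    x = np.asarray(x, dtype=float).copy()
    finite = np.isfinite(x)
    if not finite.any():
        raise InsufficientDataError("cannot interpolate an all-missing vector")
    if finite.all():
        return x
    idx = np.arange(x.size)
    x[~finite] = np.interp(idx[~finite], idx[finite], x[finite])
    return x


def normalize_minmax(stream: SensorStream, grouping: str = "per-animal") -> SensorStream:
    """Scale each channel to [0, 1] via (x - min) / (max - min).

    A :class:`SensorStream` holds one animal's session, so 'per-animal' and
    'global' coincide at this level; the distinction matters when pooling
    streams (see :func:`normalize_streams`).  Constant channels map to 0.
    Run after :func:`fill_missing` — NaNs would poison min/max.
    """
    if grouping not in ("per-animal", "global"):
        raise ValueError("grouping must be 'per-animal' or 'global'")
    out = stream.copy()
    for x in out.channels().values():
        _scale_inplace(x)
    return out


def _scale_inplace(x: np.ndarray, lo: float | None = None, hi: float | None = None) -> None:
    if x.size == 0:
        return
    lo = float(np.min(x)) if lo is None else lo
    hi = float(np.max(x)) if hi is None else hi
    if hi > lo:
        x -= lo
        x /= hi - lo
    else:
        x[:] = 0.0


def normalize_streams(streams: list[SensorStream], grouping: str = "per-animal") -> list[SensorStream]:
    """Min-max scale a collection of streams, grouped per animal or globally."""
    if grouping not in ("per-animal", "global"):
        raise ValueError("grouping must be 'per-animal' or 'global'")
    outs = [s.copy() for s in streams]
    if grouping == "per-animal":
        groups: dict[str, list[SensorStream]] = {}
        for s in outs:
            groups.setdefault(s.animal_id, []).append(s)
        pools = groups.values()
    else:
        pools = [outs]
    for pool in pools:
        for name in ("ax", "ay", "az", "gx", "gy", "gz"):
            allvals = np.concatenate([s.channels()[name] for s in pool])
            lo, hi = float(np.min(allvals)), float(np.max(allvals))
            for s in pool:
                _scale_inplace(s.channels()[name], lo, hi)
    return outs


class StreamPreprocessor(BaseEstimator, TransformerMixin):
    """Censor -> interpolate -> min-max scale, as a sklearn-style transformer.

    Parameters
    ----------
    iqr_multiplier : float, default 1.5
        Tukey fence multiplier k in [q1 - k*IQR, q3 + k*IQR].
    rule : {'and', 'or'}, default 'and'
        Conjunction ('and') or disjunction ('or') of the fence and
        physical-range outlier conditions.
    ranges : PhysicalRanges, optional
        Sensor saturation bounds; defaults to 16 g / 2000 deg/s.
    grouping : {'per-animal', 'global'}, default 'per-animal'
        Pooling unit for the final min-max scaling.

    Attributes
    ----------
    fences_ : dict[str, Fences]
        Per-channel fences computed from the stream passed to :meth:`fit`.
    """

    def __init__(
        self,
        iqr_multiplier: float = 1.5,
        rule: str = "and",
        ranges: PhysicalRanges | None = None,
        grouping: str = "per-animal",
    ):
        self.iqr_multiplier = iqr_multiplier
        self.rule = rule
        self.ranges = ranges
        self.grouping = grouping

    def fit(self, stream: SensorStream, y=None) -> "StreamPreprocessor":
        self.fences_ = {
            name: iqr_fences(x, self.iqr_multiplier)
            for name, x in stream.channels().items()
            if np.isfinite(x).sum() >= 4
        }
        return self

    def transform(self, stream: SensorStream) -> SensorStream:
        out = censor_outliers(
            stream,
            ranges=self.ranges,
            multiplier=self.iqr_multiplier,
            rule=self.rule,
        )
        for name, x in out.channels().items():
            x[:] = fill_missing(x)
        return normalize_minmax(out, grouping=self.grouping)

    def fit_transform(self, stream: SensorStream, y=None) -> SensorStream:
        return self.fit(stream).transform(stream)


def preprocess_stream(
    stream: SensorStream,
    iqr_multiplier: float = 1.5,
    rule: str = "and",
    ranges: PhysicalRanges | None = None,
) -> SensorStream:
    """One-call censor -> fill -> normalize (thin wrapper over the transformer)."""
    return StreamPreprocessor(
        iqr_multiplier=iqr_multiplier, rule=rule, ranges=ranges
    ).fit_transform(stream)
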