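"""Per-window feature extraction in the time and frequency domains.

Each window yields 14 statistics per channel per domain over 8 channels
(the six raw axes plus the acceleration and angular-velocity magnitude
vectors), for 14 x 8 x 2 = 224 core features, plus the accelerometer pitch
and roll angles.  Conventions that must be pinned for reproducibility:

* standard deviation uses denominator n - 1;
* IQR quantiles interpolate linearly at position (m - 1) * q;
* positive/negative counts are of mean-centered samples strictly >0 / <0
  (min-max normalized inputs are non-negative, so raw-sign counts would be
  degenerate);
* skewness is the bias-uncorrected standardized third moment, kurtosis the
  excess standardized fourth moment (0 for a normal distribution);
* the zero-crossing count is over adjacent sign changes of the mean-centered
  signal, zeros inheriting the previous nonzero sign;
* the spectrum is the one-sided rfft magnitude of the mean-removed window
  with the DC bin excluded (length floor(ws/2)); no further scaling, so
  sum_k w_k S_k^2 = ws * SSE with w_k = 2 except 1 at the Nyquist bin.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .sensor_io import InsufficientDataError, SensorStream
from .segmentation import SegmentSet

STATISTIC_NAMES = (
    "mean",
    "sd",
    "max",
    "min",
    "iqr",
    "range",
    "pos_count",
    "neg_count",
    "skewness",
    "kurtosis",
    "zero_cross",
    "sse",
    "abs_sum_changes",
    "l2norm",
)

CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz", "acc_mag", "gyro_mag")

DOMAIN_NAMES = ("time", "freq")


@dataclass(frozen=True)
class FeatureRegistry:
    """Which statistics, channels and domains make up the feature vector."""

    statistics: tuple[str, ...] = STATISTIC_NAMES
    channels: tuple[str, ...] = CHANNEL_NAMES
    domains: tuple[str, ...] = DOMAIN_NAMES
    include_orientation: bool = True

    def __post_init__(self) -> None:
        for s in self.statistics:
            if s not in STATISTIC_NAMES:
                raise ValueError(f"unknown statistic {s!r}")
        for c in self.channels:
            if c not in CHANNEL_NAMES:
                raise ValueError(f"unknown channel {c!r}")
        for d in self.domains:
            if d not in DOMAIN_NAMES:
                raise ValueError(f"unknown domain {d!r}")

    @property
    def feature_names(self) -> list[str]:
        names = [
            f"{ch}_{dom}_{st}"
            for dom in self.domains
            for ch in self.channels
            for st in self.statistics
        ]
        if self.include_orientation:
            names += ["pitch", "roll"]
        return names

    @property
    def size(self) -> int:
        return len(self.feature_names)

    @property
    def config_hash(self) -> str:
        key = "|".join((*self.statistics, *self.channels, *self.domains, str(self.include_orientation)))
        return hashlib.md5(key.encode()).hexdigest()[:12]


@dataclass
class FeatureTable:
    """Windows x features matrix with labels and provenance.

    ``frame`` has columns window_start, window_end, label, then one column
    per registry feature in registry order.
    """

    frame: pd.DataFrame
    ws: int
    ss: int
    registry_hash: str

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("window_start", "window_end", "label")]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, ws: int = 0, ss: int = 0, registry_hash: str = "") -> "FeatureTable":
        return cls(frame=pd.read_csv(path), ws=ws, ss=ss, registry_hash=registry_hash)


def _stats_matrix(W: np.ndarray) -> np.ndarray:
    """The 14 statistics of each row of ``W`` (k windows x m samples) -> (k, 14)."""
    W = np.asarray(W, dtype=float)
    k, m = W.shape
    if m < 2:
        raise InsufficientDataError("statistics need vectors of length >= 2")
    mean = W.mean(axis=1)
    centered = W - mean[:, None]
    m2 = np.mean(centered**2, axis=1)
    sse = m2 * m
    sd = np.sqrt(sse / (m - 1))
    q1, q3 = np.quantile(W, [0.25, 0.75], axis=1)
    wmax = W.max(axis=1)
    wmin = W.min(axis=1)
    pos = np.count_nonzero(centered > 0, axis=1)
    neg = np.count_nonzero(centered < 0, axis=1)
    safe_m2 = np.where(m2 > 0, m2, 1.0)
    skew = np.where(m2 > 0, np.mean(centered**3, axis=1) / safe_m2**1.5, 0.0)
    kurt = np.where(m2 > 0, np.mean(centered**4, axis=1) / safe_m2**2 - 3.0, 0.0)
    # zero crossings of the centered signal; zeros inherit the previous nonzero sign
    signs = np.sign(centered)
    prev = signs[:, 0].copy()
    zc = np.zeros(k, dtype=np.int64)
    for j in range(1, m):
        cur = signs[:, j]
        zc += ((cur != 0) & (prev != 0) & (cur != prev)).astype(np.int64)
        nz = cur != 0
        prev[nz] = cur[nz]
    asc = np.sum(np.abs(np.diff(W, axis=1)), axis=1)
    l2 = np.sqrt(np.sum(W**2, axis=1))
    return np.column_stack(
        [mean, sd, wmax, wmin, q3 - q1, wmax - wmin, pos, neg, skew, kurt, zc, sse, asc, l2]
    )


def channel_statistics(x: np.ndarray) -> dict[str, float]:
    """The 14 named statistics of one vector (length >= 2)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    row = _stats_matrix(x[None, :])[0]
    return dict(zip(STATISTIC_NAMES, row.tolist()))


def magnitude_spectrum(x: np.ndarray) -> np.ndarray:
    """One-sided magnitude spectrum of the mean-removed signal, DC excluded.

    Length is floor(len(x)/2); element i corresponds to FFT bin i + 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("spectrum needs length >= 2")
    X = np.fft.rfft(x - x.mean())
    return np.abs(X[1 : x.size // 2 + 1])


def pitch_roll(acc: np.ndarray) -> tuple[float, float]:
    """Window pitch and roll, in degrees, from triaxial acceleration.

    Pitch is the inclination of the x axis against the YZ plane,
    atan2(ax, sqrt(ay^2 + az^2)); roll the inclination of the y axis,
    atan2(ay, sqrt(ax^2 + az^2)).  Per-sample angles (range +/-90 deg, so no
    circular wrap) are averaged; all-zero samples are skipped, and a window
    of only zero samples reports 0.
    """
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    norms = np.linalg.norm(acc, axis=1)
    ok = norms > 0
    if not ok.any():
        return 0.0, 0.0
    a = acc[ok]
    pitch = np.degrees(np.arctan2(a[:, 0], np.hypot(a[:, 1], a[:, 2])))
    roll = np.degrees(np.arctan2(a[:, 1], np.hypot(a[:, 0], a[:, 2])))
    return float(pitch.mean()), float(roll.mean())


def _window_matrix(x: np.ndarray, starts: np.ndarray, ws: int) -> np.ndarray:
    return x[starts[:, None] + np.arange(ws)[None, :]]


def featurize(
    segments: SegmentSet,
    stream: SensorStream,
    registry: FeatureRegistry | None = None,
) -> FeatureTable:
    """Compute the registry's feature vector for every window of a segment set."""
    if registry is None:
        registry = FeatureRegistry()
    ws = segments.spec.ws
    if ws < 2:
        raise InsufficientDataError("windows must span at least 2 samples")
    if "freq" in registry.domains and ws < 4:
        raise InsufficientDataError("frequency-domain features need windows of >= 4 samples")
    starts = np.fromiter((w[0] for w in segments.windows), dtype=np.int64, count=len(segments))
    raw = stream.channels()
    chans: dict[str, np.ndarray] = {}
    k = len(segments)
    for name in registry.channels:
        if name == "acc_mag":
            chans[name] = np.linalg.norm(stream.acc, axis=1)
        elif name == "gyro_mag":
            chans[name] = np.linalg.norm(stream.gyro, axis=1)
        else:
            chans[name] = raw[name]
    stat_idx = [STATISTIC_NAMES.index(s) for s in registry.statistics]
    blocks: list[np.ndarray] = []
    for dom in registry.domains:
        for name in registry.channels:
            if k == 0:
                blocks.append(np.empty((0, len(stat_idx))))
                continue
            W = _window_matrix(chans[name], starts, ws)
            if dom == "freq":
                X = np.fft.rfft(W - W.mean(axis=1, keepdims=True), axis=1)
                W = np.abs(X[:, 1 : ws // 2 + 1])
            blocks.append(_stats_matrix(W)[:, stat_idx])
    columns = registry.feature_names
    core = np.hstack(blocks) if blocks else np.empty((k, 0))
    if registry.include_orientation:
        angles = np.empty((k, 2))
        for i, s in enumerate(starts):
            angles[i] = pitch_roll(stream.acc[s : s + ws])
        core = np.hstack([core, angles]) if core.size or k == 0 else angles
    frame = pd.DataFrame(core, columns=columns)
    frame.insert(0, "label", [w[2] for w in segments.windows])
    frame.insert(0, "window_end", [w[1] for w in segments.windows])
    frame.insert(0, "window_start", [w[0] for w in segments.windows])
    return FeatureTable(
        frame=frame, ws=segments.spec.ws, ss=segments.spec.ss, registry_hash=registry.config_hash
    )


class FeatureExtractor(BaseEstimator):
    """Registry-driven window featurizer as a sklearn-style transformer."""

    def __init__(self, registry: FeatureRegistry | None = None):
        self.registry = registry

    def fit(self, segments: SegmentSet, stream: SensorStream | None = None) -> "FeatureExtractor":
        return self

    def transform(self, segments: SegmentSet, stream: SensorStream) -> FeatureTable:
        return featurize(segments, stream, registry=self.registry)
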