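"""Sliding-window segmentation of labeled sensor streams.

A window of WS samples is advanced by SS samples at a time; a window gets
the behavior label covering the majority of its samples, gated by a purity
threshold so that windows straddling bout boundaries are not mislabeled as
a single behavior.  All indices are sample-counted; seconds are converted
at the stream's sampling rate (10 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .sensor_io import DEFAULT_CLASSES, LabelTrack, SensorStream

#: Ascending time-share order of the ethogram (rarest first) used to break
#: majority-coverage ties in favour of the rarer behavior.
RARITY_ORDER = (
    "sitting",
    "playing",
    "drinking",
    "standing",
    "unknown",
    "walking",
    "lying",
    "eating",
)


@dataclass(frozen=True)
class WindowSpec:
    """Window size and step size, in samples."""

    ws: int
    ss: int

    def __post_init__(self) -> None:
        if self.ws < 2:
            raise ValueError("window size must be >= 2 samples")
        if self.ss < 1:
            raise ValueError("step size must be >= 1 sample")

    @classmethod
    def from_seconds(cls, ws_s: float, ss_s: float, rate: float) -> "WindowSpec":
        return cls(ws=int(round(ws_s * rate)), ss=max(1, int(round(ss_s * rate))))


@dataclass
class SegmentSet:
    """Labeled windows over one stream: (start, end, label, purity) tuples."""

    windows: list[tuple[int, int, str, float]]
    spec: WindowSpec
    animal_id: str = ""
    session_id: str = ""

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def labels(self) -> list[str]:
        return [w[2] for w in self.windows]


def enumerate_windows(n: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open windows [start, start+ws) for start = 0, ss, 2*ss, ...

    Count is floor((n - ws)/ss) + 1 when n >= ws, else 0; e.g. 100 samples
    at ws=50, ss=25 give [0,50), [25,75), [50,100).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n < spec.ws:
        return []
    starts = range(0, n - spec.ws + 1, spec.ss)
    return [(s, s + spec.ws) for s in starts]


def _tie_break_key(label: str) -> tuple[int, str]:
    try:
        return (RARITY_ORDER.index(label), label)
    except ValueError:
        return (len(RARITY_ORDER), label)


def label_window(
    start: int,
    end: int,
    track: LabelTrack,
    rate: float,
    purity_threshold: float = 0.5,
    classes: tuple[str, ...] | None = None,
) -> tuple[str | None, float]:
    """Majority-coverage label of one window and its purity.

    Returns (None, purity) when purity falls below the threshold or the
    majority label is not in ``classes``.  Coverage ties break toward the
    rarer behavior, then lexicographically.
    """
    if start < 0 or end <= start:
        raise IndexError(f"window [{start}, {end}) is out of bounds")
    ws = end - start
    per_sample = track.labels_per_sample(end, rate)[start:end]
    counts: dict[str, int] = {}
    for lab in per_sample:
        if lab:
            counts[lab] = counts.get(lab, 0) + 1
    if not counts:
        return None, 0.0
    best = min(counts, key=lambda l: (-counts[l], _tie_break_key(l)))
    purity = counts[best] / ws
    if purity < purity_threshold:
        return None, purity
    if classes is not None and best not in classes:
        return None, purity
    return best, purity


def _segment_arrays(
    n: int,
    track: LabelTrack,
    spec: WindowSpec,
    rate: float,
    classes: tuple[str, ...],
    purity_threshold: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized window labeling: (starts, labels, purities) of retained windows."""
    bounds = enumerate_windows(n, spec)
    if not bounds:
        return np.empty(0, int), np.empty(0, object), np.empty(0, float)
    starts = np.fromiter((b[0] for b in bounds), dtype=np.int64)
    per_sample = track.labels_per_sample(n, rate)
    present = [l for l in dict.fromkeys(per_sample) if l]
    if not present:
        return np.empty(0, int), np.empty(0, object), np.empty(0, float)
    # per-class coverage of every window via cumulative indicator sums
    cov = np.empty((len(present), len(starts)), dtype=np.int64)
    for i, lab in enumerate(present):
        csum = np.concatenate(([0], np.cumsum(per_sample == lab)))
        cov[i] = csum[starts + spec.ws] - csum[starts]
    order = np.lexsort(
        (
            [_tie_break_key(l)[1] for l in present],
            [_tie_break_key(l)[0] for l in present],
        )
    )
    cov_sorted = cov[order]
    best_row = np.argmax(cov_sorted, axis=0)  # first max in tie-break order
    best_cov = cov_sorted[best_row, np.arange(len(starts))]
    labels = np.array([present[order[r]] for r in best_row], dtype=object)
    purity = best_cov / spec.ws
    keep = (purity >= purity_threshold) & np.isin(labels.astype(str), classes)
    return starts[keep], labels[keep], purity[keep]


def segment_stream(
    stream: SensorStream,
    track: LabelTrack,
    spec: WindowSpec,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    purity_threshold: float = 0.5,
) -> SegmentSet:
    """Enumerate, label and filter windows over a preprocessed stream.

    Windows whose majority label is outside ``classes`` (by default the four
    analysed behaviors — the minor classes and 'unknown' are excluded) or
    whose purity is below the threshold are dropped.  Deterministic for
    fixed inputs; an empty result is permitted.
    """
    starts, labels, purities = _segment_arrays(
        len(stream), track, spec, stream.sample_rate, tuple(classes), purity_threshold
    )
    windows = [
        (int(s), int(s) + spec.ws, str(l), float(p))
        for s, l, p in zip(starts, labels, purities)
    ]
    return SegmentSet(
        windows=windows, spec=spec, animal_id=stream.animal_id, session_id=stream.session_id
    )


class WindowSegmenter(BaseEstimator):
    """Sliding-window segmenter as a sklearn-style (stateless) transformer.

    Parameters are in seconds and converted at each stream's sampling rate.
    """

    def __init__(
        self,
        ws_s: float = 5.0,
        ss_s: float = 0.3,
        purity_threshold: float = 0.5,
        classes: tuple[str, ...] = DEFAULT_CLASSES,
    ):
        self.ws_s = ws_s
        self.ss_s = ss_s
        self.purity_threshold = purity_threshold
        self.classes = classes

    def fit(self, stream: SensorStream, track: LabelTrack | None = None) -> "WindowSegmenter":
        return self

    def transform(self, stream: SensorStream, track: LabelTrack) -> SegmentSet:
        spec = WindowSpec.from_seconds(self.ws_s, self.ss_s, stream.sample_rate)
        return segment_stream(
            stream,
            track,
            spec,
            classes=tuple(self.classes),
            purity_threshold=self.purity_threshold,
        )
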