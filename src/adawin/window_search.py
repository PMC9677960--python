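"""Grid search over window and step sizes; sliding and per-class adaptive optima.

Because behaviors differ in typical bout duration, a single sliding-window
size cannot suit them all: long windows stabilize the features of long
behaviors (eating, lying) but straddle the short bouts of walking and
standing.  This module sweeps a (WS, SS) grid, evaluates every classifier
at every grid point on a stratified 70/30 holdout, and extracts

* the *sliding* optimum — the single (WS, SS) maximizing the mean F1 over
  algorithms and classes, ties broken toward the larger window (more
  samples, stabler features) and then the smaller step; and
* the *adaptive* plan — per behavior class, the (WS, SS) maximizing that
  class's F1 for a chosen algorithm, with the same tie-break.

The adaptive per-class F1 can never fall below the sliding-optimum F1 on
the same grid and seed (argmax dominance); the improvement concentrates in
the short-bout classes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator

from .features import FeatureRegistry, featurize
from .models_eval import (
    ClassifierSpec,
    DegenerateTrainingError,
    StratificationError,
    confusion_and_metrics,
    fit_predict,
    stratified_split,
)
from .segmentation import RARITY_ORDER, SegmentSet, WindowSpec, segment_stream
from .sensor_io import DEFAULT_CLASSES, LabelTrack, SensorStream

#: Sliding-phase default grid.
SLIDING_WS_GRID_S = (2.0, 3.0, 5.0, 7.0)
SLIDING_SS_GRID_S = tuple(round(0.5 * i, 1) for i in range(1, 14))  # 0.5 .. 6.5

#: Adaptive-phase default SS axis; extends below the sliding sweep's 0.5 s
#: floor because short behaviors reward very fine steps.
ADAPTIVE_SS_GRID_S = (0.1, 0.3, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5)

DEFAULT_ALGORITHMS = ("svm", "knn", "dt", "nb", "rf")


def derive_seed(master: int, *parts) -> int:
    """Deterministic child seed (< 2^31) from a master seed and a context key."""
    key = ":".join([str(int(master)), *map(str, parts)])
    return int(hashlib.md5(key.encode()).hexdigest()[:8], 16) % (2**31)


class ClassScore(NamedTuple):
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class GridResult:
    """Per-(ws, ss, algorithm, class) precision/recall/F1 surface."""

    entries: dict[tuple[float, float, str, str], ClassScore]
    ws_list: tuple[float, ...]
    ss_list: tuple[float, ...]
    algorithms: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int
    unevaluable: list[tuple[float, float, str]] = field(default_factory=list)

    def mean_f1(self, ws_s: float, ss_s: float) -> float:
        vals = [
            s.f1
            for (w, st, _a, _c), s in self.entries.items()
            if w == ws_s and st == ss_s
        ]
        return float(np.mean(vals)) if vals else float("nan")

    def f1(self, ws_s: float, ss_s: float, algorithm: str, cls: str) -> float:
        return self.entries[(ws_s, ss_s, algorithm, cls)].f1

    def to_json(self, path) -> None:
        payload = {
            "ws_list": list(self.ws_list),
            "ss_list": list(self.ss_list),
            "algorithms": list(self.algorithms),
            "classes": list(self.classes),
            "seed": self.seed,
            "unevaluable": [[w, s, r] for w, s, r in self.unevaluable],
            "entries": {
                f"{w}|{s}|{a}|{c}": list(score)
                for (w, s, a, c), score in sorted(self.entries.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GridResult":
        with open(path) as fh:
            payload = json.load(fh)
        entries = {}
        for key, vals in payload["entries"].items():
            w, s, a, c = key.split("|")
            entries[(float(w), float(s), a, c)] = ClassScore(
                vals[0], vals[1], vals[2], int(vals[3])
            )
        return cls(
            entries=entries,
            ws_list=tuple(payload["ws_list"]),
            ss_list=tuple(payload["ss_list"]),
            algorithms=tuple(payload["algorithms"]),
            classes=tuple(payload["classes"]),
            seed=payload["seed"],
            unevaluable=[(w, s, r) for w, s, r in payload["unevaluable"]],
        )


@dataclass
class AdaptivePlan:
    """Per-class (ws_s, ss_s) under one algorithm."""

    windows: dict[str, tuple[float, float]]
    algorithm: str


def _cap_windows_per_bout(
    segments: SegmentSet, track: LabelTrack, rate: float, k: int
) -> SegmentSet:
    """Keep at most ``k`` evenly spaced windows per bout (deterministic).

    Overlapping windows cut from the same bout at a fine step are near
    duplicates; with a window-level random split they leak between train
    and test and inflate the apparent F1 of long windows over short bouts.
    Thinning each bout to a few representatives keeps the evaluation an
    honest measure of between-bout generalization.
    """
    starts_s = [iv[0] for iv in track.intervals]
    groups: dict[int, list[int]] = {}
    for i, (s, e, _lab, _p) in enumerate(segments.windows):
        mid_s = (s + e) / 2.0 / rate
        b = int(np.searchsorted(starts_s, mid_s, side="right")) - 1
        groups.setdefault(b, []).append(i)
    keep: list[int] = []
    for b in sorted(groups):
        idxs = groups[b]
        if len(idxs) <= k:
            keep.extend(idxs)
        else:
            picks = np.unique(np.linspace(0, len(idxs) - 1, k).round().astype(int))
            keep.extend(idxs[j] for j in picks)
    keep.sort()
    return SegmentSet(
        windows=[segments.windows[i] for i in keep],
        spec=segments.spec,
        animal_id=segments.animal_id,
        session_id=segments.session_id,
    )


def _subsample_segments(segments: SegmentSet, max_windows: int, seed: int) -> SegmentSet:
    """Deterministic subsample under a balanced per-class quota.

    Rare classes keep all their windows; abundant classes are thinned to
    fill the remaining budget (waterfilling), so capping compute never
    erases a minority class's support.
    """
    if len(segments) <= max_windows:
        return segments
    rng = np.random.default_rng(seed)
    labels = np.array(segments.labels, dtype=object)
    counts = {cls: int(np.sum(labels == cls)) for cls in sorted(set(labels.tolist()))}
    quota: dict[str, int] = {}
    budget = max_windows
    remaining = len(counts)
    for cls in sorted(counts, key=lambda c: (counts[c], c)):
        q = min(counts[cls], budget // remaining)
        quota[cls] = max(q, min(counts[cls], 2))
        budget -= quota[cls]
        remaining -= 1
    keep: list[np.ndarray] = []
    for cls, q in quota.items():
        rows = np.flatnonzero(labels == cls)
        keep.append(rng.choice(rows, size=q, replace=False))
    idx = np.sort(np.concatenate(keep))
    return SegmentSet(
        windows=[segments.windows[i] for i in idx],
        spec=segments.spec,
        animal_id=segments.animal_id,
        session_id=segments.session_id,
    )


def evaluate_point(
    stream: SensorStream,
    track: LabelTrack,
    ws_s: float,
    ss_s: float,
    algorithms: tuple[str, ...],
    seed: int,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    purity_threshold: float = 0.5,
    train_frac: float = 0.7,
    registry: FeatureRegistry | None = None,
    max_windows: int | None = None,
    max_windows_per_bout: int | None = None,
    n_repeats: int = 1,
) -> tuple[dict[tuple[str, str], ClassScore], str | None]:
    """Full pipeline at one (ws, ss): segment, featurize, split, fit, score.

    Returns ``(scores, reason)``: ``scores`` maps (algorithm, class) to a
    :class:`ClassScore`; ``reason`` is non-None when the point is
    unevaluable (e.g. segmentation leaves fewer than two classes).  With
    ``n_repeats > 1`` the metrics are averaged over that many independent
    stratified holdouts, damping split-selection noise.  Seeds for
    subsampling, splits and fits derive from ``seed`` and (ws, ss) only, so
    the same point always evaluates identically regardless of which grid it
    sits in — the property that makes adaptive-vs-sliding comparisons
    exact.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    spec = WindowSpec.from_seconds(ws_s, ss_s, stream.sample_rate)
    segments = segment_stream(
        stream, track, spec, classes=classes, purity_threshold=purity_threshold
    )
    present = sorted(set(segments.labels))
    if len(present) < 2:
        return {}, f"segmentation yields {len(present)} class(es)"
    if max_windows_per_bout is not None:
        segments = _cap_windows_per_bout(
            segments, track, stream.sample_rate, max_windows_per_bout
        )
        present = sorted(set(segments.labels))
        if len(present) < 2:
            return {}, f"bout thinning leaves {len(present)} class(es)"
    if max_windows is not None:
        segments = _subsample_segments(
            segments, max_windows, derive_seed(seed, "subsample", ws_s, ss_s)
        )
    table = featurize(segments, stream, registry=registry)
    acc: dict[tuple[str, str], list[ClassScore]] = {}
    for rep in range(n_repeats):
        rep_key = () if rep == 0 else ("rep", rep)
        try:
            train, test = stratified_split(
                table,
                train_frac=train_frac,
                seed=derive_seed(seed, "split", *rep_key, ws_s, ss_s),
            )
        except StratificationError as exc:
            return {}, str(exc)
        for algo in algorithms:
            cspec = ClassifierSpec(
                name=algo, seed=derive_seed(seed, "fit", *rep_key, algo, ws_s, ss_s)
            )
            try:
                y_pred, _cls, _scores = fit_predict(cspec, train, test)
            except DegenerateTrainingError as exc:
                return {}, str(exc)
            metrics = confusion_and_metrics(test.y, y_pred, classes=present)
            for cls in present:
                acc.setdefault((algo, cls), []).append(
                    ClassScore(
                        metrics.precision[cls],
                        metrics.recall[cls],
                        metrics.f1[cls],
                        metrics.support[cls],
                    )
                )
    scores = {
        key: ClassScore(
            float(np.mean([s.precision for s in vals])),
            float(np.mean([s.recall for s in vals])),
            float(np.mean([s.f1 for s in vals])),
            int(round(np.mean([s.support for s in vals]))),
        )
        for key, vals in acc.items()
    }
    return scores, None


def grid_search(
    stream: SensorStream,
    track: LabelTrack,
    ws_list: tuple[float, ...] = SLIDING_WS_GRID_S,
    ss_list: tuple[float, ...] = SLIDING_SS_GRID_S,
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS,
    seed: int = 0,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    purity_threshold: float = 0.5,
    train_frac: float = 0.7,
    registry: FeatureRegistry | None = None,
    max_windows: int | None = None,
    max_windows_per_bout: int | None = None,
    n_repeats: int = 1,
) -> GridResult:
    """Evaluate every (ws, ss, algorithm) and build the per-class F1 surface.

    Grid points whose segmentation yields fewer than two classes (or whose
    split degenerates) are recorded in ``unevaluable`` rather than dropped
    silently; it is an error for *all* points to be unevaluable.
    """
    if not ws_list or not ss_list or not algorithms:
        raise ValueError("ws_list, ss_list and algorithms must be non-empty")
    entries: dict[tuple[float, float, str, str], ClassScore] = {}
    unevaluable: list[tuple[float, float, str]] = []
    for ws_s in ws_list:
        for ss_s in ss_list:
            scores, reason = evaluate_point(
                stream,
                track,
                ws_s,
                ss_s,
                algorithms,
                seed,
                classes=classes,
                purity_threshold=purity_threshold,
                train_frac=train_frac,
                registry=registry,
                max_windows=max_windows,
                max_windows_per_bout=max_windows_per_bout,
                n_repeats=n_repeats,
            )
            if reason is not None:
                unevaluable.append((ws_s, ss_s, reason))
                continue
            for (algo, cls), score in scores.items():
                entries[(ws_s, ss_s, algo, cls)] = score
    if not entries:
        raise ValueError("all grid points were unevaluable")
    return GridResult(
        entries=entries,
        ws_list=tuple(ws_list),
        ss_list=tuple(ss_list),
        algorithms=tuple(algorithms),
        classes=tuple(classes),
        seed=seed,
        unevaluable=unevaluable,
    )


def _argmax_point(points: dict[tuple[float, float], float]) -> tuple[float, float]:
    """Argmax with ties toward larger ws, then smaller ss."""
    best = max(points.items(), key=lambda kv: (kv[1], kv[0][0], -kv[0][1]))
    return best[0]


def select_sliding_optimum(grid: GridResult, criterion: str = "mean_f1"):
    """The (ws, ss) maximizing the mean F1 over algorithms and classes.

    Ties break toward the larger window (its features are stabler) and then
    the smaller step.  ``criterion='per_algorithm'`` instead returns one
    optimum per algorithm (mean F1 over classes).
    """
    points = sorted({(w, s) for (w, s, _a, _c) in grid.entries})
    if not points:
        raise ValueError("empty grid")
    if criterion == "mean_f1":
        return _argmax_point({p: grid.mean_f1(*p) for p in points})
    if criterion == "per_algorithm":
        result = {}
        for algo in grid.algorithms:
            vals = {}
            for w, s in points:
                f1s = [
                    sc.f1
                    for (ww, ss, a, _c), sc in grid.entries.items()
                    if ww == w and ss == s and a == algo
                ]
                if f1s:
                    vals[(w, s)] = float(np.mean(f1s))
            if vals:
                result[algo] = _argmax_point(vals)
        return result
    raise ValueError("criterion must be 'mean_f1' or 'per_algorithm'")


def select_adaptive_optima(grid: GridResult, algorithm: str = "rf") -> AdaptivePlan:
    """Per class, the (ws, ss) maximizing that class's F1 for one algorithm."""
    if algorithm not in grid.algorithms:
        raise ValueError(f"grid does not cover algorithm {algorithm!r}")
    windows: dict[str, tuple[float, float]] = {}
    for cls in grid.classes:
        vals = {
            (w, s): sc.f1
            for (w, s, a, c), sc in grid.entries.items()
            if a == algorithm and c == cls
        }
        if not vals:
            raise ValueError(f"class {cls!r} absent from every evaluable grid point")
        windows[cls] = _argmax_point(vals)
    return AdaptivePlan(windows=windows, algorithm=algorithm)


def adaptive_evaluate(
    stream: SensorStream,
    track: LabelTrack,
    plan: AdaptivePlan,
    seed: int = 0,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    purity_threshold: float = 0.5,
    train_frac: float = 0.7,
    registry: FeatureRegistry | None = None,
    max_windows: int | None = None,
    max_windows_per_bout: int | None = None,
    n_repeats: int = 1,
) -> dict[str, dict[str, float]]:
    """Evaluate each class at its own (ws, ss) from the plan.

    For each class c the full pipeline runs at plan[c]'s window and c's
    precision/recall/F1 from that run are reported, together with the
    (ws, ss) used — one row per class, each at its own window.  Uses the
    same seed derivation as :func:`grid_search`, so a plan drawn from a grid
    reproduces the grid's scores exactly.
    """
    results: dict[str, dict[str, float]] = {}
    cache: dict[tuple[float, float], dict[tuple[str, str], ClassScore]] = {}
    for cls, (ws_s, ss_s) in plan.windows.items():
        if (ws_s, ss_s) not in cache:
            scores, reason = evaluate_point(
                stream,
                track,
                ws_s,
                ss_s,
                (plan.algorithm,),
                seed,
                classes=classes,
                purity_threshold=purity_threshold,
                train_frac=train_frac,
                registry=registry,
                max_windows=max_windows,
                max_windows_per_bout=max_windows_per_bout,
                n_repeats=n_repeats,
            )
            if reason is not None:
                raise ValueError(f"plan point ({ws_s}, {ss_s}) unevaluable: {reason}")
            cache[(ws_s, ss_s)] = scores
        score = cache[(ws_s, ss_s)].get((plan.algorithm, cls))
        if score is None:
            raise ValueError(f"class {cls!r} not present at plan point ({ws_s}, {ss_s})")
        results[cls] = {
            "precision": score.precision,
            "recall": score.recall,
            "f1": score.f1,
            "support": score.support,
            "ws_s": ws_s,
            "ss_s": ss_s,
        }
    return results


def fuse_predict(
    stream: SensorStream,
    plan: AdaptivePlan,
    models: dict[tuple[float, float], object],
    registry: FeatureRegistry | None = None,
) -> np.ndarray:
    """Fuse per-class windowed models into one label-per-sample timeline.

    For each time step t, class c's score is c's confidence from the model
    trained at plan[c]'s (ws, ss), read from the most recent fully observed
    window at that spec; the predicted label is the argmax, ties toward the
    more frequent class then lexicographic.  Steps before the first
    complete window are labeled 'unknown'.  Provided as an inference-time
    extension; the per-class-at-own-window evaluation above is the primary
    result.
    """
    n = len(stream)
    needed = sorted(set(plan.windows.values()))
    missing = [p for p in needed if p not in models]
    if missing:
        raise ValueError(f"no trained model for plan points {missing}")
    # score timelines per class
    class_scores: dict[str, np.ndarray] = {}
    for point in needed:
        ws_s, ss_s = point
        spec = WindowSpec.from_seconds(ws_s, ss_s, stream.sample_rate)
        bounds = [(s, s + spec.ws) for s in range(0, max(n - spec.ws, 0) + 1, spec.ss)]
        if not bounds:
            raise ValueError(f"stream shorter than plan window ({ws_s} s)")
        segs = SegmentSet(
            windows=[(s, e, "unknown", 1.0) for s, e in bounds], spec=spec
        )
        table = featurize(segs, stream, registry=registry)
        model = models[point]
        scores = model.decision_scores(table.X)
        model_classes = list(model.classes_)
        starts = np.array([b[0] for b in bounds])
        t = np.arange(n)
        # most recent fully observed window: largest enumerated start <= t+1-ws
        widx = np.floor_divide(t + 1 - spec.ws, spec.ss)
        widx = np.clip(widx, -1, len(bounds) - 1)
        for cls, pt in plan.windows.items():
            if pt != point:
                continue
            if cls not in model_classes:
                raise ValueError(f"model at {point} was not trained on class {cls!r}")
            col = model_classes.index(cls)
            vals = np.full(n, -np.inf)
            ok = widx >= 0
            vals[ok] = scores[widx[ok], col]
            class_scores[cls] = vals
    order = sorted(
        class_scores,
        key=lambda c: (-RARITY_ORDER.index(c) if c in RARITY_ORDER else 0, c),
    )
    mat = np.column_stack([class_scores[c] for c in order])
    best = np.argmax(mat, axis=1)
    timeline = np.array([order[i] for i in best], dtype=object)
    timeline[~np.isfinite(mat).any(axis=1)] = "unknown"
    return timeline


class AdaptiveWindowSearch(BaseEstimator):
    """Grid search + optimum selection as a sklearn-style meta-estimator.

    ``fit(stream, track)`` sweeps the (ws, ss) grid for every algorithm and
    exposes the surfaces and selections as fitted attributes:

    Attributes
    ----------
    grid_result_ : GridResult
        The full per-(ws, ss, algorithm, class) metric surface.
    sliding_optimum_ : tuple[float, float]
        The single best (ws_s, ss_s) by mean F1.
    sliding_metrics_ : dict[str, dict[str, float]]
        Per-class scores of ``plan_algorithm`` at the sliding optimum.
    adaptive_plan_ : AdaptivePlan
        Per-class optima for ``plan_algorithm``.
    adaptive_metrics_ : dict[str, dict[str, float]]
        Per-class scores, each class at its own plan window.
    """

    def __init__(
        self,
        ws_grid_s: tuple[float, ...] = SLIDING_WS_GRID_S,
        ss_grid_s: tuple[float, ...] = SLIDING_SS_GRID_S,
        algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS,
        plan_algorithm: str = "rf",
        classes: tuple[str, ...] = DEFAULT_CLASSES,
        purity_threshold: float = 0.5,
        train_frac: float = 0.7,
        registry: FeatureRegistry | None = None,
        max_windows: int | None = None,
        max_windows_per_bout: int | None = None,
        n_repeats: int = 1,
        seed: int = 0,
    ):
        self.ws_grid_s = ws_grid_s
        self.ss_grid_s = ss_grid_s
        self.algorithms = algorithms
        self.plan_algorithm = plan_algorithm
        self.classes = classes
        self.purity_threshold = purity_threshold
        self.train_frac = train_frac
        self.registry = registry
        self.max_windows = max_windows
        self.max_windows_per_bout = max_windows_per_bout
        self.n_repeats = n_repeats
        self.seed = seed

    def fit(self, stream: SensorStream, track: LabelTrack) -> "AdaptiveWindowSearch":
        common = dict(
            classes=tuple(self.classes),
            purity_threshold=self.purity_threshold,
            train_frac=self.train_frac,
            registry=self.registry,
            max_windows=self.max_windows,
            max_windows_per_bout=self.max_windows_per_bout,
            n_repeats=self.n_repeats,
        )
        self.grid_result_ = grid_search(
            stream,
            track,
            ws_list=tuple(self.ws_grid_s),
            ss_list=tuple(self.ss_grid_s),
            algorithms=tuple(self.algorithms),
            seed=self.seed,
            **common,
        )
        self.sliding_optimum_ = select_sliding_optimum(self.grid_result_)
        ws0, ss0 = self.sliding_optimum_
        self.sliding_metrics_ = {
            cls: {
                "precision": sc.precision,
                "recall": sc.recall,
                "f1": sc.f1,
                "support": sc.support,
                "ws_s": ws0,
                "ss_s": ss0,
            }
            for (w, s, a, cls), sc in self.grid_result_.entries.items()
            if w == ws0 and s == ss0 and a == self.plan_algorithm
        }
        self.adaptive_plan_ = select_adaptive_optima(self.grid_result_, self.plan_algorithm)
        self.adaptive_metrics_ = adaptive_evaluate(
            stream, track, self.adaptive_plan_, seed=self.seed, **common
        )
        return self
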