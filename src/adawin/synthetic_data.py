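"""Synthetic labeled inertial streams with a realistic bout-duration contrast.

The generator emulates the structure of back-mounted IMU recordings of
group-housed pigs: a 10 Hz 6-channel stream partitioned into behavior
bouts.  Eating and lying dominate the time budget and come in long bouts
(minutes); walking and standing are rare and short (seconds).  Within a
bout the acceleration is a gravity component along a class-specific
orientation plus a class-specific sinusoid and Gaussian sensor noise; the
angular velocity is Gaussian with a class-specific spread (walking adds the
derivative of its oscillation).  The goal is structural fidelity — class
imbalance, duration contrast, two sensors at 10 Hz — not biomechanical
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import GRAVITY, PhysicalRanges
from .sensor_io import BEHAVIOR_VOCABULARY, LabelTrack, SensorStream


def _unit(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    a = a / np.linalg.norm(a)
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class ClassSignalModel:
    """Within-bout signal parameters of one behavior class."""

    orientation: tuple[float, float, float]  # unit gravity direction in sensor frame
    osc_freq_hz: float
    osc_amp: float  # m/s^2, applied along the x axis
    gyro_sd: float  # deg/s
    gyro_oscillates: bool = False

    #: log-normal bout-duration parameters
    bout_median_s: float = 60.0
    bout_sigma: float = 0.5

    #: between-bout variability: log-sd of per-bout multipliers on osc_amp
    #: and gyro_sd, and sd (degrees) of per-bout orientation jitter.  Real
    #: bouts of one behavior differ in vigour and posture, so class signal
    #: distributions overlap instead of forming disjoint bands.
    bout_variability: float = 0.5
    orient_jitter_deg: float = 10.0


#: Default per-class models.  Orientations separate postures (lying is on
#: the side; eating is head-down), oscillation frequency/amplitude separate
#: rhythmic behaviors (chewing ~2 Hz, gait ~1.4 Hz), and the angular-velocity
#: spread separates activity levels.  Bout medians encode the duration
#: contrast: minutes for eating/lying, seconds for walking/standing.
DEFAULT_SIGNAL_MODELS: dict[str, ClassSignalModel] = {
    "eating": ClassSignalModel(
        _unit((0.10, 0.0, 0.995)), 2.2, 1.0, 4.0, bout_median_s=120.0, bout_sigma=0.5,
        bout_variability=0.15, orient_jitter_deg=5.0,
    ),
    "lying": ClassSignalModel(
        _unit((0.0, 0.14, 0.99)), 0.3, 0.05, 3.0, bout_median_s=300.0, bout_sigma=0.5,
        bout_variability=0.15, orient_jitter_deg=5.0,
    ),
    "walking": ClassSignalModel(
        _unit((0.0, 0.0, 1.0)), 1.4, 2.0, 12.0, gyro_oscillates=True,
        bout_median_s=8.0, bout_sigma=0.4, bout_variability=0.15, orient_jitter_deg=5.0,
    ),
    "standing": ClassSignalModel(
        _unit((0.0, 0.0, 1.0)), 0.5, 0.3, 5.5, bout_median_s=6.0, bout_sigma=0.4,
        bout_variability=0.15, orient_jitter_deg=5.0,
    ),
    "playing": ClassSignalModel(
        _unit((0.2, 0.2, 0.95)), 1.8, 1.5, 45.0, bout_median_s=10.0, bout_sigma=0.4
    ),
    "drinking": ClassSignalModel(
        _unit((0.5, 0.0, 0.87)), 1.0, 0.8, 20.0, bout_median_s=15.0, bout_sigma=0.4
    ),
    "sitting": ClassSignalModel(
        _unit((0.3, 0.0, 0.95)), 0.2, 0.1, 5.0, bout_median_s=20.0, bout_sigma=0.5
    ),
    "unknown": ClassSignalModel(
        _unit((0.0, 0.0, 1.0)), 0.8, 0.5, 15.0, bout_median_s=30.0, bout_sigma=0.5
    ),
}

#: Observed time-budget percentages of the study ethogram.
ETHOGRAM_SHARES = {
    "eating": 49.40,
    "lying": 33.33,
    "walking": 7.87,
    "standing": 1.76,
    "playing": 0.48,
    "drinking": 0.49,
    "sitting": 0.24,
    "unknown": 6.43,
}

#: Default mix: the four analysed classes, renormalized to sum to 1.
DEFAULT_CLASS_MIX = {
    c: ETHOGRAM_SHARES[c] / sum(ETHOGRAM_SHARES[k] for k in ("eating", "lying", "walking", "standing"))
    for c in ("eating", "lying", "walking", "standing")
}

LONG_BOUT_CLASSES = ("eating", "lying")
SHORT_BOUT_CLASSES = ("walking", "standing")


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator."""

    sample_rate: float = 10.0
    duration_s: float = 10_000.0
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    signal_models: dict[str, ClassSignalModel] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_MODELS)
    )
    noise_sd: float = 3.0  # m/s^2, added to the acceleration channels
    outlier_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.duration_s <= 0:
            raise ValueError("sample_rate and duration_s must be positive")
        unknown = set(self.class_mix) - set(BEHAVIOR_VOCABULARY)
        if unknown:
            raise ValueError(f"class_mix contains unknown labels {sorted(unknown)}")
        total = sum(self.class_mix.values())
        if total <= 0:
            raise ValueError("class_mix must have positive total")
        self.class_mix = {c: v / total for c, v in self.class_mix.items()}
        for rate in (self.outlier_rate, self.missing_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        for c, m in self.signal_models.items():
            if m.bout_median_s <= 0:
                raise ValueError(f"bout median of {c!r} must be positive")


@dataclass
class InjectionLog:
    """Ground truth of injected artifacts: (sample index, channel name) cells."""

    outlier_cells: list[tuple[int, str]] = field(default_factory=list)
    missing_cells: list[tuple[int, str]] = field(default_factory=list)


def simulate(config: SimConfig | None = None, seed: int | None = None) -> tuple[SensorStream, LabelTrack]:
    """Generate a labeled stream under the configured study conditions.

    Bout labels are drawn with probability proportional to
    ``class_mix / expected bout duration`` so the expected *time share* of
    each class matches the mix (the mix is a time budget, not a bout-count
    budget).  Bout lengths are log-normal.  Bit-reproducible under the seed.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rate = config.sample_rate
    n = int(round(config.duration_s * rate))
    if n < 2:
        raise ValueError("duration too short for a single bout")
    classes = sorted(config.class_mix)
    models = {c: config.signal_models[c] for c in classes}
    mean_dur = {
        c: models[c].bout_median_s * np.exp(models[c].bout_sigma**2 / 2) for c in classes
    }
    p = np.array([config.class_mix[c] / mean_dur[c] for c in classes])
    p /= p.sum()

    acc = np.empty((n, 3))
    gyro = np.empty((n, 3))
    intervals: list[tuple[float, float, str]] = []
    i = 0
    while i < n:
        cls = classes[int(rng.choice(len(classes), p=p))]
        m = models[cls]
        dur = float(rng.lognormal(np.log(m.bout_median_s), m.bout_sigma))
        length = max(1, int(round(dur * rate)))
        j = min(n, i + length)
        t = np.arange(i, j) / rate
        phase = rng.uniform(0, 2 * np.pi)
        amp = m.osc_amp * rng.lognormal(0.0, m.bout_variability)
        gsd = m.gyro_sd * rng.lognormal(0.0, m.bout_variability)
        orient = np.asarray(m.orientation) + rng.normal(
            0.0, np.sin(np.radians(m.orient_jitter_deg)), 3
        )
        orient /= np.linalg.norm(orient)
        osc = amp * np.sin(2 * np.pi * m.osc_freq_hz * t + phase)
        acc[i:j] = GRAVITY * orient[None, :]
        acc[i:j, 0] += osc
        acc[i:j] += rng.normal(0.0, config.noise_sd, size=(j - i, 3))
        gyro[i:j] = rng.normal(0.0, gsd, size=(j - i, 3))
        if m.gyro_oscillates:
            # derivative of the acceleration oscillation, read in deg/s
            gyro[i:j, 0] += amp * 2 * np.pi * m.osc_freq_hz * np.cos(
                2 * np.pi * m.osc_freq_hz * t + phase
            )
        intervals.append((i / rate, j / rate, cls))
        i = j

    stream = SensorStream(
        timestamps=np.arange(n) / rate,
        counters=np.arange(n) % (1 << 16),
        acc=acc,
        gyro=gyro,
        sample_rate=rate,
        animal_id="sim0",
        session_id="sim-session0",
    )
    track = LabelTrack(intervals=intervals)
    if config.outlier_rate > 0 or config.missing_rate > 0:
        stream, _ = inject_artifacts(
            stream, config.outlier_rate, config.missing_rate, seed=int(rng.integers(2**31))
        )
    return stream, track


def inject_artifacts(
    stream: SensorStream,
    outlier_rate: float,
    missing_rate: float,
    seed: int = 0,
    ranges: PhysicalRanges | None = None,
) -> tuple[SensorStream, InjectionLog]:
    """Corrupt a stream with range-violating spikes and missing runs.

    ``outlier_rate`` (resp. ``missing_rate``) is the expected fraction of
    samples receiving a spike beyond the physical range (resp. the start of
    a 1-3 sample missing run) on one random channel.  The returned log is
    the ground truth for testing the preprocessing stage.
    """
    for rate in (outlier_rate, missing_rate):
        if not 0 <= rate <= 1:
            raise ValueError("rates must be in [0, 1]")
    if ranges is None:
        ranges = PhysicalRanges()
    rng = np.random.default_rng(seed)
    out = stream.copy()
    chans = out.channels()
    names = list(chans)
    n = len(out)
    log = InjectionLog()
    taken: set[tuple[int, str]] = set()

    n_out = int(round(outlier_rate * n))
    if n_out:
        idx = rng.choice(n, size=min(n_out, n), replace=False)
        for i in idx:
            name = names[int(rng.integers(len(names)))]
            abs_max = ranges.acc_abs_max if name.startswith("a") else ranges.gyro_abs_max
            sign = 1.0 if rng.random() < 0.5 else -1.0
            chans[name][i] = sign * abs_max * rng.uniform(1.05, 1.5)
            log.outlier_cells.append((int(i), name))
            taken.add((int(i), name))

    n_miss = int(round(missing_rate * n))
    if n_miss:
        starts = rng.choice(n, size=min(n_miss, n), replace=False)
        for s in starts:
            name = names[int(rng.integers(len(names)))]
            run = int(rng.integers(1, 4))
            for i in range(int(s), min(n, int(s) + run)):
                if (i, name) in taken:
                    continue
                chans[name][i] = np.nan
                log.missing_cells.append((i, name))
                taken.add((i, name))

    log.outlier_cells.sort()
    log.missing_cells.sort()
    return out, log
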