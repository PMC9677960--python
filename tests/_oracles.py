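"""Independent brute-force oracles for the window statistics, the spectrum
and the orientation angles.

These are written directly from the feature definitions as plain loops (the
spectrum as an explicit DFT matrix product, not an FFT), kept deliberately
separate from the package implementation so the two can disagree.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_statistics(x) -> dict[str, float]:
    x = [float(v) for v in x]
    n = len(x)
    assert n >= 2
    mean = sum(x) / n
    centered = [v - mean for v in x]
    sse = sum(c * c for c in centered)
    sd = math.sqrt(sse / (n - 1))
    xs = sorted(x)

    def quantile(q: float) -> float:
        # linear interpolation between closest order statistics at (n-1)*q
        pos = (n - 1) * q
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return xs[lo] * (1 - frac) + xs[hi] * frac

    q1, q3 = quantile(0.25), quantile(0.75)
    xmax, xmin = max(x), min(x)
    pos_count = sum(1 for c in centered if c > 0)
    neg_count = sum(1 for c in centered if c < 0)
    m2 = sse / n
    if m2 > 0:
        m3 = sum(c**3 for c in centered) / n
        m4 = sum(c**4 for c in centered) / n
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    else:
        skew = kurt = 0.0
    # zero crossings of the centered signal; zeros inherit the previous nonzero sign
    zc = 0
    prev = 0
    for c in centered:
        s = (c > 0) - (c < 0)
        if s != 0:
            if prev != 0 and s != prev:
                zc += 1
            prev = s
    asc = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    l2 = math.sqrt(sum(v * v for v in x))
    return {
        "mean": mean,
        "sd": sd,
        "max": xmax,
        "min": xmin,
        "iqr": q3 - q1,
        "range": xmax - xmin,
        "pos_count": float(pos_count),
        "neg_count": float(neg_count),
        "skewness": skew,
        "kurtosis": kurt,
        "zero_cross": float(zc),
        "sse": sse,
        "abs_sum_changes": asc,
        "l2norm": l2,
    }


def oracle_spectrum(x) -> np.ndarray:
    """One-sided magnitude of the mean-removed signal by direct DFT, DC excluded."""
    x = np.asarray(x, dtype=float)
    n = x.size
    c = x - x.mean()
    k = np.arange(1, n // 2 + 1)
    j = np.arange(n)
    basis = np.exp(-2j * np.pi * np.outer(k, j) / n)
    return np.abs(basis @ c)


def oracle_pitch_roll(acc) -> tuple[float, float]:
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    pitches, rolls = [], []
    for ax, ay, az in acc:
        if ax == 0 and ay == 0 and az == 0:
            continue
        pitches.append(math.degrees(math.atan2(ax, math.hypot(ay, az))))
        rolls.append(math.degrees(math.atan2(ay, math.hypot(ax, az))))
    if not pitches:
        return 0.0, 0.0
    return sum(pitches) / len(pitches), sum(rolls) / len(rolls)
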