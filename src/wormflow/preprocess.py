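"""Raw two-channel fluorescence -> scaled activity matrices.

Whole-brain recordings are acquired as ratiometric calcium signals: a
calcium-sensitive YFP channel over a calcium-insensitive CFP channel.
This module applies the full cleaning cascade — temporal median
filtering, outlier removal based on CFP dips, gap completion, neuron
exclusion, photobleach detrending, z-scoring — and flags neurons whose
trace is indistinguishable from noise (the "nonrandom" autocorrelation
criterion used to gate the regression models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawFluorescenceTable",
    "ActivityMatrix",
    "median_filter_time",
    "detect_outliers",
    "complete_missing",
    "drop_bad_neurons",
    "compute_activity",
    "autocorrelation",
    "nonrandom_filter",
    "preprocess_sample",
]

#: maximum tolerated number of outlier time points per neuron
OUTLIER_COUNT_LIMIT = 400
#: outlier rule: filtered CFP below this fraction of its median
OUTLIER_FRACTION = 0.1
#: autocorrelation lag / threshold for the "nonrandom" gate
NONRANDOM_LAG = 20
NONRANDOM_THRESHOLD = 0.3


@dataclass
class RawFluorescenceTable:
    """Two-channel fluorescence traces for one animal.

    ``cfp`` and ``yfp`` are (neurons x time) arrays in arbitrary units;
    NaN marks a missing observation.
    """

    sample_id: str
    neuron_names: list[str]
    cfp: np.ndarray
    yfp: np.ndarray
    frame_rate: float = 4.0

    def __post_init__(self) -> None:
        self.cfp = np.asarray(self.cfp, dtype=float)
        self.yfp = np.asarray(self.yfp, dtype=float)
        if self.cfp.shape != self.yfp.shape:
            raise ValueError("cfp and yfp must share shape")
        if len(self.neuron_names) != self.cfp.shape[0]:
            raise ValueError("neuron_names length must match row count")
        if len(set(self.neuron_names)) != len(self.neuron_names):
            raise ValueError("neuron names must be unique within a sample")


@dataclass
class ActivityMatrix:
    """Z-scored YFP/CFP ratio traces with inclusion masks.

    ``values`` is (neurons x time); rows where ``included_mask`` is False
    are all-NaN.  ``nonrandom_mask`` marks neurons passing the
    autocorrelation criterion (only those enter the regression models).
    """

    sample_id: str
    neuron_names: list[str]
    values: np.ndarray
    included_mask: np.ndarray
    nonrandom_mask: np.ndarray
    frame_rate: float = 4.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.included_mask = np.asarray(self.included_mask, dtype=bool)
        self.nonrandom_mask = np.asarray(self.nonrandom_mask, dtype=bool)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    def series(self, neuron: str) -> np.ndarray:
        return self.values[self.neuron_names.index(neuron)]

    def usable_neurons(self) -> list[str]:
        """Neurons that survived the filters and the nonrandom gate."""
        keep = self.included_mask & self.nonrandom_mask
        return [n for n, k in zip(self.neuron_names, keep) if k]


def median_filter_time(series: np.ndarray, window: int) -> np.ndarray:
    """Running median with the window shrunk at the series boundaries.

    NaN entries are ignored inside each window; a window with no finite
    entry yields NaN.
    """
    if window < 1:
        raise ValueError("window must be a positive integer")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a non-empty 1-D array")
    if window == 1:
        return x.copy()
    half_lo = (window - 1) // 2
    half_hi = window // 2
    out = np.empty_like(x)
    for t in range(x.size):
        seg = x[max(0, t - half_lo): t + half_hi + 1]
        seg = seg[np.isfinite(seg)]
        out[t] = np.median(seg) if seg.size else np.nan
    return out


def detect_outliers(cfp_filtered: np.ndarray) -> np.ndarray:
    """Flag time points where filtered CFP drops below 1/10 of its median.

    The comparison is strict; a median of zero therefore flags nothing on
    a non-negative trace.
    """
    x = np.asarray(cfp_filtered, dtype=float)
    med = np.nanmedian(x)
    with np.errstate(invalid="ignore"):
        return x < OUTLIER_FRACTION * med


def complete_missing(series: np.ndarray, window: int = 4) -> np.ndarray:
    """Fill NaN entries with the median of observed neighbours.

    A ``window`` of 4 means the two raw positions on each side of the gap
    (the gap itself excluded); only observed values among them enter the
    median.  A gap whose neighbourhood is entirely missing stays NaN —
    the neuron is then dropped downstream.
    """
    if window < 1:
        raise ValueError("window must be a positive integer")
    x = np.asarray(series, dtype=float).copy()
    missing = np.where(~np.isfinite(x))[0]
    if missing.size == 0:
        return x
    half_lo = window // 2
    half_hi = window - half_lo
    orig = np.asarray(series, dtype=float)
    for t in missing:
        idx = np.r_[max(0, t - half_lo): t, t + 1: min(x.size, t + half_hi + 1)]
        neigh = orig[idx]
        neigh = neigh[np.isfinite(neigh)]
        if neigh.size:
            x[t] = np.median(neigh)
    return x


def drop_bad_neurons(outlier_counts: np.ndarray,
                     residual_missing: np.ndarray) -> np.ndarray:
    """Inclusion mask: drop neurons with >400 outliers or residual gaps."""
    counts = np.asarray(outlier_counts)
    residual = np.asarray(residual_missing, dtype=bool)
    return (counts <= OUTLIER_COUNT_LIMIT) & ~residual


def compute_activity(cfp: np.ndarray, yfp: np.ndarray) -> np.ndarray:
    """YFP/CFP ratio, linearly detrended, then z-scored.

    The linear trend (ordinary least squares on the time index)
    compensates for photobleaching.  Raises on a zero-variance ratio.
    """
    cfp = np.asarray(cfp, dtype=float)
    yfp = np.asarray(yfp, dtype=float)
    if not (np.isfinite(cfp).all() and np.isfinite(yfp).all()):
        raise ValueError("channels must be complete (no missing values)")
    if np.any(cfp <= 0):
        raise ValueError("CFP must be strictly positive")
    ratio = yfp / cfp
    t = np.arange(ratio.size, dtype=float)
    slope, intercept = np.polyfit(t, ratio, 1)
    detrended = ratio - (slope * t + intercept)
    sd = detrended.std()
    if sd < 1e-12:
        raise ValueError("zero-variance ratio after detrending; cannot scale")
    return (detrended - detrended.mean()) / sd


def autocorrelation(x: np.ndarray, lag: int) -> float:
    """Biased (divide-by-N) sample autocorrelation at a single lag."""
    x = np.asarray(x, dtype=float)
    if lag < 0 or lag >= x.size:
        raise ValueError("lag must satisfy 0 <= lag < len(x)")
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom < 1e-300:
        return np.nan
    return float(np.dot(xc[: x.size - lag], xc[lag:]) / denom)


def nonrandom_filter(activity: np.ndarray, lag: int = NONRANDOM_LAG,
                     threshold: float = NONRANDOM_THRESHOLD) -> bool:
    """True iff lag-``lag`` autocorrelation exceeds ``threshold``.

    Neurons failing this gate are treated as missing by the regression
    models.  A constant trace (undefined autocorrelation) fails.
    """
    x = np.asarray(activity, dtype=float)
    if x.size <= lag:
        raise ValueError("series must be longer than the lag")
    r = autocorrelation(x, lag)
    return bool(np.isfinite(r) and r > threshold)


def preprocess_sample(raw: RawFluorescenceTable, *,
                      filter_window: int = 5,
                      completion_window: int = 4) -> ActivityMatrix:
    """Full cascade from a raw table to an :class:`ActivityMatrix`.

    Order: 5-point median filter on both channels, outlier detection on
    filtered CFP, NaN both channels at outliers, 4-point completion,
    neuron exclusion (count > 400 or residual gaps), ratio + detrend +
    z-score, autocorrelation gate.
    """
    n, T = raw.cfp.shape
    values = np.full((n, T), np.nan)
    included = np.zeros(n, dtype=bool)
    nonrandom = np.zeros(n, dtype=bool)
    for i in range(n):
        cfp_f = median_filter_time(raw.cfp[i], filter_window)
        yfp_f = median_filter_time(raw.yfp[i], filter_window)
        out = detect_outliers(cfp_f)
        # pre-existing missing points count as outliers for exclusion
        out |= ~np.isfinite(cfp_f) | ~np.isfinite(yfp_f)
        cfp_f = cfp_f.copy()
        yfp_f = yfp_f.copy()
        cfp_f[out] = np.nan
        yfp_f[out] = np.nan
        cfp_c = complete_missing(cfp_f, completion_window)
        yfp_c = complete_missing(yfp_f, completion_window)
        residual = not (np.isfinite(cfp_c).all() and np.isfinite(yfp_c).all())
        keep = drop_bad_neurons(np.array([out.sum()]),
                                np.array([residual]))[0]
        if not keep:
            continue
        try:
            act = compute_activity(cfp_c, yfp_c)
        except ValueError:
            continue
        values[i] = act
        included[i] = True
        nonrandom[i] = nonrandom_filter(act)
    return ActivityMatrix(raw.sample_id, list(raw.neuron_names), values,
                          included, nonrandom, raw.frame_rate)
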