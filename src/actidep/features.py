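"""Circadian and complexity features of multi-day actigraphy recordings.

The battery comprises the 16 predictors used for severity modelling:

* ``period`` — circadian period (h) from the Lomb–Scargle periodogram,
  restricted to a 20–28 h band and oversampled (factor 10) for fine
  resolution;
* ``M10``/``L5`` — mean hourly activity over the most active 10 and least
  active 5 consecutive hours of the mean daily profile, with their clock-time
  locations ``M10L``/``L5L``, and the relative amplitude
  ``RA = (M10 − L5)/(M10 + L5)``;
* ``alpha_full``/``alpha_short``/``alpha_long`` — detrended fluctuation
  analysis (DFA-1) scaling exponents over box sizes 4 min–24 h and its
  short/long sub-ranges;
* ``IV5/30/60`` — intradaily variability (fragmentation) at 5/30/60-min bins;
* ``IS5/30/60`` — interdaily stability (day-to-day profile consistency);
* ``age`` — subject age in years.

Sex is carried for descriptive tables but is not part of the model space.
All rhythm features except M10/L5 are invariant to the magnitude of the
reported counts, which makes them comparable across recording devices.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
from scipy.signal import lombscargle

from .actigraphy_io import EPOCHS_PER_DAY, EpochSeries

#: the 16-dimensional model feature space, in canonical column order
MODEL_FEATURES = (
    "period", "M10", "M10L", "L5", "L5L", "RA",
    "alpha_full", "alpha_short", "alpha_long",
    "IV5", "IV30", "IV60", "IS5", "IS30", "IS60", "age",
)


class FeatureError(ValueError):
    """A feature is undefined for the given input (e.g. zero variance)."""


# ---------------------------------------------------------------------------
# daily profile and nonparametric circadian metrics


@dataclass
class DailyProfile:
    """Mean activity by clock minute across days (1440 values)."""

    values: np.ndarray
    n_days: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != EPOCHS_PER_DAY:
            raise ValueError("daily profile must have 1440 values")


def daily_profile(series: EpochSeries) -> DailyProfile:
    """Per-clock-minute mean across days; masked epochs are excluded."""
    n = series.n_epochs
    if n % EPOCHS_PER_DAY != 0:
        raise ValueError("series length must be a whole number of days")
    days = n // EPOCHS_PER_DAY
    x = series.counts.reshape(days, EPOCHS_PER_DAY)
    ok = ~series.gap_mask.reshape(days, EPOCHS_PER_DAY)
    n_obs = ok.sum(axis=0)
    if np.any(n_obs == 0):
        raise FeatureError("some clock minutes have no unmasked observations")
    vals = np.where(ok, x, 0.0).sum(axis=0) / n_obs
    return DailyProfile(values=vals, n_days=days)


def m10_l5(profile: DailyProfile) -> dict[str, float]:
    """M10/L5 (counts per hour), their clock locations (window midpoints, h)
    and the relative amplitude, from an exhaustive circular window search at
    1-min steps.  Ties are broken by the earliest window start."""
    v = profile.values
    if np.all(v == 0):
        raise FeatureError("relative amplitude undefined for an all-zero profile")

    def window_means(length: int) -> np.ndarray:
        ext = np.concatenate([v, v[:length - 1]])
        c = np.concatenate([[0.0], np.cumsum(ext)])
        return (c[length:] - c[:-length]) / length

    w10 = window_means(600)
    w5 = window_means(300)
    i10 = int(np.argmax(w10))
    i5 = int(np.argmin(w5))
    m10 = float(w10[i10]) * 60.0
    l5 = float(w5[i5]) * 60.0
    return {
        "M10": m10,
        "M10L": ((i10 + 300) % EPOCHS_PER_DAY) / 60.0,
        "L5": l5,
        "L5L": ((i5 + 150) % EPOCHS_PER_DAY) / 60.0,
        "RA": (m10 - l5) / (m10 + l5),
    }


def circadian_peak_trough(profile: DailyProfile) -> dict[str, float]:
    """Max/min of the hour-binned daily profile and their clock positions
    (bin centres, hours).  Descriptive only; not part of the model space."""
    hourly = profile.values.reshape(24, 60).mean(axis=1)
    ipk = int(np.argmax(hourly))
    itr = int(np.argmin(hourly))
    return {"peak": float(hourly[ipk]), "peak_time": ipk + 0.5,
            "trough": float(hourly[itr]), "trough_time": itr + 0.5}


# ---------------------------------------------------------------------------
# circadian period (Lomb–Scargle)


def circadian_period(series: EpochSeries,
                     search_band: tuple[float, float] = (20.0, 28.0),
                     ofac: int = 10) -> float:
    """Period (h) at the maximum of the Lomb–Scargle periodogram within the
    search band, on a frequency grid oversampled by ``ofac`` relative to the
    1/T Fourier spacing.  Masked epochs are simply omitted (the estimator
    handles uneven sampling natively)."""
    lo, hi = search_band
    if not (0 < lo < hi):
        raise ValueError("search band must satisfy 0 < lo < hi")
    if series.n_days < 5:
        raise ValueError("need at least 5 days to estimate the circadian period")
    t_hours = np.arange(series.n_epochs) * series.epoch_min / 60.0
    ok = ~series.gap_mask
    t, y = t_hours[ok], series.counts[ok]
    y = y - y.mean()
    if np.ptp(y) == 0:
        raise FeatureError("period undefined for a constant series")
    span = series.n_epochs * series.epoch_min / 60.0
    df = 1.0 / (span * ofac)            # cycles/hour
    freqs = np.arange(1.0 / hi, 1.0 / lo + df / 2, df)
    if len(freqs) < 3:
        raise ValueError("search band too narrow for the frequency grid")
    power = lombscargle(t, y, 2 * np.pi * freqs, normalize=True)
    return float(1.0 / freqs[np.argmax(power)])


# ---------------------------------------------------------------------------
# detrended fluctuation analysis (DFA-1)


@dataclass
class DfaResult:
    alpha_full: float
    alpha_short: float
    alpha_long: float
    box_sizes: np.ndarray
    fluctuation: np.ndarray


def dfa_box_sizes(min_box: int = 4, max_box: int = 1440,
                  n_boxes: int = 50) -> np.ndarray:
    """Log-spaced candidate box sizes, deduplicated to unique integers."""
    sizes = np.unique(np.round(np.logspace(
        np.log10(min_box), np.log10(max_box), n_boxes)).astype(int))
    return sizes[(sizes >= min_box) & (sizes <= max_box)]


def dfa_alpha(series: np.ndarray | EpochSeries, min_box: int = 4,
              max_box: int = 1440, n_boxes: int = 50,
              short_max: int = 90, long_min: int = 120) -> DfaResult:
    """DFA-1 scaling exponents of a 1-min activity series.

    The mean-centred series is integrated; for each box size the integrated
    profile is split into non-overlapping boxes, a per-box linear trend is
    removed, and F(n) is the RMS residual.  ``alpha_full`` is the slope of
    log F(n) vs log n over all boxes, ``alpha_short``/``alpha_long`` over
    boxes ≤ ``short_max`` / ≥ ``long_min`` samples.  Boxes larger than a
    quarter of the series are dropped.
    """
    x = series.counts if isinstance(series, EpochSeries) else np.asarray(series, float)
    if np.ptp(x) == 0:
        raise FeatureError("DFA undefined for a constant series")
    n = len(x)
    sizes = dfa_box_sizes(min_box, max_box, n_boxes)
    sizes = sizes[sizes <= n // 4]
    if len(sizes) < 3:
        raise FeatureError("series too short for DFA box range")

    y = np.cumsum(x - x.mean())
    flucts = np.empty(len(sizes))
    for k, box in enumerate(sizes):
        nb = n // box
        seg = y[:nb * box].reshape(nb, box)
        t = np.arange(box) - (box - 1) / 2.0
        tv = float((t * t).sum())
        beta = (seg * t).sum(axis=1) / tv
        resid = seg - seg.mean(axis=1, keepdims=True) - beta[:, None] * t
        flucts[k] = np.sqrt(np.mean(resid ** 2))

    def slope(sel: np.ndarray) -> float:
        if sel.sum() < 3:
            raise FeatureError("fewer than 3 boxes in DFA sub-range")
        return float(np.polyfit(np.log(sizes[sel]), np.log(flucts[sel]), 1)[0])

    return DfaResult(
        alpha_full=slope(np.ones(len(sizes), dtype=bool)),
        alpha_short=slope(sizes <= short_max),
        alpha_long=slope(sizes >= long_min),
        box_sizes=sizes,
        fluctuation=flucts,
    )


# ---------------------------------------------------------------------------
# intradaily variability / interdaily stability


def _binned(series: EpochSeries, bin_min: int) -> np.ndarray:
    """Non-overlapping bin means; masked epochs are excluded from each bin
    mean (bins with no unmasked epoch fall back to the stored/imputed values);
    trailing epochs beyond a whole bin are dropped."""
    if bin_min % series.epoch_min != 0:
        raise ValueError("bin_min must be a multiple of the epoch length")
    per = bin_min // series.epoch_min
    nb = series.n_epochs // per
    if nb < 2:
        raise ValueError("need at least 2 bins")
    x = series.counts[:nb * per].reshape(nb, per)
    ok = ~series.gap_mask[:nb * per].reshape(nb, per)
    cnt = ok.sum(axis=1)
    out = np.where(cnt > 0,
                   np.where(ok, x, 0.0).sum(axis=1) / np.maximum(cnt, 1),
                   x.mean(axis=1))
    return out


def intradaily_variability(series: EpochSeries, bin_min: int = 60) -> float:
    """IV: mean squared successive difference of the binned series over its
    variance.  ≈2 for uncorrelated data, →0 for a smooth profile, >2 for
    rapidly alternating (fragmented) activity."""
    x = _binned(series, bin_min)
    n = len(x)
    denom = float(((x - x.mean()) ** 2).sum())
    if denom == 0:
        raise FeatureError("IV undefined for a constant binned series")
    num = float((np.diff(x) ** 2).sum())
    return n * num / ((n - 1) * denom)


def interdaily_stability(series: EpochSeries, bin_min: int = 60) -> float:
    """IS: variance of the mean daily profile over total variance of the
    binned series; 1 for perfectly repeating days, →1/n_days for noise."""
    x = _binned(series, bin_min)
    p = EPOCHS_PER_DAY * series.epoch_min // bin_min
    if len(x) % p != 0:
        raise ValueError("series must span a whole number of days")
    n = len(x)
    xm = x.mean()
    denom = float(((x - xm) ** 2).sum())
    if denom == 0:
        raise FeatureError("IS undefined for a constant binned series")
    prof = x.reshape(-1, p).mean(axis=0)
    num = float(((prof - xm) ** 2).sum())
    return n * num / (p * denom)


# ---------------------------------------------------------------------------
# assembly


@dataclass
class FeatureVector:
    """The 16 model predictors plus sex (descriptive only)."""

    period: float
    M10: float
    M10L: float
    L5: float
    L5L: float
    RA: float
    alpha_full: float
    alpha_short: float
    alpha_long: float
    IV5: float
    IV30: float
    IV60: float
    IS5: float
    IS30: float
    IS60: float
    age: float
    sex: int = 0

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def extract_features(series: EpochSeries, age: float, sex: int = 0,
                     dfa_short_max: int = 90, dfa_long_min: int = 120,
                     period_band: tuple[float, float] = (20.0, 28.0)) -> FeatureVector:
    """Extract the full battery from a QC-passed recording.

    Component errors are re-raised with the offending feature name attached.
    """
    out: dict[str, float] = {"age": float(age), "sex": int(sex)}

    def step(name: str, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (FeatureError, ValueError) as exc:
            raise FeatureError(f"{name}: {exc}") from exc

    prof = step("daily_profile", daily_profile, series)
    out.update(step("M10/L5", m10_l5, prof))
    out["period"] = step("period", circadian_period, series, period_band)
    dfa = step("alpha", dfa_alpha, series,
               short_max=dfa_short_max, long_min=dfa_long_min)
    out["alpha_full"] = dfa.alpha_full
    out["alpha_short"] = dfa.alpha_short
    out["alpha_long"] = dfa.alpha_long
    for b in (5, 30, 60):
        out[f"IV{b}"] = step(f"IV{b}", intradaily_variability, series, b)
        out[f"IS{b}"] = step(f"IS{b}", interdaily_stability, series, b)
    return FeatureVector(**out)
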