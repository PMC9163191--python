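"""Reading, representing and quality-screening wrist-actigraphy recordings.

Two open CSV dialects are supported:

* **raw-accelerometer CSV** — two ``# key: value`` header lines declaring the
  start time (ISO-8601) and sampling rate in Hz, a ``x,y,z`` column line, then
  one tri-axial sample per row in units of g.
* **epoch-count CSV** — a ``timestamp,count`` header then one row per 1-min
  epoch: ISO-8601 timestamp and a nonnegative activity count.  Missing
  timestamps are legal and become masked gap epochs on read.

Quality control follows the screening rules used for clinical actigraphy
cohorts: subjects with MADRS above 40 are excluded, recordings must span at
least five whole midnight-to-midnight days after cropping, must not contain
shift-work periods (supplied as operator annotations; shift work is not
detectable automatically), and must not contain gaps longer than two hours.
Shorter gaps are imputed from the mean daily profile and remain flagged in
the gap mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

EPOCHS_PER_DAY = 1440  # 1-min epochs in 24 h
MAX_GAP_EPOCHS = 120   # longest tolerated stretch of missing data: 2 h
MIN_DAYS = 5
MADRS_MAX = 40


class FormatError(ValueError):
    """A device export violates the declared dialect."""


class TooShortError(ValueError):
    """A recording does not span the required number of whole days."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class RawAccelSeries:
    """Tri-axial wrist acceleration at a fixed sampling rate, in units of g."""

    start_time: pd.Timestamp
    rate_hz: float
    samples: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class EpochSeries:
    """Multi-day activity counts in fixed 1-min epochs with a gap mask.

    ``gap_mask`` is True where the epoch was missing in the source export (or
    cropped out by an operator annotation) and its count is absent or imputed.
    """

    start_time: pd.Timestamp
    counts: np.ndarray
    gap_mask: np.ndarray | None = None
    epoch_min: int = 1

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time != self.start_time.floor("min"):
            raise ValueError("start_time must be minute-aligned")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(len(self.counts), dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if len(self.counts) != len(self.gap_mask):
            raise ValueError("counts and gap_mask lengths differ")
        valid = self.counts[~self.gap_mask]
        if valid.size and (np.any(~np.isfinite(valid)) or np.any(valid < 0)):
            raise ValueError("unmasked counts must be finite and nonnegative")

    @property
    def n_epochs(self) -> int:
        return len(self.counts)

    @property
    def n_days(self) -> float:
        return self.n_epochs * self.epoch_min / EPOCHS_PER_DAY

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(minutes=self.n_epochs * self.epoch_min)

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=self.n_epochs,
                             freq=f"{self.epoch_min}min")


@dataclass(frozen=True)
class Annotation:
    """Operator-supplied span from visual screening: a crop or shift work."""

    start: pd.Timestamp
    end: pd.Timestamp
    kind: str = "crop"  # "crop" | "shift_work"

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if self.kind not in ("crop", "shift_work"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("annotation end must follow start")


@dataclass
class QCReport:
    """Outcome of automated quality screening for one recording."""

    status: str  # "accepted" | "rejected"
    reasons: list[str] = field(default_factory=list)
    cropped_span: tuple[pd.Timestamp, pd.Timestamp] | None = None
    days_retained: int = 0
    series: EpochSeries | None = None  # cleaned, gap-imputed series if accepted

    def to_json(self) -> str:
        span = None
        if self.cropped_span is not None:
            span = [str(self.cropped_span[0]), str(self.cropped_span[1])]
        return json.dumps({
            "status": self.status,
            "reasons": self.reasons,
            "cropped_span": span,
            "days_retained": self.days_retained,
        }, indent=2)


# ---------------------------------------------------------------------------
# readers / writers


def read_raw_accel(path: str | Path) -> RawAccelSeries:
    """Parse a raw-accelerometer CSV (see module docstring for the dialect)."""
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, value = line[1:].split(":", 1)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: malformed header line")
                header[key.strip()] = value.strip()
                continue
            if line.replace(" ", "") == "x,y,z":
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                xyz = tuple(float(p) for p in parts)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric sample")
            if not all(np.isfinite(v) for v in xyz):
                raise FormatError(f"{path}:{lineno}: non-finite sample")
            rows.append(xyz)
    if "start_time" not in header or "rate_hz" not in header:
        raise FormatError(f"{path}: header must declare start_time and rate_hz")
    try:
        start = pd.Timestamp(header["start_time"])
        rate = float(header["rate_hz"])
    except ValueError:
        raise FormatError(f"{path}: unparseable start_time or rate_hz header")
    if not rows:
        raise FormatError(f"{path}: no samples")
    return RawAccelSeries(start_time=start, rate_hz=rate, samples=np.array(rows))


def write_raw_accel(series: RawAccelSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# start_time: {series.start_time.isoformat()}\n")
        fh.write(f"# rate_hz: {series.rate_hz:g}\n")
        fh.write("x,y,z\n")
        for x, y, z in series.samples:
            fh.write(f"{x:.6f},{y:.6f},{z:.6f}\n")


def read_epoch_export(path: str | Path) -> EpochSeries:
    """Parse an epoch-count CSV; missing timestamps become masked gap epochs.

    Raises :class:`FormatError` for irregular spacing (not a whole multiple of
    one minute), non-monotone timestamps, or negative counts.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["timestamp", "count"]:
        raise FormatError(f"{path}: expected 'timestamp,count' header")
    if df.empty:
        raise FormatError(f"{path}: no epochs")
    try:
        ts = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError):
        raise FormatError(f"{path}: unparseable timestamp")
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        lineno = int(counts.index[counts.isna()][0]) + 2  # +1 header +1 one-based
        raise FormatError(f"{path}:{lineno}: non-numeric count")
    if (counts < 0).any():
        lineno = int(counts.index[counts < 0][0]) + 2
        raise FormatError(f"{path}:{lineno}: negative count")
    deltas = ts.diff().dropna()
    if (deltas <= pd.Timedelta(0)).any():
        lineno = int(deltas.index[deltas <= pd.Timedelta(0)][0]) + 2
        raise FormatError(f"{path}:{lineno}: non-monotone timestamp")
    offsets = (ts - ts.iloc[0]) / pd.Timedelta(minutes=1)
    if not np.allclose(offsets, np.round(offsets), atol=1e-9):
        raise FormatError(f"{path}: timestamps not on a whole-minute grid")
    idx = np.round(offsets).astype(int).to_numpy()
    n = idx[-1] + 1
    full = np.zeros(n)
    mask = np.ones(n, dtype=bool)
    full[idx] = counts.to_numpy(dtype=float)
    mask[idx] = False
    return EpochSeries(start_time=ts.iloc[0].floor("min"), counts=full, gap_mask=mask)


def write_epoch_csv(series: EpochSeries, path: str | Path) -> None:
    """Write an epoch-count CSV; masked epochs are omitted (they are gaps)."""
    times = series.times()
    keep = ~series.gap_mask
    with open(path, "w") as fh:
        fh.write("timestamp,count\n")
        for t, c in zip(times[keep], series.counts[keep]):
            fh.write(f"{t.isoformat()},{c:g}\n")


# ---------------------------------------------------------------------------
# cropping and QC


def crop_to_midnights(series: EpochSeries) -> EpochSeries:
    """Crop to the span between the first and last midnight, yielding a whole
    number of 24-h days. Idempotent; raises :class:`TooShortError` if the
    recording does not cover one full midnight-to-midnight day."""
    if series.epoch_min != 1:
        raise ValueError("crop_to_midnights expects 1-min epochs")
    start, end = series.start_time, series.end_time
    first_mid = start.ceil("D") if start != start.floor("D") else start
    last_mid = end.floor("D")
    n_days = (last_mid - first_mid) / pd.Timedelta(days=1)
    if n_days < 1:
        raise TooShortError(
            f"recording spans no full midnight-to-midnight day ({start} to {end})")
    i0 = int((first_mid - start) / pd.Timedelta(minutes=1))
    i1 = i0 + int(n_days) * EPOCHS_PER_DAY
    return EpochSeries(start_time=first_mid, counts=series.counts[i0:i1].copy(),
                       gap_mask=series.gap_mask[i0:i1].copy())


def impute_gaps(series: EpochSeries) -> EpochSeries:
    """Fill masked epochs with the mean daily-profile value at the same clock
    minute, computed from unmasked epochs; the gap mask is retained."""
    if not series.gap_mask.any():
        return series
    n = series.n_epochs
    minute = (np.arange(n) + int((series.start_time - series.start_time.floor("D"))
                                 / pd.Timedelta(minutes=1))) % EPOCHS_PER_DAY
    counts = series.counts.copy()
    ok = ~series.gap_mask
    profile = np.full(EPOCHS_PER_DAY, np.nan)
    for m in range(EPOCHS_PER_DAY):
        sel = ok & (minute == m)
        if sel.any():
            profile[m] = counts[sel].mean()
    if np.isnan(profile).any():
        # fall back to the global mean for clock minutes never observed
        profile[np.isnan(profile)] = counts[ok].mean()
    counts[series.gap_mask] = profile[minute[series.gap_mask]]
    return replace(series, counts=counts)


def _longest_gap(mask: np.ndarray) -> int:
    longest = run = 0
    for v in mask:
        run = run + 1 if v else 0
        longest = max(longest, run)
    return longest


def qc_screen(series: EpochSeries, madrs: int,
              annotations: Sequence[Annotation] = ()) -> QCReport:
    """Apply the inclusion rules and return a :class:`QCReport`.

    Rejection reasons (any may fire; all that fire are reported):

    * ``MADRS_GT_40`` — symptom severity above the included range;
    * ``SHIFT_WORK``  — a shift-work annotation is present;
    * ``TOO_SHORT``   — fewer than five whole days after cropping;
    * ``MISSING_DATA`` — a contiguous gap longer than 2 h.

    On acceptance, sub-threshold gaps are imputed (mask retained) and the
    cleaned, midnight-cropped series is attached to the report.
    """
    reasons: list[str] = []
    if madrs > MADRS_MAX:
        reasons.append("MADRS_GT_40")
    if any(a.kind == "shift_work" for a in annotations):
        reasons.append("SHIFT_WORK")

    # mask operator-cropped spans, drop fully-masked edges, crop to midnights
    mask = series.gap_mask.copy()
    times = series.times()
    for a in annotations:
        if a.kind == "crop":
            mask |= (times >= a.start) & (times < a.end)
    work = EpochSeries(series.start_time, series.counts, mask)
    keep = np.flatnonzero(~work.gap_mask)
    if keep.size:
        work = EpochSeries(work.start_time + pd.Timedelta(minutes=int(keep[0])),
                           work.counts[keep[0]:keep[-1] + 1],
                           work.gap_mask[keep[0]:keep[-1] + 1])
    try:
        cropped = crop_to_midnights(work)
    except TooShortError:
        reasons.append("TOO_SHORT")
        return QCReport(status="rejected", reasons=reasons)

    days = cropped.n_epochs // EPOCHS_PER_DAY
    if days < MIN_DAYS:
        reasons.append("TOO_SHORT")
    if _longest_gap(cropped.gap_mask) > MAX_GAP_EPOCHS:
        reasons.append("MISSING_DATA")
    span = (cropped.start_time, cropped.end_time)
    if reasons:
        return QCReport(status="rejected", reasons=reasons,
                        cropped_span=span, days_retained=days)
    return QCReport(status="accepted", reasons=[], cropped_span=span,
                    days_retained=days, series=impute_gaps(cropped))
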