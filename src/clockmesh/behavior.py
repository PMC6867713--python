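"""Wheel-running analysis.

Implements the explicit activity-onset rule — the first bin above a
threshold of 15 counts, preceded by at least 6 h of inactivity and
followed within 30 min by at least two more bins likewise above threshold
— together with its mirrored offset rule, activity duration (alpha),
free-running period from a regression on activity onsets in constant
darkness, re-entrainment after a 6-h advance of the light cycle, and
weekly tracking of alpha decompression after release into DD.

"Inactivity" means count <= threshold.  Onsets are reported as the
qualifying bin's start time, offsets as the bin's end time, so the pair
brackets the active phase.  All windows are computed in minutes and
converted to bin counts from the actogram's own bin width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "Actogram",
    "DailyMarkers",
    "DecompressionCurve",
    "detect_onset",
    "detect_offset",
    "activity_duration",
    "daily_markers",
    "free_running_period",
    "days_to_reentrain",
    "decompression_curve",
    "read_awd",
    "write_awd",
    "read_counts_csv",
    "read_lights_csv",
]

DEFAULT_THRESHOLD = 15  # counts; from the published onset rule


@dataclass
class Actogram:
    """Binned wheel-running counts with a light schedule.

    ``lights`` holds one entry per day: ``(lights_on, lights_off)`` clock
    hours, or ``None`` for constant darkness.
    """

    counts: np.ndarray
    bin_minutes: int
    lights: list | None = None
    start: str = ""
    subject: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if 1440 % self.bin_minutes != 0:
            raise ValueError("bin_minutes must divide 1440")
        bpd = 1440 // self.bin_minutes
        if c.size % bpd != 0:
            raise ValueError("counts must cover a whole number of days")
        self.counts = c
        if self.lights is not None and len(self.lights) != c.size // bpd:
            raise ValueError("lights table must have one entry per day")

    @property
    def bins_per_day(self) -> int:
        return 1440 // self.bin_minutes

    @property
    def n_days(self) -> int:
        return self.counts.size // self.bins_per_day

    @property
    def bin_hours(self) -> float:
        return self.bin_minutes / 60.0

    def day_in_dd(self, day: int) -> bool:
        return self.lights is None or self.lights[day] is None


@dataclass
class DailyMarkers:
    """Per-day activity onset/offset (clock hours) and alpha (hours)."""

    onset: list = field(default_factory=list)  # float or None per day
    offset: list = field(default_factory=list)
    alpha: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": np.arange(len(self.onset)),
                "onset_h": [np.nan if v is None else v for v in self.onset],
                "offset_h": [np.nan if v is None else v for v in self.offset],
                "alpha_h": [np.nan if v is None else v for v in self.alpha],
            }
        )


def _windows_in_bins(actogram: Actogram, inactivity_h: float, confirm_min: float):
    look = int(round(inactivity_h * 60.0 / actogram.bin_minutes))
    confirm = int(round(confirm_min / actogram.bin_minutes))
    return look, confirm


def detect_onset(
    actogram: Actogram,
    day: int,
    threshold: int = DEFAULT_THRESHOLD,
    inactivity_h: float = 6.0,
    confirm_min: float = 30.0,
    confirm_bins: int = 2,
) -> float | None:
    """Activity onset for one day, or ``None`` when no bin qualifies.

    A bin qualifies iff (a) its count exceeds ``threshold``, (b) every bin
    in the preceding ``inactivity_h`` hours is at or below threshold, and
    (c) at least ``confirm_bins`` of the bins within the following
    ``confirm_min`` minutes exceed threshold.  Returns the first
    qualifying bin's start time in clock hours.
    """
    counts = actogram.counts
    bpd = actogram.bins_per_day
    look, confirm = _windows_in_bins(actogram, inactivity_h, confirm_min)
    lo, hi = day * bpd, (day + 1) * bpd
    if hi > counts.size:
        raise IndexError("day outside the record")
    for j in range(lo, hi):
        if counts[j] <= threshold:
            continue
        if j - look < 0 or j + confirm >= counts.size:
            logger.debug("day %d bin %d: insufficient context for onset rule", day, j)
            continue
        if np.any(counts[j - look : j] > threshold):
            continue
        if np.count_nonzero(counts[j + 1 : j + 1 + confirm] > threshold) < confirm_bins:
            continue
        return (j - lo) * actogram.bin_hours
    return None


def detect_offset(
    actogram: Actogram,
    day: int,
    threshold: int = DEFAULT_THRESHOLD,
    inactivity_h: float = 6.0,
    confirm_min: float = 30.0,
    confirm_bins: int = 2,
) -> float | None:
    """Activity offset for one day: the mirrored onset rule.

    The last bin above threshold that is followed by at least
    ``inactivity_h`` hours of bins at or below threshold and preceded
    within ``confirm_min`` minutes by at least ``confirm_bins`` bins above
    threshold.  Returns the qualifying bin's end time in clock hours.
    """
    counts = actogram.counts
    bpd = actogram.bins_per_day
    look, confirm = _windows_in_bins(actogram, inactivity_h, confirm_min)
    lo, hi = day * bpd, (day + 1) * bpd
    if hi > counts.size:
        raise IndexError("day outside the record")
    for j in range(hi - 1, lo - 1, -1):
        if counts[j] <= threshold:
            continue
        if j + 1 + look > counts.size or j - confirm < 0:
            logger.debug("day %d bin %d: insufficient context for offset rule", day, j)
            continue
        if np.any(counts[j + 1 : j + 1 + look] > threshold):
            continue
        if np.count_nonzero(counts[j - confirm : j] > threshold) < confirm_bins:
            continue
        return (j - lo + 1) * actogram.bin_hours
    return None


def activity_duration(onset: float | None, offset: float | None) -> float | None:
    """Alpha in hours: ``(offset - onset) mod 24`` taken in ``(0, 24]``."""
    if onset is None or offset is None:
        return None
    alpha = (offset - onset) % 24.0
    return 24.0 if alpha == 0.0 else alpha


def daily_markers(actogram: Actogram, threshold: int = DEFAULT_THRESHOLD, **kw) -> DailyMarkers:
    """Onset, offset, and alpha for every day of the record."""
    markers = DailyMarkers()
    for day in range(actogram.n_days):
        on = detect_onset(actogram, day, threshold, **kw)
        off = detect_offset(actogram, day, threshold, **kw)
        markers.onset.append(on)
        markers.offset.append(off)
        markers.alpha.append(activity_duration(on, off))
    return markers


def _unwrap_onsets(days: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    """Cumulative onset times: add 24 h per day, then resolve wrap jumps."""
    x = onsets + 24.0 * days
    out = x.copy()
    for i in range(1, x.size):
        expected = out[i - 1] + 24.0 * (days[i] - days[i - 1])
        k = np.round((expected - x[i]) / 24.0)
        out[i] = x[i] + 24.0 * k
    return out


def free_running_period(onsets, min_onsets: int = 7) -> float:
    """Free-running period from the slope of a regression on activity onsets.

    ``onsets`` is a per-day sequence of clock hours (``None``/nan for days
    without a detected onset).  Onsets are unwrapped cumulatively (24 h per
    day plus drift) and the least-squares slope in hours/day is the period.
    """
    vals = [(d, v) for d, v in enumerate(onsets) if v is not None and np.isfinite(v)]
    if len(vals) < min_onsets:
        raise ValueError(f"need at least {min_onsets} onsets, got {len(vals)}")
    days = np.array([d for d, _ in vals], dtype=float)
    onset_h = np.array([v for _, v in vals], dtype=float)
    x = _unwrap_onsets(days, onset_h)
    slope = np.polyfit(days, x, 1)[0]
    return float(slope)


def days_to_reentrain(
    onsets,
    shift_day: int,
    shift_h: float = 6.0,
    tolerance_min: float = 30.0,
) -> int | None:
    """Days needed to shift activity onset by ``shift_h`` (advance) after a jetlag.

    ``shift_day`` indexes the first day under the new schedule.  Returns
    the first post-shift day (1-based relative to the shift) whose onset is
    within tolerance of (mean pre-shift onset - ``shift_h``) and stays
    within tolerance on every later recorded day; ``None`` if the record
    never realigns.
    """
    from clockmesh.network import circular_mean_time, wrap_phase

    pre = [v for v in onsets[:shift_day] if v is not None and np.isfinite(v)]
    if not pre:
        raise ValueError("no pre-shift onsets")
    target = (circular_mean_time(pre) - shift_h) % 24.0
    tol_h = tolerance_min / 60.0
    post = onsets[shift_day:]
    aligned = [
        abs(wrap_phase(v - target)) <= tol_h + 1e-9
        if v is not None and np.isfinite(v)
        else None
        for v in post
    ]
    for i, ok in enumerate(aligned):
        if ok and all(a is not False for a in aligned[i:]):
            return i + 1
    logger.info("record never realigned to the shifted schedule")
    return None


@dataclass
class DecompressionCurve:
    """Weekly alpha means after DD release, with an exponential summary fit."""

    week: np.ndarray  # week index, 0-based
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    tau_days: float  # inf when alpha is flat
    alpha_start: float
    alpha_end: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"week": self.week, "alpha_mean_h": self.mean, "alpha_sem_h": self.sem,
             "n": self.n}
        )


def decompression_curve(alphas) -> DecompressionCurve:
    """Weekly alpha means +/- SEM and a fitted exponential time constant.

    ``alphas`` is the per-day alpha sequence over the DD epoch.  The
    summary fit is ``a_end - (a_end - a_start) * exp(-t / tau)`` by least
    squares on the weekly means; a flat profile is flagged with an
    infinite time constant.
    """
    arr = np.array(
        [np.nan if v is None else float(v) for v in alphas], dtype=float
    )
    if arr.size < 1:
        raise ValueError("need at least one alpha")
    n_weeks = int(np.ceil(arr.size / 7))
    means, sems, ns = [], [], []
    for w in range(n_weeks):
        chunk = arr[w * 7 : (w + 1) * 7]
        chunk = chunk[np.isfinite(chunk)]
        ns.append(chunk.size)
        means.append(np.mean(chunk) if chunk.size else np.nan)
        sems.append(
            np.std(chunk, ddof=1) / np.sqrt(chunk.size) if chunk.size > 1 else np.nan
        )
    week = np.arange(n_weeks)
    means = np.asarray(means)
    sems = np.asarray(sems)
    ok = np.isfinite(means)
    tau = float("inf")
    a0 = float(means[ok][0]) if ok.any() else float("nan")
    a1 = float(means[ok][-1]) if ok.any() else float("nan")
    if ok.sum() >= 3 and np.ptp(means[ok]) > 1e-9:
        t = (week[ok] + 0.5) * 7.0  # week centers in days

        def model(tt, a_end, a_start, tau_d):
            return a_end - (a_end - a_start) * np.exp(-tt / tau_d)

        try:
            popt, _ = curve_fit(
                model,
                t,
                means[ok],
                p0=[a1, a0, max(7.0, t[-1] / 3.0)],
                maxfev=10000,
            )
            a1, a0, tau = float(popt[0]), float(popt[1]), float(abs(popt[2]))
        except RuntimeError:
            logger.warning("decompression fit did not converge; tau left infinite")
    return DecompressionCurve(
        week=week,
        mean=means,
        sem=sems,
        n=np.asarray(ns),
        tau_days=tau,
        alpha_start=a0,
        alpha_end=a1,
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def read_awd(path) -> Actogram:
    """Read an AWD-style text record: 3 header lines, then one count per line."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    subject = lines[0]
    start = lines[1]
    bin_minutes = int(float(lines[2]))
    counts = np.array([int(float(x)) for x in lines[3:]], dtype=int)
    return Actogram(
        counts=counts, bin_minutes=bin_minutes, start=start, subject=subject
    )


def write_awd(actogram: Actogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{actogram.subject or 'subject'}\n")
        fh.write(f"{actogram.start or '2000-01-01 00:00'}\n")
        fh.write(f"{actogram.bin_minutes}\n")
        for c in actogram.counts:
            fh.write(f"{int(c)}\n")


def read_counts_csv(path, bin_minutes: int | None = None) -> Actogram:
    """Read a (timestamp, counts) CSV; the bin width is inferred if omitted."""
    df = pd.read_csv(path)
    ts = pd.to_datetime(df.iloc[:, 0])
    counts = df.iloc[:, 1].to_numpy(int)
    if bin_minutes is None:
        deltas = ts.diff().dropna().dt.total_seconds() / 60.0
        bin_minutes = int(round(deltas.mode().iloc[0]))
    start = str(ts.iloc[0])
    return Actogram(counts=counts, bin_minutes=bin_minutes, start=start)


def read_lights_csv(path) -> list:
    """Light schedule CSV (date, lights_on, lights_off | DD) -> per-day list."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        on = str(row["lights_on"]).strip()
        if on.upper() == "DD":
            out.append(None)
        else:
            out.append((float(on), float(row["lights_off"])))
    return out
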