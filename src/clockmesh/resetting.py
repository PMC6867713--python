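"""Phase-response-curve assay from whole-dish luminometry.

A culture is monitored for at least three cycles, a stimulus (e.g. GABA)
is applied, and the resetting response is the difference between the
predicted and the actual time of the first post-pulse peak: the pre-pulse
peaks define a period and an extrapolated lattice; a peak arriving earlier
than predicted is a phase advance (positive), later a delay (negative).
The circadian time of the pulse is assigned relative to the last pre-pulse
peak, with the reporter peak conventionally at CT12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clockmesh import rhythms
from clockmesh.network import wrap_phase
from clockmesh.rhythms import PeakList, TimeSeries

__all__ = [
    "PulseRecord",
    "PhaseShift",
    "predicted_peak",
    "phase_shift",
    "circadian_time",
    "measure_shift",
    "assemble_prc",
]

CT_OF_PEAK_DEFAULT = 12.0  # PER2::LUC peak conventionally assigned CT12


@dataclass
class PulseRecord:
    """A luminometry trace with the time and label of its pulse."""

    trace: TimeSeries
    pulse_time: float
    label: str = ""

    def __post_init__(self) -> None:
        t = self.trace.times
        if not (t[0] < self.pulse_time < t[-1]):
            raise ValueError("pulse_time must lie inside the trace's span")


@dataclass(frozen=True)
class PhaseShift:
    """A signed resetting response: advance positive, delay negative."""

    shift: float  # hours
    ct_pulse: float  # circadian hours in [0, 24)
    pre_period: float  # hours

    def __post_init__(self) -> None:
        if abs(self.shift) > self.pre_period / 2.0 + 1e-9:
            raise ValueError("|shift| cannot exceed half the pre-pulse period")
        if not (0.0 <= self.ct_pulse < 24.0):
            raise ValueError("ct_pulse must lie in [0, 24)")


def predicted_peak(pre_peaks: PeakList) -> tuple[float, float]:
    """Extrapolate the next peak from the pre-pulse peaks.

    Returns ``(predicted_time, pre_period)`` where the pre-pulse period is
    the mean of all pre-pulse peak intervals and the prediction is the
    last pre-pulse peak plus one period.
    """
    times = pre_peaks.peak_times
    if times.size < 2:
        raise ValueError("need at least 2 pre-pulse peaks")
    pre_period = float(np.mean(np.diff(times)))
    return float(times[-1] + pre_period), pre_period


def phase_shift(predicted: float, actual: float, pre_period: float) -> float:
    """Signed shift in hours: wrapped(predicted - actual).

    A peak arriving later than predicted gives a negative (delay) shift.
    """
    if pre_period <= 0:
        raise ValueError("pre_period must be positive")
    return wrap_phase(predicted - actual, pre_period)


def circadian_time(
    pulse_time: float,
    last_pre_peak: float,
    pre_period: float,
    ct_of_peak: float = CT_OF_PEAK_DEFAULT,
) -> float:
    """Circadian time of the pulse, anchored to the reporter peak.

    ``ct = (ct_of_peak + 24 * (pulse_time - last_pre_peak) / pre_period) mod 24``.
    """
    if pre_period <= 0:
        raise ValueError("pre_period must be positive")
    if pulse_time < last_pre_peak - pre_period:
        raise ValueError("pulse precedes the last pre-pulse cycle")
    return float(
        (ct_of_peak + 24.0 * (pulse_time - last_pre_peak) / pre_period) % 24.0
    )


def _condition_segment(ts: TimeSeries, smooth: bool) -> TimeSeries:
    out = rhythms.detrend_exponential(ts)
    if smooth:
        out = rhythms.lowpass(out)
    return out


def measure_shift(
    record: PulseRecord,
    preprocess=None,
    min_separation: float = 16.0,
    ct_of_peak: float = CT_OF_PEAK_DEFAULT,
    smooth: bool = True,
) -> PhaseShift:
    """Full resetting measurement on one trace.

    The pre- and post-pulse segments are conditioned separately (so the
    waveform discontinuity at the pulse cannot leak into either side
    through a zero-phase filter): each is detrended by an exponential
    envelope fit and optionally low-pass smoothed.  Pre-pulse peaks give
    the period and the predicted peak; the first post-pulse peak gives the
    signed shift, and the pulse is assigned a circadian time relative to
    the last pre-pulse peak.
    """
    if preprocess is None:
        preprocess = lambda ts: _condition_segment(ts, smooth)
    t, v = record.trace.times, record.trace.values
    split = int(np.searchsorted(t, record.pulse_time))
    if split < 4 or t.size - split < 4:
        raise ValueError("too few samples on one side of the pulse")
    pre_seg = preprocess(TimeSeries(t[:split], v[:split]))
    post_seg = preprocess(TimeSeries(t[split:], v[split:]))
    pre = rhythms.find_peaks(pre_seg, min_separation).peak_times
    post = rhythms.find_peaks(post_seg, min_separation).peak_times
    if pre.size < 2:
        raise ValueError("need at least 2 pre-pulse peaks")
    if post.size < 1:
        raise ValueError("no post-pulse peak detected")
    predicted, pre_period = predicted_peak(PeakList(pre, np.zeros_like(pre)))
    shift = phase_shift(predicted, float(post[0]), pre_period)
    ct = circadian_time(record.pulse_time, float(pre[-1]), pre_period, ct_of_peak)
    return PhaseShift(shift=shift, ct_pulse=ct, pre_period=pre_period)


def assemble_prc(
    shifts: list[PhaseShift],
    vehicle: list[PhaseShift] | None = None,
    bins=(0.0, 6.0, 12.0, 18.0),
    window: float = 4.0,
    double_plot: bool = False,
) -> dict:
    """Assemble a phase-response curve from measured shifts.

    Returns a dict with the smoothed curve (4-h circular running average
    over circadian time), bin means +/- SEM at the requested circadian
    times, and the vehicle mean +/- SEM as the zero band.  With
    ``double_plot`` the exported table repeats every point at ct + 24.
    """
    if not shifts:
        raise ValueError("need at least one shift")
    ct = np.array([s.ct_pulse for s in shifts])
    y = np.array([s.shift for s in shifts])
    sm = rhythms.running_average(
        np.column_stack([ct, y]), window=window, circular_period=24.0, bins=bins
    )
    table = pd.DataFrame({"ct": ct, "shift_h": y})
    if double_plot:
        table = pd.concat(
            [table, table.assign(ct=table["ct"] + 24.0)], ignore_index=True
        )
    out = {
        "table": table.sort_values("ct").reset_index(drop=True),
        "smoothed": sm,
        "bin_centers": np.asarray(bins, dtype=float),
        "bin_mean": sm.bin_mean,
        "bin_sem": sm.bin_sem,
        "bin_n": sm.bin_n,
    }
    if vehicle:
        vy = np.array([s.shift for s in vehicle])
        out["vehicle_mean"] = float(np.mean(vy))
        out["vehicle_sem"] = (
            float(np.std(vy, ddof=1) / np.sqrt(vy.size)) if vy.size > 1 else float("nan")
        )
    return out
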