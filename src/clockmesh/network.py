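"""Shell-core network statistics.

The central quantity is psi, the shell-core phase relationship: the
circular-mean peak time of core ROIs minus the circular-mean peak time of
shell ROIs on a given cycle in vitro, wrapped to a half-period interval.
Negative psi means the core phase-leads (peaks before) the shell.

The coupling response delta-psi is the wrapped change in psi between an
early and a late cycle; its sign relative to the starting psi classifies
the direction of network resynchronization ("negative": the gap closes
directly toward zero; "positive": the network resynchronizes the long way
round, through the half-period boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from clockmesh import rhythms

logger = logging.getLogger(__name__)

__all__ = [
    "wrap_phase",
    "circular_mean_time",
    "CouplingRecord",
    "ResponseCurve",
    "slice_psi",
    "psi_by_cycle",
    "coupling_response",
    "per_cell_records",
    "records_to_frame",
    "coupling_response_curve",
    "period_response_curve",
    "classify_direction",
]


def wrap_phase(x, period: float = 24.0, center: float = 0.0):
    """Wrap hours into ``(center - period/2, center + period/2]``.

    With the default center the result lies in ``(-period/2, period/2]``;
    exactly half a period away maps to the positive boundary.  A non-zero
    ``center`` re-centres the branch cut, e.g. ``center=-4`` represents
    phase gaps in ``(-16, +8]`` — the convention used for long-photoperiod
    ensembles where the core is known to phase-lead.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    x = np.asarray(x, dtype=float)
    r = (x - center) % period  # [0, period)
    r = np.where(r > period / 2.0, r - period, r)
    out = r + center
    return float(out) if out.ndim == 0 else out


def circular_mean_time(times, period: float = 24.0) -> float:
    """Vector-average times on a ``period``-hour circle, result in [0, period)."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("cannot average an empty set of times")
    ang = 2.0 * np.pi * t / period
    mean_ang = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    v = (mean_ang * period / (2.0 * np.pi)) % period
    return 0.0 if period - v < 1e-9 else float(v)


@dataclass
class CouplingRecord:
    """Per-cell record of coupling and period responses.

    ``rel_peak_c2`` is the cell's cycle-2 peak time minus the circular-mean
    cycle-2 peak time of the complementary region, wrapped to (-12, 12].
    ``psi_early``/``psi_late`` are slice-level psi at the early/late cycle;
    ``delta_psi`` is the wrapped difference (the coupling response).
    """

    cell_id: str
    region: str
    rel_peak_c2: float
    period: float
    psi_early: float
    psi_late: float
    delta_psi: float
    slice_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.region not in ("shell", "core"):
            raise ValueError("region must be 'shell' or 'core'")
        for name in ("rel_peak_c2", "psi_early", "psi_late"):
            v = getattr(self, name)
            if np.isfinite(v) and not (-12.0 < v <= 12.0):
                raise ValueError(f"{name} must lie in (-12, 12]")


@dataclass
class ResponseCurve:
    """A smoothed response curve with bin summaries, on a 24-h circular abscissa."""

    abscissa: np.ndarray
    ordinate: np.ndarray
    smoothed: rhythms.SmoothedCurve
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "abscissa_h": self.abscissa,
                "ordinate": self.ordinate,
                "smoothed": self.smoothed.y,
            }
        )
        return df


def _region_peaks_on_cycle(peaks_by_cell, regions, cycle: int, region: str):
    out = []
    for cell_peaks, reg in zip(peaks_by_cell, regions):
        if reg != region:
            continue
        if len(cell_peaks) >= cycle:
            out.append(cell_peaks.peak_times[cycle - 1])
    return np.asarray(out, dtype=float)


def slice_psi(
    peaks_by_cell,
    regions,
    cycle: int = 2,
    period: float = 24.0,
    method: str = "circular",
) -> float:
    """Slice-level shell-core phase relationship on one cycle, in hours.

    ``peaks_by_cell`` is a sequence of :class:`~clockmesh.rhythms.PeakList`
    (one per cell) and ``regions`` the matching 'shell'/'core' labels.
    psi = wrapped(core mean peak time - shell mean peak time); negative
    values mean the core peaks first (phase-leads).  Returns ``nan`` when
    either region has no peak on that cycle.
    """
    core = _region_peaks_on_cycle(peaks_by_cell, regions, cycle, "core")
    shell = _region_peaks_on_cycle(peaks_by_cell, regions, cycle, "shell")
    if core.size == 0 or shell.size == 0:
        logger.warning("cycle %d: a region has no detected peak; psi undefined", cycle)
        return float("nan")
    if method == "circular":
        mc = circular_mean_time(core, period)
        ms = circular_mean_time(shell, period)
    elif method == "arithmetic":
        mc, ms = float(np.mean(core)), float(np.mean(shell))
    else:
        raise ValueError("method must be 'circular' or 'arithmetic'")
    return wrap_phase(mc - ms, period)


def psi_by_cycle(
    peaks_by_cell,
    regions,
    cycles=(1, 2, 3, 4, 5),
    period: float = 24.0,
    method: str = "circular",
) -> dict[int, float]:
    """psi evaluated on each requested cycle (nan where undefined)."""
    return {
        c: slice_psi(peaks_by_cell, regions, c, period=period, method=method)
        for c in cycles
    }


def coupling_response(
    psi_map: dict[int, float], early: int = 2, late: int = 5, period: float = 24.0
) -> float:
    """Coupling response delta-psi = wrapped(psi_late - psi_early), hours.

    Positive delta-psi from a negative psi_early means the gap closed
    directly toward zero; recovery through the half-period boundary shows
    up with the same sign as psi_early.
    """
    if early not in psi_map or late not in psi_map:
        return float("nan")
    pe, pl = psi_map[early], psi_map[late]
    if not (np.isfinite(pe) and np.isfinite(pl)):
        return float("nan")
    return wrap_phase(pl - pe, period)


def per_cell_records(
    traces,
    regions,
    cell_ids=None,
    *,
    preprocess=None,
    min_separation: float = 16.0,
    period_cycles: tuple[int, int] = (2, 4),
    early_cycle: int = 2,
    late_cycle: int = 5,
    psi_method: str = "circular",
    slice_id: str = "",
    condition: str = "",
    preprocessed: bool = False,
) -> list[CouplingRecord]:
    """Build per-cell coupling/period records from cell traces.

    Each trace is detrended, band-pass filtered, and peak-detected (unless
    ``preprocessed``).  Cells lacking the required peaks are omitted and
    the omission count is logged.
    """
    regions = list(regions)
    if cell_ids is None:
        cell_ids = [f"c{i:03d}" for i in range(len(regions))]
    if preprocess is None:
        preprocess = rhythms.preprocess_trace
    peaks_by_cell = []
    for ts in traces:
        if not preprocessed:
            ts = preprocess(ts)
        peaks_by_cell.append(rhythms.find_peaks(ts, min_separation))

    psis = psi_by_cycle(
        peaks_by_cell,
        regions,
        cycles=sorted({early_cycle, late_cycle}),
        method=psi_method,
    )
    p_early, p_late = psis[early_cycle], psis[late_cycle]
    dpsi = coupling_response({early_cycle: p_early, late_cycle: p_late},
                             early_cycle, late_cycle)

    # circular mean cycle-2 peak per region, for relative peak times
    region_mean_c2 = {}
    for reg in ("shell", "core"):
        pk = _region_peaks_on_cycle(peaks_by_cell, regions, early_cycle, reg)
        region_mean_c2[reg] = circular_mean_time(pk) if pk.size else float("nan")

    records: list[CouplingRecord] = []
    skipped = 0
    need = max(period_cycles[1], early_cycle)
    for cid, reg, pk in zip(cell_ids, regions, peaks_by_cell):
        if len(pk) < need:
            skipped += 1
            continue
        comp = "shell" if reg == "core" else "core"
        rel = wrap_phase(pk.peak_times[early_cycle - 1] - region_mean_c2[comp])
        per = rhythms.mean_period(pk, period_cycles)
        records.append(
            CouplingRecord(
                cell_id=cid,
                region=reg,
                rel_peak_c2=rel,
                period=per,
                psi_early=p_early,
                psi_late=p_late,
                delta_psi=dpsi,
                slice_id=slice_id,
                condition=condition,
            )
        )
    if skipped:
        logger.info("omitted %d cell(s) lacking required peaks", skipped)
    return records


def records_to_frame(records) -> pd.DataFrame:
    """CouplingRecord list -> tidy table (the source-data CSV layout)."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "region": [r.region for r in records],
            "rel_peak_c2_h": [r.rel_peak_c2 for r in records],
            "period_h": [r.period for r in records],
            "psi_early_h": [r.psi_early for r in records],
            "psi_late_h": [r.psi_late for r in records],
            "delta_psi_h": [r.delta_psi for r in records],
            "slice_id": [r.slice_id for r in records],
            "condition": [r.condition for r in records],
        }
    )


def _make_curve(x, y, window, bins, label) -> ResponseCurve:
    pts = np.column_stack([x, y])
    sm = rhythms.running_average(pts, window=window, circular_period=24.0, bins=bins)
    return ResponseCurve(
        abscissa=np.asarray(x, dtype=float),
        ordinate=np.asarray(y, dtype=float),
        smoothed=sm,
        label=label,
    )


def coupling_response_curve(
    records,
    window: float = 4.0,
    bins=None,
    abscissa: str = "psi_early",
    abscissa_center: float = 0.0,
) -> ResponseCurve:
    """Coupling response curve: delta-psi against the early-cycle state.

    ``abscissa`` selects the slice-level early psi (one point per slice is
    conventional) or the per-cell relative peak time.  ``abscissa_center``
    re-centres the circular abscissa, e.g. -4 for long-photoperiod
    ensembles where core lead beyond -12 h is meaningful.
    """
    if abscissa not in ("psi_early", "rel_peak_c2"):
        raise ValueError("abscissa must be 'psi_early' or 'rel_peak_c2'")
    x = np.array([getattr(r, abscissa) for r in records], dtype=float)
    y = np.array([r.delta_psi for r in records], dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        raise ValueError("no finite records for the coupling response curve")
    x = wrap_phase(x[ok], 24.0, abscissa_center)
    return _make_curve(x, y[ok], window, bins, "coupling_response")


def period_response_curve(
    records,
    window: float = 4.0,
    bins=None,
    abscissa_center: float = 0.0,
) -> dict[str, ResponseCurve]:
    """Per-region period response curves: cellular period vs rel. peak time."""
    out: dict[str, ResponseCurve] = {}
    for reg in ("shell", "core"):
        sel = [r for r in records if r.region == reg
               and np.isfinite(r.rel_peak_c2) and np.isfinite(r.period)]
        if not sel:
            continue
        x = wrap_phase(
            np.array([r.rel_peak_c2 for r in sel]), 24.0, abscissa_center
        )
        y = np.array([r.period for r in sel])
        out[reg] = _make_curve(x, y, window, bins, f"period_response_{reg}")
    return out


def classify_direction(record: CouplingRecord, psi_early: float | None = None) -> str:
    """Classify a coupling response as 'negative', 'positive', or 'none'.

    'negative': the shell-core gap closes directly toward zero (the sign of
    delta-psi opposes the sign of the starting psi).  'positive': the
    network resynchronizes the long way round, through the half-period
    boundary (delta-psi carries the same sign as the starting psi).
    ``psi_early`` may override the stored value, e.g. with a re-centred
    representation when the starting polarity is known from the protocol.
    """
    dpsi = record.delta_psi
    if not np.isfinite(dpsi):
        raise ValueError("delta_psi is undefined for this record")
    pe = record.psi_early if psi_early is None else psi_early
    if dpsi == 0:
        return "none"
    if np.sign(dpsi) == -np.sign(pe):
        return "negative"
    return "positive"
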