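"""Ratiometric KCC2/NKCC1 quantification from ROI intensity tables.

The KCC2/NKCC1 ratio is computed per lobe and then averaged across the two
SCN lobes (ratio-then-average, not average-then-ratio); daily means
collapse the samples from all timepoints rather than averaging timepoint
means, which matters for unbalanced designs.  Rhythmicity of each
channel/region profile is assessed with the cosinor F-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clockmesh import rhythms

__all__ = [
    "RoiSample",
    "DailyProfile",
    "roi_mean",
    "sample_ratio",
    "average_then_ratio",
    "daily_mean_ratio",
    "profile_and_test",
]

REQUIRED_COLUMNS = ("animal", "zt", "region", "lobe", "channel", "mean_intensity")


@dataclass(frozen=True)
class RoiSample:
    """One ROI measurement: animal, timepoint, region, lobe, channel."""

    animal_id: str
    zt: float
    region: str
    lobe: str
    channel: str
    mean_intensity: float

    def __post_init__(self) -> None:
        if self.mean_intensity < 0:
            raise ValueError("intensity must be non-negative")
        if not (0.0 <= self.zt < 24.0):
            raise ValueError("zt must lie in [0, 24)")


@dataclass
class DailyProfile:
    """Timepoint means +/- SEM and the collapsed daily mean, per channel/region."""

    timepoints: pd.DataFrame  # columns: channel, region, zt, mean, sem, n
    daily_means: pd.DataFrame  # columns: channel, region, daily_mean, n
    cosinor: dict  # (channel, region) -> CosinorFit


def roi_mean(image: np.ndarray, roi: np.ndarray, background_threshold: float) -> float:
    """Mean ROI intensity after thresholded background subtraction.

    ``roi`` is a boolean mask or an (n, 2) pixel index array.  The
    threshold is subtracted from every pixel and negatives are clamped
    before averaging.
    """
    img = np.asarray(image, dtype=float)
    roi = np.asarray(roi)
    if roi.dtype == bool:
        vals = img[roi]
    else:
        roi = roi.reshape(-1, 2)
        vals = img[roi[:, 0], roi[:, 1]]
    if vals.size == 0:
        raise ValueError("empty ROI")
    return float(np.mean(np.clip(vals - background_threshold, 0.0, None)))


def sample_ratio(
    kcc2_left: float, nkcc1_left: float, kcc2_right: float, nkcc1_right: float
) -> float:
    """KCC2/NKCC1 ratio per lobe, averaged across the two lobes.

    Returns ``nan`` when either NKCC1 value is zero.
    """
    if nkcc1_left <= 0 or nkcc1_right <= 0:
        return float("nan")
    return 0.5 * (kcc2_left / nkcc1_left + kcc2_right / nkcc1_right)


def average_then_ratio(
    kcc2_left: float, nkcc1_left: float, kcc2_right: float, nkcc1_right: float
) -> float:
    """Comparison utility: lobe-averaged KCC2 over lobe-averaged NKCC1."""
    denom = 0.5 * (nkcc1_left + nkcc1_right)
    if denom <= 0:
        return float("nan")
    return 0.5 * (kcc2_left + kcc2_right) / denom


def daily_mean_ratio(kcc2_daily_mean: float, nkcc1_daily_mean: float) -> float:
    """Quotient of the two daily means (report at 2 decimals alongside)."""
    if nkcc1_daily_mean <= 0:
        return float("nan")
    return kcc2_daily_mean / nkcc1_daily_mean


def _as_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return df
    return pd.DataFrame(
        {
            "animal": [s.animal_id for s in samples],
            "zt": [s.zt for s in samples],
            "region": [s.region for s in samples],
            "lobe": [s.lobe for s in samples],
            "channel": [s.channel for s in samples],
            "mean_intensity": [s.mean_intensity for s in samples],
        }
    )


def profile_and_test(
    samples,
    base_period: float = 24.0,
    max_harmonics: int = 1,
) -> DailyProfile:
    """Daily expression profiles with rhythmicity tests.

    ``samples`` is a tidy table (or list of :class:`RoiSample`).  Lobes
    are first averaged within animal/channel/region, then timepoint means
    +/- SEM, the collapsed daily mean, and a cosinor fit are computed per
    channel/region.  Needs samples at >= 3 distinct timepoints.
    """
    df = _as_frame(samples)
    if df["zt"].nunique() < 3:
        raise ValueError("need samples at >= 3 distinct timepoints")
    per_animal = (
        df.groupby(["channel", "region", "zt", "animal"], as_index=False)[
            "mean_intensity"
        ]
        .mean()
    )
    tp = (
        per_animal.groupby(["channel", "region", "zt"])["mean_intensity"]
        .agg(
            mean="mean",
            sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
            n="count",
        )
        .reset_index()
    )
    daily = (
        per_animal.groupby(["channel", "region"])["mean_intensity"]
        .agg(daily_mean="mean", n="count")
        .reset_index()
    )
    fits = {}
    for (channel, region), grp in per_animal.groupby(["channel", "region"]):
        try:
            fits[(channel, region)] = rhythms.cosinor_test(
                np.column_stack(
                    [grp["zt"].to_numpy(float) % base_period,
                     grp["mean_intensity"].to_numpy(float)]
                ),
                base_period=base_period,
                max_harmonics=max_harmonics,
            )
        except ValueError:
            fits[(channel, region)] = None
    return DailyProfile(timepoints=tp, daily_means=daily, cosinor=fits)
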