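"""Bioluminescence movie analysis.

Grid-ROI trace extraction (12-pixel-diameter disks on a 2-pixel lattice),
background and local-noise subtraction, iterative brightest-first detection
of cell-like ROIs gated by a cosinor rhythmicity test, per-ROI phase and
period maps, and alignment of slices by minimizing the sum of squared
differences of their 24-h-summed bioluminescence images so that maps from
many slices can be composited on shared coordinates.

Pixel coordinates are 0-based ``(row, col)``; an ROI disk is the set of
pixels whose center distance from the ROI center is at most the radius
(radius 6 px for the standard 12-pixel diameter).  ``Shift2D.dx`` is the
translation along rows and ``dy`` along columns that the target has
undergone relative to the reference; subtracting it aligns the target back
onto the reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as _ndimage

from clockmesh import rhythms
from clockmesh.rhythms import TimeSeries

__all__ = [
    "Movie",
    "ROISet",
    "PhaseMap",
    "Shift2D",
    "extract_grid_traces",
    "subtract_background",
    "detect_cells",
    "build_phase_map",
    "build_period_map",
    "align_by_summed_ssd",
    "composite_map",
    "rle_encode",
    "rle_decode",
]

GRID_SPACING = 2  # px between grid-ROI centers
ROI_RADIUS = 6  # px; 12-pixel diameter


@dataclass
class Movie:
    """A T x H x W non-negative intensity stack with its time geometry."""

    frames: np.ndarray
    frame_interval: float  # hours
    origin: float = 0.0  # hours since culture start

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[0] < 2:
            raise ValueError("frames must be a T x H x W stack with T >= 2")
        if np.any(f < 0):
            raise ValueError("intensities must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.frames = f

    @property
    def times(self) -> np.ndarray:
        return self.origin + np.arange(self.frames.shape[0]) * self.frame_interval

    @property
    def duration(self) -> float:
        return float((self.frames.shape[0] - 1) * self.frame_interval)

    def to_tiff(self, path, sidecar_path=None, region_masks=None) -> None:
        """Write a 16-bit multi-page TIFF plus a JSON sidecar."""
        import tifffile

        data = np.clip(np.round(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack")
        if sidecar_path is not None:
            sidecar = {
                "frame_interval_h": self.frame_interval,
                "origin_h": self.origin,
            }
            if region_masks is not None:
                sidecar["region_masks"] = {
                    name: {
                        "shape": list(np.asarray(m).shape),
                        "rle": rle_encode(np.asarray(m, dtype=bool)),
                    }
                    for name, m in region_masks.items()
                }
            with open(sidecar_path, "w") as fh:
                json.dump(sidecar, fh)

    @classmethod
    def from_tiff(cls, path, sidecar_path) -> tuple["Movie", dict | None]:
        import tifffile

        frames = tifffile.imread(path).astype(float)
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        movie = cls(
            frames=frames,
            frame_interval=float(sidecar["frame_interval_h"]),
            origin=float(sidecar.get("origin_h", 0.0)),
        )
        masks = None
        if "region_masks" in sidecar:
            masks = {
                name: rle_decode(entry["rle"], tuple(entry["shape"]))
                for name, entry in sidecar["region_masks"].items()
            }
        return movie, masks


def rle_encode(mask: np.ndarray) -> list:
    """Run-length encode a boolean mask (row-major [start, length] runs)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], flat.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        runs.append([int(start), int(stop - start)])
    return runs


def rle_decode(runs: list, shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in runs:
        flat[start : start + length] = True
    return flat.reshape(shape)


@dataclass
class ROISet:
    """A set of disk ROIs with one trace per ROI.

    ``kind`` is 'grid' (lattice ROIs) or 'cell' (detected cell-like ROIs,
    pairwise center distance >= 2 * radius).  ``regions`` optionally labels
    each ROI 'shell' or 'core'.
    """

    centers: np.ndarray  # (n, 2) row, col
    radius: float
    traces: list  # list[TimeSeries]
    kind: str = "grid"
    regions: list | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if len(self.traces) != c.shape[0]:
            raise ValueError("one trace per ROI required")
        if self.kind == "cell" and c.shape[0] > 1:
            d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if np.min(d2) < (2 * self.radius) ** 2 - 1e-9:
                raise ValueError("cell ROIs must be at least 2*radius apart")
        if self.regions is not None and len(self.regions) != c.shape[0]:
            raise ValueError("one region label per ROI required")
        self.centers = c

    def __len__(self) -> int:
        return int(self.centers.shape[0])


@dataclass(frozen=True)
class Shift2D:
    """Integer-pixel translation (rows, cols) with its alignment SSD."""

    dx: int
    dy: int
    ssd: float


@dataclass
class PhaseMap:
    """Per-ROI peak time (or period) with a validity mask."""

    centers: np.ndarray  # (n, 2)
    values: np.ndarray  # hours
    valid: np.ndarray  # bool per ROI
    cycle: int | tuple
    kind: str = "phase"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": self.centers[:, 0],
                "col": self.centers[:, 1],
                "value_h": self.values,
                "masked": ~self.valid,
            }
        )


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    sel = yy**2 + xx**2 <= radius**2
    return np.column_stack([yy[sel], xx[sel]])


def extract_grid_traces(
    movie: Movie, radius: float = ROI_RADIUS, spacing: int = GRID_SPACING
) -> ROISet:
    """Mean-intensity traces of 12-px-diameter disks on a uniform lattice.

    Lattice points are every ``spacing`` pixels, keeping only centers whose
    disk fits inside the frame.
    """
    t, h, w = movie.frames.shape
    r = int(np.ceil(radius))
    if h < 2 * r + 1 or w < 2 * r + 1:
        raise ValueError("frame too small for the ROI diameter")
    rows = np.arange(r, h - r, spacing)
    cols = np.arange(r, w - r, spacing)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    centers = np.column_stack([rr.ravel(), cc.ravel()])
    offsets = _disk_offsets(radius)
    acc = np.zeros((t, centers.shape[0]))
    for dy, dx in offsets:
        acc += movie.frames[:, centers[:, 0] + dy, centers[:, 1] + dx]
    acc /= offsets.shape[0]
    times = movie.times
    traces = [TimeSeries(times, acc[:, i]) for i in range(centers.shape[0])]
    return ROISet(centers=centers.astype(float), radius=radius, traces=traces,
                  kind="grid")


def subtract_background(
    movie: Movie, percentile: float = 0.10, noise_window: int = 5
) -> Movie:
    """Remove per-frame background and local noise.

    Per frame, the given low percentile of the frame's intensities is
    subtracted (background), the result is median filtered within
    ``noise_window`` pixels (local noise), and negative values are clamped
    to zero.
    """
    if not (0.0 < percentile <= 0.5):
        raise ValueError("percentile must lie in (0, 0.5]")
    frames = movie.frames
    bg = np.quantile(frames.reshape(frames.shape[0], -1), percentile, axis=1)
    out = frames - bg[:, None, None]
    out = _ndimage.median_filter(out, size=(1, noise_window, noise_window))
    np.clip(out, 0.0, None, out=out)
    return Movie(frames=out, frame_interval=movie.frame_interval, origin=movie.origin)


def _roi_trace(movie: Movie, center, offsets) -> TimeSeries:
    vals = movie.frames[:, center[0] + offsets[:, 0], center[1] + offsets[:, 1]]
    return TimeSeries(movie.times, vals.mean(axis=1))


def detect_cells(
    movie: Movie,
    min_amplitude: float = 5.0,
    p_threshold: float = 0.05,
    radius: float = ROI_RADIUS,
    base_period: float = 24.0,
    region_masks: dict | None = None,
) -> ROISet:
    """Iterative brightest-first detection of cell-like ROIs.

    Repeatedly takes the brightest remaining pixel of the time-averaged
    (background-subtracted) image, centers an ROI disk there, and accepts
    it when its trace is rhythmic (cosinor p < ``p_threshold``) with
    detrended amplitude >= ``min_amplitude``.  Accepted disks mask a
    2-radius neighbourhood (so cell ROIs never overlap), rejected
    candidates mask their own disk, and the scan stops when the brightest
    remaining pixel falls below ``min_amplitude``.
    """
    t, h, w = movie.frames.shape
    mean_img = movie.frames.mean(axis=0)
    r = int(np.ceil(radius))
    available = np.zeros((h, w), dtype=bool)
    available[r : h - r, r : w - r] = True
    offsets = _disk_offsets(radius)
    yy, xx = np.mgrid[0:h, 0:w]

    centers, traces, regions = [], [], []
    while True:
        masked_img = np.where(available, mean_img, -np.inf)
        flat_idx = int(np.argmax(masked_img))
        cy, cx = np.unravel_index(flat_idx, (h, w))
        if not np.isfinite(masked_img[cy, cx]) or masked_img[cy, cx] < min_amplitude:
            break
        trace = _roi_trace(movie, (cy, cx), offsets)
        det = rhythms.detrend(trace)
        amplitude = 0.5 * (np.max(det.values) - np.min(det.values))
        accept = False
        if amplitude >= min_amplitude:
            try:
                fit = rhythms.cosinor_test(
                    np.column_stack([trace.times % base_period, det.values]),
                    base_period=base_period,
                )
                accept = fit.p_value < p_threshold
            except ValueError:
                accept = False
        if accept:
            centers.append((cy, cx))
            traces.append(trace)
            if region_masks is not None:
                label = None
                for name, mask in region_masks.items():
                    if np.asarray(mask, dtype=bool)[cy, cx]:
                        label = name
                        break
                regions.append(label)
            mask_r = 2 * radius
        else:
            mask_r = radius
        available &= (yy - cy) ** 2 + (xx - cx) ** 2 > mask_r**2
    return ROISet(
        centers=np.array(centers, dtype=float).reshape(-1, 2),
        radius=radius,
        traces=traces,
        kind="cell",
        regions=regions if region_masks is not None else None,
    )


def _peaks_for_rois(rois: ROISet, preprocess, min_separation, preprocessed):
    if preprocess is None:
        preprocess = rhythms.preprocess_trace
    out = []
    for ts in rois.traces:
        if not preprocessed:
            ts = preprocess(ts)
        out.append(rhythms.find_peaks(ts, min_separation))
    return out


def build_phase_map(
    rois: ROISet,
    cycle: int = 2,
    preprocess=None,
    min_separation: float = 16.0,
    preprocessed: bool = False,
) -> PhaseMap:
    """Peak time of each ROI on a stated (1-based) cycle; missing peaks masked."""
    peaks = _peaks_for_rois(rois, preprocess, min_separation, preprocessed)
    n = len(rois)
    values = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, pk in enumerate(peaks):
        if len(pk) >= cycle:
            values[i] = pk.peak_times[cycle - 1]
            valid[i] = True
    return PhaseMap(rois.centers, values, valid, cycle, kind="phase")


def build_period_map(
    rois: ROISet,
    cycles: tuple[int, int] = (2, 4),
    preprocess=None,
    min_separation: float = 16.0,
    preprocessed: bool = False,
) -> PhaseMap:
    """Mean peak-to-peak period of each ROI over a cycle range."""
    peaks = _peaks_for_rois(rois, preprocess, min_separation, preprocessed)
    n = len(rois)
    values = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, pk in enumerate(peaks):
        per = rhythms.mean_period(pk, cycles)
        if np.isfinite(per):
            values[i] = per
            valid[i] = True
    return PhaseMap(rois.centers, values, valid, cycles, kind="period")


def _summed_image(movie: Movie, hours: float = 24.0) -> np.ndarray:
    n = max(2, int(round(hours / movie.frame_interval)))
    if movie.duration + movie.frame_interval < hours:
        raise ValueError("movie must cover at least 24 h for alignment")
    return movie.frames[:n].sum(axis=0)


def align_by_summed_ssd(
    reference: Movie, target: Movie, max_shift: int = 10
) -> Shift2D:
    """Best integer translation of ``target`` relative to ``reference``.

    Both movies' first 24 h are summed into single images; an exhaustive
    search over shifts within ``+/- max_shift`` minimizes the sum of
    squared differences over the overlapping region.  Ties go to the
    smaller ``|dx| + |dy|``, then lexicographically.
    """
    if reference.frames.shape[1:] != target.frames.shape[1:]:
        raise ValueError("frame shapes must match")
    h, w = reference.frames.shape[1:]
    if max_shift >= min(h, w):
        raise ValueError("max_shift must be smaller than the frame")
    ref = _summed_image(reference)
    tgt = _summed_image(target)
    best = None
    for dx in range(-max_shift, max_shift + 1):
        for dy in range(-max_shift, max_shift + 1):
            # target has been translated by (dx, dy): tgt[r, c] = ref[r-dx, c-dy]
            r0, r1 = max(0, dx), h + min(0, dx)
            c0, c1 = max(0, dy), w + min(0, dy)
            if r1 <= r0 or c1 <= c0:
                continue
            diff = tgt[r0:r1, c0:c1] - ref[r0 - dx : r1 - dx, c0 - dy : c1 - dy]
            ssd = float(np.sum(diff * diff))
            key = (ssd, abs(dx) + abs(dy), dx, dy)
            if best is None or key < best[0]:
                best = (key, Shift2D(dx, dy, ssd))
    return best[1]


def composite_map(
    maps: list[PhaseMap], shifts: list[Shift2D], period: float = 24.0
) -> PhaseMap:
    """Circular-mean composite of aligned per-slice maps.

    Each map's ROI centers are translated back by its recorded shift, and
    the peak times contributed to each aligned lattice point are averaged
    on the ``period``-hour circle.  Points with no contributor are absent.
    """
    if not maps:
        raise ValueError("need at least one map")
    if len(shifts) != len(maps):
        raise ValueError("one shift per map required")
    acc: dict[tuple[int, int], list[float]] = {}
    for pm, sh in zip(maps, shifts):
        aligned = pm.centers - np.array([sh.dx, sh.dy], dtype=float)
        for (ry, cx), val, ok in zip(aligned, pm.values, pm.valid):
            if not ok:
                continue
            acc.setdefault((int(round(ry)), int(round(cx))), []).append(float(val))
    if not acc:
        raise ValueError("no valid contributions to composite")
    keys = sorted(acc)
    centers = np.array(keys, dtype=float)
    values = np.empty(len(keys))
    for i, k in enumerate(keys):
        ang = 2.0 * np.pi * np.asarray(acc[k]) / period
        mean_ang = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
        v = (mean_ang * period / (2.0 * np.pi)) % period
        values[i] = 0.0 if period - v < 1e-9 else v
    valid = np.ones(len(keys), dtype=bool)
    cycle = maps[0].cycle
    return PhaseMap(centers, values, valid, cycle, kind=maps[0].kind)
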