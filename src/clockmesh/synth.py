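"""Seeded generators for every input the pipeline consumes.

The slice simulator emulates PER2::LUC bioluminescence from an SCN slice
polarized by a long photoperiod: two populations of damped single-cell
oscillators (dorsomedial shell, ventral core) whose phases obey a
mean-field Kuramoto model,

    dphi_i/dt = 2 pi / tau_i + K_region(i) * sin(Phi_opp - phi_i - beta_region(i)),

where ``Phi_opp`` is the circular-mean phase of the complementary region.
The phase lag ``beta`` (parametrised in hours by ``psi_lock_h``, the
core-minus-shell peak-time gap the coupling pulls toward) makes the
watershed between the two resynchronization directions sit at a core lead
of roughly ``psi_lock_h - tau/2`` hours rather than exactly at anti-phase,
which is where long-photoperiod SCN slices empirically reverse direction.
With ``psi_lock_h = 0`` the model reduces to the plain symmetric sine
coupling and the shell-core gap relaxes to zero along the shortest arc.

Drug scenarios act as pure multipliers on the coupling constants plus an
optional uniform period offset.  The actogram simulator produces nocturnal
wheel-running counts with photoperiod-compressed alpha and exponential
decompression in constant darkness; the luminometry simulator produces a
damped cosine with an imposed phase step; the IHC simulator draws
two-channel intensities with cosinor structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clockmesh.behavior import Actogram
from clockmesh.imaging import Movie
from clockmesh.rhythms import TimeSeries

__all__ = [
    "SliceSimConfig",
    "SliceGroundTruth",
    "PulseSimConfig",
    "ActogramSimConfig",
    "IhcSimConfig",
    "ChannelParams",
    "Scenario",
    "SCENARIOS",
    "apply_scenario",
    "default_region_masks",
    "simulate_cell_traces",
    "simulate_slice_movie",
    "simulate_luminometry",
    "simulate_actogram",
    "simulate_ihc",
]

_MAX_STEP_H = 0.05  # phase ODE integration step ceiling


# ---------------------------------------------------------------------------
# Slice simulator
# ---------------------------------------------------------------------------


def default_region_masks(grid_shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Disjoint shell (dorsal, top rows) and core (ventral, bottom rows) masks."""
    h, w = grid_shape
    shell = np.zeros(grid_shape, dtype=bool)
    core = np.zeros(grid_shape, dtype=bool)
    mid = h // 2
    shell[: mid - 1, :] = True
    core[mid + 1 :, :] = True
    return {"shell": shell, "core": core}


@dataclass
class SliceSimConfig:
    """Configuration of a simulated two-population SCN slice recording."""

    grid_shape: tuple[int, int] = (140, 140)
    n_shell: int = 30
    n_core: int = 30
    region_masks: dict | None = None  # {'shell': bool HxW, 'core': bool HxW}
    tau_shell: float = 24.5  # h, mean intrinsic period
    tau_core: float = 24.5
    tau_sd: float = 0.2  # h, between-cell spread
    psi0: float = -11.0  # h, initial core-minus-shell peak-time gap
    K_shell: float = 0.0  # rad/h, shell pulled toward core mean field
    K_core: float = 0.008  # rad/h, core pulled toward shell mean field
    psi_lock_h: float = 4.75  # h, preferred core-minus-shell gap of the coupling
    damping: float = 0.01  # 1/h amplitude decay
    noise_sd: float = 0.05  # frame noise, fraction of cell amplitude
    cell_sigma: float = 2.0  # px, rendered blob width
    frame_interval: float = 0.5  # h
    duration: float = 144.0  # h
    amplitude: float = 100.0  # intensity units per cell
    baseline: float = 10.0  # camera offset
    first_peak_h: float = 20.0  # shell population peak time on cycle 1
    min_cell_distance: float = 14.0  # px between rendered cell centers
    trace_noise_sd: float = 0.0  # per-cell trace noise (trace-level simulation)
    seed: int = 0

    def validate(self) -> None:
        if self.n_shell < 1 or self.n_core < 1:
            raise ValueError("need at least one cell per region")
        if not (-12.0 < self.psi0 <= 12.0):
            raise ValueError("psi0 must lie in (-12, 12]")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        tau_max = max(self.tau_shell, self.tau_core)
        if self.duration < 3.0 * tau_max:
            raise ValueError("duration too short for three cycles")
        if self.tau_sd < 0 or self.damping < 0 or self.noise_sd < 0:
            raise ValueError("spreads, damping, and noise must be non-negative")
        masks = self.masks()
        if np.any(masks["shell"] & masks["core"]):
            raise ValueError("region masks must be disjoint")

    def masks(self) -> dict[str, np.ndarray]:
        if self.region_masks is not None:
            return {k: np.asarray(v, dtype=bool) for k, v in self.region_masks.items()}
        return default_region_masks(self.grid_shape)

    @property
    def n_cells(self) -> int:
        return self.n_shell + self.n_core

    @property
    def frame_times(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.frame_interval)) + 1
        return np.arange(n) * self.frame_interval


@dataclass
class SliceGroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    cell_centers: np.ndarray  # (n, 2) row, col
    cell_regions: list  # 'shell' | 'core' per cell
    cell_periods: np.ndarray  # intrinsic tau_i, h
    phase_trajectories: np.ndarray  # (n, T) radians, unwrapped
    true_peak_times: list  # per cell, strictly increasing hours
    frame_times: np.ndarray

    def region_mean_peak(self, region: str, cycle: int) -> float:
        """Circular-mean true peak time of one region on a 1-based cycle."""
        from clockmesh.network import circular_mean_time

        times = [
            pk[cycle - 1]
            for pk, reg in zip(self.true_peak_times, self.cell_regions)
            if reg == region and len(pk) >= cycle
        ]
        return circular_mean_time(times) if times else float("nan")

    def true_psi(self, cycle: int) -> float:
        """Ground-truth shell-core gap on a cycle, wrapped to (-12, 12]."""
        from clockmesh.network import wrap_phase

        return wrap_phase(
            self.region_mean_peak("core", cycle) - self.region_mean_peak("shell", cycle)
        )

    def observed_period(self, cell: int, cycle_range=(2, 4)) -> float:
        """Mean true peak-to-peak interval of one cell over a cycle range."""
        pk = self.true_peak_times[cell]
        first, last = cycle_range
        if len(pk) < last:
            return float("nan")
        return float(np.mean(np.diff(pk[first - 1 : last])))


@dataclass(frozen=True)
class Scenario:
    """Drug scenario: multipliers on coupling plus a uniform period offset."""

    k_core_mult: float = 1.0
    k_shell_mult: float = 1.0
    period_offset_h: float = 0.0


SCENARIOS: dict[str, Scenario] = {
    "vehicle": Scenario(1.0, 1.0, 0.0),
    "ace": Scenario(0.0, 1.0, 0.0),  # blocks core coupling responses
    "bu": Scenario(0.25, 1.0, 0.35),  # NKCC1 block: slows recovery, lengthens period
    "vu": Scenario(2.0, 1.0, 0.35),  # KCC2 block: accelerates core responses
    "clp290": Scenario(0.25, 0.25, 0.35),  # KCC2 activator: attenuates both
}


def apply_scenario(config: SliceSimConfig, scenario: str | Scenario) -> SliceSimConfig:
    """Return a copy of ``config`` with a drug scenario applied."""
    sc = SCENARIOS[scenario] if isinstance(scenario, str) else scenario
    return dataclasses.replace(
        config,
        K_core=config.K_core * sc.k_core_mult,
        K_shell=config.K_shell * sc.k_shell_mult,
        tau_shell=config.tau_shell + sc.period_offset_h,
        tau_core=config.tau_core + sc.period_offset_h,
    )


def _circ_mean_angle(phases: np.ndarray) -> float:
    return float(np.arctan2(np.mean(np.sin(phases)), np.mean(np.cos(phases))))


def _integrate_phases(config: SliceSimConfig, omegas: np.ndarray, is_core: np.ndarray):
    """Euler integration of the mean-field phase ODE at <= 0.05-h steps.

    Returns unwrapped phases at frame times, (n_cells, T).
    """
    frame_times = config.frame_times
    n_sub = max(1, int(np.ceil(config.frame_interval / _MAX_STEP_H)))
    dt = config.frame_interval / n_sub
    tau_ref = 0.5 * (config.tau_shell + config.tau_core)
    beta = 2.0 * np.pi * config.psi_lock_h / tau_ref

    n = omegas.size
    phases = np.empty((n, frame_times.size))
    # shell population peaks at first_peak_h; core offset by psi0
    phi = np.where(
        is_core,
        -2.0 * np.pi * (config.first_peak_h + config.psi0) / tau_ref,
        -2.0 * np.pi * config.first_peak_h / tau_ref,
    ).astype(float)
    phases[:, 0] = phi
    shell_idx = ~is_core
    for f in range(1, frame_times.size):
        for _ in range(n_sub):
            mean_shell = _circ_mean_angle(phi[shell_idx])
            mean_core = _circ_mean_angle(phi[is_core])
            pull = np.where(
                is_core,
                config.K_core * np.sin(mean_shell - phi - beta),
                config.K_shell * np.sin(mean_core - phi + beta),
            )
            phi = phi + dt * (omegas + pull)
        phases[:, f] = phi
    return phases


def _peaks_from_phases(frame_times: np.ndarray, phases: np.ndarray) -> list:
    """Times where each cell's unwrapped phase crosses multiples of 2 pi."""
    out = []
    for row in phases:
        k_first = int(np.ceil(row[0] / (2.0 * np.pi) + 1e-12))
        k_last = int(np.floor(row[-1] / (2.0 * np.pi)))
        targets = 2.0 * np.pi * np.arange(k_first, k_last + 1)
        # phase is monotone increasing (coupling << intrinsic rate)
        out.append(np.interp(targets, row, frame_times))
    return out


def _place_cells(config: SliceSimConfig, rng: np.random.Generator):
    """Jittered-lattice cell placement: guaranteed min spacing and capacity.

    Lattice pitch is ``min_cell_distance + 2`` with +/-1 px jitter, so the
    pairwise distance floor holds by construction.
    """
    masks = config.masks()
    h, w = config.grid_shape
    margin = int(np.ceil(6 + 3 * config.cell_sigma))
    pitch = config.min_cell_distance + 2.0
    rows = np.arange(margin, h - margin, pitch)
    cols = np.arange(margin, w - margin, pitch)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    lattice = np.column_stack([rr.ravel(), cc.ravel()])
    centers = []
    regions = []
    for region, count in (("shell", config.n_shell), ("core", config.n_core)):
        mask = masks[region]
        in_region = np.array(
            [mask[int(round(y)), int(round(x))] for y, x in lattice]
        )
        candidates = lattice[in_region]
        if candidates.shape[0] < count:
            raise ValueError(
                f"cannot place {count} cells {config.min_cell_distance} px apart "
                f"in region '{region}' (capacity {candidates.shape[0]})"
            )
        chosen = candidates[
            rng.choice(candidates.shape[0], size=count, replace=False)
        ]
        jitter = rng.uniform(-1.0, 1.0, size=chosen.shape)
        for c in chosen + jitter:
            centers.append(c)
            regions.append(region)
    return np.array(centers), regions


def _simulate_truth(config: SliceSimConfig, rng: np.random.Generator):
    centers, regions = _place_cells(config, rng)
    is_core = np.array([r == "core" for r in regions])
    taus = np.where(is_core, config.tau_core, config.tau_shell) + (
        rng.normal(0.0, config.tau_sd, size=is_core.size) if config.tau_sd > 0 else 0.0
    )
    omegas = 2.0 * np.pi / taus
    phases = _integrate_phases(config, omegas, is_core)
    peaks = _peaks_from_phases(config.frame_times, phases)
    truth = SliceGroundTruth(
        cell_centers=centers,
        cell_regions=regions,
        cell_periods=taus,
        phase_trajectories=phases,
        true_peak_times=peaks,
        frame_times=config.frame_times,
    )
    return truth


def _cell_intensities(config: SliceSimConfig, truth: SliceGroundTruth) -> np.ndarray:
    t = truth.frame_times
    decay = np.exp(-config.damping * t)
    return config.amplitude * decay * (1.0 + np.cos(truth.phase_trajectories))


def simulate_cell_traces(
    config: SliceSimConfig,
) -> tuple[list[TimeSeries], SliceGroundTruth]:
    """Per-cell intensity traces (no rendering) with ground truth.

    The trace-level route feeds the network statistics directly; use
    :func:`simulate_slice_movie` when the imaging stage itself is under
    test.  ``config.trace_noise_sd`` (fraction of cell amplitude) adds
    Gaussian noise per sample.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _simulate_truth(config, rng)
    intensities = _cell_intensities(config, truth)
    if config.trace_noise_sd > 0:
        intensities = intensities + rng.normal(
            0.0, config.trace_noise_sd * config.amplitude, size=intensities.shape
        )
    traces = [TimeSeries(truth.frame_times, row) for row in intensities]
    return traces, truth


def simulate_slice_movie(config: SliceSimConfig) -> tuple[Movie, SliceGroundTruth]:
    """Render a bioluminescence movie of the simulated slice.

    Frames are Gaussian blobs at the cell centers on a constant baseline
    plus Gaussian frame noise (photon-counting regime), clamped
    non-negative.  Identical seeds give bit-identical movies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _simulate_truth(config, rng)
    intensities = _cell_intensities(config, truth)  # (n, T)

    h, w = config.grid_shape
    t_frames = truth.frame_times.size
    frames = np.full((t_frames, h, w), float(config.baseline))
    half = int(np.ceil(3 * config.cell_sigma))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    kernel = np.exp(-(yy**2 + xx**2) / (2.0 * config.cell_sigma**2))
    for i, (cy, cx) in enumerate(truth.cell_centers):
        cy, cx = int(round(cy)), int(round(cx))
        frames[:, cy - half : cy + half + 1, cx - half : cx + half + 1] += (
            intensities[i][:, None, None] * kernel[None, :, :]
        )
    if config.noise_sd > 0:
        frames += rng.normal(
            0.0, config.noise_sd * config.amplitude, size=frames.shape
        )
    np.clip(frames, 0.0, None, out=frames)
    movie = Movie(frames=frames, frame_interval=config.frame_interval, origin=0.0)
    return movie, truth


# ---------------------------------------------------------------------------
# Luminometry (resetting assay)
# ---------------------------------------------------------------------------


@dataclass
class PulseSimConfig:
    """Whole-dish luminometry trace with an imposed phase step at a pulse."""

    baseline_period: float = 24.5  # h
    pulse_time: float = 78.0  # h; after three pre-treatment cycles
    true_shift: float = 0.0  # h, advance positive
    damping: float = 0.01  # 1/h
    noise_sd: float = 0.05  # fraction of amplitude
    frame_interval: float = 0.5  # h
    duration: float = 168.0  # h
    first_peak_h: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_period <= 0 or self.frame_interval <= 0:
            raise ValueError("period and frame_interval must be positive")
        if self.pulse_time <= 3.0 * self.baseline_period:
            raise ValueError("pulse must follow three pre-treatment cycles")
        if self.pulse_time >= self.duration - self.baseline_period:
            raise ValueError("need at least one full post-pulse cycle")


def simulate_luminometry(config: PulseSimConfig) -> tuple[TimeSeries, float]:
    """Damped cosine with a phase step of ``2 pi shift / period`` at the pulse.

    A positive ``true_shift`` advances all post-pulse peaks by that many
    hours relative to the unperturbed lattice.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(np.floor(config.duration / config.frame_interval)) + 1
    t = np.arange(n) * config.frame_interval
    omega = 2.0 * np.pi / config.baseline_period
    theta = -omega * config.first_peak_h + np.where(
        t >= config.pulse_time, omega * config.true_shift, 0.0
    )
    values = np.exp(-config.damping * t) * (1.0 + np.cos(omega * t + theta))
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    return TimeSeries(t, values), float(config.true_shift)


# ---------------------------------------------------------------------------
# Actograms
# ---------------------------------------------------------------------------


@dataclass
class ActogramSimConfig:
    """Nocturnal wheel-running records under LD then constant darkness.

    Alpha (active-phase duration) is compressed to ``alpha_start`` by the
    photoperiod and decompresses exponentially toward ``alpha_end`` with
    time constant ``alpha_tau`` days after release into DD.
    """

    photoperiod: float = 20.0  # h of light per day
    weeks_entrained: int = 1
    weeks_dd: int = 4
    free_period: float = 23.6  # h
    alpha_start: float = 4.0  # h
    alpha_end: float = 10.0  # h
    alpha_tau: float = 10.0  # days
    bin_minutes: int = 6
    active_rate: float = 60.0  # mean counts per bin while active
    inactive_rate: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.alpha_start <= self.alpha_end <= 24.0):
            raise ValueError("need 0 < alpha_start <= alpha_end <= 24")
        if 1440 % self.bin_minutes != 0:
            raise ValueError("bin_minutes must divide 1440")
        if not (0.0 <= self.photoperiod <= 24.0):
            raise ValueError("photoperiod must lie in [0, 24]")
        if self.alpha_tau <= 0:
            raise ValueError("alpha_tau must be positive")


def simulate_actogram(
    config: ActogramSimConfig,
) -> tuple[Actogram, pd.DataFrame]:
    """Simulate binned wheel counts; returns the actogram and daily truth.

    The truth table has one row per day: ``onset_h``/``offset_h`` (clock
    hours of the active window, offset may exceed 24 when activity spills
    past midnight) and ``alpha_h``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_ld = 7 * config.weeks_entrained
    n_dd = 7 * config.weeks_dd
    n_days = n_ld + n_dd
    bins_per_day = 1440 // config.bin_minutes
    bin_h = config.bin_minutes / 60.0

    onsets = np.empty(n_days)
    alphas = np.empty(n_days)
    for d in range(n_days):
        if d < n_ld:
            onsets[d] = config.photoperiod  # activity starts at lights-off
            alphas[d] = config.alpha_start
        else:
            dd = d - n_ld
            onsets[d] = config.photoperiod + (config.free_period - 24.0) * (dd + 1)
            alphas[d] = config.alpha_end - (
                config.alpha_end - config.alpha_start
            ) * np.exp(-dd / config.alpha_tau)

    # mark active bins on the absolute time axis
    active = np.zeros(n_days * bins_per_day, dtype=bool)
    bin_mids = (np.arange(active.size) + 0.5) * bin_h
    for d in range(n_days):
        start = d * 24.0 + onsets[d]
        active |= (bin_mids >= start) & (bin_mids < start + alphas[d])
    counts = np.where(
        active,
        rng.poisson(config.active_rate, size=active.size),
        rng.poisson(config.inactive_rate, size=active.size),
    ).astype(int)

    lights = [
        (0.0, config.photoperiod) if d < n_ld else None for d in range(n_days)
    ]
    actogram = Actogram(counts=counts, bin_minutes=config.bin_minutes, lights=lights)
    truth = pd.DataFrame(
        {
            "day": np.arange(n_days),
            "in_dd": np.arange(n_days) >= n_ld,
            "onset_h": onsets % 24.0,
            "offset_h": (onsets + alphas) % 24.0,
            "alpha_h": alphas,
        }
    )
    return actogram, truth


# ---------------------------------------------------------------------------
# IHC intensities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelParams:
    """Cosinor structure of one channel in one region."""

    mesor: float
    amplitude: float
    acrophase: float  # h

    def validate(self) -> None:
        if self.mesor - self.amplitude < 0:
            raise ValueError(
                "mesor - amplitude < 0 would force negative mean intensity"
            )

    def value(self, zt) -> np.ndarray:
        return self.mesor + self.amplitude * np.cos(
            2.0 * np.pi * (np.asarray(zt, dtype=float) - self.acrophase) / 24.0
        )


def _default_ihc_params() -> dict:
    # long-photoperiod-like scenario: KCC2 low and arrhythmic in the shell,
    # NKCC1 high and rhythmic; scales follow the daily means reported for
    # whole-SCN chloride co-transporter staining
    return {
        ("KCC2", "shell"): ChannelParams(5.0, 1.5, 8.0),
        ("KCC2", "core"): ChannelParams(25.0, 5.0, 8.0),
        ("NKCC1", "shell"): ChannelParams(125.0, 25.0, 16.0),
        ("NKCC1", "core"): ChannelParams(95.0, 15.0, 16.0),
    }


@dataclass
class IhcSimConfig:
    """Per-animal ROI intensities with cosinor structure, two lobes each."""

    params: dict = field(default_factory=_default_ihc_params)
    zt_grid: tuple = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0)
    n_per_timepoint: int = 4
    noise_sd: float = 3.0  # intensity units
    lobe_sd: float = 0.0  # extra left/right lobe scatter
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_timepoint < 1:
            raise ValueError("need at least one animal per timepoint")
        if self.noise_sd < 0 or self.lobe_sd < 0:
            raise ValueError("noise levels must be non-negative")
        for p in self.params.values():
            p.validate()


def simulate_ihc(config: IhcSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate an ROI intensity table plus the generating cosinor truth.

    Returns a tidy frame (animal, zt, region, lobe, channel,
    mean_intensity; intensities clamped non-negative) and the parameter
    dictionary keyed by (channel, region).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    animal = 0
    for zt in config.zt_grid:
        for _ in range(config.n_per_timepoint):
            animal += 1
            for (channel, region), p in config.params.items():
                for lobe in ("left", "right"):
                    val = p.value(zt) + rng.normal(0.0, config.noise_sd)
                    if config.lobe_sd > 0:
                        val += rng.normal(0.0, config.lobe_sd)
                    rows.append(
                        {
                            "animal": f"a{animal:03d}",
                            "zt": float(zt),
                            "region": region,
                            "lobe": lobe,
                            "channel": channel,
                            "mean_intensity": max(0.0, float(val)),
                        }
                    )
    return pd.DataFrame(rows), dict(config.params)
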