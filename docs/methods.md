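# Methods

`clockmesh` quantifies the state of the suprachiasmatic nucleus (SCN)
clock network at four levels of observation — single-cell bioluminescence
movies, whole-dish luminometry, wheel-running behavior, and ratiometric
immunostaining — and ships a seeded generator for each input so that every
estimator can be validated against known ground truth.

## The shell–core phase relationship ψ

The central statistic is ψ, the phase relationship between the two major
SCN subdivisions: the circular-mean PER2::LUC peak time of core (ventral)
ROIs minus that of shell (dorsomedial) ROIs on a stated cycle in vitro,
wrapped to a half-period interval. Negative ψ means the core phase-leads.
All phase aggregation uses vector averaging on the 24-h circle; arithmetic
averaging is exposed as an option but is wrong whenever peaks straddle the
wrap boundary (a test pins the difference).

The coupling response Δψ = wrap(ψ_late − ψ_early) between cycles 2 and 5
measures the magnitude and direction of network resynchronization.
A response is classified **negative** when the gap closes directly toward
zero (sign Δψ = −sign ψ_early) and **positive** when the network
resynchronizes the long way round, through the ±12 h boundary. A slice
whose core leads by more than 12 h is indistinguishable, from wrapped
cycle-2 endpoints alone, from one whose core lags; when the experimental
protocol fixes the polarity (a long-photoperiod ensemble reorganizes the
network with the core advanced, ψ ≈ −11 ± 2 h), analyses may re-centre the
wrap interval (`abscissa_center=-4`, giving (−16, +8]) so that such slices
are signed by the known polarity. This matches how coupling-response
curves are conventionally drawn with abscissas extending beyond −12 h.

## Synthetic slice model

Each simulated cell i carries a phase obeying a mean-field
Sakaguchi–Kuramoto equation,

    dφ_i/dt = 2π/τ_i + K_r(i) · sin(Φ_opp − φ_i − β_r(i)),

where Φ_opp is the circular-mean phase of the complementary region and
β parametrises a preferred phase offset between the regions, expressed in
hours as `psi_lock_h` (the core-minus-shell peak-time gap toward which the
coupling pulls; default +4.75 h, i.e. the shell leading the core by a few
hours, as in steady-state SCN slices). Intensity is a damped cosine,
I_i(t) = A·e^(−damping·t)·(1 + cos φ_i), rendered as Gaussian blobs plus
baseline and Gaussian frame noise (photon-counting regime); actogram
counts are Poisson (event-counting regime).

The lag term is the load-bearing modelling choice. With β = 0 the model
reduces to the plain symmetric sine coupling: the shell–core gap relaxes
to zero along the shortest arc and the watershed between the two recovery
directions sits exactly at anti-phase (±τ/2). Real long-photoperiod
slices reverse direction much earlier — core leads of 2–6 h close
directly, while leads of 8–16 h resynchronize in the opposite direction —
which no odd pairwise coupling can reproduce while keeping anti-phase
unstable. The phase lag moves the unstable configuration to
ψ ≈ psi_lock_h − τ/2 ≈ −7.5 h, reproducing the observed reversal together
with its regional period signature: in direct ("negative") recoveries the
core decelerates (core period > shell period over cycles 2–4), in
boundary-crossing ("positive") recoveries it accelerates. Setting
`psi_lock_h = 0` recovers the symmetric law
sign(dψ/dt) = −sign(sin(2πψ/τ)) exactly, and a property test asserts it.

Drug scenarios are pure multipliers on the coupling constants plus an
optional uniform period offset: vehicle (1, 1, 0); a GABA_A blocker-like
scenario (K_core → 0) that locks the reorganized state; an NKCC1
blocker-like scenario (K_core ↓, period +0.35 h); a KCC2 blocker-like
scenario (K_core ↑); and a KCC2 activator-like scenario (both ↓). The
shell coupling defaults to zero because resynchronization of the
reorganized network is carried by period/phase modulation of core
neurons; K_core = 0.008 rad/h puts Δψ over three cycles at 1.4–2.5 h,
the empirically observed scale.

Defaults: frame interval 0.5 h, duration 144 h, τ = 24.5 ± 0.2 h between
cells, damping 0.01 h⁻¹, frame noise 5% of cell amplitude, blob width
2 px, 140×140 px frames. Cells are placed on a jittered lattice
(pitch = minimum distance + 2 px), which guarantees both capacity and the
spacing floor by construction. The shell population's first peak is at
20 h so that every cell's first peak is interior to the record for any
initial gap — this keeps detected cycle indices aligned with ground-truth
cycle indices.

## Trace conditioning

Peak-based statistics need peak times that are unbiased *relative to one
another*; absolute bias that is constant within a trace cancels in ψ, Δψ,
and periods. Zero-phase IIR band-passing of a damped oscillation turns
out to displace peaks near the record edges by up to ~0.9 h (the filter's
acausal edge transient interacts with the envelope), so the default
conditioning (`rhythms.preprocess_trace`) is: linear detrend → 24-h
centered moving-average subtraction (envelope removal; truncated windows
at the boundaries) → zero-phase Butterworth low-pass (16-h cutoff,
order 3) for high-frequency noise. Interior peaks then carry a small
constant per-trace offset (~0.24 h at default damping) and nothing else.
A classical Butterworth band-pass in period space (default 16–32 h,
order 3, forward–backward so it never biases phase) is provided and
tested for workflows that expect it.

The resetting assay is the one place where a discontinuity sits inside
the record: the pulse steps the phase, and any acausal filter leaks that
step backward into the pre-pulse peaks. `measure_shift` therefore
conditions the pre- and post-pulse segments separately, each with a
parametric exponential-envelope fit (a·e^(−bt)+c, no edge transients)
plus low-pass. The pre-pulse peaks give the period (mean of the 2–3
pre-pulse intervals — too few points for a regression to help) and the
extrapolated peak; shift = wrap(predicted − actual) with advances
positive; the pulse's circadian time is anchored to the last pre-pulse
peak with the reporter peak at CT12 (configurable).

## Peak detection and cosinor

Peaks are local maxima refined by quadratic interpolation through the
three surrounding samples, with a 16-h minimum separation resolving
shoulders in favour of the larger maximum. Record-endpoint samples are
excluded (no interior neighbourhood to refine against). The cosinor
model fits mesor plus harmonics (default: fundamental only) by least
squares and tests rhythmicity with an F statistic against the flat model;
amplitude is reported for the fundamental and acrophase as the time of
the fitted maximum. Null calibration and power (amplitude = noise SD,
n = 32) are checked by simulation.

## Movie analysis

Grid ROIs are 12-px-diameter disks on a 2-px lattice (only disks fully
inside the frame). Background subtraction removes each frame's 10th
percentile and median-filters (5 px) the remainder, clamped at zero —
so a spatially uniform offset added to every frame leaves all traces
unchanged. Cell detection is greedy brightest-first on the time-averaged
image: accept a candidate disk when its detrended trace passes the
cosinor gate (p < 0.05) with amplitude above threshold; accepted cells
mask a 2-radius neighbourhood (so cell ROIs never overlap), rejected
candidates mask their own disk; the scan stops when the brightest
remaining pixel falls below the amplitude floor. Slices are aligned by
exhaustive integer-pixel search minimizing the SSD of their first-24-h
summed images (ties: smaller |dx|+|dy|, then lexicographic); composites
take circular means of peak times at aligned lattice points.

## Behavior

Activity onset: the first bin above 15 counts, preceded by ≥ 6 h of bins
at or below threshold, and confirmed by ≥ 2 of the next 5 bins (30 min at
6-min bins) above threshold; offsets by the mirrored rule, returning the
bin's end time so the two markers bracket the active phase. "Inactivity"
means at-or-below threshold, otherwise the look-back clause could never
engage. All windows are specified in minutes and converted using the
record's own bin width. Both detectors are verified bin-for-bin against
a brute-force clause-by-clause scanner on 1000 random records.

Free-running period is the least-squares slope of cumulatively unwrapped
onsets versus day (exact for any noiseless drift within ±2 h/day);
re-entrainment after a 6-h advance is the first post-shift day whose
onset is within tolerance (30 min) of the shifted target and stays there;
alpha decompression after DD release is summarized by weekly means ± SEM
and a fitted exponential time constant (flat records flagged with τ = ∞).

## IHC

Ratios are computed per lobe and then averaged across the two lobes —
not the other way round; a regression test pins this ordering, which
matters whenever lobes are heterogeneous. Daily means collapse all
samples across timepoints (not the mean of timepoint means; identical
only for balanced designs). Rhythmicity per channel/region uses the same
cosinor machinery.

## What the generators do and do not emulate

The generators reproduce the statistical structure the estimators assume:
region-specific periods with between-cell spread, mean-field coupling with
a direction-dependent recovery, damped intensities, Poisson counts,
photoperiod-compressed alpha with exponential decompression, cosinor-
structured staining intensities. They do not emulate cell heterogeneity in
damping or amplitude, non-stationary noise, slice drift or deformation
(alignment is pure translation), partial-cell occlusion, or any
biophysics of chloride transport and GABA signalling. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated observation model, not robustness to every artifact of real
recordings.

## Numerical choices

Phase ODE: Euler at ≤ 0.05-h substeps (validated against a 10× finer
reference); true peak times by linear interpolation of unwrapped-phase
crossings of 2πk. Wrapping maps exactly half a period to the positive
boundary. Circular means canonicalize values within 1e-9 of the period
to zero. The coupling curves use a 4-h boxcar running average on the
24-h circle with caller-specified bins (means ± SEM). Determinism: every
simulator draws from one `numpy` Generator seeded from its config; pipeline
manifests record config hashes and output checksums, and identical seeds
give byte-identical outputs.

## Problem sizes

The validation suites use 6-slice ensembles of 60 cells (movie route) or
30 cells (trace route), 1000 random actograms for the onset/offset
equivalence, 100 seeds for resetting and alignment Monte-Carlo, 1000/500
replicates for cosinor calibration/power, and 50 simulated DD records for
the period check; these sizes give stable percentages while keeping the
whole suite under a minute of compute.
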