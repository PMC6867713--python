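# clockmesh

Analysis toolkit for quantifying the state of the suprachiasmatic nucleus
(SCN) clock network — the brain's master circadian pacemaker — from the
four kinds of recordings used to study its seasonal reorganization:

* **Bioluminescence movies** of PER2::LUC slices → per-cell phase and
  period maps, and the shell–core phase relationship **ψ** (circular-mean
  core peak time minus shell peak time; negative = core leads) with its
  coupling response **Δψ** across cycles in vitro;
* **Whole-dish luminometry** with a drug pulse → phase-response curves
  (shift = predicted − actual peak, advances positive, pulse assigned a
  circadian time with the reporter peak at CT12);
* **Wheel-running records** → activity onset/offset by the explicit
  threshold rule (first bin above 15 counts after ≥ 6 h of inactivity,
  confirmed within 30 min), alpha, free-running period by onset
  regression in constant darkness, re-entrainment after a 6-h advance,
  and alpha decompression after release into darkness;
* **Immunostaining ROI tables** → ratiometric KCC2/NKCC1 quantification
  (per-lobe ratio, then lobe average), daily profiles, and cosinor
  rhythmicity tests (harmonic least squares + F-test against a flat
  model).

Every input has a seeded generator (`clockmesh.synth`) that attaches
ground truth — coupled two-population oscillator slices, pulsed damped
cosines, Poisson actograms, cosinor-structured staining intensities — so
each estimator is validated by parameter recovery. The slice generator
couples the two cell populations through a phase-lagged mean-field sine
(`dφ_i/dt = 2π/τ_i + K·sin(Φ_opp − φ_i − β)`), which reproduces the
direction-dependent resynchronization of a long-photoperiod-reorganized
network: core leads of 2–6 h close directly while the core slows; leads
of 8–16 h resynchronize the long way round, through the ±12 h boundary,
while the core speeds up. See `docs/methods.md` for the model and every
numerical choice.

## Worked example

Simulate a reorganized slice (core leading by 11 h), run the full imaging
pipeline, and read off the network state:

```python
import numpy as np
from clockmesh import synth, imaging, network

cfg = synth.SliceSimConfig(psi0=-11.0, seed=42)       # 30 shell + 30 core cells
movie, truth = synth.simulate_slice_movie(cfg)        # 289 frames, 140x140 px
clean = imaging.subtract_background(movie)
rois = imaging.detect_cells(clean, region_masks=cfg.masks())
records = network.per_cell_records(rois.traces, rois.regions)

rec = records[0]
print(f"cells detected : {len(rois)}")
print(f"psi (cycle 2)  : {rec.psi_early:+.2f} h   [truth {truth.true_psi(2):+.2f} h]")
print(f"psi (cycle 5)  : {rec.psi_late:+.2f} h")
print(f"delta psi      : {rec.delta_psi:+.2f} h")
print(f"direction      : {network.classify_direction(rec)}")
core = np.mean([r.period for r in records if r.region == 'core'])
shell = np.mean([r.period for r in records if r.region == 'shell'])
print(f"mean period    : core {core:.2f} h, shell {shell:.2f} h")
```

prints

```
cells detected : 60
psi (cycle 2)  : -11.91 h   [truth -11.95 h]
psi (cycle 5)  : +9.95 h
delta psi      : -2.14 h
direction      : positive
mean period    : core 23.81 h, shell 24.52 h
```

All 60 simulated cells are recovered; the measured cycle-2 gap matches
the ground truth within 0.05 h. Because the core led by more than the
direction watershed (~7.5 h), the network resynchronizes in the
"positive" direction: ψ runs through the ±12 h boundary (−11.9 → +10.0,
Δψ < 0) and the core cells cycle ~0.7 h faster than the shell while they
catch up — the signature of a reorganized network recovering the long way
round. A slice started at ψ0 = −4 instead shows Δψ > 0 with the core
running slower than the shell ("negative" direction).

The same operations are available from the shell:

```
clockmesh simulate slice --seed 42 --out run/         # TIFF + sidecar + truth
clockmesh pipeline slice --seed 42 --out run/         # movie -> records/maps/curves
clockmesh behavior period --in wheel.awd --lights lights.csv
clockmesh ihc profile --in ihc.csv --out out/
```

`clockmesh pipeline slice` writes `records/records.csv` (one row per cell:
region, cycle-2 relative peak time, period over cycles 2–4, ψ, Δψ),
phase/period maps, smoothed coupling- and period-response curves (4-h
circular running average with bin means ± SEM), and a `manifest.json`
with config hash and output checksums — identical seeds give
byte-identical runs.

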