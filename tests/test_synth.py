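"""Synthetic-data generators: determinism, closed forms, and ODE oracles."""

import dataclasses

import numpy as np
import pytest

from clockmesh import network, synth


def uncoupled_config(**kw):
    base = dict(
        grid_shape=(96, 96),
        n_shell=4,
        n_core=4,
        K_shell=0.0,
        K_core=0.0,
        tau_sd=0.0,
        noise_sd=0.0,
        psi0=-4.0,
        psi_lock_h=0.0,
        seed=5,
    )
    base.update(kw)
    return synth.SliceSimConfig(**base)


class TestSliceValidation:
    def test_psi0_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            synth.SliceSimConfig(psi0=-12.0).validate()

    def test_duration_too_short_rejected(self):
        with pytest.raises(ValueError):
            synth.SliceSimConfig(duration=48.0).validate()

    def test_overlapping_masks_rejected(self):
        masks = {
            "shell": np.ones((96, 96), dtype=bool),
            "core": np.ones((96, 96), dtype=bool),
        }
        with pytest.raises(ValueError):
            synth.SliceSimConfig(grid_shape=(96, 96), region_masks=masks).validate()


class TestSliceDeterminism:
    def test_same_seed_bit_identical_movie(self):
        cfg = synth.SliceSimConfig(
            grid_shape=(96, 96), n_shell=4, n_core=4, duration=80.0, seed=3
        )
        m1, t1 = synth.simulate_slice_movie(cfg)
        m2, t2 = synth.simulate_slice_movie(cfg)
        assert np.array_equal(m1.frames, m2.frames)
        assert np.array_equal(t1.cell_centers, t2.cell_centers)

    def test_different_seed_differs(self):
        cfg = synth.SliceSimConfig(
            grid_shape=(96, 96), n_shell=4, n_core=4, duration=80.0, seed=3
        )
        cfg2 = dataclasses.replace(cfg, seed=4)
        m1, _ = synth.simulate_slice_movie(cfg)
        m2, _ = synth.simulate_slice_movie(cfg2)
        assert not np.array_equal(m1.frames, m2.frames)


class TestSlicePhaseDynamics:
    def test_uncoupled_peaks_follow_closed_form(self):
        cfg = uncoupled_config()
        _, truth = synth.simulate_cell_traces(cfg)
        for pk, reg, tau in zip(
            truth.true_peak_times, truth.cell_regions, truth.cell_periods
        ):
            first = cfg.first_peak_h + (cfg.psi0 if reg == "core" else 0.0)
            expected = first + tau * np.arange(len(pk))
            np.testing.assert_allclose(pk, expected, atol=1e-6)
        # gap between region-mean peaks stays psi0 on every cycle
        for cycle in (1, 2, 3, 4):
            assert truth.true_psi(cycle) == pytest.approx(cfg.psi0, abs=1e-6)

    def test_uncoupled_phase_linear_in_time(self):
        cfg = uncoupled_config()
        _, truth = synth.simulate_cell_traces(cfg)
        t = truth.frame_times
        for row, tau in zip(truth.phase_trajectories, truth.cell_periods):
            fitted = np.polyfit(t, row, 1)
            assert fitted[0] == pytest.approx(2 * np.pi / tau, rel=1e-9)

    def test_symmetric_coupling_shrinks_gap_every_cycle(self):
        cfg = uncoupled_config(K_core=0.02)
        _, truth = synth.simulate_cell_traces(cfg)
        psis = [abs(truth.true_psi(c)) for c in range(1, 6)]
        assert all(a > b for a, b in zip(psis, psis[1:]))

    def test_matches_fine_step_reference_integrator(self):
        cfg = uncoupled_config(n_shell=3, n_core=3, K_core=0.02, K_shell=0.01,
                               duration=96.0)
        _, truth = synth.simulate_cell_traces(cfg)
        # independent Euler reference at a 10x finer step
        taus = truth.cell_periods
        is_core = np.array([r == "core" for r in truth.cell_regions])
        omegas = 2 * np.pi / taus
        phi = np.where(is_core, -2 * np.pi * (20.0 + cfg.psi0) / 24.5,
                       -2 * np.pi * 20.0 / 24.5).astype(float)
        dt = 0.005
        t_grid = truth.frame_times
        ref = np.empty((phi.size, t_grid.size))
        ref[:, 0] = phi
        for f in range(1, t_grid.size):
            steps = int(round((t_grid[f] - t_grid[f - 1]) / dt))
            for _ in range(steps):
                ms = np.arctan2(
                    np.mean(np.sin(phi[~is_core])), np.mean(np.cos(phi[~is_core]))
                )
                mc = np.arctan2(
                    np.mean(np.sin(phi[is_core])), np.mean(np.cos(phi[is_core]))
                )
                pull = np.where(
                    is_core,
                    cfg.K_core * np.sin(ms - phi),
                    cfg.K_shell * np.sin(mc - phi),
                )
                phi = phi + dt * (omegas + pull)
            ref[:, f] = phi
        assert np.max(np.abs(ref - truth.phase_trajectories)) < 5e-3

    @pytest.mark.parametrize("psi0", [-8.0, -4.0, 5.0, 11.0])
    def test_shortest_arc_sign_law_without_lag(self, psi0):
        # with symmetric coupling the gap velocity obeys
        # sign(dpsi/dt) = -sign(sin(2 pi psi / tau))
        cfg = uncoupled_config(psi0=psi0, K_core=0.02)
        _, truth = synth.simulate_cell_traces(cfg)
        dpsi = network.wrap_phase(truth.true_psi(2) - truth.true_psi(1))
        expected_sign = -np.sign(np.sin(2 * np.pi * psi0 / cfg.tau_core))
        assert np.sign(dpsi) == expected_sign

    def test_symmetric_recovery_does_not_cross_zero(self):
        cfg = uncoupled_config(psi0=-4.0, K_core=0.02)
        _, truth = synth.simulate_cell_traces(cfg)
        psis = [truth.true_psi(c) for c in range(1, 6)]
        assert all(p <= 1e-9 for p in psis)

    def test_default_lag_sends_large_lead_through_boundary(self):
        # with the default phase-lagged coupling a core lead of 11 h
        # resynchronizes the long way round (through the +/-12 boundary)
        cfg = synth.SliceSimConfig(
            grid_shape=(96, 96), n_shell=6, n_core=6, psi0=-11.0,
            tau_sd=0.0, noise_sd=0.0, seed=2,
        )
        _, truth = synth.simulate_cell_traces(cfg)
        recentered = [
            network.wrap_phase(truth.true_psi(c), 24.0, -4.0) for c in (1, 3, 5)
        ]
        assert recentered[0] > -12.0
        assert all(a > b for a, b in zip(recentered, recentered[1:]))

    def test_scenarios_scale_coupling_and_period(self):
        cfg = synth.SliceSimConfig()
        ace = synth.apply_scenario(cfg, "ace")
        assert ace.K_core == 0.0 and ace.K_shell == cfg.K_shell
        bu = synth.apply_scenario(cfg, "bu")
        assert bu.K_core == pytest.approx(0.25 * cfg.K_core)
        assert bu.tau_core == pytest.approx(cfg.tau_core + 0.35)


class TestLuminometry:
    def test_deterministic(self):
        cfg = synth.PulseSimConfig(true_shift=2.0, seed=9)
        t1, _ = synth.simulate_luminometry(cfg)
        t2, _ = synth.simulate_luminometry(cfg)
        assert np.array_equal(t1.values, t2.values)

    def test_zero_shift_continues_lattice(self):
        cfg = synth.PulseSimConfig(true_shift=0.0, noise_sd=0.0)
        ts, _ = synth.simulate_luminometry(cfg)
        lattice = cfg.first_peak_h + cfg.baseline_period * np.arange(7)
        lattice = lattice[lattice < ts.times[-1] - 1]
        for peak in lattice:
            # the local intensity maximum sits within a sample of the
            # phase peak (the damped envelope pulls it slightly early)
            i = np.argmin(np.abs(ts.times - peak))
            window = slice(max(0, i - 6), i + 7)
            local_max = ts.times[window][np.argmax(ts.values[window])]
            assert abs(local_max - peak) <= 0.5

    def test_delay_moves_first_post_pulse_peak_later(self):
        base_cfg = synth.PulseSimConfig(true_shift=0.0, noise_sd=0.0)
        late_cfg = synth.PulseSimConfig(true_shift=-2.0, noise_sd=0.0)
        base, _ = synth.simulate_luminometry(base_cfg)
        late, _ = synth.simulate_luminometry(late_cfg)

        def first_post_peak(ts, pulse):
            sel = ts.times > pulse + 2
            v = ts.values[sel]
            i = 1 + np.argmax(
                (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
            )
            return ts.times[sel][i]

        t0 = first_post_peak(base, base_cfg.pulse_time)
        t1 = first_post_peak(late, late_cfg.pulse_time)
        assert t1 - t0 == pytest.approx(2.0, abs=0.5)

    def test_pulse_before_three_cycles_rejected(self):
        with pytest.raises(ValueError):
            synth.PulseSimConfig(pulse_time=48.0).validate()


class TestActogram:
    def test_deterministic(self):
        cfg = synth.ActogramSimConfig(seed=4)
        a1, t1 = synth.simulate_actogram(cfg)
        a2, t2 = synth.simulate_actogram(cfg)
        assert np.array_equal(a1.counts, a2.counts)
        assert t1.equals(t2)

    def test_clean_onset_is_first_active_bin(self):
        cfg = synth.ActogramSimConfig(
            inactive_rate=0.0, active_rate=100.0, weeks_entrained=1, weeks_dd=1,
            seed=1,
        )
        act, truth = synth.simulate_actogram(cfg)
        bpd = act.bins_per_day
        for d in range(act.n_days):
            day_counts = act.counts[d * bpd : (d + 1) * bpd]
            active_bins = np.flatnonzero(day_counts > 0)
            if active_bins.size:
                first_active_h = active_bins[0] * act.bin_hours
                assert first_active_h == pytest.approx(
                    truth.loc[d, "onset_h"], abs=act.bin_hours
                )

    def test_dd_onsets_advance_at_free_period_drift(self):
        cfg = synth.ActogramSimConfig(free_period=23.6, weeks_dd=2)
        _, truth = synth.simulate_actogram(cfg)
        dd = truth[truth.in_dd].reset_index(drop=True)
        diffs = np.diff(dd.onset_h.to_numpy())
        np.testing.assert_allclose(diffs, -0.4, atol=1e-9)

    def test_alpha_decompression_time_constants_order_weekly_means(self):
        slow = synth.ActogramSimConfig(alpha_tau=25.0, seed=1)
        fast = synth.ActogramSimConfig(alpha_tau=8.0, seed=1)
        _, t_slow = synth.simulate_actogram(slow)
        _, t_fast = synth.simulate_actogram(fast)
        for w in range(4):
            sel = slice(7 + w * 7, 7 + (w + 1) * 7)
            mean_slow = t_slow.alpha_h.iloc[sel].mean()
            mean_fast = t_fast.alpha_h.iloc[sel].mean()
            assert mean_slow < mean_fast
            # weekly means of the stated exponential
            days = np.arange(w * 7, (w + 1) * 7)
            expect = np.mean(
                slow.alpha_end
                - (slow.alpha_end - slow.alpha_start) * np.exp(-days / slow.alpha_tau)
            )
            assert mean_slow == pytest.approx(expect)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            synth.ActogramSimConfig(alpha_start=0.0).validate()


class TestIhc:
    def test_deterministic(self):
        cfg = synth.IhcSimConfig(seed=6)
        t1, _ = synth.simulate_ihc(cfg)
        t2, _ = synth.simulate_ihc(cfg)
        assert t1.equals(t2)

    def test_zero_amplitude_means_flat_profile(self):
        params = {
            ("KCC2", "core"): synth.ChannelParams(20.0, 0.0, 0.0),
        }
        cfg = synth.IhcSimConfig(
            params=params, n_per_timepoint=12, noise_sd=1.0, seed=0
        )
        table, _ = synth.simulate_ihc(cfg)
        tp_means = table.groupby("zt")["mean_intensity"].mean()
        # sampling error bound: 4 sigma of the timepoint mean
        bound = 4 * 1.0 / np.sqrt(12 * 2)
        assert np.all(np.abs(tp_means - 20.0) < bound)

    def test_ninety_one_fold_scenario_reproduced(self):
        params = {
            ("KCC2", "core"): synth.ChannelParams(29.12, 0.0, 0.0),
            ("KCC2", "shell"): synth.ChannelParams(29.12 / 91.0, 0.0, 0.0),
        }
        cfg = synth.IhcSimConfig(
            params=params, n_per_timepoint=8, noise_sd=0.05, seed=3
        )
        table, _ = synth.simulate_ihc(cfg)
        daily = table.groupby("region")["mean_intensity"].mean()
        assert daily["core"] / daily["shell"] == pytest.approx(91.0, rel=0.10)

    def test_negative_mean_intensity_rejected(self):
        params = {("KCC2", "core"): synth.ChannelParams(1.0, 2.0, 0.0)}
        with pytest.raises(ValueError):
            synth.IhcSimConfig(params=params).validate()
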