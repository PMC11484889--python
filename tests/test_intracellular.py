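import numpy as np
import pytest

import finchcall as fc


SR = 20000


def _trace_with_spike(at_s=0.1, height=35.0, dur_s=0.3, baseline=-70.0):
    vm = np.full(int(dur_s * SR), baseline)
    c = int(at_s * SR)
    t = np.arange(-20, 21) / SR
    vm[c - 20: c + 21] += height * np.exp(-(t**2) / (2 * 0.0005**2))
    return vm


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        vm = np.full(1000, -70.0)
        assert len(fc.detect_spikes(vm, SR, -70.0)) == 0

    def test_single_transient_detected_at_crossing(self):
        vm = _trace_with_spike(at_s=0.1)
        times = fc.detect_spikes(vm, SR, -70.0)
        assert len(times) == 1
        assert abs(times[0] - 0.1) < 0.002

    def test_generator_spikes_all_recovered(self):
        cfg = fc.TrialSimConfig(lambda_locked=3, background_rate_hz=2.0, noise_sd_mV=2.0, seed=42)
        ts, gt = fc.simulate_intracellular_trialset(cfg)
        for vm, true_times in zip(ts.vm_mV, gt.spike_times):
            det = fc.detect_spikes(vm, ts.sample_rate, ts.baseline_mV)
            assert len(det) == len(true_times)
            if len(det):
                np.testing.assert_allclose(det, true_times, atol=0.002)

    def test_refractory_merge(self):
        vm = np.full(1000, -70.0)
        vm[100:130] = -30.0  # one long crossing: single spike
        assert len(fc.detect_spikes(vm, SR, -70.0)) == 1


class TestStimulusWindows:
    @pytest.mark.parametrize(
        "call,analysis,silence",
        [
            ((1.00, 1.15), (1.00, 1.20), (0.75, 0.95)),
            ((0.30, 0.40), (0.30, 0.45), (0.10, 0.25)),
        ],
    )
    def test_window_arithmetic(self, call, analysis, silence):
        a, s = fc.stimulus_windows(call)
        assert a == pytest.approx(analysis)
        assert s == pytest.approx(silence)

    def test_call_at_trace_start_rejected(self):
        with pytest.raises(ValueError):
            fc.stimulus_windows((0.0, 0.1))


class TestFiringRate:
    def test_zero_spikes(self):
        assert fc.firing_rate(np.array([]), (0, 1.0)) == 0.0

    def test_two_spikes_in_200ms(self):
        assert fc.firing_rate(np.array([0.05, 0.10]), (0.0, 0.200)) == pytest.approx(10.0)

    def test_unbiased_on_poisson(self, rng):
        rates = [
            fc.firing_rate(rng.uniform(0, 1, rng.poisson(5.0)), (0, 1.0)) for _ in range(1000)
        ]
        m, se = np.mean(rates), np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(m - 5.0) < 3 * se


class TestSpikingPrecision:
    def test_identical_spike_times_maximally_precise(self, rng):
        trains = [np.array([0.05, 0.12])] * 10
        res = fc.spiking_precision(trains, (0.0, 0.2), n_perm=200, rng=rng)
        # cross-trial pairs at the same latencies still include the 0.05/0.12
        # cross-latency pairs, but identical trains beat virtually every shuffle
        assert res.responsive
        assert res.score > 2

    def test_perfectly_locked_single_latency_gives_zero_dobs(self, rng):
        trains = [np.array([0.07])] * 8
        res = fc.spiking_precision(trains, (0.0, 0.2), n_perm=200, rng=rng)
        assert res.d_obs_s == 0.0
        assert res.responsive

    def test_insufficient_spikes_absent_not_zero(self, rng):
        assert fc.spiking_precision([np.array([0.1])], (0, 0.2), rng=rng) is None
        assert (
            fc.spiking_precision([np.array([0.1]), np.array([])], (0, 0.2), rng=rng) is None
        )

    def test_locked_generator_detected(self):
        hits = 0
        for s in range(20):
            cfg = fc.TrialSimConfig(lambda_locked=3, jitter_sd_s=0.002, seed=700 + s)
            ts, _ = fc.simulate_intracellular_trialset(cfg)
            trains = [fc.detect_spikes(v, ts.sample_rate, ts.baseline_mV) for v in ts.vm_mV]
            res = fc.spiking_precision(trains, ts.window, n_perm=500, rng=np.random.default_rng(s))
            hits += res is not None and res.responsive
        assert hits >= 18

    def test_isi_shuffle_variant_runs(self, rng):
        trains = [np.array([0.05, 0.12]), np.array([0.05, 0.13]), np.array([0.06])]
        res = fc.spiking_precision(trains, (0.0, 0.2), n_perm=100, rng=rng, method="isi")
        assert res is not None and len(res.null_s) == 100


class TestExtractSubthreshold:
    def test_spike_free_trace_unchanged(self, rng):
        vm = -70 + rng.normal(0, 2, 2000)
        out, flagged = fc.extract_subthreshold(vm, -70.0)
        np.testing.assert_array_equal(out, vm)
        assert flagged == []

    def test_clipped_trace_never_exceeds_threshold(self):
        cfg = fc.TrialSimConfig(lambda_locked=4, background_rate_hz=3.0, seed=9)
        ts, _ = fc.simulate_intracellular_trialset(cfg)
        for vm in ts.vm_mV:
            out, flagged = fc.extract_subthreshold(vm, ts.baseline_mV)
            assert flagged == []
            assert np.all(out < ts.baseline_mV + 15.0)

    def test_rmse_vs_ground_truth_below_half_mv(self):
        cfg = fc.TrialSimConfig(lambda_locked=3, background_rate_hz=2.0, seed=5)
        ts, gt = fc.simulate_intracellular_trialset(cfg)
        for vm, sub, times in zip(ts.vm_mV, gt.subthreshold_mV, gt.spike_times):
            out, _ = fc.extract_subthreshold(vm, ts.baseline_mV)
            mask = np.ones(len(vm), bool)
            for t0 in times:
                c = int(t0 * ts.sample_rate)
                w = int(0.002 * ts.sample_rate)
                mask[max(0, c - w): c + w] = False
            rmse = np.sqrt(np.mean((out[mask] - sub[mask]) ** 2))
            assert rmse < 0.5

    def test_overlapping_cuts_merge_into_one_segment(self):
        # two spikes whose dip between them stays above the clip level form
        # one maximal supra-level run, hence a single interpolation segment
        vm = np.full(1000, -70.0)
        vm[100:120] = -50.0
        vm[120] = -54.0  # dip, still above the -55 mV clip level
        vm[121:140] = -50.0
        out, _ = fc.extract_subthreshold(vm, -70.0)
        np.testing.assert_allclose(out[100:140], -70.0)
        assert np.all(out < -55.0)

    def test_boundary_spike_flagged(self):
        vm = np.full(500, -70.0)
        vm[:30] = -40.0
        out, flagged = fc.extract_subthreshold(vm, -70.0)
        assert flagged == [(0, 30)]
        assert np.all(out[:30] == vm[30])


class TestSubthresholdCorrelation:
    def test_identical_traces(self, rng):
        x = rng.normal(-70, 2, 2000)
        r, n = fc.subthreshold_correlation(np.stack([x, x, x]), SR, (0.0, 0.1))
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_sin_cos_orthogonal(self):
        t = np.arange(2000) / SR
        s = np.sin(2 * np.pi * 100 * t)
        c = np.cos(2 * np.pi * 100 * t)
        r, _ = fc.subthreshold_correlation(np.stack([s, c]), SR, (0.0, 0.1))
        assert abs(r) < 1e-6

    def test_symmetry_and_affine_invariance(self, rng):
        X = rng.normal(0, 1, (4, 2000))
        r1, _ = fc.subthreshold_correlation(X, SR, (0.0, 0.1))
        r2, _ = fc.subthreshold_correlation(X[::-1], SR, (0.0, 0.1))
        r3, _ = fc.subthreshold_correlation(3.0 * X + 5.0, SR, (0.0, 0.1))
        assert r1 == pytest.approx(r2)
        assert r1 == pytest.approx(r3)

    def test_zero_variance_trace_skipped(self, rng):
        X = np.vstack([rng.normal(0, 1, (2, 2000)), np.zeros(2000)])
        r, n = fc.subthreshold_correlation(X, SR, (0.0, 0.1))
        assert n == 1  # only the non-degenerate pair

    def test_shared_fraction_recovered(self):
        cfg = fc.TrialSimConfig(n_trials=64, shared_fraction=0.5, seed=7)
        ts, _ = fc.simulate_intracellular_trialset(cfg)
        r, n = fc.subthreshold_correlation(ts.vm_mV, ts.sample_rate, ts.window)
        assert n >= 2000
        assert abs(r - 0.5) < 0.05


class TestDeltaSubthreshold:
    def test_identical_windows_give_zero(self, rng):
        x = np.tile(rng.normal(-70, 1, 1000), 4)
        mean, per = fc.delta_subthreshold(
            np.stack([x, x]), SR, (0.10, 0.15), (0.0, 0.05)
        )
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_boxcar_deflection_measured_exactly(self):
        vm = np.full(int(0.6 * SR), -70.0)
        a, b = int(0.3 * SR), int(0.45 * SR)
        vm = np.stack([vm, vm]).copy()
        vm[:, a:b] += 3.0
        mean, _ = fc.delta_subthreshold(vm, SR, (0.30, 0.45), (0.10, 0.25))
        assert mean == pytest.approx(3.0)

    def test_generator_deflection_recovered(self):
        vals = []
        for s in range(50):
            cfg = fc.TrialSimConfig(deflection_mV=2.5, noise_sd_mV=2.0, seed=1000 + s)
            ts, _ = fc.simulate_intracellular_trialset(cfg)
            analysis, silence = fc.stimulus_windows(ts.window)
            mean, _ = fc.delta_subthreshold(ts.vm_mV, ts.sample_rate, analysis, silence)
            vals.append(mean)
        m, se = np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals))
        # analysis window includes the 50 ms pad where the boxcar is absent:
        # expected dilution factor = call_dur / (call_dur + pad)
        expect = 2.5 * 0.15 / 0.20
        assert abs(m - expect) < 3 * se


class TestPerturbationDelta:
    def test_delta_arithmetic(self):
        res = fc.perturbation_spike_delta([3], [1, 1, 1])
        assert res.deltas[0] == 2.0

    def test_stereotyped_renditions_give_zero_ci_and_no_flags(self):
        res = fc.perturbation_spike_delta([2, 2], [2, 2, 2, 2])
        assert res.ci == (0.0, 0.0)
        assert not res.flags.any()
        assert res.delta_mean == 0.0

    def test_constructed_plus_two_spikes_all_flagged(self):
        cfg = fc.PerturbationSimConfig(extra_spikes=2, seed=13)
        ts, _ = fc.simulate_singing_perturbation(cfg)
        epoch = (cfg.call_onset_s, cfg.call_offset_s + cfg.pad_s)
        counts = fc.count_spikes_in_epoch(ts, epoch)
        pert = counts[list(ts.perturbed)]
        unp = counts[[i for i in range(ts.n_trials) if i not in ts.perturbed]]
        res = fc.perturbation_spike_delta(pert, unp)
        assert np.all(res.deltas == 2.0)
        assert res.flags.all()

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            fc.perturbation_spike_delta([2], [1])


class TestFullPipelineRecovery:
    def test_configured_regime_recovered_across_seeded_runs(self):
        """Generator with known (rho, deflection, jitter): the pipeline's
        (mean r, delta subthreshold, responsive flag) land in the configured
        regime in >= 90 of 100 seeded runs."""
        rho, d, lam = 0.4, 2.0, 3.0
        hits = 0
        for s in range(100):
            cfg = fc.TrialSimConfig(
                shared_fraction=rho, deflection_mV=d, lambda_locked=lam,
                jitter_sd_s=0.002, seed=20_000 + s,
            )
            ts, _ = fc.simulate_intracellular_trialset(cfg)
            analysis, silence = fc.stimulus_windows(ts.window)
            trains = [
                fc.detect_spikes(v, ts.sample_rate, ts.baseline_mV) for v in ts.vm_mV
            ]
            prec = fc.spiking_precision(
                trains, analysis, n_perm=500, rng=np.random.default_rng(s)
            )
            sub = np.array(
                [fc.extract_subthreshold(v, ts.baseline_mV)[0] for v in ts.vm_mV]
            )
            r, _ = fc.subthreshold_correlation(sub, ts.sample_rate, ts.window)
            dmean, _ = fc.delta_subthreshold(sub, ts.sample_rate, analysis, silence)
            diluted = d * 0.15 / 0.20  # pad dilutes the boxcar deflection
            ok = (
                (prec is not None and prec.responsive)
                and r > 0.1  # shared input clearly present (clipping attenuates r)
                and abs(dmean - diluted) < 1.5
            )
            hits += ok
        assert hits >= 90


class TestPerturbationSubthresholdFlag:
    def test_zero_delta_not_flagged(self):
        assert not fc.perturbation_subthreshold_flag([0.0], 2.0)[0]

    def test_boundary_not_flagged(self):
        assert not fc.perturbation_subthreshold_flag([2.0, -2.0], 2.0).any()

    def test_above_threshold_flagged(self):
        flags = fc.perturbation_subthreshold_flag([2.1, -3.0, 0.5], 2.0)
        assert list(flags) == [True, True, False]

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            fc.perturbation_subthreshold_flag([1.0], 0.0)
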