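import numpy as np
import pytest

import finchcall as fc


class TestTutorAudio:
    def test_total_motif_duration(self, tutor):
        clip, truth = tutor
        # 0.185+0.119+0.155+0.124+0.185+0.119+0.155
        assert clip.duration_s == pytest.approx(1.042, abs=1e-4)
        assert truth.events[-1].offset_s == pytest.approx(1.042, abs=1e-9)

    def test_four_syllables_with_printed_durations(self, tutor):
        _, truth = tutor
        durs = [round(e.duration_s * 1000) for e in truth.events]
        assert durs == [185, 155, 185, 155]
        assert [e.label for e in truth.events] == ["A", "B", "A", "B"]

    def test_determinism(self):
        c1, _ = fc.render_tutor_audio(sample_rate=22050, seed=3)
        c2, _ = fc.render_tutor_audio(sample_rate=22050, seed=3)
        np.testing.assert_array_equal(c1.samples, c2.samples)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            fc.render_tutor_audio(sample_rate=4000)


class TestSessionSimulation:
    def test_zero_rates_give_zero_calls(self):
        cfg = fc.SessionSimConfig(call_base_rate_hz=0.0, call_rate_out_song_hz=0.0, seed=1)
        truth = fc.simulate_session_events(cfg)
        assert len(truth.of_kind("call")) == 0

    def test_zero_bout_rate_gives_no_syllables(self):
        cfg = fc.SessionSimConfig(bout_rate_per_min=0.0, seed=1)
        truth = fc.simulate_session_events(cfg)
        assert len(truth.of_kind("syllable")) == 0
        assert len(truth.of_kind("song_bout")) == 0

    def test_rate_floor_at_zero(self):
        cfg = fc.SessionSimConfig(
            call_base_rate_hz=0.1, call_age_slope_hz_per_day=-0.05, call_age0_dph=60
        )
        assert cfg.call_rate_in_song_hz(90) == 0.0

    def test_ground_truth_satisfies_event_invariants(self, small_session):
        _, _, truth = small_session
        for ch in ("box", "backpack"):
            ev = [e for e in truth.events if e.channel_tag == ch]
            assert all(a.onset_s <= b.onset_s for a, b in zip(ev, ev[1:]))
        assert all(e.offset_s > e.onset_s for e in truth.events)

    def test_syllables_on_box_calls_on_backpack(self, small_session):
        _, _, truth = small_session
        assert all(e.channel_tag == "box" for e in truth.of_kind("syllable").events)
        assert all(e.channel_tag == "backpack" for e in truth.of_kind("call").events)

    def test_backpack_attenuates_juvenile(self, small_session):
        # per-syllable RMS medians so a call overlapping one syllable
        # cannot dominate the comparison
        box, bp, truth = small_session
        sylls = truth.of_kind("syllable")
        box_rms = np.median(
            [np.sqrt(np.mean(box.slice(e.onset_s, e.offset_s) ** 2)) for e in sylls.events]
        )
        bp_rms = np.median(
            [np.sqrt(np.mean(bp.slice(e.onset_s, e.offset_s) ** 2)) for e in sylls.events]
        )
        assert bp_rms < 0.2 * box_rms

    def test_determinism(self):
        cfg = fc.SessionSimConfig(session_dur_s=20, seed=7)
        b1, p1, t1 = fc.simulate_session(cfg)
        b2, p2, t2 = fc.simulate_session(cfg)
        np.testing.assert_array_equal(b1.samples, b2.samples)
        assert t1.events == t2.events


class TestDevelopmentSimulation:
    def test_zero_slope_gives_equal_rates(self):
        tpl = fc.SessionSimConfig(call_base_rate_hz=0.5, call_age_slope_hz_per_day=0.0)
        rates = {tpl.call_rate_in_song_hz(a) for a in range(50, 90)}
        assert rates == {0.5}

    def test_ages_must_increase(self):
        tpl = fc.SessionSimConfig()
        with pytest.raises(ValueError):
            fc.simulate_development(tpl, [60, 60, 70])

    def test_summaries_consistent_with_events(self):
        tpl = fc.SessionSimConfig(call_base_rate_hz=0.8, session_dur_s=120, seed=5)
        sims, slope = fc.simulate_development(tpl, [55, 60, 65])
        assert slope == 0.0
        for truth, summary in sims:
            bouts = fc.true_bouts(truth)
            assert summary.n_bouts == len(bouts)
            if summary.total_song_dur_s > 0:
                assert summary.call_ratio == pytest.approx(
                    fc.call_ratio(bouts, truth.of_kind("call"))
                )


class TestIntracellularGenerator:
    def test_rho_one_zero_noise_identical_subthreshold(self):
        cfg = fc.TrialSimConfig(shared_fraction=1.0, n_trials=5, seed=2)
        ts, gt = fc.simulate_intracellular_trialset(cfg)
        i0 = int(cfg.call_onset_s * cfg.sample_rate)
        i1 = int(cfg.call_offset_s * cfg.sample_rate)
        W = gt.subthreshold_mV[:, i0:i1]
        np.testing.assert_allclose(W - W[0], 0.0, atol=1e-9)

    def test_zero_rates_give_zero_spikes(self):
        cfg = fc.TrialSimConfig(lambda_locked=0.0, background_rate_hz=0.0, seed=2)
        _, gt = fc.simulate_intracellular_trialset(cfg)
        assert all(len(t) == 0 for t in gt.spike_times)

    def test_spike_height_invariant(self):
        with pytest.raises(ValueError):
            fc.TrialSimConfig(spike_height_mV=20.0)

    def test_determinism(self):
        cfg = fc.TrialSimConfig(lambda_locked=2, background_rate_hz=1, seed=11)
        t1, g1 = fc.simulate_intracellular_trialset(cfg)
        t2, g2 = fc.simulate_intracellular_trialset(cfg)
        np.testing.assert_array_equal(t1.vm_mV, t2.vm_mV)


class TestPerturbationGenerator:
    def test_no_effect_means_statistically_identical(self):
        cfg = fc.PerturbationSimConfig(seed=3)
        ts, _ = fc.simulate_singing_perturbation(cfg)
        epoch = (cfg.call_onset_s, cfg.call_offset_s + cfg.pad_s)
        counts = fc.count_spikes_in_epoch(ts, epoch)
        assert counts.std() == 0.0

    def test_deflection_mean_recovered(self):
        vals = []
        for s in range(40):
            cfg = fc.PerturbationSimConfig(deflection_mV=8.0, noise_sd_mV=1.0, seed=s)
            ts, gt = fc.simulate_singing_perturbation(cfg)
            i0 = int(cfg.call_onset_s * cfg.sample_rate)
            i1 = int((cfg.call_offset_s + cfg.pad_s) * cfg.sample_rate)
            unp = [i for i in range(ts.n_trials) if i not in ts.perturbed]
            d = (
                gt.subthreshold_mV[list(ts.perturbed), i0:i1].mean()
                - gt.subthreshold_mV[unp, i0:i1].mean()
            )
            vals.append(d)
        m, se = np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(m - 8.0) < 3 * se

    def test_bad_perturbed_indices_rejected(self):
        with pytest.raises(ValueError):
            fc.PerturbationSimConfig(n_renditions=4, perturbed=(5,))


class TestPopulationGenerator:
    def test_projection_rates_below_two_hz(self):
        cfg = fc.PopulationSimConfig(n_units=12, projection_fraction=1.0, seed=5)
        units, sched, dur = fc.simulate_population_units(cfg)
        for u in units:
            assert fc.spontaneous_rate(u, sched, dur) <= 2.0

    def test_schedule_span(self):
        sched = fc.make_stimulus_schedule(60, 1.5, 0.15)
        assert sched[-1].onset_s - sched[0].onset_s == pytest.approx(88.5)
        assert len(sched) == 60

    def test_determinism(self):
        cfg = fc.PopulationSimConfig(n_units=3, n_trials=10, seed=12)
        u1, _, _ = fc.simulate_population_units(cfg)
        u2, _, _ = fc.simulate_population_units(cfg)
        for a, b in zip(u1, u2):
            np.testing.assert_array_equal(a.spike_times, b.spike_times)


class TestMonteCarloMeans:
    def test_session_call_ratio_converges_to_rate(self):
        ratios = []
        for s in range(80):
            cfg = fc.SessionSimConfig(call_base_rate_hz=0.5, session_dur_s=240, seed=3000 + s)
            truth = fc.simulate_session_events(cfg)
            bouts = fc.true_bouts(truth)
            if bouts:
                ratios.append(fc.call_ratio(bouts, truth.of_kind("call")))
        m = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(m - 0.5) < 3 * se

    def test_development_slope_sampling_distribution(self):
        slopes = []
        ages = list(range(50, 90, 4))
        for s in range(40):
            tpl = fc.SessionSimConfig(
                call_base_rate_hz=0.5,
                call_age_slope_hz_per_day=0.02,
                call_age0_dph=60,
                session_dur_s=300,
                seed=101 + 31 * s,
            )
            sims, _ = fc.simulate_development(tpl, ages)
            tr = fc.development_trend([ss for _, ss in sims])
            slopes.append(tr.slope)
        m = np.mean(slopes)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(m - 0.02) < 3 * se
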