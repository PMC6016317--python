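"""Synthetic kindling-EEG generator: calibration, determinism, titration."""
import numpy as np
import pytest

from kindleeg import (
    DEFAULT_PROFILES,
    GroupProfile,
    PhaseProfile,
    ResponseCurve,
    ScheduledEvent,
    SimConfig,
    band_fractions,
    baseline_stats,
    default_schedule,
    detect_ad_events,
    generate_ad_segment,
    generate_baseline,
    simulate_session,
    simulate_threshold_titration,
    welch_psd,
)
from kindleeg.addetect import sliding_rms
from kindleeg.exceptions import CalibrationError, ConfigurationError, SchedulingError


class TestBaseline:
    def test_sample_count(self, sim_config):
        rec = generate_baseline(sim_config)
        assert rec.n_samples == 7000

    def test_zero_amplitude_gives_zero_trace(self):
        cfg = SimConfig(baseline_amplitude=0.0, seed=1)
        assert np.all(generate_baseline(cfg).samples == 0.0)

    def test_seed_determinism(self):
        a = generate_baseline(SimConfig(seed=11))
        b = generate_baseline(SimConfig(seed=11))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_low_frequency_band_dominant(self, sim_config):
        # resting EEG is delta-theta dominated: mean LFB fraction > 0.6
        rng = np.random.default_rng(0)
        lfb = []
        for _ in range(100):
            rec = generate_baseline(sim_config, rng=rng)
            lfb.append(band_fractions(welch_psd(rec)).fraction["LFB"])
        assert np.mean(lfb) > 0.6

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(sampling_rate=50.0)
        with pytest.raises(ConfigurationError):
            SimConfig(baseline_duration=-1.0)
        with pytest.raises(ConfigurationError):
            SimConfig(ad_envelope_ratio=0.9)


class TestADSegment:
    def test_kindle_iss_calibration(self, sim_config):
        # mean recovered (LFB, MFB, HFB) within ±0.03 of the profile targets
        entry = DEFAULT_PROFILES["Kindle"].phases["ISS"]
        rng = np.random.default_rng(1)
        fracs = []
        for _ in range(50):
            seg = generate_ad_segment(entry, 8.0, sim_config, rng=rng)
            fr = band_fractions(welch_psd(seg))
            fracs.append([fr.fraction[n] for n in ("LFB", "MFB", "HFB")])
        recovered = np.mean(fracs, axis=0)
        np.testing.assert_allclose(recovered, entry.target_fractions, atol=0.03)

    def test_pure_low_band_target(self, sim_config):
        entry = PhaseProfile((1.0, 0.0, 0.0), 8.0, 0.0, 1)
        seg = generate_ad_segment(entry, 8.0, sim_config, rng=np.random.default_rng(2),
                                  jitter_fractions=False)
        fr = band_fractions(welch_psd(seg))
        assert fr.fraction["LFB"] >= 0.99

    @pytest.mark.parametrize("seed", range(5))
    def test_envelope_floor(self, sim_config, seed):
        # every 0.5 s RMS window at least 2.5× the baseline RMS
        entry = DEFAULT_PROFILES["Kindle"].phases["LSS"]
        seg = generate_ad_segment(entry, 10.0, sim_config, rng=np.random.default_rng(seed))
        _, env = sliding_rms(seg.samples, sim_config.sampling_rate, window=0.5, overlap=0.5)
        assert env.min() >= 2.5 * sim_config.baseline_amplitude

    def test_bad_fractions_rejected(self):
        with pytest.raises(CalibrationError):
            PhaseProfile((0.5, 0.1, 0.1), 8.0, 1.0, 1)
        with pytest.raises(CalibrationError):
            PhaseProfile((0.8, 0.1, 0.1), 4.0, 1.0, 1)  # mean below 6 s floor

    def test_printed_rows_renormalized(self):
        entry = DEFAULT_PROFILES["Kindle"].phases["ISS"]
        assert sum(entry.target_fractions) == pytest.approx(1.0, abs=1e-9)


class TestSession:
    def test_default_kindle_counts(self, tiny_profile):
        counts = {"ISS": 0, "LSS": 0, "GSS": 0}
        for ev in default_schedule(DEFAULT_PROFILES["Kindle"]):
            counts[ev.phase] += 1
        assert counts == {"ISS": 61, "LSS": 42, "GSS": 35}

    def test_session_annotations_match_schedule(self, sim_config, tiny_profile):
        record, anns = simulate_session(tiny_profile, config=sim_config, seed=5)
        assert len(anns) == 10
        phases = [a.phase for a in anns]
        assert phases.count("ISS") == 4 and phases.count("LSS") == 3
        # annotations lie inside the record and do not overlap
        for a, b in zip(anns[:-1], anns[1:]):
            assert b.onset_s >= a.onset_s + a.duration_s
        assert anns[-1].onset_s + anns[-1].duration_s <= record.duration

    def test_empty_schedule_baseline_only(self, sim_config, tiny_profile):
        record, anns = simulate_session(tiny_profile, schedule=[], config=sim_config, seed=5)
        assert anns == []
        base = baseline_stats(record, window=min(7.0, record.duration))
        assert detect_ad_events(record, base) == []

    def test_bitwise_determinism(self, sim_config, tiny_profile):
        rec_a, ann_a = simulate_session(tiny_profile, config=sim_config, seed=9)
        rec_b, ann_b = simulate_session(tiny_profile, config=sim_config, seed=9)
        np.testing.assert_array_equal(rec_a.samples, rec_b.samples)
        assert [(a.onset_s, a.duration_s, a.racine_stage) for a in ann_a] == [
            (b.onset_s, b.duration_s, b.racine_stage) for b in ann_b
        ]

    def test_overlapping_explicit_onsets_rejected(self, sim_config, tiny_profile):
        schedule = [
            ScheduledEvent(animal_id="r1", racine_stage=3, onset=10.0, duration=8.0),
            ScheduledEvent(animal_id="r1", racine_stage=3, onset=12.0, duration=8.0),
        ]
        with pytest.raises(SchedulingError):
            simulate_session(tiny_profile, schedule=schedule, config=sim_config, seed=1)

    def test_durations_respect_floor(self, sim_config):
        profile = GroupProfile(
            group_label="Kindle", n_animals=1,
            phases={"ISS": PhaseProfile((0.83, 0.08, 0.09), 6.5, 2.0, 20)},
        )
        _, anns = simulate_session(profile, config=sim_config, seed=3)
        assert all(a.duration_s >= 6.5 for a in anns)


class TestTitration:
    def test_first_grid_point_at_or_above_threshold(self):
        res = simulate_threshold_titration(ResponseCurve(true_threshold=100.0), seed=0)
        assert res.threshold_intensity == 105.0
        assert not res.excluded

    def test_non_responder_excluded(self):
        res = simulate_threshold_titration(ResponseCurve(true_threshold=None), seed=0)
        assert res.excluded and res.threshold_intensity is None
        assert res.steps_taken == 22  # 30, 45, ..., 345 µA

    def test_low_threshold_first_step(self):
        res = simulate_threshold_titration(ResponseCurve(true_threshold=20.0), seed=0)
        assert res.threshold_intensity == 30.0 and res.steps_taken == 1

    @pytest.mark.parametrize("true_thr", [31.0, 77.0, 200.0, 340.0])
    def test_output_on_staircase_grid(self, true_thr):
        res = simulate_threshold_titration(ResponseCurve(true_threshold=true_thr), seed=1)
        k = (res.threshold_intensity - 30.0) / 15.0
        assert k == int(k) and 30.0 <= res.threshold_intensity <= 350.0

    def test_threshold_above_last_grid_point_excluded(self):
        # grid tops out at 345 µA, so a 349 µA threshold is a non-responder
        res = simulate_threshold_titration(ResponseCurve(true_threshold=349.0), seed=1)
        assert res.excluded

    def test_stochastic_curve_seeded(self):
        curve = ResponseCurve(prob=lambda i: min(1.0, i / 400.0))
        a = simulate_threshold_titration(curve, seed=5)
        b = simulate_threshold_titration(curve, seed=5)
        assert a == b
        assert a.excluded or a.threshold_intensity in {30.0 + 15 * k for k in range(22)}
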