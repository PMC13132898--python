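import numpy as np
import pytest

from eegfatigue.constants import CHANNELS
from eegfatigue.errors import ConfigurationError, ScheduleError
from eegfatigue.features import compute_spectral
from eegfatigue.segmentation import partition_events, segment_event
from eegfatigue.synthetic import (
    FatigueScores,
    SessionPlan,
    SubjectProfile,
    default_plans,
    generate_cohort,
    generate_recording,
    generate_scores,
    write_cohort,
)


def tiny_plan(intensity="high", **kwargs) -> SessionPlan:
    durations = {"s1": 10, "m1": 10, "s2": 10, "m2": 10, "s3": 10, "m3": 10}
    return SessionPlan(3, intensity, event_durations=durations, **kwargs)


def theta_alpha_power(samples: np.ndarray) -> float:
    _, theta, alpha, _, _ = compute_spectral(samples)
    return theta + alpha


def event_windows(recording, plan, channel, event):
    ranges = {r.event: r for r in partition_events(recording, plan.schedule)}
    rng = ranges[event]
    return segment_event(recording.channels[channel][rng.start_sample : rng.end_sample])


class TestProfiles:
    def test_missing_channel_rejected(self):
        with pytest.raises(ConfigurationError):
            SubjectProfile("s", channel_gains={"TP9": 1.0})

    def test_negative_gain_rejected(self):
        with pytest.raises(ConfigurationError):
            SubjectProfile("s", fatigue_gain_physical=-1.0)

    def test_zero_sum_band_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            SubjectProfile(
                "s", baseline_band_weights={"delta": 0, "theta": 0, "alpha": 0, "beta": 0}
            )


class TestSessionPlan:
    def test_invalid_intensity(self):
        with pytest.raises(ScheduleError):
            SessionPlan(1, "extreme")

    def test_default_durations(self):
        plan = SessionPlan(1, "low", s3_duration_s=540)
        assert plan.total_duration_s == 1260

    def test_s3_bound(self):
        with pytest.raises(ScheduleError):
            SessionPlan(1, "low", s3_duration_s=901)


class TestGenerateRecording:
    def test_deterministic(self):
        profile = SubjectProfile("s1")
        plan = tiny_plan()
        a = generate_recording(profile, plan, seed=9)
        b = generate_recording(profile, plan, seed=9)
        for ch in CHANNELS:
            np.testing.assert_array_equal(a.channels[ch], b.channels[ch])

    def test_seed_changes_samples(self):
        profile = SubjectProfile("s1")
        plan = tiny_plan()
        a = generate_recording(profile, plan, seed=9)
        b = generate_recording(profile, plan, seed=10)
        assert not np.array_equal(a.channels["TP9"], b.channels["TP9"])

    def test_standard_plan_length(self):
        profile = SubjectProfile("s1")
        plan = SessionPlan(1, "low", s3_duration_s=540)
        rec = generate_recording(profile, plan, seed=0)
        assert rec.n_samples == (180 + 120 + 180 + 120 + 540 + 120) * 256 == 322_560

    def test_null_effect_when_gains_zero(self):
        # fatigue gains 0 -> theta power in s2 windows matches s1 windows
        plan = tiny_plan()
        diffs = []
        for seed in range(30):
            profile = SubjectProfile(
                "s", fatigue_gain_physical=0.0, fatigue_gain_mental=0.0, noise_scale=0.2
            )
            rec = generate_recording(profile, plan, seed=seed)
            s1 = np.mean([theta_alpha_power(w) for w in event_windows(rec, plan, "TP9", "s1")])
            s2 = np.mean([theta_alpha_power(w) for w in event_windows(rec, plan, "TP9", "s2")])
            diffs.append(s2 - s1)
        diffs = np.asarray(diffs)
        ci_half = 1.96 * diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= ci_half * 1.5  # 95% CI (with slack) covers 0

    def test_fatigue_effect_raises_theta_alpha(self):
        plan = tiny_plan()
        shifts = []
        for seed in range(30):
            profile = SubjectProfile("s", fatigue_gain_physical=2.0, noise_scale=0.1)
            rec = generate_recording(profile, plan, seed=seed)
            s1 = np.mean([theta_alpha_power(w) for w in event_windows(rec, plan, "TP9", "s1")])
            s2 = np.mean([theta_alpha_power(w) for w in event_windows(rec, plan, "TP9", "s2")])
            shifts.append(s2 - s1)
        assert np.mean(shifts) > 0
        assert np.mean(np.asarray(shifts) > 0) >= 0.9

    def test_informative_channels_carry_larger_shift(self):
        # effect injection: informative channel shift strictly exceeds the
        # non-informative channel's, measured over >= 30 seeds
        plan = tiny_plan()
        gains = {"TP9": 1.0, "AF7": 1.0, "AF8": 0.0, "TP10": 0.0}
        info, noninfo = [], []
        for seed in range(30):
            profile = SubjectProfile(
                "s", fatigue_gain_physical=2.0, noise_scale=0.1, channel_gains=gains
            )
            rec = generate_recording(profile, plan, seed=seed)
            for channel, sink in (("TP9", info), ("AF8", noninfo)):
                s1 = np.mean(
                    [theta_alpha_power(w) for w in event_windows(rec, plan, channel, "s1")]
                )
                s2 = np.mean(
                    [theta_alpha_power(w) for w in event_windows(rec, plan, channel, "s2")]
                )
                sink.append(s2 - s1)
        assert np.mean(info) > np.mean(noninfo)

    def test_spectral_placement_tone(self):
        # a single configured oscillation at 10 Hz, zero noise -> >95% of
        # the 0.4-30 Hz power lands in the alpha band
        profile = SubjectProfile(
            "s",
            baseline_band_weights={"delta": 0, "theta": 0, "alpha": 1.0, "beta": 0},
            noise_scale=0.0,
            fatigue_gain_physical=0.0,
            fatigue_gain_mental=0.0,
        )
        plan = tiny_plan()
        rec = generate_recording(profile, plan, seed=1, oscillation_mode="tone")
        for window in event_windows(rec, plan, "AF7", "s1"):
            delta, theta, alpha, beta, _ = compute_spectral(window)
            assert alpha > 0.95 * (delta + theta + alpha + beta)

    def test_smoothing_reduces_complexity(self):
        from eegfatigue.features import compute_regularity_entropies

        plan = tiny_plan()
        ses, se0 = [], []
        for seed in range(10):
            profile = SubjectProfile("s", fatigue_gain_physical=2.5, noise_scale=0.3)
            rec = generate_recording(profile, plan, seed=seed)
            se0.append(
                np.mean([
                    compute_regularity_entropies(w)[0]
                    for w in event_windows(rec, plan, "TP9", "s1")
                ])
            )
            ses.append(
                np.mean([
                    compute_regularity_entropies(w)[0]
                    for w in event_windows(rec, plan, "TP9", "s2")
                ])
            )
        assert np.mean(ses) < np.mean(se0)


class TestGenerateScores:
    def test_zero_noise_zero_gain_equals_baseline(self):
        profile = SubjectProfile(
            "s", fatigue_gain_physical=0.0, fatigue_gain_mental=0.0,
            noise_scale=0.0, baseline_score=25.0,
        )
        scores = generate_scores(profile, tiny_plan(), seed=3)
        assert scores.physical_score == 25.0
        assert scores.mental_score == 25.0
        assert scores.baseline_score == 25.0

    def test_intensity_ordering_over_seeds(self):
        high, low = [], []
        for seed in range(100):
            profile = SubjectProfile("s", fatigue_gain_physical=1.0, noise_scale=0.3)
            high.append(generate_scores(profile, tiny_plan("high"), seed).physical_score)
            low.append(generate_scores(profile, tiny_plan("low"), seed).physical_score)
        assert np.mean(high) > np.mean(low)

    def test_deterministic(self):
        profile = SubjectProfile("s")
        a = generate_scores(profile, tiny_plan(), seed=5)
        b = generate_scores(profile, tiny_plan(), seed=5)
        assert (a.baseline_score, a.physical_score, a.mental_score) == (
            b.baseline_score, b.physical_score, b.mental_score,
        )

    def test_scores_nonnegative(self):
        profile = SubjectProfile("s", noise_scale=5.0, baseline_score=0.0)
        for seed in range(20):
            s = generate_scores(profile, tiny_plan(), seed)
            assert min(s.baseline_score, s.physical_score, s.mental_score) >= 0

    def test_rows(self):
        rows = FatigueScores("s", 2, 1.0, 2.0, 3.0).to_rows()
        assert [r["event"] for r in rows] == ["s1", "s2", "s3"]


class TestGenerateCohort:
    def test_counts(self, small_cohort):
        assert len(small_cohort.recordings) == 5 * 3
        streams = sum(len(r.channels) for r in small_cohort.recordings.values())
        assert streams == 5 * 3 * 4

    def test_twelve_subject_counts(self, desk_durations):
        cohort = generate_cohort(
            n_subjects=12, plans=default_plans(event_durations=desk_durations),
            master_seed=0, noise_scale=0.0,
        )
        assert len(cohort.recordings) == 36
        assert sum(len(r.channels) for r in cohort.recordings.values()) == 144
        assert len(cohort.scores) == 36 * 3

    def test_single_subject_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(n_subjects=1)

    def test_reproducible(self, desk_durations):
        kwargs = dict(
            n_subjects=3, plans=default_plans(event_durations=desk_durations),
            master_seed=77,
        )
        a = generate_cohort(**kwargs)
        b = generate_cohort(**kwargs)
        assert a.manifest == b.manifest
        assert a.scores.equals(b.scores)
        for key in a.recordings:
            np.testing.assert_array_equal(
                a.recordings[key].channels["AF7"], b.recordings[key].channels["AF7"]
            )

    def test_write_cohort(self, tmp_path, desk_durations):
        cohort = generate_cohort(
            n_subjects=2, plans=default_plans(event_durations=desk_durations),
            master_seed=5,
        )
        out = write_cohort(cohort, tmp_path / "cohort")
        assert (out / "manifest.json").exists()
        assert (out / "scores.csv").exists()
        assert (out / "sub01_session1.csv").exists()

    def test_complementary_split(self):
        from eegfatigue.synthetic import make_profile

        profile = make_profile(
            0, 0, informative_channels=("TP9", "AF7"), uninformative_gain=0.0,
            complementary=True,
        )
        assert profile.channel_gains["TP9"] == 1.0
        assert profile.channel_gains["AF7"] == 0.0
        assert profile.channel_gains_mental["AF7"] == 1.0
        assert profile.channel_gains_mental["TP9"] == 0.0
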