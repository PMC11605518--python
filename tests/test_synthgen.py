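"""Kinematic profiles, EMG synthesis, day drift, and study generation."""

import numpy as np
import pytest
from scipy import stats

from emgagg.data import N_DOF
from emgagg.preprocess import mav_features
from emgagg.synthgen import (
    GAUSS_RECTIFIED_MEAN,
    DriftModel,
    MovementProtocol,
    MovementSpec,
    SubjectModel,
    apply_day_drift,
    default_protocol,
    default_subject,
    generate_study,
    make_kinematic_trace,
    performed_kinematics,
    synthesize_emg,
    synthesize_features,
)


class TestKinematicTrace:
    def test_default_trial_lasts_seven_seconds(self):
        protocol = default_protocol(n_movements=1, trials_per_movement=1)
        _, ann = make_kinematic_trace(protocol, frame_rate=30.0)
        assert ann[0].n_frames == 210  # 7 s at 30 Hz

    def test_mid_hold_reaches_signed_amplitude(self):
        protocol = MovementProtocol(
            movements=[MovementSpec(0, (3,), direction=1, target_amplitude=1.0)],
            trials_per_movement=1,
        )
        kin, ann = make_kinematic_trace(protocol)
        mid_hold = ann[0].frame_start + 90 + 15  # rise 3 s + half of hold
        assert kin.values[3, mid_hold] == 1.0
        others = np.delete(kin.values[:, mid_hold], 3)
        assert np.all(others == 0.0)

    def test_time_dilation_maps_frames_exactly(self):
        base = default_protocol(n_movements=1, trials_per_movement=1)
        dilated = default_protocol(
            n_movements=1, trials_per_movement=1,
            rise_s=6.0, hold_s=2.0, return_s=6.0, inter_trial_s=4.0,
        )
        kin1, ann1 = make_kinematic_trace(base)
        kin2, ann2 = make_kinematic_trace(dilated)
        s1, s2 = ann1[0].frame_start, ann2[0].frame_start
        for k in range(ann1[0].n_frames):
            assert kin2.values[:, s2 + 2 * k + 1] == pytest.approx(kin1.values[:, s1 + k])

    def test_zero_outside_annotated_spans_and_inactive_dofs(self):
        protocol = default_protocol(n_movements=3, trials_per_movement=2)
        kin, ann = make_kinematic_trace(protocol)
        mask = np.zeros(kin.n_frames, dtype=bool)
        for a in ann:
            mask[a.frame_start : a.frame_end] = True
            inactive = [d for d in range(N_DOF) if d not in a.active_dofs]
            assert np.all(kin.values[inactive, a.frame_start : a.frame_end] == 0.0)
        assert np.all(kin.values[:, ~mask] == 0.0)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            MovementProtocol(movements=[])
        with pytest.raises(ValueError):
            MovementSpec(0, (0,), target_amplitude=1.5)


class TestSynthesizeEmg:
    def test_rest_mav_matches_rectified_gaussian_mean(self):
        """At rest the per-contact MAV equals baseline * E|N(0,1)| closed-form."""
        subject = default_subject(n_contacts=3, seed=0)
        subject.noise_sd[:] = 0.0
        kin_rest = make_kinematic_trace(
            MovementProtocol(
                movements=[MovementSpec(0, (0,), target_amplitude=0.01)],
                trials_per_movement=1, inter_trial_s=30.0,
            )
        )[0]
        kin_rest.values[:] = 0.0
        emg = synthesize_emg(kin_rest, subject, seed=4)
        mav = np.mean(np.abs(emg.data), axis=1)
        expected = subject.rest_baseline * GAUSS_RECTIFIED_MEAN
        assert np.allclose(mav, expected, rtol=0.10)

    def test_mixing_row_doubling_doubles_rest_subtracted_mav(self):
        protocol = default_protocol(n_movements=1, trials_per_movement=2)
        kin, ann = make_kinematic_trace(protocol)
        subject = default_subject(n_contacts=3, seed=2)
        subject.noise_sd[:] = 0.0
        emg1 = synthesize_emg(kin, subject, seed=9)
        doubled = subject.copy()
        doubled.mixing[1] *= 2.0
        emg2 = synthesize_emg(kin, doubled, seed=9)
        span = slice(ann[0].frame_start * 33, ann[0].frame_end * 33)
        rest = subject.rest_baseline[1] * GAUSS_RECTIFIED_MEAN
        m1 = np.mean(np.abs(emg1.data[1, span])) - rest
        m2 = np.mean(np.abs(emg2.data[1, span])) - rest
        assert m2 == pytest.approx(2.0 * m1, rel=0.05)

    def test_zero_everything_gives_zero_recording(self, small_protocol):
        kin, _ = make_kinematic_trace(small_protocol)
        kin.values[:] = 0.0
        subject = default_subject(n_contacts=2, seed=1)
        subject.noise_sd[:] = 0.0
        subject.rest_baseline[:] = 0.0
        emg = synthesize_emg(kin, subject, seed=3)
        assert np.all(emg.data == 0.0)

    def test_shortcut_features_track_full_chain_envelope(self, small_protocol):
        """Feature-level generator agrees with filter+MAV on the full chain."""
        subject = default_subject(n_contacts=3, seed=6)
        kin, _ = make_kinematic_trace(small_protocol)
        emg = synthesize_emg(kin, subject, seed=8)
        full = mav_features(emg)
        short = synthesize_features(kin, subject, seed=8, include_pairs=False, jitter_sd=0.0)
        n = min(full.n_frames, short.n_frames)
        # Compare session means per contact (window transients differ frame-wise).
        assert np.allclose(
            full.values[:, 30:n].mean(axis=1), short.values[:, 30:n].mean(axis=1), rtol=0.10
        )


class TestDayDrift:
    def test_day_zero_is_identity(self, subject):
        out = apply_day_drift(subject, DriftModel(seed=1), 0)
        assert np.array_equal(out.mixing, subject.mixing)
        assert np.array_equal(out.rest_baseline, subject.rest_baseline)

    def test_zero_rates_change_nothing(self, subject, zero_drift):
        out = apply_day_drift(subject, zero_drift, 40)
        assert np.allclose(out.mixing, subject.mixing)
        assert np.allclose(out.rest_baseline, subject.rest_baseline)

    def test_deterministic_given_seed_and_day(self, subject):
        drift = DriftModel(seed=9)
        a = apply_day_drift(subject, drift, 17)
        b = apply_day_drift(subject, drift, 17)
        assert np.array_equal(a.mixing, b.mixing)
        assert np.array_equal(a.rest_baseline, b.rest_baseline)

    def test_negative_day_rejected(self, subject):
        with pytest.raises(ValueError):
            apply_day_drift(subject, DriftModel(), -1)

    def test_centroid_distance_grows_with_days(self):
        """Mean feature-centroid displacement from day 0 is increasing in
        expectation (checked across 20 drift seeds)."""
        protocol = default_protocol(n_movements=1, trials_per_movement=2)
        kin, ann = make_kinematic_trace(protocol)
        span = np.concatenate([np.arange(a.frame_start, a.frame_end) for a in ann])
        dists = {d: [] for d in (5, 30, 90)}
        for seed in range(20):
            subject = default_subject(n_contacts=4, seed=seed)
            drift = DriftModel(seed=seed, session_scale=0.0)
            base = synthesize_features(kin, subject, seed=seed, jitter_sd=0.0)
            c0 = base.values[:, span].mean(axis=1)
            for d in dists:
                drifted = apply_day_drift(subject, drift, d)
                feats = synthesize_features(kin, drifted, seed=seed, jitter_sd=0.0)
                dists[d].append(np.linalg.norm(feats.values[:, span].mean(axis=1) - c0))
        means = [np.mean(dists[d]) for d in (5, 30, 90)]
        assert means[0] < means[1] < means[2]


class TestGenerateStudy:
    def test_one_session_per_day_with_matching_index(self, subject, small_protocol):
        days = list(range(0, 30, 3)) + [33, 40, 47, 54, 61, 68]
        sessions = generate_study(subject, small_protocol, DriftModel(seed=2), days, mode="features")
        assert len(sessions) == 16
        assert [s.day_index for s in sessions] == days

    def test_empty_day_list_gives_empty_study(self, subject, small_protocol):
        assert generate_study(subject, small_protocol, DriftModel(), [], mode="features") == []

    def test_unsorted_days_rejected(self, subject, small_protocol):
        with pytest.raises(ValueError):
            generate_study(subject, small_protocol, DriftModel(), [3, 1], mode="features")

    def test_zero_drift_sessions_statistically_indistinguishable(self, zero_drift):
        """With all drift rates zero, day 0 and day 100 sessions have the
        same per-trial MAV distribution (two-sample test, alpha=0.01)."""
        subject = default_subject(n_contacts=4, seed=8)
        protocol = default_protocol(n_movements=1, trials_per_movement=12)
        sessions = generate_study(subject, protocol, zero_drift, [0, 100], mode="features")
        means = []
        for ses in sessions:
            per_trial = [
                ses.features.values[:4, a.frame_start : a.frame_end].mean()
                for a in ses.annotations
            ]
            means.append(per_trial)
        _, p = stats.ttest_ind(means[0], means[1])
        assert p > 0.01

    def test_emg_mode_sample_count_matches_frames(self, subject):
        protocol = default_protocol(n_movements=1, trials_per_movement=1)
        ses = generate_study(subject, protocol, DriftModel(seed=1), [0], mode="emg")[0]
        expected = ses.kinematics.n_frames * 1000 / 30.0
        assert abs(ses.emg.n_samples - expected) <= 34  # within one frame


class TestPerformedKinematics:
    def test_effort_scales_whole_trial_and_preserves_rest(self, rng):
        # Sub-maximal amplitude so the [-1, 1] clip never binds.
        kin, ann = make_kinematic_trace(
            default_protocol(n_movements=2, trials_per_movement=3, amplitude=0.7)
        )
        performed = performed_kinematics(kin, ann, rng, effort_sd=0.2, lag_jitter_sd=0.0)
        for a in ann:
            seg_t = kin.values[a.active_dofs[0], a.frame_start : a.frame_end]
            seg_p = performed.values[a.active_dofs[0], a.frame_start : a.frame_end]
            ratio = seg_p[np.abs(seg_t) > 0.5] / seg_t[np.abs(seg_t) > 0.5]
            assert np.allclose(ratio, ratio[0], atol=1e-9)
            assert 0.6 <= abs(ratio[0]) <= 1.4

    def test_zero_noise_reproduces_target(self, small_protocol, rng):
        kin, ann = make_kinematic_trace(small_protocol)
        performed = performed_kinematics(kin, ann, rng, effort_sd=0.0, lag_jitter_sd=0.0)
        assert np.allclose(performed.values, kin.values)
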