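"""Aggregation bookkeeping, offline experiment wiring, PCA, TTT replay."""

import numpy as np
import pytest

from emgagg.cnn import TrainConfig
from emgagg.data import FeatureMatrix, KinematicTrace, N_DOF, Session
from emgagg.experiment import (
    ExperimentConfig,
    build_aggregated_training,
    pca_feature_space,
    prepare_session,
    run_offline_experiment,
    run_ttt_replay,
    ttt_protocol,
)
from emgagg.synthgen import DriftModel, default_protocol, default_subject, generate_study


@pytest.fixture(scope="module")
def tiny_study():
    """Three feature-level sessions, two movements x three trials."""
    subject = default_subject(n_contacts=4, seed=21)
    protocol = default_protocol(n_movements=2, trials_per_movement=3)
    return generate_study(subject, protocol, DriftModel(seed=4), [0, 2, 4, 9], mode="features")


class TestAggregation:
    def test_trial_counts_sum_across_sessions(self, tiny_study):
        prepared = [prepare_session(s) for s in tiny_study]
        agg = build_aggregated_training(prepared, 3)
        assert len(agg.annotations) == 3 * len(prepared[0].annotations)

    def test_k1_is_identical_to_last_session(self, tiny_study):
        prepared = [prepare_session(s) for s in tiny_study]
        agg = build_aggregated_training(prepared, 1)
        assert np.array_equal(agg.features.values, prepared[-1].features.values)
        assert agg.day_indices == [prepared[-1].day_index]

    def test_frame_count_is_additive(self, tiny_study):
        prepared = [prepare_session(s) for s in tiny_study]
        agg = build_aggregated_training(prepared, 3)
        assert agg.n_frames == sum(p.features.n_frames for p in prepared[-3:])

    def test_annotation_offsets_index_original_frames(self, tiny_study):
        prepared = [prepare_session(s) for s in tiny_study]
        agg = build_aggregated_training(prepared, 2)
        a_last = agg.annotations[-1]
        src = prepared[-1].annotations[-1]
        offset = prepared[-2].features.n_frames
        assert a_last.frame_start == src.frame_start + offset
        assert np.array_equal(
            agg.features.values[:, a_last.frame_start : a_last.frame_end],
            prepared[-1].features.values[:, src.frame_start : src.frame_end],
        )

    def test_invalid_k_rejected(self, tiny_study):
        prepared = [prepare_session(s) for s in tiny_study]
        with pytest.raises(ValueError):
            build_aggregated_training(prepared, 0)
        with pytest.raises(ValueError):
            build_aggregated_training(prepared, 99)


class TestOfflineExperiment:
    def test_six_conditions_from_two_decoders_three_sizes(self):
        config = ExperimentConfig(
            train_day_indices=list(range(10)), test_day_indices=[12],
            aggregation_sizes=(1, 5, 10), decoders=("mkf", "cnn"),
        )
        n_conditions = len(config.aggregation_sizes) * len(config.decoders)
        assert n_conditions == 6

    def test_oracle_stub_scores_zero_rmse(self, tiny_study):
        config = ExperimentConfig(
            train_day_indices=[0, 2, 4], test_day_indices=[9],
            aggregation_sizes=(1, 3), decoders=("oracle",),
        )
        df = run_offline_experiment(config, tiny_study)
        assert np.allclose(df["intended_rmse"], 0.0)
        assert np.allclose(df["unintended_rmse"], 0.0)

    def test_row_count_is_conditions_x_sessions_x_trials(self, tiny_study):
        config = ExperimentConfig(
            train_day_indices=[0, 2], test_day_indices=[4, 9],
            aggregation_sizes=(1, 2), decoders=("oracle",),
        )
        df = run_offline_experiment(config, tiny_study)
        n_trials = len(tiny_study[0].annotations)
        assert len(df) == 2 * 2 * n_trials

    def test_training_days_must_precede_test_days(self):
        with pytest.raises(ValueError):
            ExperimentConfig(train_day_indices=[0, 8], test_day_indices=[5],
                             aggregation_sizes=(1,))

    def test_missing_day_reported(self, tiny_study):
        config = ExperimentConfig(
            train_day_indices=[0, 2], test_day_indices=[7], aggregation_sizes=(1,),
            decoders=("oracle",),
        )
        with pytest.raises(ValueError, match="day indices"):
            run_offline_experiment(config, tiny_study)

    def test_offline_experiment_is_deterministic(self, tiny_study):
        config = ExperimentConfig(
            train_day_indices=[0, 2, 4], test_day_indices=[9],
            aggregation_sizes=(1, 3), decoders=("mkf",), k_channels=6, seeds=(5,),
        )
        df1 = run_offline_experiment(config, tiny_study)
        df2 = run_offline_experiment(config, tiny_study)
        assert df1.equals(df2)

    def test_mkf_decodes_drift_free_study_accurately(self):
        """End-to-end sanity floor: on drift-free data the Kalman decoder's
        intended-movement error stays below 0.35."""
        subject = default_subject(n_contacts=6, seed=3)
        protocol = default_protocol(n_movements=4, trials_per_movement=4)
        drift = DriftModel(0.0, 0.0, 0.0, seed=1)
        study = generate_study(
            subject, protocol, drift, [0, 1, 2], mode="features",
            effort_sd=0.0, lag_jitter_sd=0.0,
        )
        config = ExperimentConfig(
            train_day_indices=[0, 1], test_day_indices=[2],
            aggregation_sizes=(2,), decoders=("mkf",), k_channels=15,
        )
        df = run_offline_experiment(config, study)
        assert df["intended_rmse"].median() < 0.35


class TestPcaFeatureSpace:
    def test_planar_data_fully_explained_by_two_components(self, rng):
        basis = rng.standard_normal((2, 8))
        scores = rng.standard_normal((300, 2))
        values = (scores @ basis).T
        kin = KinematicTrace(np.zeros((N_DOF, 150)))
        sessions = [
            Session(kinematics=kin, features=FeatureMatrix(values[:, i * 150 : (i + 1) * 150]),
                    day_index=i)
            for i in range(2)
        ]
        proj = pca_feature_space(sessions)
        assert sum(proj.explained_variance) == pytest.approx(1.0, abs=1e-9)

    def test_matches_covariance_eigendecomposition(self, rng):
        values = rng.standard_normal((5, 100))
        kin = KinematicTrace(np.zeros((N_DOF, 50)))
        sessions = [
            Session(kinematics=kin, features=FeatureMatrix(values[:, i * 50 : (i + 1) * 50]),
                    day_index=i)
            for i in range(2)
        ]
        proj = pca_feature_space(sessions)
        pooled = values.T - values.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(pooled.T))
        order = np.argsort(evals)[::-1]
        for j in range(2):
            v = evecs[:, order[j]]
            dot = abs(float(v @ proj.components[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn_pca(self, rng):
        from sklearn.decomposition import PCA

        values = rng.standard_normal((6, 120))
        kin = KinematicTrace(np.zeros((N_DOF, 60)))
        sessions = [
            Session(kinematics=kin, features=FeatureMatrix(values[:, i * 60 : (i + 1) * 60]),
                    day_index=i)
            for i in range(2)
        ]
        proj = pca_feature_space(sessions)
        sk = PCA(n_components=2).fit(values.T)
        for j in range(2):
            dot = abs(float(sk.components_[j] @ proj.components[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)
        assert proj.explained_variance == pytest.approx(
            tuple(sk.explained_variance_ratio_), abs=1e-8
        )

    def test_duplicating_frames_leaves_components_unchanged(self, tiny_study):
        proj1 = pca_feature_space(tiny_study)
        doubled = []
        for s in tiny_study:
            feats = FeatureMatrix(np.concatenate([s.features.values] * 2, axis=1))
            kin = KinematicTrace(np.concatenate([s.kinematics.values] * 2, axis=1))
            doubled.append(Session(kinematics=kin, features=feats, day_index=s.day_index))
        proj2 = pca_feature_space(doubled)
        for j in range(2):
            assert abs(float(proj1.components[:, j] @ proj2.components[:, j])) == pytest.approx(
                1.0, abs=1e-8
            )

    def test_single_session_rejected(self, tiny_study):
        with pytest.raises(ValueError):
            pca_feature_space(tiny_study[:1])

    def test_scores_keyed_by_day_and_movement(self, tiny_study):
        proj = pca_feature_space(tiny_study)
        days = {d for d, _ in proj.scores_by_movement}
        assert days == {s.day_index for s in tiny_study}


class TestTttReplay:
    def test_enumerates_120_trials_of_150_frames(self):
        protocol = ttt_protocol()
        from emgagg.synthgen import make_kinematic_trace

        _, ann = make_kinematic_trace(protocol)
        assert len(ann) == 120
        assert all(a.n_frames == 150 for a in ann)  # 5 s at 30 Hz
        assert len({a.movement_id for a in ann}) == 12
        amps = [a.target_amplitude for a in ann]
        assert amps.count(0.5) == 60 and amps.count(1.0) == 60

    def test_oracle_decoder_always_in_target(self):
        subject = default_subject(n_contacts=4, seed=2)
        df = run_ttt_replay("oracle", subject, seeds=(0,),
                            protocol=ttt_protocol(n_dofs=2, trials_per_target=1))
        assert np.allclose(df["pct_time_in_target"], 100.0)
        assert np.allclose(df["intended_rmse"], 0.0)

    def test_trained_decoder_runs_end_to_end(self):
        subject = default_subject(n_contacts=4, seed=2)

        def half_oracle(feats):
            from emgagg.data import DecodedTrace

            return DecodedTrace(np.zeros((N_DOF, feats.n_frames)))

        df = run_ttt_replay(half_oracle, subject, seeds=(0,),
                            protocol=ttt_protocol(n_dofs=2, trials_per_target=1))
        assert (df["pct_time_in_target"] < 100.0).all()
        assert {"max_hold_s", "log_mean_abs_jerk"} <= set(df.columns)
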