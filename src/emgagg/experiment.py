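"""Study designs: dataset aggregation, robustness over days, PCA drift, TTT replay.

The central question exercised here: when a regression decoder is
recalibrated, should the new calibration data *replace* the old (the
traditional paradigm) or be *aggregated* with the previous K sessions?
``run_offline_experiment`` trains each decoder on aggregates of the last
1/5/10 training sessions and evaluates intended/unintended RMSE on held-out
later-day sessions; ``run_aggregation_study`` repeats that over many
synthetic subjects and summarizes accuracy, improvement percentages and
RMSE-per-day robustness slopes.  ``pca_feature_space`` visualizes the
between-day feature-space drift that motivates the whole exercise, and
``run_ttt_replay`` replays the virtual target-touching task offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .cnn import CnnSpec, TrainConfig, build_cnn, predict_cnn, train_cnn
from .data import (
    N_DOF,
    DecodedTrace,
    FeatureMatrix,
    KinematicTrace,
    Session,
    TrainingSet,
    TrialAnnotation,
    clamp_unit,
)
from .metrics import intended_unintended_rmse, log_mean_abs_jerk, robustness_slopes, ttt_occupancy, windowed_rmse
from .mkf import fit_kalman, predict_kalman
from .preprocess import (
    align_lag,
    baseline_subtract,
    extract_features,
    rest_baseline_vector,
    rest_frame_indices,
    shift_annotations,
)
from .selection import gram_schmidt_select
from .synthgen import (
    DriftModel,
    MovementProtocol,
    MovementSpec,
    SubjectModel,
    default_protocol,
    default_subject,
    generate_study,
    make_kinematic_trace,
    synthesize_features,
)


@dataclass
class ExperimentConfig:
    """One offline aggregation experiment."""

    train_day_indices: list[int]
    test_day_indices: list[int]
    aggregation_sizes: tuple[int, ...] = (1, 5, 10)
    decoders: tuple[str, ...] = ("mkf", "cnn")
    seeds: tuple[int, ...] = (0,)
    k_channels: int = 48
    mkf_threshold: float = 0.2
    #: Frame stride used only inside Gram-Schmidt channel selection.
    selection_stride: int = 1
    cnn_train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if max(self.aggregation_sizes) > len(self.train_day_indices):
            raise ValueError("largest aggregation size exceeds the number of training sessions")
        if self.train_day_indices and self.test_day_indices:
            if max(self.train_day_indices) >= min(self.test_day_indices):
                raise ValueError("training days must precede testing days")


@dataclass
class PreparedSession:
    """Session after feature extraction and reaction-lag alignment."""

    features: FeatureMatrix
    kinematics: KinematicTrace
    annotations: list[TrialAnnotation]
    day_index: int
    lag_frames: int
    rest_frames: np.ndarray
    baseline: np.ndarray


def prepare_session(session: Session) -> PreparedSession:
    """Extract features if needed, align the reaction lag, locate rest frames."""
    feats = session.features if session.features is not None else extract_features(session.emg)
    lag, kin = align_lag(feats, session.kinematics)
    annotations = shift_annotations(session.annotations, lag, kin.n_frames)
    rest = rest_frame_indices(annotations, kin.n_frames)
    if rest.size == 0:  # degenerate protocol with no rest; fall back to all frames
        rest = np.arange(kin.n_frames)
    baseline = rest_baseline_vector(feats, rest)
    return PreparedSession(
        features=feats,
        kinematics=kin,
        annotations=annotations,
        day_index=session.day_index,
        lag_frames=lag,
        rest_frames=rest,
        baseline=baseline,
    )


def build_aggregated_training(
    sessions: list[PreparedSession],
    K: int,
    baseline_subtracted: bool = False,
) -> TrainingSet:
    """Concatenate the K sessions immediately preceding the train/test boundary.

    Per-session lag alignment is preserved; trial annotations are offset
    into the concatenated frame axis.  With ``baseline_subtracted`` each
    session's own rest baseline is removed first (the Kalman path).
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if K > len(sessions):
        raise ValueError("K exceeds the number of available sessions")
    chosen = sessions[-K:]
    blocks, kin_blocks, annotations, days = [], [], [], []
    offset = 0
    for ses in chosen:
        feats = baseline_subtract(ses.features, ses.rest_frames) if baseline_subtracted else ses.features
        blocks.append(feats.values)
        kin_blocks.append(ses.kinematics.values)
        for a in ses.annotations:
            annotations.append(
                dc_replace(a, frame_start=a.frame_start + offset, frame_end=a.frame_end + offset)
            )
        days.append(ses.day_index)
        offset += ses.features.n_frames
    features = FeatureMatrix(
        values=np.concatenate(blocks, axis=1),
        frame_rate=chosen[0].features.frame_rate,
        channel_labels=chosen[0].features.channel_labels,
    )
    kin = KinematicTrace(values=np.concatenate(kin_blocks, axis=1))
    return TrainingSet(features=features, kinematics=kin, annotations=annotations, day_indices=days)


# ---------------------------------------------------------------------------
# Decoder adapters: train on an aggregate, return a per-session predictor.
# ---------------------------------------------------------------------------

def _train_mkf_decoder(train_sessions, K, config: ExperimentConfig, seed: int):
    agg = build_aggregated_training(train_sessions, K, baseline_subtracted=True)
    k = min(config.k_channels, agg.features.n_features)
    stride = max(1, config.selection_stride)
    sel_feats = FeatureMatrix(
        values=agg.features.values[:, ::stride], frame_rate=agg.features.frame_rate
    )
    sel_kin = KinematicTrace(values=agg.kinematics.values[:, ::stride])
    sel = gram_schmidt_select(sel_feats, sel_kin, k=k)
    idx = np.array(sel.selected_indices, dtype=int)
    model = fit_kalman(
        agg.features.values[idx],
        agg.kinematics,
        threshold=config.mkf_threshold,
        channel_indices=sel,
    )

    def predict(ses: PreparedSession) -> DecodedTrace:
        feats = baseline_subtract(ses.features, ses.rest_frames)
        return predict_kalman(model, feats.values[idx])

    return predict


def _train_cnn_decoder(train_sessions, K, config: ExperimentConfig, seed: int):
    agg = build_aggregated_training(train_sessions, K, baseline_subtracted=False)
    spec = CnnSpec(n_features=agg.features.n_features)
    train_cfg = dc_replace(config.cnn_train, seed=seed)
    model = train_cnn(build_cnn(spec, seed=seed), agg, train_cfg)

    def predict(ses: PreparedSession) -> DecodedTrace:
        return predict_cnn(model, ses.features)

    return predict


def _train_oracle_decoder(train_sessions, K, config: ExperimentConfig, seed: int):
    """Perfect decoder stub: returns the session's aligned target kinematics."""

    def predict(ses: PreparedSession) -> DecodedTrace:
        return DecodedTrace(values=clamp_unit(ses.kinematics.values.copy()))

    return predict


DECODER_FACTORIES = {
    "mkf": _train_mkf_decoder,
    "cnn": _train_cnn_decoder,
    "oracle": _train_oracle_decoder,
}


def _iter_decoded(config: ExperimentConfig, study: list[Session]):
    """Yield (condition, test session, decoded trace) for every condition."""
    by_day = {s.day_index: s for s in study}
    missing = [d for d in list(config.train_day_indices) + list(config.test_day_indices) if d not in by_day]
    if missing:
        raise ValueError(f"study does not cover day indices {missing}")
    train_prepared = [prepare_session(by_day[d]) for d in config.train_day_indices]
    test_prepared = [prepare_session(by_day[d]) for d in config.test_day_indices]
    last_train_day = train_prepared[-1].day_index

    for seed in config.seeds:
        for decoder in config.decoders:
            factory = DECODER_FACTORIES[decoder]
            for K in config.aggregation_sizes:
                try:
                    predict = factory(train_prepared, K, config, seed)
                except Exception as err:  # surface the failing condition
                    raise RuntimeError(
                        f"training failed for decoder={decoder} K={K} seed={seed}: {err}"
                    ) from err
                for ses in test_prepared:
                    cond = {
                        "seed": seed,
                        "decoder": decoder,
                        "n_aggregated": K,
                        "test_day": ses.day_index,
                        "days_since_training": ses.day_index - last_train_day,
                    }
                    yield cond, ses, predict(ses)


def _trial_rows(cond: dict, ses: PreparedSession, decoded: DecodedTrace) -> list[dict]:
    rows = []
    for trial, a in enumerate(ses.annotations):
        intended, unintended = intended_unintended_rmse(decoded, ses.kinematics, a)
        rows.append(
            {
                **cond,
                "trial": trial,
                "movement_id": a.movement_id,
                "active_dof": a.active_dofs[0],
                "intended_rmse": intended,
                "unintended_rmse": unintended,
            }
        )
    return rows


def session_dof_rmse(decoded: DecodedTrace, target: KinematicTrace, dofs: list[int]) -> dict[int, float]:
    """Whole-session RMSE per DOF (intended and cross-talk frames pooled)."""
    err = decoded.values - target.values
    return {d: float(np.sqrt(np.mean(np.square(err[d])))) for d in dofs}


def run_offline_experiment(config: ExperimentConfig, study: list[Session]) -> pd.DataFrame:
    """Train every (decoder x aggregation size x seed) condition and score it.

    Returns one row per decoded test trial with intended/unintended RMSE
    and days since the most recent aggregated training session.
    """
    rows = []
    for cond, ses, decoded in _iter_decoded(config, study):
        rows.extend(_trial_rows(cond, ses, decoded))
    return pd.DataFrame(rows)


@dataclass
class PcaProjection:
    """First two principal components of the pooled feature space."""

    components: np.ndarray
    explained_variance: tuple[float, float]
    scores_by_movement: dict

    def __post_init__(self) -> None:
        g = self.components.T @ self.components
        if not np.allclose(g, np.eye(2), atol=1e-8):
            raise ValueError("components must be orthonormal")
        if self.explained_variance[0] + 1e-12 < self.explained_variance[1]:
            raise ValueError("explained variances must be nonincreasing")


def pca_feature_space(sessions: list[Session]) -> PcaProjection:
    """SVD-based PCA over the frames of all sessions pooled together.

    One set of components is fitted per pooled matrix; the 2-D scores are
    returned keyed by ``(day_index, movement_id)`` so between-day drift
    of each movement's cluster can be plotted.
    """
    if len(sessions) < 2:
        raise ValueError("need at least two sessions")
    feats = [s.features if s.features is not None else extract_features(s.emg) for s in sessions]
    pooled = np.concatenate([f.values for f in feats], axis=1).T  # frames x features
    centered = pooled - pooled.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if np.sum(s > 1e-12 * s[0]) < 2:
        raise ValueError("pooled feature matrix has rank < 2")
    var = s**2
    explained = (float(var[0] / var.sum()), float(var[1] / var.sum()))
    components = vt[:2].T

    scores_by_movement: dict = {}
    offset = 0
    for ses, f in zip(sessions, feats):
        scores = centered[offset : offset + f.n_frames] @ components
        for a in ses.annotations:
            key = (ses.day_index, a.movement_id)
            scores_by_movement.setdefault(key, []).append(scores[a.frame_start : a.frame_end])
        offset += f.n_frames
    scores_by_movement = {k: np.concatenate(v, axis=0) for k, v in scores_by_movement.items()}
    return PcaProjection(
        components=components, explained_variance=explained, scores_by_movement=scores_by_movement
    )


def ttt_protocol(n_dofs: int = 6, trials_per_target: int = 5) -> MovementProtocol:
    """Target-touching protocol: 12 movements x (5 + 5) trials, 5 s each.

    Movements are both directions of ``n_dofs`` DOFs; each is tested five
    times at 50% and five times at 100% of full range.  Trials are 5 s
    (1 s approach + 4 s hold) separated by 2 s of rest.
    """
    movements = []
    for dof in range(n_dofs):
        for direction in (1, -1):
            movement_id = dof * 2 + (0 if direction == 1 else 1)
            for amplitude in (0.5, 1.0):
                movements.append(
                    MovementSpec(
                        movement_id=movement_id,
                        active_dofs=(dof,),
                        direction=direction,
                        target_amplitude=amplitude,
                    )
                )
    return MovementProtocol(
        movements=movements,
        trials_per_movement=trials_per_target,
        rise_s=1.0,
        hold_s=4.0,
        return_s=0.0,
        inter_trial_s=2.0,
    )


def run_ttt_replay(
    predictor,
    subject: SubjectModel,
    seeds: tuple[int, ...] = (0,),
    protocol: MovementProtocol | None = None,
    window: float = 0.15,
) -> pd.DataFrame:
    """Replay the target-touching task offline on synthetic sessions.

    ``predictor`` maps a FeatureMatrix to a DecodedTrace (a trained
    decoder's predict function), or the string ``"oracle"`` for a perfect
    decoder that reproduces the aligned target.  Per trial the windowed
    intended/unintended RMSE, percent time in target, longest hold and log
    mean absolute jerk are reported.
    """
    protocol = protocol or ttt_protocol()
    rows = []
    for seed in seeds:
        kin, annotations = make_kinematic_trace(protocol)
        feats = synthesize_features(kin, subject, seed=seed)
        lag, kin_aligned = align_lag(feats, kin)
        annotations_aligned = shift_annotations(annotations, lag, kin.n_frames)
        if predictor == "oracle":
            decoded = DecodedTrace(values=clamp_unit(kin_aligned.values.copy()))
        else:
            decoded = predictor(feats)
        fr = kin.frame_rate
        for trial, a in enumerate(annotations_aligned):
            active = list(a.active_dofs)
            resting = [d for d in range(N_DOF) if d not in a.active_dofs]
            intended = windowed_rmse(decoded, kin_aligned, window, active, a.span())
            unintended = windowed_rmse(decoded, kin_aligned, window, resting, a.span())
            pct, hold = ttt_occupancy(decoded, kin_aligned, window, fr, a.span())
            jerk = log_mean_abs_jerk(decoded, fr, active, a.span())
            rows.append(
                {
                    "seed": seed,
                    "trial": trial,
                    "movement_id": a.movement_id,
                    "target_amplitude": a.target_amplitude,
                    "intended_rmse": intended,
                    "unintended_rmse": unintended,
                    "pct_time_in_target": pct,
                    "max_hold_s": hold,
                    "log_mean_abs_jerk": jerk,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Multi-subject aggregation study (the headline design, scaled to simulation)
# ---------------------------------------------------------------------------

DEFAULT_TRAIN_DAYS = tuple(range(0, 30, 3))  # ten calibration sessions, 3 days apart
DEFAULT_TEST_DAYS = (33, 89)  # held-out sessions, up to ~2 months later


@dataclass
class StudyResult:
    metrics: pd.DataFrame
    slopes: pd.DataFrame
    summary: dict


def _study_cnn_config() -> TrainConfig:
    # Simulation-scale training budget: a fixed number of window visits per
    # condition keeps a full multi-subject study tractable on one CPU core
    # while giving every aggregation size the same optimizer work.
    return TrainConfig(
        max_epochs=2000, batch_size=8, window_stride=4,
        visit_budget=144_000, max_val_windows=800,
    )


def run_aggregation_study(
    n_seeds: int = 10,
    base_seed: int = 0,
    aggregation_sizes: tuple[int, ...] = (1, 5, 10),
    decoders: tuple[str, ...] = ("mkf", "cnn"),
    n_contacts: int = 11,
    n_movements: int = 8,
    trials_per_movement: int = 6,
    train_days: tuple[int, ...] = DEFAULT_TRAIN_DAYS,
    test_days: tuple[int, ...] = DEFAULT_TEST_DAYS,
    drift: DriftModel | None = None,
    cnn_train: TrainConfig | None = None,
    mode: str = "features",
) -> StudyResult:
    """Aggregation-versus-recalibration study across synthetic subjects.

    Each seed is one synthetic participant: a fresh contact layout with its
    own drift realization.  Ten calibration sessions precede two later test
    sessions; both decoders are trained on the last 1, 5 and 10 sessions
    and scored on the test sessions.  Returns per-trial metrics, per-DOF
    robustness slopes and a pooled summary.
    """
    drift = drift or DriftModel()
    cnn_train = cnn_train or _study_cnn_config()
    protocol = default_protocol(n_movements=n_movements, trials_per_movement=trials_per_movement)
    all_days = list(train_days) + list(test_days)

    protocol_dofs = sorted({d for mv in protocol.movements for d in mv.active_dofs})

    trial_rows: list[dict] = []
    dof_rows: list[dict] = []
    for i in range(n_seeds):
        subject_seed, drift_seed, train_seed = (
            int(x % (2**31))
            for x in np.random.SeedSequence([base_seed, i]).generate_state(3)
        )
        subject = default_subject(n_contacts=n_contacts, seed=subject_seed)
        subject_drift = dc_replace(drift, seed=drift_seed)
        study = generate_study(subject, protocol, subject_drift, all_days, mode=mode)
        config = ExperimentConfig(
            train_day_indices=list(train_days),
            test_day_indices=list(test_days),
            aggregation_sizes=aggregation_sizes,
            decoders=decoders,
            seeds=(train_seed,),
            selection_stride=3,
            cnn_train=cnn_train,
        )
        for cond, ses, decoded in _iter_decoded(config, study):
            for row in _trial_rows(cond, ses, decoded):
                trial_rows.append({**row, "subject": i})
            for dof, rmse in session_dof_rmse(decoded, ses.kinematics, protocol_dofs).items():
                dof_rows.append(
                    {
                        "subject": i,
                        "decoder": cond["decoder"],
                        "n_aggregated": cond["n_aggregated"],
                        "dof": dof,
                        "day_since_training": cond["days_since_training"],
                        "rmse": rmse,
                    }
                )

    metrics = pd.DataFrame(trial_rows)
    slope_rows = []
    for (i, decoder, K), grp in pd.DataFrame(dof_rows).groupby(
        ["subject", "decoder", "n_aggregated"]
    ):
        for fit in robustness_slopes(grp[["dof", "day_since_training", "rmse"]]):
            slope_rows.append(
                {
                    "subject": i,
                    "decoder": decoder,
                    "n_aggregated": K,
                    "dof": fit.dof_index,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                }
            )
    slopes = pd.DataFrame(slope_rows)
    return StudyResult(metrics=metrics, slopes=slopes, summary=summarize_study(metrics, slopes))


def summarize_study(metrics: pd.DataFrame, slopes: pd.DataFrame) -> dict:
    """Pooled medians, improvement percentages and slope statistics."""
    from scipy import stats as sps

    summary: dict = {}
    med = metrics.groupby(["decoder", "n_aggregated"])[["intended_rmse", "unintended_rmse"]].median()
    summary["median_rmse"] = {
        f"{dec}_k{K}": {
            "intended": float(row["intended_rmse"]),
            "unintended": float(row["unintended_rmse"]),
        }
        for (dec, K), row in med.iterrows()
    }

    sizes = sorted(metrics["n_aggregated"].unique())
    k1 = sizes[0]
    pooled = metrics.groupby("n_aggregated")["unintended_rmse"].median()
    summary["unintended_improvement_pct"] = {
        f"k{K}": float(100.0 * (pooled[k1] - pooled[K]) / pooled[k1]) for K in sizes if K != k1
    }
    summary["intended_improvement_pct"] = {}
    for dec in metrics["decoder"].unique():
        dm = metrics[metrics["decoder"] == dec].groupby("n_aggregated")["intended_rmse"].median()
        summary["intended_improvement_pct"][dec] = {
            f"k{K}": float(100.0 * (dm[k1] - dm[K]) / dm[k1]) for K in sizes if K != k1
        }

    summary["slopes"] = {}
    if not slopes.empty:
        for (dec, K), grp in slopes.groupby(["decoder", "n_aggregated"]):
            vals = grp["slope"].to_numpy()
            q1, q2, q3 = np.percentile(vals, [25, 50, 75])
            summary["slopes"][f"{dec}_k{K}"] = {
                "median": float(q2),
                "iqr": (float(q1), float(q3)),
                "n": int(vals.size),
            }
        if "cnn" in slopes["decoder"].unique():
            kmax = max(sizes)
            per_subject = (
                slopes[slopes["decoder"] == "cnn"]
                .groupby(["subject", "n_aggregated"])["slope"]
                .median()
                .unstack("n_aggregated")
            )
            wins = int((per_subject[kmax] < per_subject[k1]).sum())
            n = int(per_subject.shape[0])
            test = sps.binomtest(wins, n, 0.5, alternative="greater")
            summary["cnn_slope_sign_test"] = {"wins": wins, "n": n, "p": float(test.pvalue)}
            med1 = float(np.median(slopes.query("decoder=='cnn' and n_aggregated==@k1")["slope"]))
            medmax = float(np.median(slopes.query("decoder=='cnn' and n_aggregated==@kmax")["slope"]))
            if med1 > 0:
                summary["robustness_improvement_pct"] = float(100.0 * (med1 - medmax) / med1)
    return summary
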