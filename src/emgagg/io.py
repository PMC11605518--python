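"""Session directory layout: plain CSV/JSON, one directory per session.

* ``emg.csv``         samples x contacts, header row of contact ids (raw sessions)
* ``features.csv``    frames x feature channels (feature-level sessions)
* ``kinematics.csv``  frames x 12 DOF positions
* ``annotations.json``  trial records
* ``meta.json``       day index and generator provenance
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .data import EmgRecording, FeatureMatrix, KinematicTrace, N_DOF, Session, TrialAnnotation

_DOF_COLUMNS = [f"dof{d:02d}" for d in range(N_DOF)]


def save_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if session.emg is not None:
        pd.DataFrame(session.emg.data.T, columns=session.emg.contact_ids).to_csv(
            path / "emg.csv", index=False
        )
    if session.features is not None:
        labels = session.features.channel_labels or [
            f"f{i}" for i in range(session.features.n_features)
        ]
        pd.DataFrame(session.features.values.T, columns=labels).to_csv(
            path / "features.csv", index=False
        )
    pd.DataFrame(session.kinematics.values.T, columns=_DOF_COLUMNS).to_csv(
        path / "kinematics.csv", index=False
    )
    with open(path / "annotations.json", "w") as fh:
        json.dump([asdict(a) for a in session.annotations], fh, indent=1)
    meta = {
        "day_index": session.day_index,
        "frame_rate": session.kinematics.frame_rate,
        "emg_fs": session.emg.fs if session.emg is not None else None,
        **session.meta,
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def load_session(path: str | Path) -> Session:
    path = Path(path)
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    with open(path / "annotations.json") as fh:
        annotations = [
            TrialAnnotation(**{**rec, "active_dofs": tuple(rec["active_dofs"])})
            for rec in json.load(fh)
        ]
    kin_df = pd.read_csv(path / "kinematics.csv")
    kin = KinematicTrace(values=kin_df.to_numpy().T, frame_rate=meta.get("frame_rate", 30.0))
    emg = features = None
    if (path / "emg.csv").exists():
        df = pd.read_csv(path / "emg.csv")
        emg = EmgRecording(
            data=df.to_numpy().T, fs=meta.get("emg_fs") or 1000.0, contact_ids=list(df.columns)
        )
    if (path / "features.csv").exists():
        df = pd.read_csv(path / "features.csv")
        features = FeatureMatrix(
            values=df.to_numpy().T,
            frame_rate=meta.get("frame_rate", 30.0),
            channel_labels=list(df.columns),
        )
    extra = {k: v for k, v in meta.items() if k not in ("day_index", "frame_rate", "emg_fs")}
    return Session(
        kinematics=kin,
        annotations=annotations,
        day_index=int(meta["day_index"]),
        emg=emg,
        features=features,
        meta=extra,
    )
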