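"""Standard-format I/O: NIfTI volumes and masks, BIDS-style events TSV,
behavior CSV, model/template JSON, and full synthetic-dataset round trips.

Conventions
-----------
* NIfTI 4D images are float32, ``(X, Y, Z, T)``, identity affine (simulated
  data lives in ROI space, not scanner space).
* Events TSV columns: ``onset`` and ``duration`` in seconds from run start
  (pre-discard), ``trial_type`` in {task, replay} — the BIDS convention.
* Volume indices elsewhere in the package are 0-based post-discard; the
  conversion happens in :func:`reactivate.features.epoch_blocks` only.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CONDITIONS, BlockEvents, RoiMask, RoiTimeSeries
from .decoding import DecoderModel
from .preprocess import extract_roi
from .rsa import TemplatePair
from .synthetic import GroundTruth, SimConfig, SyntheticSubject

__all__ = [
    "write_bold",
    "read_bold",
    "write_mask",
    "read_mask",
    "write_events_tsv",
    "read_events_tsv",
    "write_behavior_csv",
    "read_behavior_csv",
    "write_model",
    "read_model",
    "write_templates",
    "read_templates",
    "write_dataset",
    "read_dataset",
]


# ---------------------------------------------------------------------------
# NIfTI


def write_bold(ts: RoiTimeSeries, mask: RoiMask, path) -> Path:
    """Embed a ``T x V`` ROI series into a 4D NIfTI on the mask's grid."""
    path = Path(path)
    vol = np.zeros((*mask.grid_shape, ts.n_volumes), dtype=np.float32)
    idx = mask.voxel_indices
    vol[idx[:, 0], idx[:, 1], idx[:, 2], :] = ts.data.T.astype(np.float32)
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, ts.tr_s))
    nib.save(img, path)
    return path


def read_bold(path, mask: RoiMask, session_id: str = "", subject_id: str = "") -> RoiTimeSeries:
    """Read a 4D NIfTI and extract the ROI series in canonical mask order."""
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path
        raise IOError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return extract_roi(data, mask, tr, session_id=session_id, subject_id=subject_id)


def write_mask(mask: RoiMask, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.to_volume(), affine=np.eye(4)), path)
    return path


def read_mask(path) -> RoiMask:
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read NIfTI mask {path}: {exc}") from exc
    return RoiMask.from_volume(np.asanyarray(img.dataobj))


# ---------------------------------------------------------------------------
# events / behavior tables


def write_events_tsv(events: BlockEvents, path) -> Path:
    path = Path(path)
    events.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path, session_id: str = "") -> BlockEvents:
    """Read and validate a BIDS-style events TSV.

    Raises ``ValueError`` naming the offending line (1-based, counting the
    header) for non-numeric onset/duration, negative values, or unknown
    trial types.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("onset", "duration", "trial_type"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    onsets, durations, conditions = [], [], []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        try:
            onset = float(row["onset"])
            duration = float(row["duration"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{line}: non-numeric onset/duration") from exc
        if onset < 0 or duration <= 0:
            raise ValueError(
                f"{path}:{line}: onset must be >= 0 and duration > 0 "
                f"(got onset={onset}, duration={duration})"
            )
        if row["trial_type"] not in CONDITIONS:
            raise ValueError(
                f"{path}:{line}: trial_type '{row['trial_type']}' not in {CONDITIONS}"
            )
        onsets.append(onset)
        durations.append(duration)
        conditions.append(row["trial_type"])
    return BlockEvents(
        np.array(onsets), np.array(durations), tuple(conditions), session_id=session_id
    )


def write_behavior_csv(rows: pd.DataFrame, path) -> Path:
    """Write a behavior table (columns subject, session, tracking_error)."""
    path = Path(path)
    rows.to_csv(path, index=False)
    return path


def read_behavior_csv(path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("subject", "session", "tracking_error"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if (frame["tracking_error"] <= 0).any():
        raise ValueError(f"{path}: tracking_error values must be positive")
    return frame


# ---------------------------------------------------------------------------
# models and templates


def write_model(model: DecoderModel, path) -> Path:
    path = Path(path)
    payload = {
        "kind": "linear-svm",
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "C": model.C,
        "training_sessions": list(model.training_sessions),
        "feature_contract": list(model.feature_contract),
    }
    path.write_text(json.dumps(payload))
    return path


def read_model(path) -> DecoderModel:
    payload = json.loads(Path(path).read_text())
    L, V, ordering = payload["feature_contract"]
    if ordering != "volume-major":
        raise ValueError(f"unsupported feature ordering '{ordering}'")
    return DecoderModel(
        weights=np.array(payload["weights"]),
        bias=float(payload["bias"]),
        C=float(payload["C"]),
        training_sessions=tuple(payload["training_sessions"]),
        window_len=int(L),
        n_voxels=int(V),
    )


def write_templates(templates: TemplatePair, path) -> Path:
    path = Path(path)
    payload = {
        "kind": "rsa-templates",
        "task_template": templates.task_template.tolist(),
        "nontask_template": templates.nontask_template.tolist(),
        "n_task_blocks": templates.n_task_blocks,
        "n_nontask_blocks": templates.n_nontask_blocks,
        "feature_contract": list(templates.feature_contract),
    }
    path.write_text(json.dumps(payload))
    return path


def read_templates(path) -> TemplatePair:
    payload = json.loads(Path(path).read_text())
    L, V, _ = payload["feature_contract"]
    return TemplatePair(
        task_template=np.array(payload["task_template"]),
        nontask_template=np.array(payload["nontask_template"]),
        n_task_blocks=int(payload["n_task_blocks"]),
        n_nontask_blocks=int(payload["n_nontask_blocks"]),
        window_len=int(L),
        n_voxels=int(V),
    )


# ---------------------------------------------------------------------------
# dataset round trip


def write_dataset(subjects, directory, config: SimConfig | None = None) -> Path:
    """Write a cohort as a file tree of standard formats.

    Per subject: 4D BOLD NIfTI per session, events TSV per task session,
    and a JSON ground-truth sidecar; shared across the cohort: the ROI mask
    NIfTI and one behavior CSV.  Round-trips losslessly (float32) through
    :func:`read_dataset`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_voxels = subjects[0].rest_pre.n_voxels
    mask = RoiMask.cube_for(n_voxels)
    write_mask(mask, directory / "roi_mask.nii.gz")
    if config is not None:
        (directory / "sim_config.json").write_text(json.dumps(vars(config), indent=2))

    behavior_rows = []
    for subject in subjects:
        sub_dir = directory / subject.subject_id
        sub_dir.mkdir(exist_ok=True)
        for i, (series, events) in enumerate(subject.task_sessions, start=1):
            write_bold(series, mask, sub_dir / f"task-{i}_bold.nii.gz")
            write_events_tsv(events, sub_dir / f"task-{i}_events.tsv")
        write_bold(subject.rest_pre, mask, sub_dir / "rest-pre_bold.nii.gz")
        write_bold(subject.rest_post, mask, sub_dir / "rest-post_bold.nii.gz")
        truth = subject.truth
        sidecar = {
            "group": subject.group,
            "pattern_task": truth.pattern_task.tolist(),
            "pattern_replay": truth.pattern_replay.tolist(),
            "pattern_correlation": truth.pattern_correlation,
            "rest_event_onsets": {k: np.asarray(v).tolist() for k, v in truth.rest_event_onsets.items()},
            "true_reactivation_fraction": truth.true_reactivation_fraction,
            "true_behavior_improvement": truth.true_behavior_improvement,
        }
        (sub_dir / "ground_truth.json").write_text(json.dumps(sidecar))
        for s, err in enumerate(subject.behavior, start=1):
            behavior_rows.append(
                {"subject": subject.subject_id, "session": s, "tracking_error": err}
            )
    write_behavior_csv(pd.DataFrame(behavior_rows), directory / "behavior.csv")
    return directory


def read_dataset(directory) -> list:
    """Read a cohort written by :func:`write_dataset`."""
    directory = Path(directory)
    mask = read_mask(directory / "roi_mask.nii.gz")
    behavior = read_behavior_csv(directory / "behavior.csv")
    subjects = []
    for sub_dir in sorted(p for p in directory.iterdir() if p.is_dir()):
        subject_id = sub_dir.name
        sidecar = json.loads((sub_dir / "ground_truth.json").read_text())
        truth = GroundTruth(
            pattern_task=np.array(sidecar["pattern_task"]),
            pattern_replay=np.array(sidecar["pattern_replay"]),
            pattern_correlation=float(sidecar["pattern_correlation"]),
            rest_event_onsets={
                k: np.array(v, dtype=int) for k, v in sidecar["rest_event_onsets"].items()
            },
            true_reactivation_fraction=sidecar["true_reactivation_fraction"],
            true_behavior_improvement=float(sidecar["true_behavior_improvement"]),
        )
        task_sessions = []
        i = 1
        while (sub_dir / f"task-{i}_bold.nii.gz").exists():
            series = read_bold(
                sub_dir / f"task-{i}_bold.nii.gz",
                mask,
                session_id=f"task-{i}",
                subject_id=subject_id,
            )
            events = read_events_tsv(
                sub_dir / f"task-{i}_events.tsv", session_id=f"task-{i}"
            )
            task_sessions.append((series, events))
            i += 1
        rest = {
            key: read_bold(
                sub_dir / f"rest-{key}_bold.nii.gz",
                mask,
                session_id=f"rest-{key}",
                subject_id=subject_id,
            )
            for key in ("pre", "post")
        }
        errors = (
            behavior[behavior["subject"] == subject_id]
            .sort_values("session")["tracking_error"]
            .to_numpy()
        )
        subjects.append(
            SyntheticSubject(
                subject_id=subject_id,
                group=sidecar["group"],
                task_sessions=tuple(task_sessions),
                rest_pre=rest["pre"],
                rest_post=rest["post"],
                behavior=errors,
                truth=truth,
            )
        )
    return subjects
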