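"""Trial CSV / manifest reading and writing, validation, participant splits.

On-disk layout: one CSV per trial with header ``t,ax,ay,az,gx,gy,gz,pitch,
roll,yaw`` (``t`` is the 0-based sample index; accel in g, gyro in deg/s,
angles in deg) plus a manifest CSV with one row per trial.  Sample index k
corresponds to time k * 1000 / 90.9 ms.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import CHANNELS, SAMPLE_RATE_HZ, TrialRecording

MANIFEST_COLUMNS = [
    "trial_id",
    "participant_id",
    "run",
    "stance",
    "label",
    "n_samples",
    "true_onset_sample",
    "file",
]


def ms_per_sample(sample_rate_hz: float = SAMPLE_RATE_HZ) -> float:
    return 1000.0 / sample_rate_hz


def save_dataset(
    trials: Sequence[TrialRecording],
    manifest: pd.DataFrame,
    out_dir: str | os.PathLike,
) -> Path:
    """Write one CSV per trial plus ``manifest.csv``; returns manifest path.

    Floats are written with Python's shortest round-trip repr, so a
    save/load cycle is bit-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    files = []
    for rec in trials:
        fname = f"{rec.trial_id}.csv"
        df = pd.DataFrame(rec.channels, columns=list(CHANNELS))
        df.insert(0, "t", np.arange(rec.n_samples, dtype=int))
        # %.17g preserves every float64 bit-exactly across the round trip
        df.to_csv(out / fname, index=False, float_format="%.17g")
        files.append(fname)
    manifest["file"] = files
    path = out / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path


def _validate_manifest(manifest: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns and c != "true_onset_sample"]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    if manifest["trial_id"].duplicated().any():
        dupes = manifest.loc[manifest["trial_id"].duplicated(), "trial_id"].tolist()
        raise ValueError(f"duplicate trial_id(s) in manifest: {dupes[:5]}")
    bad = set(manifest["label"].unique()) - {"face_touch", "no_touch"}
    if bad:
        raise ValueError(f"non-binary labels in manifest: {sorted(bad)}")


def load_dataset(
    manifest_path: str | os.PathLike,
) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Load all trials referenced by a manifest, preserving manifest order.

    Raises with the offending ``trial_id`` on a missing file and with the
    row number on a non-numeric cell or wrong column count.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    _validate_manifest(manifest)
    base = manifest_path.parent
    expected_cols = ["t", *CHANNELS]

    trials = []
    for row in manifest.itertuples(index=False):
        fpath = base / str(row.file)
        if not fpath.is_file():
            raise FileNotFoundError(
                f"trial {row.trial_id!r}: data file {fpath} does not exist"
            )
        df = pd.read_csv(fpath, float_precision="round_trip")
        if list(df.columns) != expected_cols:
            raise ValueError(
                f"trial {row.trial_id!r}: expected columns {expected_cols}, "
                f"got {list(df.columns)}"
            )
        values = df[list(CHANNELS)]
        for col in values.columns:
            if values[col].dtype == object:
                coerced = pd.to_numeric(values[col], errors="coerce")
                bad = coerced.isna() & values[col].notna()
                bad_row = int(bad.idxmax()) if bad.any() else int(coerced.isna().idxmax())
                raise ValueError(
                    f"trial {row.trial_id!r}: non-numeric cell at data row "
                    f"{bad_row} (column {col!r})"
                )
        onset = getattr(row, "true_onset_sample", None)
        if onset is not None and not pd.isna(onset):
            onset = int(onset)
        else:
            onset = None
        trials.append(
            TrialRecording(
                participant_id=str(row.participant_id),
                run=int(row.run),
                stance=str(row.stance),
                label=str(row.label),
                sample_rate_hz=SAMPLE_RATE_HZ,
                channels=values.to_numpy(dtype=float),
                true_onset_sample=onset,
                trial_id=str(row.trial_id),
            )
        )
    return trials, manifest


def split_by_participant(
    manifest: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Partition participants (not trials) into train/test id lists.

    Participants are shuffled with the given seed; the first
    ``round(train_fraction * P)`` go to training.  All of a participant's
    trials land on one side, so a held-out evaluation measures resilience to
    between-person behavioral differences rather than identity memorization.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    participants = sorted(manifest["participant_id"].unique())
    if len(participants) < 2:
        raise ValueError("need at least 2 participants for a participant-wise split")
    rng = np.random.default_rng(seed)
    order = [participants[i] for i in rng.permutation(len(participants))]
    n_train = int(np.floor(train_fraction * len(participants) + 0.5))
    n_train = min(max(n_train, 1), len(participants) - 1)
    return sorted(order[:n_train]), sorted(order[n_train:])


def select_trials(
    trials: Sequence[TrialRecording], participant_ids: Sequence[str]
) -> list[TrialRecording]:
    """Subset trials by participant id, preserving order."""
    wanted = set(participant_ids)
    return [t for t in trials if t.participant_id in wanted]
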