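"""CSV/YAML readers and writers, run configuration and manifests.

File formats (comma-separated, UTF-8, "." decimal, mandatory header,
missing values as empty strings):

* ``trials.csv`` — subject_id, trial, option, inflation_pct, burst, reward,
  rt_ms (optional).
* ``subjects.csv`` — subject_id, sss_score, group_label, rs_proxy, plus
  ``true_<param>`` columns for simulated cohorts.
* Task configuration in YAML with :class:`bitrl.task.TaskConfig` keys;
  omitted keys fall back to the canonical defaults.

Every CLI run writes a JSON manifest (seed, config hash, package versions)
so artifacts are reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, KLParams, RWParams, Session, SubjectProfile, PARAM_NAMES
from .task import TaskConfig, default_config

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_trials",
    "write_trials",
    "read_subjects",
    "write_subjects",
    "read_cohort",
    "write_cohort",
    "sessions_from_frame",
    "write_manifest",
]

TRIAL_COLUMNS = ["subject_id", "trial", "option", "inflation_pct", "burst", "reward"]


class ValidationError(ValueError):
    """Raised when an input file violates the declared format."""


@dataclass
class RunConfig:
    """End-to-end run settings for the CLI."""

    seed: int = 0
    model: str = "kl"
    n_subjects: int = 40
    task_config: Optional[str] = None
    out_dir: str = "bitrl_out"
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    thin: int = 5


def sessions_from_frame(df: pd.DataFrame, n_options: int = 9) -> list:
    """Validate a trials frame and split it into Session objects."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trials file missing columns: {missing}")
    sessions = []
    if len(df) == 0:
        return sessions
    bad = df[(df["option"] < 1) | (df["option"] > n_options)]
    if len(bad):
        raise ValidationError(
            f"option outside 1..{n_options} for subject(s) "
            f"{sorted(bad['subject_id'].unique().tolist())}"
        )
    df = df.sort_values(["subject_id", "trial"], kind="stable")
    for sid, grp in df.groupby("subject_id", sort=False):
        trials = grp["trial"].to_numpy(dtype=int)
        expect = np.arange(1, trials.size + 1)
        if not np.array_equal(trials, expect):
            gap = expect[trials != expect][0] if trials.size else 1
            raise ValidationError(
                f"subject {sid}: non-contiguous trials (first gap at trial {gap})"
            )
        rt = grp["rt_ms"].to_numpy(dtype=float) if "rt_ms" in grp else None
        if rt is not None and np.all(np.isnan(rt)):
            rt = None
        sessions.append(
            Session(
                subject_id=sid,
                trial=trials,
                option=grp["option"].to_numpy(dtype=int),
                inflation_pct=grp["inflation_pct"].to_numpy(dtype=float),
                burst=grp["burst"].to_numpy(dtype=bool),
                reward=grp["reward"].to_numpy(dtype=float),
                rt_ms=rt,
            )
        )
    return sessions


def read_trials(path) -> list:
    """Read and validate a trials.csv into Session objects, ordered by
    (subject, trial)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file without header")
    return sessions_from_frame(df)


def write_trials(sessions, path) -> None:
    Cohort(
        subjects=[SubjectProfile(subject_id=s.subject_id) for s in sessions],
        sessions=list(sessions),
    ).to_trials_frame().to_csv(path, index=False)


def write_subjects(cohort: Cohort, path) -> None:
    cohort.to_subjects_frame().to_csv(path, index=False)


def read_subjects(path, model: Optional[str] = None) -> list:
    """Read subjects.csv into SubjectProfile objects; ``true_<param>``
    columns are reassembled into parameter objects when complete."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file without header")
    if "subject_id" not in df.columns:
        raise ValidationError("subjects file missing column subject_id")
    out = []
    for _, row in df.iterrows():
        params = None
        for m, cls in (("rw", RWParams), ("kl", KLParams)):
            if model is not None and m != model:
                continue
            cols = [f"true_{p}" for p in PARAM_NAMES[m]]
            if all(c in df.columns and pd.notna(row[c]) for c in cols):
                params = cls(
                    **{p: float(row[f"true_{p}"]) for p in PARAM_NAMES[m]}
                )
                break
        out.append(
            SubjectProfile(
                subject_id=row["subject_id"],
                sss_score=(
                    float(row["sss_score"])
                    if pd.notna(row.get("sss_score"))
                    else None
                ),
                group_label=(
                    str(row["group_label"])
                    if pd.notna(row.get("group_label"))
                    else None
                ),
                params=params,
                rs_proxy=(
                    float(row["rs_proxy"])
                    if pd.notna(row.get("rs_proxy"))
                    else None
                ),
            )
        )
    return out


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write trials.csv + subjects.csv (+ task.yaml); returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.csv",
        "subjects": out / "subjects.csv",
        "task": out / "task.yaml",
    }
    cohort.to_trials_frame().to_csv(paths["trials"], index=False)
    cohort.to_subjects_frame().to_csv(paths["subjects"], index=False)
    cohort.task.save(paths["task"])
    return paths


def read_cohort(out_dir, model: Optional[str] = None) -> Cohort:
    out = Path(out_dir)
    task_path = out / "task.yaml"
    task = TaskConfig.load(task_path) if task_path.exists() else default_config()
    sessions = read_trials(out / "trials.csv")
    subjects = read_subjects(out / "subjects.csv", model=model)
    by_id = {s.subject_id: s for s in subjects}
    ordered = [by_id[s.subject_id] for s in sessions]
    return Cohort(subjects=ordered, sessions=sessions, task=task, model=model)


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, seed: int, config: dict, **extra) -> dict:
    """JSON run manifest: seed, config and its hash, package versions."""
    import scipy

    from . import __version__

    manifest = {
        "seed": int(seed),
        "config": config,
        "config_hash": _config_hash(config),
        "versions": {
            "bitrl": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
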