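"""Plain-text serialization of recordings, manifests and questionnaires.

Trajectories travel as tidy CSV with columns
``subject_id, trial_id, condition, t, x``; the cohort manifest as CSV
with ``subject_id, label`` plus one column per covariate; questionnaire
tables as CSV with ``subject_id, label`` plus one integer column per
item.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .synthetic_data import Cohort, Trajectory

RECORDING_COLUMNS = ["subject_id", "trial_id", "condition", "t", "x"]


def write_recordings_csv(recordings: list[Trajectory], path: str) -> None:
    frames = []
    for tr in recordings:
        frames.append(pd.DataFrame({
            "subject_id": tr.subject_id, "trial_id": tr.trial_id,
            "condition": tr.condition, "t": tr.t, "x": tr.x,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_recordings_csv(path: str) -> list[Trajectory]:
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[~np.isfinite(df["t"]) | ~np.isfinite(df["x"])]
    if len(bad):
        raise ValueError(f"{path}: non-numeric t/x at row {bad[0] + 2}")
    out: list[Trajectory] = []
    for (sid, tid, cond), g in df.groupby(
            ["subject_id", "trial_id", "condition"], sort=True):
        t = g["t"].to_numpy(float)
        x = g["x"].to_numpy(float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = g.index[1:][dt <= 0][0] + 2
            raise ValueError(f"{path}: non-monotone time at row {row}")
        if x.min() < 0 or x.max() > 1:
            row = g.index[(x < 0) | (x > 1)][0] + 2
            raise ValueError(f"{path}: position outside [0,1] at row {row}")
        rate = 1.0 / np.median(dt)
        out.append(Trajectory(t=t, x=x, rate=float(rate), subject_id=str(sid),
                              trial_id=str(tid), condition=str(cond)))
    return out


def write_manifest_csv(cohort: Cohort, path: str) -> None:
    rows = []
    for sid in cohort.subjects():
        row = {"subject_id": sid, "label": cohort.labels[sid]}
        row.update(cohort.covariates.get(sid, {}))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest_csv(path: str) -> tuple[dict[str, str], dict[str, dict[str, float]]]:
    df = pd.read_csv(path)
    for col in ("subject_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    labels = dict(zip(df["subject_id"].astype(str), df["label"].astype(str)))
    covariate_cols = [c for c in df.columns if c not in ("subject_id", "label")]
    covariates = {
        str(r["subject_id"]): {c: float(r[c]) for c in covariate_cols}
        for _, r in df.iterrows()
    }
    return labels, covariates


def write_cohort(cohort: Cohort, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    write_recordings_csv(cohort.recordings, os.path.join(directory, "recordings.csv"))
    write_manifest_csv(cohort, os.path.join(directory, "manifest.csv"))


def read_cohort(directory: str) -> Cohort:
    recs = read_recordings_csv(os.path.join(directory, "recordings.csv"))
    labels, covariates = read_manifest_csv(os.path.join(directory, "manifest.csv"))
    unknown = sorted({r.subject_id for r in recs} - set(labels))
    if unknown:
        raise ValueError(f"recordings reference subjects missing from the "
                         f"manifest: {unknown}")
    return Cohort(recordings=recs, labels=labels, covariates=covariates)


def write_nss_csv(table: np.ndarray, labels: list[str], item_names: list[str],
                  path: str) -> None:
    df = pd.DataFrame(table, columns=item_names)
    df.insert(0, "label", labels)
    df.insert(0, "subject_id", [f"s{i:03d}" for i in range(len(labels))])
    df.to_csv(path, index=False)


def read_nss_csv(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path)
    for col in ("subject_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    items = [c for c in df.columns if c not in ("subject_id", "label")]
    return df[items].to_numpy(float), list(df["label"].astype(str)), items
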