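"""File I/O: TSV time courses, cohort read/write, stack and partition serialization."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynec import ECMatrix, ECWindowStack, WindowSpec
from .errors import DataError, FormatError
from .states import StatePartition
from .synthdata import Cohort, GroundTruth, SubjectTimeCourses, SubjectTruth

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "write_cohort",
    "read_cohort",
    "save_stack",
    "load_stack",
    "save_partition",
    "load_partition",
]


def read_timecourses(path, subject_id: str | None = None,
                     group: str | None = None) -> SubjectTimeCourses:
    """Read one subject's TSV (header = component names, rows = time points).

    Ragged rows, non-numeric cells, and NaN cells raise a format error
    naming the offending line (1-based, header = line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV ({exc})") from exc
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: file is empty") from exc
    if df.shape[0] == 0:
        raise DataError(f"{path}: header only, no data rows")
    probe = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = probe.isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raw = df.loc[row, col]
        what = "missing/NaN" if (pd.isna(raw) or str(raw).lower() == "nan") else f"non-numeric {raw!r}"
        raise FormatError(f"{path}: {what} cell at line {row + 2}, column {col!r}")
    return SubjectTimeCourses(
        subject_id=subject_id or path.stem,
        # astype(float) is correctly rounded; to_numeric's fast path is not
        data=df.astype(float).to_numpy(),
        component_names=list(df.columns),
        group=group,
    )


def write_timecourses(subject: SubjectTimeCourses, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(subject.data, columns=subject.component_names).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_cohort(cohort: Cohort, outdir, seed: int | None = None) -> Path:
    """One TSV per subject + manifest JSON + clinical TSV + truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for subject in cohort.subjects:
        write_timecourses(subject, outdir / f"{subject.subject_id}.tsv")
        manifest.append({"subject_id": subject.subject_id, "group": subject.group,
                         "seed": seed})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    truth = cohort.truth
    sidecar = {
        "effect_edges": [list(e) for e in truth.effect_edges],
        "clinical_coefficients": truth.clinical_coefficients,
        "stay_probs": {g: list(p) for g, p in truth.stay_probs.items()},
        "group_couplings": {
            g: {str(s): np.asarray(a).tolist() for s, a in per_state.items()}
            for g, per_state in truth.group_couplings.items()
        },
        "states": {sid: t.states.tolist() for sid, t in truth.subjects.items()},
        "occupancy": {sid: t.occupancy.tolist() for sid, t in truth.subjects.items()},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, sort_keys=True))
    return outdir


def read_cohort(indir) -> Cohort:
    """Read back a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    subjects = [
        read_timecourses(indir / f"{e['subject_id']}.tsv",
                         subject_id=e["subject_id"], group=e.get("group"))
        for e in manifest
    ]
    clinical = pd.read_csv(indir / "clinical.tsv", sep="\t")
    truth_path = indir / "ground_truth.json"
    truth = None
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        truth = GroundTruth(
            subjects={
                sid: SubjectTruth(
                    subject_id=sid,
                    states=np.asarray(states, dtype=int),
                    couplings={},
                    occupancy=np.asarray(raw["occupancy"][sid]),
                )
                for sid, states in raw["states"].items()
            },
            group_couplings={
                g: {int(s): np.asarray(a) for s, a in per_state.items()}
                for g, per_state in raw["group_couplings"].items()
            },
            effect_edges=tuple(tuple(e) for e in raw["effect_edges"]),
            clinical_coefficients=raw["clinical_coefficients"],
            stay_probs={g: tuple(p) for g, p in raw["stay_probs"].items()},
        )
    return Cohort(subjects=subjects, clinical=clinical, truth=truth)


def save_stack(stack: ECWindowStack, path) -> Path:
    """Serialize one subject's window stack as a compressed npz archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": stack.subject_id,
        "group": stack.group or "",
        "width": stack.spec.width,
        "step": stack.spec.step,
        "order": stack.order,
        "ridge": stack.ridge,
        "mode": stack.mode,
        "component_names": stack.component_names,
    }
    np.savez_compressed(path, matrices=stack.as_array(), meta=json.dumps(meta, sort_keys=True))
    return path


def load_stack(path) -> ECWindowStack:
    with np.load(Path(path), allow_pickle=False) as npz:
        matrices = npz["matrices"]
        meta = json.loads(str(npz["meta"]))
    names = meta["component_names"]
    return ECWindowStack(
        subject_id=meta["subject_id"],
        matrices=[ECMatrix(values=m, component_names=names, window=i)
                  for i, m in enumerate(matrices)],
        spec=WindowSpec(meta["width"], meta["step"]),
        order=meta["order"],
        ridge=meta["ridge"],
        mode=meta["mode"],
        group=meta["group"] or None,
        component_names=names,
    )


def stack_to_long_tsv(stack: ECWindowStack, path) -> Path:
    """Optional long-format export: window, source, target, value."""
    rows = []
    for w, m in enumerate(stack.matrices):
        for i, src in enumerate(m.component_names):
            for j, tgt in enumerate(m.component_names):
                rows.append((w, src, tgt, m.values[i, j]))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["window", "source", "target", "value"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def save_partition(partition: StatePartition, outdir) -> Path:
    """Partition as JSON (labels, occupancy, settings) + one TSV per centroid."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "k": partition.k,
        "metric": partition.metric,
        "seed": partition.seed,
        "inertia": partition.inertia,
        "occupancy": partition.occupancy.tolist(),
        "subject_ids": partition.subject_ids.tolist(),
        "window_indices": partition.window_indices.tolist(),
        "labels": partition.labels.tolist(),
        "groups": partition.groups,
    }
    (outdir / "partition.json").write_text(json.dumps(payload, sort_keys=True))
    for s, cen in enumerate(partition.centroids, start=1):
        pd.DataFrame(cen.values, index=cen.component_names,
                     columns=cen.component_names).to_csv(
            outdir / f"centroid_state{s}.tsv", sep="\t"
        )
    return outdir


def load_partition(indir) -> StatePartition:
    indir = Path(indir)
    payload = json.loads((indir / "partition.json").read_text())
    centroids = []
    for s in range(1, payload["k"] + 1):
        df = pd.read_csv(indir / f"centroid_state{s}.tsv", sep="\t", index_col=0)
        centroids.append(ECMatrix(values=df.to_numpy(), component_names=list(df.columns),
                                  window=f"state{s}"))
    return StatePartition(
        k=payload["k"],
        centroids=centroids,
        subject_ids=np.asarray(payload["subject_ids"]),
        window_indices=np.asarray(payload["window_indices"]),
        labels=np.asarray(payload["labels"]),
        occupancy=np.asarray(payload["occupancy"]),
        inertia=payload["inertia"],
        metric=payload["metric"],
        seed=payload["seed"],
        groups=payload["groups"],
    )
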