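"""Causal-flow degree measures and temporal properties of state sequences.

Degrees are computed on a single directed influence matrix (rows = sources):
``out(i)`` sums i's outgoing off-diagonal entries, ``in(j)`` sums j's
incoming ones, and the net degree is ``in - out`` (positive = net receiver).
Temporal properties of a subject's window-label sequence are the fractional
windows per state (F), mean dwell time in windows (MDT), and the number of
transitions (NT); run-length encoding is the computation core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynec import ECMatrix, ECWindowStack, WindowSpec
from .errors import DataError, ParameterError
from .states import StatePartition

__all__ = [
    "DegreeProfile",
    "TemporalProfile",
    "SubjectStateSummary",
    "degree_profile",
    "temporal_properties",
    "run_lengths",
    "subject_state_summary",
    "cohort_metrics_table",
    "dwell_windows_to_seconds",
]


@dataclass
class DegreeProfile:
    """Per-component in-, out-, and net (in - out) weighted degrees."""

    in_weighted: np.ndarray
    out_weighted: np.ndarray
    in_out_weighted: np.ndarray
    component_names: list[str]
    context: str = "single-window"
    use_abs: bool = True


@dataclass
class TemporalProfile:
    """Per-subject state-sequence summaries.

    ``mdt`` of an unvisited state is reported as 0 with ``visited`` False so
    group tables stay rectangular without silently imputing a dwell time.
    """

    fractions: np.ndarray  # (k,) F, sums to 1
    mean_dwell: np.ndarray  # (k,) MDT in windows; 0 where unvisited
    n_transitions: int  # NT
    visited: np.ndarray  # (k,) bool
    subject_id: str = ""


def degree_profile(ec, use_abs: bool = True, context: str = "single-window") -> DegreeProfile:
    """Weighted degree triple of one influence matrix.

    ``use_abs=True`` (default) sums magnitudes, since signed coefficients
    can cancel; ``use_abs=False`` sums signed entries, in which case the net
    degrees sum to zero exactly over components.
    """
    if isinstance(ec, ECMatrix):
        values, names = ec.values, ec.component_names
    else:
        values = np.asarray(ec, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ParameterError(f"degree_profile needs a square matrix, got {values.shape}")
        names = [f"c{i:02d}" for i in range(values.shape[0])]
    v = np.abs(values) if use_abs else values.copy()
    np.fill_diagonal(v, 0.0)
    out_w = v.sum(axis=1)
    in_w = v.sum(axis=0)
    return DegreeProfile(
        in_weighted=in_w, out_weighted=out_w, in_out_weighted=in_w - out_w,
        component_names=list(names), context=context, use_abs=use_abs,
    )


def run_lengths(labels: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encode a label sequence as (label, length) pairs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]


def temporal_properties(labels, k: int, subject_id: str = "") -> TemporalProfile:
    """F, MDT, and NT of one subject's ordered window state labels."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise DataError("label sequence is empty")
    if labels.min() < 1 or labels.max() > k:
        raise DataError(
            f"labels must lie in 1..{k}; found range [{labels.min()}, {labels.max()}]"
        )
    runs = run_lengths(labels)
    fractions = np.bincount(labels - 1, minlength=k) / labels.size
    mean_dwell = np.zeros(k)
    visited = np.zeros(k, dtype=bool)
    for s in range(1, k + 1):
        lens = [length for lab, length in runs if lab == s]
        if lens:
            visited[s - 1] = True
            mean_dwell[s - 1] = float(np.mean(lens))
    return TemporalProfile(
        fractions=fractions, mean_dwell=mean_dwell, n_transitions=len(runs) - 1,
        visited=visited, subject_id=subject_id,
    )


@dataclass
class SubjectStateSummary:
    """Per-subject, per-state aggregates used by the group statistics stage."""

    subject_id: str
    group: str
    state_means: list[ECMatrix | None]  # None where the subject never visits the state
    degrees: list[DegreeProfile | None]
    temporal: TemporalProfile


def subject_state_summary(
    stack: ECWindowStack,
    partition: StatePartition,
    use_abs: bool = True,
) -> SubjectStateSummary:
    """Average a subject's windows within each estimated state.

    Returns the per-state mean EC matrix, its degree profile, and the
    subject's temporal profile; states the subject never occupies carry
    ``None`` (missing-flag) entries.
    """
    labels = partition.labels_for(stack.subject_id)
    if labels.size != len(stack):
        raise DataError(
            f"partition has {labels.size} windows for subject {stack.subject_id!r}, "
            f"stack has {len(stack)}"
        )
    arr = stack.as_array()
    state_means: list[ECMatrix | None] = []
    degrees: list[DegreeProfile | None] = []
    for s in range(1, partition.k + 1):
        member = arr[labels == s]
        if member.size == 0:
            state_means.append(None)
            degrees.append(None)
            continue
        mean = ECMatrix(values=member.mean(axis=0),
                        component_names=stack.component_names, window=f"state{s}")
        state_means.append(mean)
        degrees.append(degree_profile(mean, use_abs=use_abs, context=f"state{s}-mean"))
    temporal = temporal_properties(labels, partition.k, subject_id=stack.subject_id)
    group = partition.groups.get(stack.subject_id, "") or (stack.group or "")
    return SubjectStateSummary(
        subject_id=stack.subject_id, group=group,
        state_means=state_means, degrees=degrees, temporal=temporal,
    )


def cohort_metrics_table(
    stacks: list[ECWindowStack],
    partition: StatePartition,
    use_abs: bool = True,
) -> pd.DataFrame:
    """Tidy per-subject-per-state metrics table.

    One row per subject x state with F, MDT, NT and one column per
    component per degree type (``in_``, ``out_``, ``net_`` prefixes).
    Degree columns are NaN for states the subject never visits.
    """
    rows = []
    for stack in stacks:
        summ = subject_state_summary(stack, partition, use_abs=use_abs)
        names = stack.component_names
        for s in range(partition.k):
            row = {
                "subject_id": summ.subject_id,
                "group": summ.group,
                "state": s + 1,
                "F": summ.temporal.fractions[s],
                "MDT": summ.temporal.mean_dwell[s],
                "visited": bool(summ.temporal.visited[s]),
                "NT": summ.temporal.n_transitions,
            }
            deg = summ.degrees[s]
            for j, name in enumerate(names):
                row[f"in_{name}"] = deg.in_weighted[j] if deg else np.nan
                row[f"out_{name}"] = deg.out_weighted[j] if deg else np.nan
                row[f"net_{name}"] = deg.in_out_weighted[j] if deg else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def dwell_windows_to_seconds(mdt_windows, spec: WindowSpec, tr: float = 2.0):
    """Convert mean dwell time from windows to seconds (windows x step x TR)."""
    return np.asarray(mdt_windows, dtype=float) * spec.step * tr
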