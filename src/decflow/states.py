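"""K-means decomposition of pooled windowed EC matrices into recurring states.

Matrices are vectorized over their off-diagonal entries (self-influence is
not an inter-regional edge), pooled across subjects, and clustered with
best-of-``n_init`` k-means.  States are renumbered by descending occupancy
so "state 1" is always the most frequent pattern.  To make the solution
invariant to subject ordering, the model is fitted on a canonically sorted
copy of the pooled window vectors and labels are then assigned in the
caller's order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .dynec import ECMatrix, ECWindowStack
from .errors import DataError, ParameterError

__all__ = ["StatePartition", "cluster_states", "occupancy_report", "suggest_k"]


@dataclass
class StatePartition:
    """Result of clustering pooled windowed EC matrices into k states."""

    k: int
    centroids: list[ECMatrix]  # mean member matrix per state (full, incl. diagonal)
    subject_ids: np.ndarray  # (n_windows,) subject id per pooled window
    window_indices: np.ndarray  # (n_windows,) within-subject window index
    labels: np.ndarray  # (n_windows,) state labels in 1..k
    occupancy: np.ndarray  # (k,) fractions, descending
    inertia: float
    metric: str
    seed: int
    groups: dict[str, str]  # subject id -> group label ("" when unknown)

    def labels_for(self, subject_id: str) -> np.ndarray:
        """One subject's ordered window state labels."""
        mask = self.subject_ids == subject_id
        if not mask.any():
            raise DataError(f"subject {subject_id!r} not present in partition")
        order = np.argsort(self.window_indices[mask])
        return self.labels[mask][order]

    @property
    def n_windows(self) -> int:
        return self.labels.size


def _pool(stacks: list[ECWindowStack]):
    if not stacks:
        raise ParameterError("no window stacks given")
    d = stacks[0].matrices[0].n_components
    offmask = ~np.eye(d, dtype=bool)
    vecs, sids, widx, full = [], [], [], []
    groups = {}
    for stack in stacks:
        groups[stack.subject_id] = stack.group or ""
        for i, m in enumerate(stack.matrices):
            if m.n_components != d:
                raise ParameterError("stacks have inconsistent matrix dimensions")
            vecs.append(m.values[offmask])
            full.append(m.values)
            sids.append(stack.subject_id)
            widx.append(i)
    return (np.asarray(vecs), np.asarray(full), np.asarray(sids), np.asarray(widx),
            groups, stacks[0].component_names)


def _kmedians(x: np.ndarray, k: int, n_init: int, seed: int, max_iter: int = 300):
    """Lloyd-style k-medians under the L1 metric (manhattan distances)."""
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers = x[rng.choice(x.shape[0], size=k, replace=False)]
        labels = np.zeros(x.shape[0], dtype=int)
        for _ in range(max_iter):
            dist = cdist(x, centers, metric="cityblock")
            new_labels = dist.argmin(axis=1)
            if np.array_equal(new_labels, labels) and _ > 0:
                break
            labels = new_labels
            for j in range(k):
                member = x[labels == j]
                if member.size:
                    centers[j] = np.median(member, axis=0)
        inertia = float(cdist(x, centers, metric="cityblock").min(axis=1).sum())
        if best is None or inertia < best[2]:
            best = (labels.copy(), centers.copy(), inertia)
    return best


def _fit(x: np.ndarray, k: int, metric: str, n_init: int, seed: int):
    # Canonical row order -> clustering invariant to subject ordering.
    order = np.lexsort(x.T[::-1])
    xs = x[order]
    if metric == "l2":
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        sorted_labels = km.fit_predict(xs)
        inertia = float(km.inertia_)
    elif metric == "l1":
        sorted_labels, _, inertia = _kmedians(xs, k, n_init=n_init, seed=seed)
    else:
        raise ParameterError(f"unknown metric {metric!r}; expected 'l1' or 'l2'")
    labels = np.empty(x.shape[0], dtype=int)
    labels[order] = sorted_labels
    return labels, inertia


def cluster_states(
    stacks: list[ECWindowStack],
    k: int = 2,
    metric: str = "l2",
    n_init: int = 10,
    seed: int = 0,
    zscore: bool = False,
) -> StatePartition:
    """Cluster all windows of all subjects into ``k`` recurring states.

    Parameters
    ----------
    zscore : bool
        Standardize each off-diagonal feature across windows before
        clustering (off by default; raw coefficients are clustered).
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    vecs, full, sids, widx, groups, names = _pool(stacks)
    n = vecs.shape[0]
    if k > n:
        raise ParameterError(f"k={k} exceeds the {n} pooled windows")
    feats = vecs
    if zscore:
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        feats = (feats - feats.mean(axis=0)) / sd
    raw, inertia = _fit(feats, k, metric, n_init, seed)

    counts = np.bincount(raw, minlength=k)
    # Renumber by descending occupancy (stable on ties).
    new_of_old = np.empty(k, dtype=int)
    new_of_old[np.argsort(-counts, kind="stable")] = np.arange(k)
    labels = new_of_old[raw] + 1
    occupancy = np.bincount(labels - 1, minlength=k) / n

    centroids = []
    for s in range(1, k + 1):
        member = full[labels == s]
        cen = member.mean(axis=0) if member.size else np.zeros_like(full[0])
        centroids.append(ECMatrix(values=cen, component_names=names, window=f"state{s}"))
    return StatePartition(
        k=k, centroids=centroids, subject_ids=sids, window_indices=widx,
        labels=labels, occupancy=occupancy, inertia=inertia, metric=metric,
        seed=seed, groups=groups,
    )


def occupancy_report(partition: StatePartition):
    """Group-level occupancy percentages and per-subject window shares."""
    if partition.n_windows == 0:
        raise ParameterError("partition is empty")
    percentages = partition.occupancy * 100.0
    rows = []
    for sid in dict.fromkeys(partition.subject_ids.tolist()):
        lab = partition.labels_for(sid)
        share = np.bincount(lab - 1, minlength=partition.k) / lab.size
        row = {"subject_id": sid, "group": partition.groups.get(sid, "")}
        row.update({f"state{s + 1}": share[s] for s in range(partition.k)})
        rows.append(row)
    return percentages, pd.DataFrame(rows)


def suggest_k(
    stacks: list[ECWindowStack],
    k_range=range(2, 7),
    metric: str = "l2",
    n_init: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Silhouette and inertia diagnostics over a range of k (never auto-selects)."""
    vecs, _, _, _, _, _ = _pool(stacks)
    rows = []
    for k in k_range:
        if not 2 <= k <= vecs.shape[0] - 1:
            raise ParameterError(f"k={k} outside the valid range for {vecs.shape[0]} windows")
        part_labels, inertia = _fit(vecs, k, metric, n_init, seed)
        sil = float(
            silhouette_score(
                vecs, part_labels,
                metric="manhattan" if metric == "l1" else "euclidean",
            )
        )
        rows.append({"k": k, "silhouette": sil, "inertia": inertia})
    return pd.DataFrame(rows)
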