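"""Group statistics: edgewise Welch tests, NBS-style permutation inference,
Benjamini-Hochberg FDR, Spearman clinical associations, and ICC(2,1)
reliability of temporal properties across sliding-window settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .dynec import WindowSpec, windowed_ec
from .errors import DataError, ParameterError
from .netmetrics import temporal_properties
from .states import cluster_states

__all__ = [
    "EdgeTestResult",
    "NBSComponent",
    "ICCResult",
    "edgewise_ttest",
    "nbs_component_test",
    "fdr_bh",
    "spearman_assoc",
    "icc_2_1",
    "reliability_across_windows",
]


@dataclass
class NBSComponent:
    """One weakly connected suprathreshold component with its permutation p."""

    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    size: int  # edge count (extent statistic)
    p_value: float


@dataclass
class EdgeTestResult:
    """Edgewise statistics plus optional correction / NBS metadata."""

    t: np.ndarray
    p: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    method: str
    surviving: np.ndarray | None = None  # bool mask after correction
    components: list[NBSComponent] = field(default_factory=list)
    primary_threshold: float | None = None
    n_perm: int | None = None
    seed: int | None = None


def _stack_groups(group_a, group_b):
    a = np.asarray([np.asarray(m, dtype=float) for m in group_a], dtype=float)
    b = np.asarray([np.asarray(m, dtype=float) for m in group_b], dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ParameterError("groups must be stacks of equally sized square matrices")
    if a.shape[1] != a.shape[2]:
        raise ParameterError("matrices must be square")
    return a, b


def _welch(a: np.ndarray, b: np.ndarray):
    """NaN-aware elementwise Welch t over the subject axis (axis 0)."""
    n_a = np.sum(~np.isnan(a), axis=0)
    n_b = np.sum(~np.isnan(b), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m_a, m_b = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
        v_a = np.nanvar(a, axis=0, ddof=1)
        v_b = np.nanvar(b, axis=0, ddof=1)
        se2 = v_a / n_a + v_b / n_b
        t = (m_a - m_b) / np.sqrt(se2)
        df = se2**2 / ((v_a / n_a) ** 2 / (n_a - 1) + (v_b / n_b) ** 2 / (n_b - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        # zero-variance, zero-difference edges: t is 0/0 -> define as no effect
        both_zero = (se2 == 0) & (m_a == m_b)
    t = np.where(both_zero, 0.0, t)
    p = np.where(both_zero, 1.0, p)
    invalid = (n_a < 2) | (n_b < 2)
    t = np.where(invalid, np.nan, t)
    p = np.where(invalid, np.nan, p)
    return t, p, n_a, n_b


def edgewise_ttest(group_a, group_b) -> EdgeTestResult:
    """Welch two-sample t per off-diagonal edge.

    ``group_a`` / ``group_b`` are sequences of per-subject (state-mean) EC
    matrices; a subject whose matrix is entirely NaN (state never visited)
    is excluded per-edge, with the retained counts recorded.  Diagonal
    entries are reported as NaN.
    """
    a, b = _stack_groups(group_a, group_b)
    d = a.shape[1]
    if np.all(np.isnan(a)) or np.all(np.isnan(b)):
        raise DataError("a group has no subjects with data in this state")
    t, p, n_a, n_b = _welch(a, b)
    eye = np.eye(d, dtype=bool)
    t[eye] = np.nan
    p[eye] = np.nan
    return EdgeTestResult(t=t, p=p, n_a=n_a, n_b=n_b, method="welch")


def _components_from_threshold(t: np.ndarray, threshold: float) -> list[tuple]:
    d = t.shape[0]
    supra = np.abs(t) >= threshold
    supra &= ~np.eye(d, dtype=bool)
    supra &= ~np.isnan(t)
    g = nx.DiGraph()
    for i, j in zip(*np.nonzero(supra)):
        g.add_edge(int(i), int(j))
    comps = []
    for nodes in nx.weakly_connected_components(g):
        sub = g.subgraph(nodes)
        comps.append((tuple(sorted(nodes)), tuple(sorted(sub.edges())), sub.number_of_edges()))
    return comps


def nbs_component_test(
    group_a,
    group_b,
    primary_t_threshold: float = 3.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EdgeTestResult:
    """Network-based statistic with an extent (edge-count) component statistic.

    Edgewise Welch |t| values are thresholded at ``primary_t_threshold``;
    weakly connected components of the surviving directed edges are scored
    by edge count against the permutation null distribution of the maximum
    component size under group-label exchange.  Component p-values use the
    add-one estimator ``(1 + #null >= observed) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ParameterError(f"n_perm must be >= 100, got {n_perm}")
    a, b = _stack_groups(group_a, group_b)
    t, p, n_a_e, n_b_e = _welch(a, b)
    d = a.shape[1]
    eye = np.eye(d, dtype=bool)
    t[eye] = np.nan
    observed = _components_from_threshold(t, primary_t_threshold)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b], axis=0)
    n_a = a.shape[0]
    null_max = np.zeros(n_perm)
    if observed:
        for r in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            t_null, _, _, _ = _welch(pooled[perm[:n_a]], pooled[perm[n_a:]])
            t_null[eye] = np.nan
            comps = _components_from_threshold(t_null, primary_t_threshold)
            null_max[r] = max((c[2] for c in comps), default=0)

    components = [
        NBSComponent(
            nodes=nodes, edges=edges, size=size,
            p_value=float((1 + np.sum(null_max >= size)) / (1 + n_perm)),
        )
        for nodes, edges, size in sorted(observed, key=lambda c: -c[2])
    ]
    surviving = np.zeros_like(t, dtype=bool)
    for comp in components:
        if comp.p_value < 0.05:
            for i, j in comp.edges:
                surviving[i, j] = True
    t[eye] = np.nan
    p[eye] = np.nan
    return EdgeTestResult(
        t=t, p=p, n_a=n_a_e, n_b=n_b_e, method="welch+nbs", surviving=surviving,
        components=components, primary_threshold=primary_t_threshold,
        n_perm=n_perm, seed=seed,
    )


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, reject)``; NaN entries are excluded from the family
    and propagate as NaN / False.  Adjusted p-values are monotone
    non-decreasing in raw-p order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise ParameterError(f"q must lie in (0, 1), got {q}")
    flat = p.ravel()
    valid = ~np.isnan(flat)
    pv = flat[valid]
    if np.any((pv < 0) | (pv > 1)):
        raise DataError("p-values must lie in [0, 1]")
    adjusted = np.full(flat.shape, np.nan)
    reject = np.zeros(flat.shape, dtype=bool)
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        adj_full = np.empty(m)
        adj_full[order] = adj
        adjusted[valid] = adj_full
        # step-up rejection: largest i with p_(i) <= q*i/m, reject all smaller
        below = pv[order] <= q * np.arange(1, m + 1) / m
        if below.any():
            cutoff = np.max(np.flatnonzero(below))
            rej = np.zeros(m, dtype=bool)
            rej[order[: cutoff + 1]] = True
            reject[valid] = rej
    return adjusted.reshape(p.shape), reject.reshape(p.shape)


def spearman_assoc(
    metrics: pd.DataFrame,
    clinical: pd.DataFrame,
    metric_cols=None,
    clinical_cols=("HbA1c", "MoCA", "DBP", "education"),
    q: float = 0.05,
    on: str = "subject_id",
) -> pd.DataFrame:
    """Spearman rank correlations between metric and clinical columns.

    Rows are joined on ``on``; each (metric, clinical) pair with at least 4
    complete observations contributes one association, BH-adjusted across
    the whole returned family.  Constant variables yield undefined rho and
    are flagged and excluded from the family.
    """
    merged = metrics.merge(clinical, on=on, how="inner", suffixes=("", "_clin"))
    if metric_cols is None:
        skip = {on, "group", "state", "visited"} | set(clinical_cols)
        metric_cols = [c for c in metrics.columns
                       if c not in skip and pd.api.types.is_numeric_dtype(metrics[c])]
    rows = []
    for mcol in metric_cols:
        for ccol in clinical_cols:
            if ccol not in merged.columns:
                continue
            sub = merged[[mcol, ccol]].dropna()
            flag = ""
            rho = p = np.nan
            if len(sub) < 4:
                flag = "insufficient-n"
            elif sub[mcol].nunique() < 2 or sub[ccol].nunique() < 2:
                flag = "constant"
            else:
                rho, p = stats.spearmanr(sub[mcol], sub[ccol])
            rows.append({"metric": mcol, "clinical": ccol, "n": len(sub),
                         "rho": rho, "p": p, "flag": flag})
    out = pd.DataFrame(rows)
    if len(out):
        adj, rej = fdr_bh(out["p"].to_numpy(), q=q)
        out["p_adj"] = adj
        out["significant"] = rej
    return out


@dataclass
class ICCResult:
    """Two-way random-effects, absolute-agreement, single-measures ICC."""

    metric: str
    icc: float
    f_statistic: float
    p_value: float
    df1: int
    df2: int
    n_subjects: int
    n_settings: int


def icc_2_1(measurements, metric: str = "") -> ICCResult:
    """ICC(2,1) from the two-way ANOVA mean squares.

    ``measurements`` is a subjects x settings matrix with no missing cells.
    The value is ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``;
    the p-value comes from the F test of MSR against MSE.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ParameterError("measurements must be a 2-D subjects x settings matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ParameterError(f"need >= 3 subjects and >= 2 settings, got {x.shape}")
    if np.isnan(x).any():
        raise DataError("measurements contain missing cells")
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - gm) ** 2) / (n - 1)
    msc = n * np.sum((col_means - gm) ** 2) / (k - 1)
    mse = np.sum((x - row_means[:, None] - col_means[None, :] + gm) ** 2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = 1.0 if denom == 0 and msr == mse else (msr - mse) / denom
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        f, p = np.inf, 0.0
    else:
        f = msr / mse
        p = float(stats.f.sf(f, df1, df2))
    return ICCResult(metric=metric, icc=float(icc), f_statistic=float(f), p_value=p,
                     df1=df1, df2=df2, n_subjects=n, n_settings=k)


def _match_states(reference, other) -> np.ndarray:
    """Map each reference state to the nearest centroid of another partition."""
    d = reference.centroids[0].n_components
    offmask = ~np.eye(d, dtype=bool)
    ref = np.asarray([c.values[offmask] for c in reference.centroids])
    oth = np.asarray([c.values[offmask] for c in other.centroids])
    cost = np.linalg.norm(ref[:, None, :] - oth[None, :, :], axis=2)
    _, cols = linear_sum_assignment(cost)
    return cols  # cols[s] = other-partition state index matched to reference state s


def reliability_across_windows(
    subjects,
    settings: list[WindowSpec],
    k: int = 2,
    order: int = 1,
    ridge: float = 0.1,
    mode: str = "coef",
    metric: str = "l2",
    n_init: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """ICC(2,1) of temporal properties across sliding-window settings.

    The full windowing -> clustering -> temporal-property chain is re-run
    per setting with matched ``k`` and ``seed``; states of non-reference
    settings are matched to the first setting's states by minimal centroid
    distance.  Each non-reference setting is paired with the reference and
    one ICC is reported per temporal property.
    """
    if len(settings) < 2:
        raise ParameterError("need at least two window settings")
    per_setting = []
    for spec in settings:
        stacks = [windowed_ec(s, spec, order=order, ridge=ridge, mode=mode) for s in subjects]
        part = cluster_states(stacks, k=k, metric=metric, n_init=n_init, seed=seed)
        per_setting.append(part)

    ref = per_setting[0]
    subject_ids = [s.subject_id for s in subjects]

    def _profiles(part, mapping):
        f = np.zeros((len(subject_ids), k))
        mdt = np.zeros((len(subject_ids), k))
        nt = np.zeros(len(subject_ids))
        for i, sid in enumerate(subject_ids):
            prof = temporal_properties(part.labels_for(sid), k)
            f[i] = prof.fractions[mapping]
            mdt[i] = prof.mean_dwell[mapping]
            nt[i] = prof.n_transitions
        return f, mdt, nt

    ref_f, ref_mdt, ref_nt = _profiles(ref, np.arange(k))
    rows = []
    for spec, part in zip(settings[1:], per_setting[1:]):
        mapping = _match_states(ref, part)
        f, mdt, nt = _profiles(part, mapping)
        pair = (f"w{settings[0].width}s{settings[0].step}", f"w{spec.width}s{spec.step}")
        for s in range(k):
            res = icc_2_1(np.column_stack([ref_f[:, s], f[:, s]]), metric=f"F_state{s + 1}")
            rows.append({"pair": "-vs-".join(pair), "metric": res.metric,
                         "icc": res.icc, "p": res.p_value})
            res = icc_2_1(np.column_stack([ref_mdt[:, s], mdt[:, s]]),
                          metric=f"MDT_state{s + 1}")
            rows.append({"pair": "-vs-".join(pair), "metric": res.metric,
                         "icc": res.icc, "p": res.p_value})
        res = icc_2_1(np.column_stack([ref_nt, nt]), metric="NT")
        rows.append({"pair": "-vs-".join(pair), "metric": res.metric,
                     "icc": res.icc, "p": res.p_value})
    return pd.DataFrame(rows)
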