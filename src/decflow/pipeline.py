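"""One-command end-to-end runner: simulate/ingest -> windowed EC -> states ->
metrics -> group statistics, with every stage output written under a
directory named by the config hash and seed."""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np

from . import io as dio
from .config import PipelineConfig, config_hash
from .dynec import WindowSpec, windowed_ec
from .errors import DecflowError
from .inference import (
    edgewise_ttest,
    fdr_bh,
    nbs_component_test,
    reliability_across_windows,
    spearman_assoc,
)
from .netmetrics import cohort_metrics_table
from .states import cluster_states, occupancy_report
from .synthdata import CONTROL, PATIENT, SimConfig, simulate_cohort

__all__ = ["run_pipeline", "sim_config_from_section"]

log = logging.getLogger("decflow")


def sim_config_from_section(sim, seed: int) -> SimConfig:
    return SimConfig(
        n_subjects=(sim.n_patients, sim.n_controls),
        n_timepoints=sim.n_timepoints,
        n_components=sim.n_components,
        noise_sd=sim.noise_sd,
        stay_probs={PATIENT: tuple(sim.stay_patient), CONTROL: tuple(sim.stay_control)},
        effect_attenuation=sim.effect_attenuation,
        clinical_coupling=sim.clinical_coupling,
        seed=seed,
    )


def _jsonify(obj):
    """Make a report JSON-safe and deterministic (NaN/inf -> None)."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if (math.isnan(v) or math.isinf(v)) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def _group_state_matrices(stacks, partition, summaries, state, group):
    """Per-subject state-mean matrices of one group; NaN plane when unvisited."""
    mats = []
    for stack in stacks:
        if (partition.groups.get(stack.subject_id) or stack.group) != group:
            continue
        summ = summaries[stack.subject_id]
        mean = summ.state_means[state - 1]
        if mean is None:
            d = len(stack.component_names)
            mats.append(np.full((d, d), np.nan))
        else:
            mats.append(mean.values)
    return mats


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Execute all enabled stages and return (and optionally write) the report."""
    from .netmetrics import subject_state_summary

    digest = config_hash(config)
    rundir = Path(config.outdir) / f"run-{digest}-seed{config.seed}"
    ss = np.random.SeedSequence(config.seed)
    sim_seed, cluster_seed, perm_seed = (int(s.generate_state(1)[0]) % 2**31
                                         for s in ss.spawn(3))

    # --- stage 1: cohort -------------------------------------------------
    if config.input_dir:
        log.info("ingesting cohort from %s", config.input_dir)
        cohort = dio.read_cohort(config.input_dir)
    else:
        log.info("simulating cohort (seed %d)", sim_seed)
        cohort = simulate_cohort(sim_config_from_section(config.sim, sim_seed))

    # --- stage 2: windowed EC -------------------------------------------
    spec = WindowSpec(config.window.width, config.window.step)
    stacks = []
    for subject in cohort.subjects:
        try:
            stacks.append(windowed_ec(subject, spec, order=config.mvar.order,
                                      ridge=config.mvar.ridge, mode=config.mvar.mode))
        except DecflowError as exc:
            raise type(exc)(f"dynec stage failed for {subject.subject_id}: {exc}") from exc
    windows_per_subject = {s.subject_id: len(s) for s in stacks}
    total_windows = sum(windows_per_subject.values())
    log.info("windowed EC: %d subjects, %d matrices", len(stacks), total_windows)

    # --- stage 3: states -------------------------------------------------
    partition = cluster_states(
        stacks, k=config.cluster.k, metric=config.cluster.metric,
        n_init=config.cluster.n_init, seed=cluster_seed, zscore=config.cluster.zscore,
    )
    occupancy_pct, per_subject_shares = occupancy_report(partition)

    # --- stage 4: metrics ------------------------------------------------
    summaries = {s.subject_id: subject_state_summary(s, partition, config.use_abs_degree)
                 for s in stacks}
    metrics = cohort_metrics_table(stacks, partition, use_abs=config.use_abs_degree)

    # --- stage 5: inference ---------------------------------------------
    group_tests = {}
    for state in range(1, config.cluster.k + 1):
        mats_a = _group_state_matrices(stacks, partition, summaries, state, PATIENT)
        mats_b = _group_state_matrices(stacks, partition, summaries, state, CONTROL)
        entry = {}
        if mats_a and mats_b:
            edge = edgewise_ttest(mats_a, mats_b)
            adj, rej = fdr_bh(edge.p, q=config.inference.alpha)
            nbs = nbs_component_test(mats_a, mats_b,
                                     primary_t_threshold=config.inference.primary_t,
                                     n_perm=config.inference.n_perm, seed=perm_seed)
            entry = {
                "n_edges_fdr_significant": int(np.nansum(rej)),
                "fdr_significant_edges": [
                    [int(i), int(j)] for i, j in zip(*np.nonzero(rej))
                ],
                "min_p_edge": (
                    [int(v) for v in np.unravel_index(np.nanargmin(edge.p), edge.p.shape)]
                    if np.any(~np.isnan(edge.p)) else None
                ),
                "nbs_components": [
                    {"nodes": list(c.nodes), "size": c.size, "p": c.p_value}
                    for c in nbs.components
                ],
            }
        group_tests[f"state{state}"] = entry

    # temporal-property group comparisons
    temporal_tests = {}
    from scipy import stats as sps
    for name in ("F", "MDT"):
        for state in range(1, config.cluster.k + 1):
            sub = metrics[metrics["state"] == state]
            a = sub[sub["group"] == PATIENT][name].to_numpy()
            b = sub[sub["group"] == CONTROL][name].to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                t, p = sps.ttest_ind(a, b, equal_var=False)
                temporal_tests[f"{name}_state{state}"] = {
                    "mean_patient": float(np.mean(a)), "mean_control": float(np.mean(b)),
                    "t": float(t), "p": float(p),
                }
    nt = metrics[metrics["state"] == 1]
    a = nt[nt["group"] == PATIENT]["NT"].to_numpy()
    b = nt[nt["group"] == CONTROL]["NT"].to_numpy()
    if len(a) >= 2 and len(b) >= 2:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        temporal_tests["NT"] = {"mean_patient": float(np.mean(a)),
                                "mean_control": float(np.mean(b)),
                                "t": float(t), "p": float(p)}

    # clinical associations: family per state over temporal properties
    associations = []
    if cohort.clinical is not None and len(cohort.clinical):
        for state in range(1, config.cluster.k + 1):
            sub = metrics[metrics["state"] == state][["subject_id", "F", "MDT", "NT"]]
            assoc = spearman_assoc(sub, cohort.clinical,
                                   clinical_cols=tuple(config.inference.clinical_vars),
                                   q=config.inference.alpha)
            assoc.insert(0, "state", state)
            associations.append(assoc)
    import pandas as pd
    associations = pd.concat(associations, ignore_index=True) if associations else None

    # reliability across window settings
    reliability = None
    if config.run_reliability and config.reliability_windows:
        settings = [spec] + [WindowSpec(w, s) for w, s in config.reliability_windows]
        reliability = reliability_across_windows(
            cohort.subjects, settings, k=config.cluster.k, order=config.mvar.order,
            ridge=config.mvar.ridge, mode=config.mvar.mode,
            metric=config.cluster.metric, n_init=config.cluster.n_init,
            seed=cluster_seed,
        )

    report = _jsonify({
        "config_hash": digest,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_subjects": len(cohort.subjects),
        "windows_per_subject": windows_per_subject,
        "total_windows": total_windows,
        "occupancy_percent": occupancy_pct,
        "group_tests": group_tests,
        "temporal_tests": temporal_tests,
        "associations": associations.to_dict(orient="records") if associations is not None else [],
        "reliability_icc": reliability.to_dict(orient="records") if reliability is not None else [],
    })

    if write_outputs:
        rundir.mkdir(parents=True, exist_ok=True)
        if not config.input_dir:
            dio.write_cohort(cohort, rundir / "cohort", seed=sim_seed)
        for stack in stacks:
            dio.save_stack(stack, rundir / "stacks" / f"{stack.subject_id}.npz")
        dio.save_partition(partition, rundir / "states")
        metrics.to_csv(rundir / "metrics.tsv", sep="\t", index=False)
        per_subject_shares.to_csv(rundir / "occupancy_per_subject.tsv", sep="\t", index=False)
        if associations is not None:
            associations.to_csv(rundir / "associations.tsv", sep="\t", index=False)
        if reliability is not None:
            reliability.to_csv(rundir / "reliability_icc.tsv", sep="\t", index=False)
        (rundir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
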