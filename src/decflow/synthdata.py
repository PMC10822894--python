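"""Regime-switching MVAR cohort simulator with known ground truth.

Each subject's component time courses follow a hidden-Markov state chain:
at every time point the active state selects a coupling matrix, and the
signal evolves as a VAR process driven by diagonal Gaussian noise.  The
patient-like group receives attenuated designated edges in the state-1
coupling and a higher state-1 stay probability; a synthetic clinical table
(HbA1c, MoCA, DBP, education years) is generated with configurable linear
coupling to each subject's true state-1 occupancy so downstream rank
correlations have a recoverable monotone signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "SimConfig",
    "SubjectTimeCourses",
    "SubjectTruth",
    "GroundTruth",
    "Cohort",
    "default_couplings",
    "simulate_state_chain",
    "simulate_subject",
    "simulate_cohort",
]

PATIENT = "patient"
CONTROL = "control"
BURN_IN = 50


@dataclass
class SubjectTimeCourses:
    """One subject's component-by-time data plus identifying metadata."""

    subject_id: str
    data: np.ndarray  # (T, n_components)
    component_names: list[str]
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("time-course data must be 2-D (time x component)")
        if len(self.component_names) != self.data.shape[1]:
            raise ParameterError(
                f"{len(self.component_names)} component names for "
                f"{self.data.shape[1]} columns"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectTruth:
    """Per-subject hidden truth: state sequence and the couplings that drove it."""

    subject_id: str
    states: np.ndarray  # (T,), labels in 1..k
    couplings: dict[int, np.ndarray]  # state -> (p, d, d)
    occupancy: np.ndarray  # (k,) empirical state fractions


@dataclass
class GroundTruth:
    """Cohort-level truth channel for parameter-recovery tests."""

    subjects: dict[str, SubjectTruth]
    group_couplings: dict[str, dict[int, np.ndarray]]  # group -> state -> (p, d, d)
    effect_edges: tuple[tuple[int, int], ...]  # (source, target), 0-based
    clinical_coefficients: dict[str, float]
    stay_probs: dict[str, tuple[float, ...]]


@dataclass
class Cohort:
    subjects: list[SubjectTimeCourses]
    clinical: pd.DataFrame
    truth: GroundTruth

    def __len__(self) -> int:
        return len(self.subjects)


def default_couplings(n_components: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic weak (state 1) and strong (state 2) coupling matrices.

    Matrices are in row=target, column=source convention.  Both regimes are
    comfortably stationary; the strong regime plants a distinct set of large
    off-diagonal edges so windowed estimates of the two regimes separate.
    """
    d = n_components
    a1 = np.eye(d) * 0.30
    for src, tgt, w in [(1, 6, 0.30), (1, 10, 0.30), (0, 4, 0.25), (3, 8, 0.25)]:
        a1[tgt % d, src % d] = w
    a2 = np.eye(d) * 0.25
    strong = [
        (0, 1, 0.55), (2, 3, -0.55), (4, 5, 0.55), (6, 7, -0.55),
        (8, 9, 0.55), (10, 11, 0.55), (1, 4, 0.55), (5, 2, 0.55),
        (0, 3, 0.50), (2, 7, -0.50), (6, 9, 0.50), (8, 11, 0.50),
    ]
    for src, tgt, w in strong:
        a2[tgt % d, src % d] = w
    return a1, a2


def _as_lag_stack(a: np.ndarray, order: int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 2:
        if order != 1:
            raise ParameterError("2-D coupling matrix given but mvar_order != 1")
        return a[None, :, :]
    if a.ndim == 3 and a.shape[0] == order:
        return a
    raise ParameterError(f"coupling must be (d, d) or (order, d, d); got shape {a.shape}")


def companion_spectral_radius(coupling: np.ndarray, order: int = 1) -> float:
    """Spectral radius of the VAR companion matrix (< 1 means stationary)."""
    lags = _as_lag_stack(coupling, order)
    p, d, _ = lags.shape
    comp = np.zeros((d * p, d * p))
    comp[:d] = np.concatenate(list(lags), axis=1)
    if p > 1:
        comp[d:, : d * (p - 1)] = np.eye(d * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class SimConfig:
    """Parameters of the state-switching MVAR cohort generator.

    ``n_subjects`` is ``(n_patients, n_controls)``; defaults mirror a
    76-subject two-group cohort with 170 retained time points over 12
    components.  ``stay_probs`` maps group to per-state stay probabilities;
    the patient default dwells longer in state 1.  ``effect_edges`` are the
    (source, target) pairs whose state-1 coupling is attenuated by
    ``effect_attenuation`` in the patient group.
    """

    n_subjects: tuple[int, int] = (36, 40)
    n_timepoints: int = 170
    n_components: int = 12
    mvar_order: int = 1
    coupling_state1: np.ndarray | None = None
    coupling_state2: np.ndarray | None = None
    stay_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {PATIENT: (0.99, 0.97), CONTROL: (0.97, 0.97)}
    )
    effect_edges: tuple[tuple[int, int], ...] = ((1, 6), (1, 10))
    effect_attenuation: float = 0.5
    stay_prob_shift: float = 0.0  # extra additive patient state-1 stay prob, capped below 1
    clinical_coupling: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_state1 is None or self.coupling_state2 is None:
            a1, a2 = default_couplings(self.n_components)
            if self.coupling_state1 is None:
                self.coupling_state1 = a1
            if self.coupling_state2 is None:
                self.coupling_state2 = a2
        self.coupling_state1 = np.asarray(self.coupling_state1, dtype=float)
        self.coupling_state2 = np.asarray(self.coupling_state2, dtype=float)
        # fold default edges into range for small component counts
        d = self.n_components
        self.effect_edges = tuple(
            (src % d, tgt % d) for src, tgt in self.effect_edges if src % d != tgt % d
        )

    @property
    def n_states(self) -> int:
        return 2

    def validate(self) -> None:
        if min(self.n_subjects) < 2:
            raise ParameterError(f"need >= 2 subjects per group, got {self.n_subjects}")
        if self.n_timepoints <= self.mvar_order:
            raise ParameterError("n_timepoints must exceed mvar_order")
        if self.noise_sd <= 0:
            raise ParameterError(f"noise_sd must be positive, got {self.noise_sd}")
        if not 0.0 <= self.effect_attenuation <= 1.0:
            raise ParameterError("effect_attenuation must lie in [0, 1]")
        for group, probs in self.stay_probs.items():
            for p in probs:
                if not 0.0 < p < 1.0:
                    raise ParameterError(
                        f"stay probability {p} for group {group!r} not in (0, 1)"
                    )
        for name, a in [("state 1", self.coupling_state1), ("state 2", self.coupling_state2)]:
            rho = companion_spectral_radius(a, self.mvar_order)
            if rho >= 1.0:
                raise ParameterError(
                    f"coupling for {name} is non-stationary "
                    f"(companion spectral radius {rho:.3f} >= 1)"
                )

    def group_couplings(self, group: str) -> dict[int, np.ndarray]:
        """State -> lag-stacked coupling for one group, with patient attenuation."""
        a1 = _as_lag_stack(self.coupling_state1, self.mvar_order).copy()
        a2 = _as_lag_stack(self.coupling_state2, self.mvar_order).copy()
        if group == PATIENT:
            for src, tgt in self.effect_edges:
                a1[:, tgt, src] *= 1.0 - self.effect_attenuation
        return {1: a1, 2: a2}

    def group_stay_probs(self, group: str) -> tuple[float, ...]:
        probs = self.stay_probs[group]
        if group == PATIENT and self.stay_prob_shift:
            shifted = min(probs[0] + self.stay_prob_shift, 1.0 - 1e-6)
            probs = (shifted,) + tuple(probs[1:])
        return probs

    def component_names(self) -> list[str]:
        return [f"c{i + 1:02d}" for i in range(self.n_components)]


def simulate_state_chain(
    n_timepoints: int,
    k: int,
    stay_probs,
    seed=None,
) -> np.ndarray:
    """Simulate a Markov state sequence with labels in ``1..k``.

    At every step the chain keeps its state with the current state's stay
    probability and otherwise moves to one of the other ``k - 1`` states
    uniformly.  The initial state is uniform.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if n_timepoints < 1:
        raise ParameterError(f"n_timepoints must be >= 1, got {n_timepoints}")
    probs = np.atleast_1d(np.asarray(stay_probs, dtype=float))
    if probs.size == 1:
        probs = np.repeat(probs, k)
    if probs.size != k:
        raise ParameterError(f"expected {k} stay probabilities, got {probs.size}")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ParameterError(f"stay probabilities must lie in [0, 1], got {probs}")
    rng = np.random.default_rng(seed)
    states = np.empty(n_timepoints, dtype=int)
    state = int(rng.integers(k))
    states[0] = state + 1
    if k == 1:
        states[:] = 1
        return states
    u = rng.random(n_timepoints - 1)
    jumps = rng.integers(0, k - 1, size=n_timepoints - 1)
    for t in range(1, n_timepoints):
        if u[t - 1] >= probs[state]:
            other = jumps[t - 1]
            state = other if other < state else other + 1
        states[t] = state + 1
    return states


def simulate_subject(
    cfg: SimConfig,
    group: str = CONTROL,
    seed=None,
    subject_id: str = "sub-001",
) -> tuple[SubjectTimeCourses, SubjectTruth]:
    """Simulate one subject's state-switching VAR time courses.

    A burn-in of ``BURN_IN`` samples is simulated and discarded so the
    emitted series starts near the within-state stationary distribution.
    """
    cfg.validate()
    if group not in cfg.stay_probs:
        raise ParameterError(f"unknown group {group!r}; expected one of {list(cfg.stay_probs)}")
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    couplings = cfg.group_couplings(group)
    d, p = cfg.n_components, cfg.mvar_order
    total = cfg.n_timepoints + BURN_IN
    chain = simulate_state_chain(total, cfg.n_states, cfg.group_stay_probs(group), rng)
    noise = rng.normal(0.0, cfg.noise_sd, size=(total, d))
    x = np.zeros((total + p, d))
    for t in range(total):
        a = couplings[chain[t]]
        acc = noise[t].copy()
        for lag in range(p):
            acc += a[lag] @ x[t + p - 1 - lag]
        x[t + p] = acc
    data = x[p + BURN_IN :]
    states = chain[BURN_IN:]
    occ = np.array([(states == s).mean() for s in range(1, cfg.n_states + 1)])
    tcs = SubjectTimeCourses(
        subject_id=subject_id, data=data, component_names=cfg.component_names(), group=group
    )
    truth = SubjectTruth(subject_id=subject_id, states=states, couplings=couplings, occupancy=occ)
    return tcs, truth


def _clinical_row(rng, group: str, occ1: float, slope: float) -> dict[str, float]:
    # Linear-in-truth plus Gaussian noise; scales echo typical clinical ranges.
    patient = group == PATIENT
    hba1c = (10.6 if patient else 4.9) + 0.6 * slope * (occ1 - 0.7) + rng.normal(0.0, 0.6)
    moca = 27.6 - slope * (occ1 - 0.7) + rng.normal(0.0, 0.8)
    dbp = 71.0 + 2.0 * slope * (occ1 - 0.7) + rng.normal(0.0, 6.0)
    edu = 13.5 + rng.normal(0.0, 2.7)
    return {
        "HbA1c": max(round(float(hba1c), 2), 3.0),
        "MoCA": float(np.clip(round(moca), 0, 30)),
        "DBP": round(float(dbp), 1),
        "education": float(np.clip(round(edu), 0, 25)),
    }


def simulate_cohort(cfg: SimConfig, seed=None) -> Cohort:
    """Simulate the full two-group cohort plus clinical table and ground truth.

    Patients receive attenuated ``cfg.effect_edges`` in the state-1 coupling
    and their (optionally shifted) group stay probabilities; each subject's
    clinical row is tied linearly to that subject's true state-1 occupancy.
    """
    cfg.validate()
    root = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    n_pat, n_ctl = cfg.n_subjects
    n_total = n_pat + n_ctl
    child_seeds = root.spawn(n_total + 1)
    clin_rng = np.random.default_rng(child_seeds[-1])

    subjects: list[SubjectTimeCourses] = []
    truths: dict[str, SubjectTruth] = {}
    rows = []
    for i in range(n_total):
        group = PATIENT if i < n_pat else CONTROL
        sid = f"sub-{i + 1:03d}"
        tcs, truth = simulate_subject(cfg, group=group, seed=child_seeds[i], subject_id=sid)
        subjects.append(tcs)
        truths[sid] = truth
        row = {"subject_id": sid, "group": group}
        row.update(_clinical_row(clin_rng, group, truth.occupancy[0], cfg.clinical_coupling))
        rows.append(row)

    clinical = pd.DataFrame(rows)
    truth = GroundTruth(
        subjects=truths,
        group_couplings={g: cfg.group_couplings(g) for g in (PATIENT, CONTROL)},
        effect_edges=tuple(cfg.effect_edges),
        clinical_coefficients={
            "MoCA_vs_occ1": -cfg.clinical_coupling,
            "HbA1c_vs_occ1": 0.6 * cfg.clinical_coupling,
            "DBP_vs_occ1": 2.0 * cfg.clinical_coupling,
        },
        stay_probs={g: cfg.group_stay_probs(g) for g in (PATIENT, CONTROL)},
    )
    return Cohort(subjects=subjects, clinical=clinical, truth=truth)


def null_config(**overrides) -> SimConfig:
    """A config with all group effects switched off (exchangeable groups)."""
    cfg = SimConfig(**overrides)
    stay = cfg.stay_probs[CONTROL]
    return replace(cfg, effect_attenuation=0.0, stay_prob_shift=0.0,
                   stay_probs={PATIENT: stay, CONTROL: stay})
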