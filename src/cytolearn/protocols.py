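"""The four experiments: classification, turnover sweeps, pulsation, adaptation.

These orchestrate the training engine into the tasks the model is meant to
solve — classifying environmental strain gradients, learning through edge
turnover, self-organised learning via actomyosin-like pulsation, and
strain homeostasis (adaptation) — plus the parameter-sweep and
quantitative phase-classification machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .mechanochemistry import EventCounters
from .network import NetworkState, TaskGeometry, relax
from .params import ModelParams, steady_state
from .training import (
    DriveProtocol,
    LearningConfig,
    TrainingTrace,
    TrainingUnstableError,
    apply_source_strain,
    evaluate_response,
    prepare_free_state,
    run_cycles,
    train,
)
from .turnover import TurnoverConfig

__all__ = [
    "ClassificationTask",
    "gradient_input",
    "run_classification",
    "run_pulsation",
    "run_adaptation",
    "PhasePoint",
    "PhaseThresholds",
    "classify_phase",
    "sweep_phase_diagram",
]


# ----------------------------------------------------------------------
# classification of strain gradients
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationTask:
    """Two-class strain-gradient classification setup.

    Ten ordered source edges S1…S10 (ascending y) receive a strain pattern
    whose slope is drawn from U1 (positive class) or U2 (negative class);
    the network is trained to answer at one of two target edges with
    desired strains ϵT*(+) / ϵT*(−). A test is successful iff the matching
    target lands within E_tol of its set point *and* closer to it than the
    other target is to its own.
    """

    source_edges: tuple
    target_plus: int
    target_minus: int
    eps_target_plus: float = 0.25
    eps_target_minus: float = -0.25
    slope_dist_pos: tuple = (0.01, 0.1)
    slope_dist_neg: tuple = (-0.1, -0.01)
    noise_max: float = 0.2
    E_tol: float = 0.025
    noise_mode: str = "multiplicative"  # or "literal"

    def __post_init__(self) -> None:
        if self.E_tol <= 0:
            raise ValueError("E_tol must be > 0")
        if not (self.slope_dist_pos[0] > 0 and self.slope_dist_neg[1] < 0):
            raise ValueError("slope supports must be disjoint about 0")
        if self.target_plus in self.source_edges or self.target_minus in self.source_edges:
            raise ValueError("target edges must be distinct from all source edges")
        if self.noise_mode not in ("multiplicative", "literal"):
            raise ValueError("noise_mode must be 'multiplicative' or 'literal'")

    def as_geometry(self) -> TaskGeometry:
        n = len(self.source_edges)
        return TaskGeometry(
            source_edges=list(self.source_edges),
            target_edges=[self.target_plus, self.target_minus],
            eps_source=[0.0] * n,
            eps_target=[self.eps_target_plus, self.eps_target_minus],
        )


def gradient_input(
    task: ClassificationTask, sign: str, rng: np.random.Generator
) -> np.ndarray:
    """Draw one per-source strain pattern for the given class.

    Noiseless patterns: ϵS(n) = n·s (positive slope s from U1, strictly
    increasing across S1…S10) and ϵS(n) = 1 − (n−1)·s (s = |slope| from
    U2, strictly decreasing). The default noise convention scales the
    whole pattern by (1 + r), r ~ Uniform[0, noise_max]; ``literal`` mode
    instead multiplies the slope term by r directly.
    """
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    n = np.arange(1, len(task.source_edges) + 1, dtype=float)
    if sign == "+":
        s = rng.uniform(*task.slope_dist_pos)
    else:
        s = abs(rng.uniform(*task.slope_dist_neg))
    r = rng.uniform(0.0, task.noise_max) if task.noise_max > 0 else 0.0
    if task.noise_mode == "literal":
        s_eff = s * r if task.noise_max > 0 else s
        return n * s_eff if sign == "+" else 1.0 - (n - 1) * s_eff
    base = n * s if sign == "+" else 1.0 - (n - 1) * s
    return base * (1.0 + r)


def _repin_sources(state: NetworkState, task: TaskGeometry, strains,
                   params: ModelParams | None = None) -> NetworkState:
    """Impose a new source pattern quasi-statically.

    The environmental signal changes slowly compared with the drive, so
    the network is relaxed into the new free state and the chemistry
    re-equilibrated before the next clamp cycle; without this, the
    mechanical transient of the sudden re-pinning swamps the contrastive
    motor signal.
    """
    for e, eps in zip(task.source_edges, strains):
        apply_source_strain(state, e, eps)
    if params is not None:
        state = relax(state, params)
        ss = steady_state(params)
        state.motor[:] = ss.m0
        state.protein[:] = ss.n0
    state.prev_strain = state.strains()
    return state


def classification_accuracy(
    state: NetworkState,
    task: ClassificationTask,
    params: ModelParams,
    n_tests: int,
    rng: np.random.Generator,
) -> float:
    """Fraction of fresh held-out gradients the network classifies correctly."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    geo = task.as_geometry()
    successes = 0
    for _ in range(n_tests):
        sign = "+" if rng.random() < 0.5 else "-"
        strains = gradient_input(task, sign, rng)
        g = replace_sources(geo, strains)
        eps_p, eps_m = evaluate_response(state, g, params)
        d_p = abs(eps_p - task.eps_target_plus)
        d_m = abs(eps_m - task.eps_target_minus)
        if sign == "+":
            ok = d_p < task.E_tol and d_p < d_m
        else:
            ok = d_m < task.E_tol and d_m < d_p
        successes += int(ok)
    return successes / n_tests


def replace_sources(geo: TaskGeometry, strains) -> TaskGeometry:
    return TaskGeometry(
        source_edges=list(geo.source_edges),
        target_edges=list(geo.target_edges),
        eps_source=[float(x) for x in strains],
        eps_target=list(geo.eps_target),
        protected_edges=list(geo.protected_edges),
    )


def run_classification(
    state: NetworkState,
    task: ClassificationTask,
    params: ModelParams,
    protocol: DriveProtocol,
    config: LearningConfig,
    n_cycles: int,
    n_tests: int,
    seed: int = 0,
    eval_every: int = 10,
) -> tuple[NetworkState, TrainingTrace]:
    """Train the gradient classifier and track held-out accuracy.

    Each cycle draws a class at random, imposes a fresh strain gradient on
    the ten sources and drives only that class's target toward its set
    point. Every ``eval_every`` cycles the current network is tested on
    ``n_tests`` freshly drawn gradients; the accuracy trace is stored in
    ``trace.extras``.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    ss_train, ss_eval = np.random.SeedSequence([seed, 2]).spawn(2)
    rng_train = np.random.default_rng(ss_train)
    rng_eval = np.random.default_rng(ss_eval)
    geo = task.as_geometry()
    geo.validate_against(state)
    st = prepare_free_state(state, replace_sources(geo, gradient_input(task, "+", rng_train)), params)
    st.rng_seed = seed
    counters = EventCounters()
    n_t = len(geo.target_edges)
    errors = np.zeros((n_cycles, n_t))
    strains_rec = np.zeros((n_cycles, n_t))
    signs = np.empty(n_cycles, dtype="U1")
    eval_cycles, accuracies = [], []
    L0_start = st.rest_length.copy()
    for cycle in range(n_cycles):
        sign = "+" if rng_train.random() < 0.5 else "-"
        signs[cycle] = sign
        pattern = gradient_input(task, sign, rng_train)
        geo_c = replace_sources(geo, pattern)
        st = _repin_sources(st, geo_c, pattern, params)
        tr = run_cycles(
            st, geo_c, params, protocol, config, 1,
            active_targets=[0 if sign == "+" else 1], counters=counters,
        )
        errors[cycle] = tr.errors[0]
        strains_rec[cycle] = tr.target_strains[0]
        if (cycle + 1) % eval_every == 0 or cycle == n_cycles - 1:
            acc = classification_accuracy(st, task, params, n_tests, rng_eval)
            eval_cycles.append(cycle + 1)
            accuracies.append(acc)
    trace = TrainingTrace(
        errors=errors,
        target_strains=strains_rec,
        dL0=st.rest_length - L0_start,
        dk=np.zeros(st.n_edges),
        sever_events=np.zeros(n_cycles, dtype=int),
        reconnect_events=np.zeros(n_cycles, dtype=int),
        counters=counters.as_dict(),
        seed=seed,
        extras={
            "eval_cycles": eval_cycles,
            "accuracy": accuracies,
            "cycle_signs": signs.tolist(),
        },
    )
    return st, trace


# ----------------------------------------------------------------------
# self-organised pulsation
# ----------------------------------------------------------------------

def run_pulsation(
    state: NetworkState,
    task: TaskGeometry,
    params: ModelParams,
    protocol: DriveProtocol,
    config: LearningConfig,
    n_cycles: int,
    seed: int = 0,
) -> tuple[NetworkState, TrainingTrace]:
    """Drive the target edge with contractile pulses instead of a supervisor.

    ``pulsation_const``: fixed pulse amplitude A0 — the target strain
    drifts with training duration, no set point exists. ``pulsation_feedback``:
    amplitude a0·L follows the current edge length, a negative feedback
    (shorter edge ⇒ weaker pulse) that selects a finite emergent target
    strain. No desired strain enters the drive in either mode.
    """
    if protocol.mode not in ("pulsation_const", "pulsation_feedback"):
        raise ValueError("protocol.mode must be a pulsation mode")
    if len(task.target_edges) != 1:
        raise ValueError("pulsation drives a single target edge")
    task.validate_against(state)
    st = prepare_free_state(state, task, params)
    st.rng_seed = seed
    trace = run_cycles(st, task, params, protocol, config, n_cycles)
    return st, trace


# ----------------------------------------------------------------------
# adaptation / strain homeostasis
# ----------------------------------------------------------------------

def run_adaptation(
    state: NetworkState,
    task: TaskGeometry,
    params: ModelParams,
    protocol: DriveProtocol,
    config: LearningConfig,
    n_cycles: int,
    perturbation_schedule: dict | None = None,
    seed: int = 0,
) -> tuple[NetworkState, TrainingTrace]:
    """Continuous homeostatic training toward zero strain in a target region.

    The drive force is −λ(t)∇½ϵTi² per target edge: purely a function of
    the local target strain, so no external supervisor or set point is
    involved. ``perturbation_schedule`` maps cycle index → new per-source
    strain list, imposed at the start of that cycle; the trace records the
    transient rise and recovery of Σ|ϵTi| (stored per target in
    ``errors``; the adaptation error is their row-sum).
    """
    if protocol.mode != "adaptation":
        raise ValueError("protocol.mode must be 'adaptation'")
    if any(e != 0 for e in task.eps_target):
        raise ValueError("adaptation targets must have zero desired strain")
    task.validate_against(state)
    perturbation_schedule = perturbation_schedule or {}
    st = prepare_free_state(state, task, params)
    st.rng_seed = seed
    counters = EventCounters()
    chunks = []
    current = task
    start = 0
    boundaries = sorted(c for c in perturbation_schedule if 0 < c < n_cycles)
    for b in boundaries + [n_cycles]:
        if b > start:
            tr = run_cycles(st, current, params, protocol, config, b - start,
                            counters=counters)
            chunks.append(tr)
        if b < n_cycles:
            current = replace_sources(current, perturbation_schedule[b])
            st = _repin_sources(st, current, current.eps_source, params)
        start = b
    trace = TrainingTrace(
        errors=np.vstack([c.errors for c in chunks]),
        target_strains=np.vstack([c.target_strains for c in chunks]),
        dL0=sum((c.dL0 for c in chunks[1:]), chunks[0].dL0),
        dk=sum((c.dk for c in chunks[1:]), chunks[0].dk),
        sever_events=np.concatenate([c.sever_events for c in chunks]),
        reconnect_events=np.concatenate([c.reconnect_events for c in chunks]),
        counters=counters.as_dict(),
        seed=seed,
        extras={"perturbation_cycles": boundaries},
    )
    return st, trace


# ----------------------------------------------------------------------
# phase diagrams
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseThresholds:
    """Quantitative (configurable) criteria replacing by-eye phase labels."""

    e_learn: float = 0.2          # final error below this = learning
    delta_min: float = 1e-3       # max |ΔL0| below this = no remodeling at all
    length_collapse_frac: float = 0.1   # any edge shorter than this × initial
    dL0_frac: float = 0.5         # any |ΔL0|/L0_init above this = altered geometry


@dataclass
class PhasePoint:
    """One grid point of a sweep with its label and diagnostics."""

    coords: dict
    label: str
    diagnostics: dict = field(default_factory=dict)
    seed: int = 0


def classify_phase(
    diagnostics: dict, thresholds: PhaseThresholds, kind: str = "supervised"
) -> str:
    """Deterministic label from run diagnostics (pure function).

    ``supervised`` sweeps distinguish learning / loss_of_learning by the
    final training error. ``pulsation`` sweeps use geometry diagnostics:
    no remodeling at all → no_learning; collapsed or heavily rescaled
    edges → altered_geometry; otherwise conserved_geometry.
    """
    if diagnostics.get("aborted", False):
        return "altered_geometry" if kind == "pulsation" else "loss_of_learning"
    if kind == "supervised":
        err = diagnostics["final_error"]
        return "learning" if err < thresholds.e_learn else "loss_of_learning"
    if kind == "pulsation":
        if diagnostics["max_abs_dL0"] < thresholds.delta_min:
            return "no_learning"
        if (diagnostics["min_length_frac"] < thresholds.length_collapse_frac
                or diagnostics["max_dL0_frac"] > thresholds.dL0_frac):
            return "altered_geometry"
        return "conserved_geometry"
    raise ValueError("kind must be 'supervised' or 'pulsation'")


def pulsation_diagnostics(state: NetworkState, trace: TrainingTrace,
                          initial: NetworkState) -> dict:
    L = state.lengths()
    L_init = initial.lengths()
    L0_init = initial.rest_length
    return {
        "aborted": trace.aborted,
        "final_error": trace.final_error(),
        "final_target_strain": float(trace.target_strains[-1].sum()) if trace.n_cycles else float("nan"),
        "max_abs_dL0": float(np.abs(trace.dL0).max()),
        "max_dL0_frac": float(np.abs(trace.dL0 / L0_init).max()),
        "min_length_frac": float((L / np.maximum(L_init, 1e-12)).min()),
    }


def sweep_phase_diagram(
    axis1: tuple,
    axis2: tuple,
    runner,
    seeds=(0,),
    thresholds: PhaseThresholds | None = None,
    kind: str = "supervised",
) -> list[PhasePoint]:
    """Run ``runner`` over the grid axis1 × axis2 and label every point.

    ``axis1``/``axis2`` are (name, values); ``runner(coords: dict, seed)``
    must return a diagnostics dict (see `pulsation_diagnostics`). Failures
    of individual points are recorded (label from the aborted flag) and the
    sweep continues. Thresholds are part of the result, not hidden state:
    each point's diagnostics carry everything needed to re-label it.
    """
    thresholds = thresholds or PhaseThresholds()
    name1, vals1 = axis1
    name2, vals2 = axis2
    points = []
    for v1, v2, seed in itertools.product(vals1, vals2, seeds):
        coords = {name1: v1, name2: v2}
        try:
            diag = runner(coords, seed)
        except TrainingUnstableError as err:
            diag = {"aborted": True, "final_error": float("inf"),
                    "error_message": str(err)}
        label = classify_phase(diag, thresholds, kind)
        points.append(PhasePoint(coords=coords, label=label,
                                 diagnostics=diag, seed=seed))
    return points
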