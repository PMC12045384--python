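"""Contrastive free↔clamped driving and the local learning rules.

Training drives the network through sawtooth cycles of a clamp strength
λ(t): a fast linear ramp 0 → λmax over τf takes the system from the free
state (input imposed at the source, output unconstrained) to the clamped
state (target edge additionally nudged toward its desired strain), and a
slow ramp back over τs > τf returns it. Because the motor density carries
a zero-mean memory of the local strain (see mechanochemistry), the active
force fa = ξ·δm spikes during the fast ramp and responds only weakly
during the slow return; the threshold nonlinearity g rectifies this
asymmetry, so the learning degrees of freedom (rest length L0 or stiffness
k) integrate a signal proportional to the local free/clamped strain
difference — a physically local estimate of the contrastive gradient.

Learning rules (per unsevered edge):

* rest length: L̇0 = α · g(fa),     with g(x) = x for |x| ≥ gc else 0,
* stiffness:   k̇  = α · g(ϵ · fa).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mechanochemistry import (
    EventCounters,
    active_force,
    net_nodal_forces,
    step_motors,
    step_nodes,
    step_proteins,
)
from .network import NetworkState, TaskGeometry, relax
from .params import ModelParams, steady_state

__all__ = [
    "DriveProtocol",
    "LearningConfig",
    "TrainingTrace",
    "TrainingUnstableError",
    "lambda_of_t",
    "threshold_g",
    "clamp_force",
    "apply_source_strain",
    "release_source",
    "update_ldof",
    "training_error",
    "train",
    "run_cycles",
    "evaluate_response",
]

MODES = ("supervised", "pulsation_const", "pulsation_feedback", "adaptation")


@dataclass(frozen=True)
class DriveProtocol:
    """Sawtooth clamp schedule λ(t) and its mode.

    λ ramps linearly 0 → λmax over the fast time τf and back to 0 over the
    slow time τs; one cycle lasts τcyc = τf + τs. The fast/slow asymmetry
    (τf < τs) is what lets the thresholded learning rule rectify the
    motor-memory signal — a warning (not an error) is issued otherwise.

    In ``pulsation_const`` mode λmax = A0 is a plain contractile pulse
    amplitude; in ``pulsation_feedback`` the amplitude is a0·L, recomputed
    each step from the current target-edge length L.
    """

    tau_f: float = 1.0
    tau_s: float = 10.0
    lambda_max: float = 0.5
    mode: str = "supervised"
    A0: float = 0.5
    a0: float = 0.5

    def __post_init__(self) -> None:
        if self.tau_f <= 0 or self.tau_s <= 0:
            raise ValueError("tau_f and tau_s must be > 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.tau_f >= self.tau_s:
            import warnings

            warnings.warn(
                "tau_f >= tau_s: the fast/slow drive asymmetry is required for "
                "the contrastive mechanism; learning will likely fail",
                stacklevel=2,
            )

    @property
    def tau_cyc(self) -> float:
        return self.tau_f + self.tau_s

    def with_(self, **kwargs) -> "DriveProtocol":
        return replace(self, **kwargs)


def lambda_of_t(t: float, protocol: DriveProtocol) -> float:
    """Periodic sawtooth: 0 → λmax over τf, λmax → 0 over τs; λ(0) = 0."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    phase = np.asarray(t) % protocol.tau_cyc
    up = phase / protocol.tau_f
    down = 1.0 - (phase - protocol.tau_f) / protocol.tau_s
    lam = np.where(phase < protocol.tau_f, up, down) * protocol.lambda_max
    return float(lam) if np.isscalar(t) else lam


@dataclass(frozen=True)
class LearningConfig:
    """Learning rule selection, rate α and activation threshold gc.

    gc is the force (rest-length rule) or force·length (stiffness rule)
    scale below which no remodeling occurs; it must sit between the
    slow-ramp and fast-ramp active-force deviations for learning to work
    (see docs/methods.md for the calibration).
    """

    alpha: float = 1.0
    gc: float = 1e-5
    ldof: str = "rest_length"
    update_every: int = 1
    rest_length_floor_frac: float = 0.1
    # A driven edge's own remodeling chases the clamp and cancels the
    # neighbour-mediated contrastive signal (its rest length tracks the
    # clamped length, leaving the free-state strain unchanged); excluding
    # driven target edges from the learning rule removes that
    # self-cancellation. Flag-switchable for comparison.
    remodel_driven: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.gc < 0:
            raise ValueError("alpha and gc must be >= 0")
        if self.ldof not in ("rest_length", "stiffness"):
            raise ValueError("ldof must be 'rest_length' or 'stiffness'")
        if self.update_every < 1:
            raise ValueError("update_every must be >= 1")

    def with_(self, **kwargs) -> "LearningConfig":
        return replace(self, **kwargs)


def threshold_g(x, gc: float):
    """g(x) = x wherever |x| >= gc (boundary included), else 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) >= gc, x, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class TrainingTrace:
    """Per-cycle record of a training run — the test surface.

    ``errors[c, i]`` is the training error of target i at the end (free
    point) of cycle c; ``target_strains`` the raw strains there. ``dL0``
    and ``dk`` are final-minus-initial per-edge changes.
    """

    errors: np.ndarray            # (n_cycles, n_targets)
    target_strains: np.ndarray    # (n_cycles, n_targets)
    dL0: np.ndarray               # (E,)
    dk: np.ndarray                # (E,)
    sever_events: np.ndarray      # (n_cycles,)
    reconnect_events: np.ndarray  # (n_cycles,)
    counters: dict = field(default_factory=dict)
    seed: int = 0
    aborted: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.errors)

    def final_error(self, aggregate: str = "sum") -> float:
        """Error of the last completed cycle (summed over targets)."""
        if self.n_cycles == 0:
            return float("nan")
        last = self.errors[-1]
        return float(last.sum() if aggregate == "sum" else last.max())


class TrainingUnstableError(RuntimeError):
    """Raised when the explicit integration blows up; carries the partial trace."""

    def __init__(self, message: str, trace: TrainingTrace):
        super().__init__(message)
        self.trace = trace


# ----------------------------------------------------------------------
# forces and source clamps
# ----------------------------------------------------------------------

def clamp_force(
    state: NetworkState,
    target_edge: int,
    eps_target_desired: float,
    lam: float,
    mode: str = "supervised",
) -> tuple[np.ndarray, np.ndarray]:
    """External drive force on the two nodes of a target edge.

    supervised / adaptation: fe = −λ ∇ ½(ϵT − ϵT*)², i.e. equal-and-
    opposite axial forces of magnitude λ·|ϵT − ϵT*| directed to shrink the
    mismatch (for adaptation ϵT* ≡ 0 and the drive needs no set point).
    pulsation modes: a plain contractile axial force of magnitude λ.

    Returns (node_ids (2,), forces (2, 2)).
    """
    if state.severed[target_edge]:
        raise ValueError(f"target edge {target_edge} is severed")
    a, b = state.edges[target_edge]
    vec = state.positions[b] - state.positions[a]
    L = float(np.linalg.norm(vec))
    if L == 0:
        raise ValueError(f"target edge {target_edge} has zero length: direction undefined")
    unit_ab = vec / L  # from a toward b
    if mode in ("pulsation_const", "pulsation_feedback"):
        f_a = lam * unit_ab          # contractile: a pulled toward b
    elif mode == "adaptation":
        eps = L - state.rest_length[target_edge]
        f_a = lam * eps * unit_ab    # −λ ϵT ∇ϵT on node a
    else:
        eps = L - state.rest_length[target_edge]
        mismatch = eps - eps_target_desired
        f_a = lam * mismatch * unit_ab
    return np.array([a, b]), np.stack([f_a, -f_a])


def apply_source_strain(state: NetworkState, source_edge: int, eps_source: float) -> None:
    """Pin the source nodes so the edge carries exactly the imposed strain.

    The two nodes are placed along the edge's current axis, centred on the
    current midpoint, at separation L0 + ϵS*; both are marked pinned.
    Modifies ``state`` in place.
    """
    a, b = state.edges[source_edge]
    vec = state.positions[b] - state.positions[a]
    L = float(np.linalg.norm(vec))
    if L == 0:
        raise ValueError(f"source edge {source_edge} has zero length")
    unit = vec / L
    mid = 0.5 * (state.positions[a] + state.positions[b])
    half = 0.5 * (state.rest_length[source_edge] + eps_source)
    state.positions[a] = mid - half * unit
    state.positions[b] = mid + half * unit
    state.pinned[a] = True
    state.pinned[b] = True


def release_source(state: NetworkState, source_edge: int) -> None:
    """Unpin the two nodes of a source edge (restores free dynamics)."""
    a, b = state.edges[source_edge]
    state.pinned[a] = False
    state.pinned[b] = False


def update_ldof(
    state: NetworkState,
    config: LearningConfig,
    params: ModelParams,
    dt: float,
    m0: float | None = None,
    counters: EventCounters | None = None,
) -> None:
    """One Euler step of the learning rule on all unsevered edges (in place)."""
    if config.alpha == 0:
        return
    if m0 is None:
        m0 = steady_state(params).m0
    act = state.active_edges()
    fa = active_force(state.motor[act], params, m0)
    if config.ldof == "rest_length":
        dL0 = dt * config.alpha * threshold_g(fa, config.gc)
        new = state.rest_length[act] + dL0
        floor = config.rest_length_floor_frac * state.initial_rest_length[act]
        hit = new < floor
        if hit.any() and counters is not None:
            counters.rest_length_floors += int(hit.sum())
        state.rest_length[act] = np.maximum(new, floor)
    else:
        eps = state.strains()[act]
        dk = dt * config.alpha * threshold_g(eps * fa, config.gc)
        new = state.stiffness[act] + dk
        hit = new < 0
        if hit.any() and counters is not None:
            counters.stiffness_floors += int(hit.sum())
        state.stiffness[act] = np.maximum(new, 0.0)


def training_error(eps_t: float, eps_star: float) -> float:
    """|ϵT − ϵT*| / |ϵT*|; plain |ϵT| when the set point is zero."""
    if eps_star == 0:
        return abs(eps_t)
    return abs(eps_t - eps_star) / abs(eps_star)


# ----------------------------------------------------------------------
# the training engine
# ----------------------------------------------------------------------

def run_cycles(
    state: NetworkState,
    task: TaskGeometry,
    params: ModelParams,
    protocol: DriveProtocol,
    config: LearningConfig,
    n_cycles: int,
    turnover_config=None,
    rng: np.random.Generator | None = None,
    active_targets: list[int] | None = None,
    protein_order=1,
    counters: EventCounters | None = None,
    cycle_hook=None,
    step_hook=None,
    engine: str = "auto",
) -> TrainingTrace:
    """Drive ``state`` through ``n_cycles`` clamp cycles, learning as it goes.

    Mutates ``state``. ``active_targets`` selects which of the task's
    targets are driven this call (default: all) — used by the
    classification protocol, which drives one class's target per cycle.
    ``cycle_hook(cycle_index, state)`` runs at each free point.
    """
    from scipy.sparse import csr_matrix

    from .turnover import turnover_step  # local import to avoid cycle

    m0 = steady_state(params).m0
    counters = counters if counters is not None else EventCounters()
    n_targets = len(task.target_edges)
    if active_targets is None:
        active_targets = list(range(n_targets))
    dt = params.dt
    if dt * params.ku >= 1.0 or dt * params.kun0 >= 1.0:
        raise ValueError("dt too large for the chemical rates; reduce dt")
    steps = int(round(protocol.tau_cyc / dt))
    L0_start = state.rest_length.copy()
    k_start = state.stiffness.copy()
    errors = np.zeros((n_cycles, n_targets))
    strains = np.zeros((n_cycles, n_targets))
    sever_events = np.zeros(n_cycles, dtype=int)
    reconnect_events = np.zeros(n_cycles, dtype=int)

    def make_trace(completed: int, aborted: bool = False) -> TrainingTrace:
        return TrainingTrace(
            errors=errors[:completed].copy(),
            target_strains=strains[:completed].copy(),
            dL0=state.rest_length - L0_start,
            dk=state.stiffness - k_start,
            sever_events=sever_events[:completed].copy(),
            reconnect_events=reconnect_events[:completed].copy(),
            counters=counters.as_dict(),
            seed=state.rng_seed,
            aborted=aborted,
        )

    # --- fast path: jitted kernel (identical semantics; see _kernel) -----
    from . import _kernel

    if (engine in ("auto", "numba") and _kernel.HAVE_NUMBA
            and cycle_hook is None and step_hook is None):
        return _run_cycles_kernel(
            state, task, params, protocol, config, n_cycles,
            turnover_config, rng, active_targets, protein_order, counters,
            errors, strains, sever_events, reconnect_events, make_trace,
        )

    # --- precomputed structures for the inner loop ------------------------
    ne, nn = state.n_edges, state.n_nodes
    e0, e1 = state.edges[:, 0], state.edges[:, 1]
    rows = np.concatenate([e0, e1])
    cols = np.concatenate([np.arange(ne), np.arange(ne)])
    vals = np.concatenate([np.ones(ne), -np.ones(ne)])
    incidence = csr_matrix((vals, (rows, cols)), shape=(nn, ne))
    free_nodes = ~state.pinned
    mob = (dt / params.gamma)
    lam_sched = lambda_of_t(np.arange(steps) * dt, protocol)
    target_edge_ids = [task.target_edges[ti] for ti in active_targets]
    target_stars = [task.eps_target[ti] for ti in active_targets]
    ldof_mask = np.ones(ne, dtype=bool)
    if not config.remodel_driven:
        ldof_mask[target_edge_ids] = False
    pos = state.positions
    k2, k3 = params.k2, params.k3
    xi, beta = params.xi, params.beta
    kb0, kb1, ku = params.kb0, params.kb1, params.ku
    kbn, kun0 = params.kbn, params.kun0
    floor = config.rest_length_floor_frac * state.initial_rest_length
    alpha_dt = config.alpha * dt * config.update_every
    any_severed = bool(state.severed.any())
    if turnover_config is not None:
        if rng is None:
            raise ValueError("turnover requires an rng")
        if dt >= min(turnover_config.tau_sev, turnover_config.tau_con):
            raise ValueError("dt must be smaller than both turnover timescales")
        protected_mask = np.zeros(ne, dtype=bool)
        if len(task.protected_edges):
            protected_mask[np.asarray(task.protected_edges, dtype=int)] = True
        p_sev = dt / turnover_config.tau_sev
        p_con = dt / turnover_config.tau_con
        eps_crit = turnover_config.eps_crit
        magnitude_load = turnover_config.strain_convention == "magnitude"

    for cycle in range(n_cycles):
        for s in range(steps):
            vec = pos[e1] - pos[e0]
            L = np.sqrt(vec[:, 0] ** 2 + vec[:, 1] ** 2)
            eps = L - state.rest_length
            strain_rate = (eps - state.prev_strain) / dt
            state.prev_strain = eps
            # forces: elastic tension + active deviation, pull-together positive
            f_scalar = (state.stiffness * eps + xi * (state.motor - m0))
            if k2 or k3:
                f_scalar += k2 * eps**2 + k3 * eps**3
            if any_severed:
                f_scalar = np.where(state.severed, 0.0, f_scalar)
            unit = vec / np.maximum(L, 1e-300)[:, None]
            forces = incidence.dot(f_scalar[:, None] * unit)
            # external clamp drive on the active targets
            for edge, star in zip(target_edge_ids, target_stars):
                lam_ramp = lam_sched[s]
                if protocol.mode == "pulsation_feedback":
                    lam = (lam_ramp / protocol.lambda_max) * protocol.a0 * L[edge] \
                        if protocol.lambda_max > 0 else 0.0
                    f_a = lam * unit[edge]
                elif protocol.mode == "pulsation_const":
                    lam = (lam_ramp / protocol.lambda_max) * protocol.A0 \
                        if protocol.lambda_max > 0 else 0.0
                    f_a = lam * unit[edge]
                elif protocol.mode == "adaptation":
                    f_a = lam_ramp * eps[edge] * unit[edge]
                else:
                    f_a = lam_ramp * (eps[edge] - star) * unit[edge]
                forces[e0[edge]] += f_a
                forces[e1[edge]] -= f_a
            pos[free_nodes] += mob * forces[free_nodes]
            # chemistry (explicit Euler, severed edges frozen)
            if protein_order == "exact":
                fac = np.exp(-beta * strain_rate)
            elif protein_order == 3:
                fac = (1.0 - beta * strain_rate
                       + 0.5 * params.beta2 * strain_rate**2
                       - params.beta3 / 6.0 * strain_rate**3)
            else:
                fac = 1.0 - beta * strain_rate
            if protein_order != "exact":
                neg = fac < 0
                if neg.any():
                    counters.unbinding_clamps += int(neg.sum())
                    fac = np.maximum(fac, 0.0)
            dn = dt * (kbn - kun0 * fac * state.protein)
            dm = dt * (kb0 + kb1 * state.protein - ku * state.motor)
            if any_severed:
                dn = np.where(state.severed, 0.0, dn)
                dm = np.where(state.severed, 0.0, dm)
            state.protein += dn
            state.motor += dm
            neg = state.protein < 0
            if neg.any():
                counters.protein_clips += int(neg.sum())
                np.maximum(state.protein, 0.0, out=state.protein)
            neg = state.motor < 0
            if neg.any():
                counters.motor_clips += int(neg.sum())
                np.maximum(state.motor, 0.0, out=state.motor)
            # learning rule
            if config.alpha and (s + 1) % config.update_every == 0:
                fa = xi * (state.motor - m0)
                if config.ldof == "rest_length":
                    upd = np.where(np.abs(fa) >= config.gc, fa, 0.0)
                else:
                    x = eps * fa
                    upd = np.where(np.abs(x) >= config.gc, x, 0.0)
                upd[~ldof_mask] = 0.0
                if any_severed:
                    upd[state.severed] = 0.0
                if config.ldof == "rest_length":
                    new = state.rest_length + alpha_dt * upd
                    hit = new < floor
                    if hit.any():
                        counters.rest_length_floors += int(hit.sum())
                        new = np.maximum(new, floor)
                    state.rest_length = new
                else:
                    new = state.stiffness + alpha_dt * upd
                    hit = new < 0
                    if hit.any():
                        counters.stiffness_floors += int(hit.sum())
                        new = np.maximum(new, 0.0)
                    state.stiffness = new
            if turnover_config is not None:
                # inline turnover (same rules as turnover_step, reusing the
                # geometry already computed this step)
                draws = rng.random(ne)
                load = np.abs(eps) if magnitude_load else eps
                sever = ((~state.severed) & (~protected_mask)
                         & (load < eps_crit) & (draws < p_sev))
                reconnect = state.severed & (draws < p_con)  # pre-step severed only
                if sever.any():
                    state.severed |= sever
                    sever_events[cycle] += int(sever.sum())
                if reconnect.any():
                    Lre = np.sqrt(vec[reconnect, 0] ** 2 + vec[reconnect, 1] ** 2)
                    state.rest_length[reconnect] = np.maximum(Lre, 1e-12)
                    state.severed[reconnect] = False
                    state.prev_strain[reconnect] = 0.0
                    reconnect_events[cycle] += int(reconnect.sum())
                if sever.any() or reconnect.any():
                    any_severed = bool(state.severed.any())
            if step_hook is not None:
                step_hook(cycle, s, state)
        if not np.all(np.isfinite(pos)):
            raise TrainingUnstableError(
                "non-finite node position — dynamics unstable, reduce dt",
                make_trace(cycle, True),
            )
        # free point: λ(τcyc) = 0
        eps_now = state.strains()
        for ti, task_i in enumerate(range(n_targets)):
            e = task.target_edges[task_i]
            strains[cycle, ti] = eps_now[e]
            errors[cycle, ti] = training_error(eps_now[e], task.eps_target[task_i])
        if cycle_hook is not None:
            cycle_hook(cycle, state)
    state.positions = pos
    return make_trace(n_cycles)


def _run_cycles_kernel(
    state, task, params, protocol, config, n_cycles,
    turnover_config, rng, active_targets, protein_order, counters,
    errors, strains, sever_events, reconnect_events, make_trace,
):
    """Dispatch to the jitted engine (see _kernel.run_cycles_kernel)."""
    from ._kernel import run_cycles_kernel

    ne = state.n_edges
    m0 = steady_state(params).m0
    dt = params.dt
    steps = int(round(protocol.tau_cyc / dt))
    mode_id = {"supervised": 0, "pulsation_const": 1,
               "pulsation_feedback": 2, "adaptation": 3}[protocol.mode]
    order_id = 0 if protein_order == "exact" else int(protein_order)
    drive_edges = np.array([task.target_edges[t] for t in active_targets],
                           dtype=np.int64)
    drive_stars = np.array([task.eps_target[t] for t in active_targets])
    record_edges = np.asarray(task.target_edges, dtype=np.int64)
    record_stars = np.asarray(task.eps_target, dtype=float)
    ldof_mask = np.ones(ne, dtype=np.bool_)
    if not config.remodel_driven:
        ldof_mask[drive_edges] = False
    protected_mask = np.zeros(ne, dtype=np.bool_)
    turnover_on = turnover_config is not None
    if turnover_on:
        if rng is None:
            raise ValueError("turnover requires an rng")
        if dt >= min(turnover_config.tau_sev, turnover_config.tau_con):
            raise ValueError("dt must be smaller than both turnover timescales")
        if len(task.protected_edges):
            protected_mask[np.asarray(task.protected_edges, dtype=int)] = True
        p_sev = dt / turnover_config.tau_sev
        p_con = dt / turnover_config.tau_con
        eps_crit = turnover_config.eps_crit
        magnitude_load = turnover_config.strain_convention == "magnitude"
        rng_seed = int(rng.integers(0, 2**31 - 1))
    else:
        p_sev = p_con = eps_crit = 0.0
        magnitude_load = True
        rng_seed = 0
    floor = config.rest_length_floor_frac * state.initial_rest_length
    kcounters = np.zeros(5, dtype=np.int64)
    completed, aborted = run_cycles_kernel(
        state.positions, state.edges[:, 0].astype(np.int64),
        state.edges[:, 1].astype(np.int64),
        state.stiffness, state.rest_length, state.motor, state.protein,
        state.prev_strain, state.severed, ~state.pinned, floor,
        params.gamma, params.xi, params.kb0, params.kb1, params.ku,
        params.kbn, params.kun0, params.beta, params.beta2, params.beta3,
        params.k2, params.k3, dt, m0,
        protocol.tau_f, protocol.tau_s, protocol.lambda_max, mode_id,
        protocol.A0, protocol.a0,
        config.alpha, config.gc, config.ldof == "stiffness",
        config.update_every, ldof_mask, drive_edges, drive_stars,
        record_edges, record_stars,
        turnover_on, p_sev, p_con, eps_crit, magnitude_load, protected_mask,
        n_cycles, steps, order_id, rng_seed,
        errors, strains, sever_events, reconnect_events, kcounters,
    )
    counters.motor_clips += int(kcounters[0])
    counters.protein_clips += int(kcounters[1])
    counters.unbinding_clamps += int(kcounters[2])
    counters.rest_length_floors += int(kcounters[3])
    counters.stiffness_floors += int(kcounters[4])
    if aborted:
        raise TrainingUnstableError(
            "non-finite node position — dynamics unstable, reduce dt",
            make_trace(completed, True),
        )
    return make_trace(n_cycles)


def calibrate_threshold(
    state: NetworkState,
    task: TaskGeometry,
    params: ModelParams,
    protocol: DriveProtocol,
    frac: float = 0.1,
    probe_cycles: int = 2,
) -> float:
    """Pick gc from a no-learning probe of the drive.

    Runs a few clamp cycles with the learning rate set to zero and
    measures the peak active-force deviation |fa| over all non-driven
    edges; gc = ``frac`` × that peak. Because every signal in the
    contrastive mechanism scales linearly with the free/clamped target
    mismatch, the training stall sets in when the mismatch has dropped to
    roughly ``frac`` of its initial value, independent of how strongly
    this particular network couples source to target.
    """
    st = prepare_free_state(state, task, params)
    m0 = steady_state(params).m0
    driven = np.asarray(task.target_edges, dtype=int)
    peak = 0.0

    def hook(cycle, s, stt):
        nonlocal peak
        if cycle < probe_cycles - 1:
            return  # first cycle still carries the start-up transient
        fa = params.xi * (stt.motor - m0)
        fa[driven] = 0.0
        peak = max(peak, float(np.abs(fa).max()))

    run_cycles(st, task, params, protocol,
               LearningConfig(alpha=0.0, gc=0.0), probe_cycles, step_hook=hook)
    if peak == 0.0:
        raise RuntimeError("no contrastive signal in probe (activity or drive off?)")
    return frac * peak


def prepare_free_state(
    state: NetworkState, task: TaskGeometry, params: ModelParams
) -> NetworkState:
    """Pin the sources at their imposed strains and relax into the free state.

    Chemistry is re-equilibrated (densities at steady state, strain-rate
    cache zeroed) so training starts without a spurious transient from the
    sudden source imposition.
    """
    st = state.copy()
    for e, eps in zip(task.source_edges, task.eps_source):
        apply_source_strain(st, e, eps)
    st = relax(st, params)
    ss = steady_state(params)
    st.motor[:] = ss.m0
    st.protein[:] = ss.n0
    st.prev_strain = st.strains()
    return st


def train(
    state: NetworkState,
    task: TaskGeometry,
    params: ModelParams,
    protocol: DriveProtocol,
    config: LearningConfig,
    n_cycles: int,
    turnover_config=None,
    seed: int = 0,
    protein_order=1,
    raise_on_instability: bool = True,
) -> tuple[NetworkState, TrainingTrace]:
    """Full supervised training run; returns (trained state, trace).

    The input strains are imposed at the sources (hard pins), the network
    is relaxed into the free state, and then driven through ``n_cycles``
    contrastive clamp cycles with the learning rule active throughout.
    Fully reproducible from ``seed`` (which drives turnover only).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    task.validate_against(state)
    st = prepare_free_state(state, task, params)
    st.rng_seed = seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    try:
        trace = run_cycles(
            st, task, params, protocol, config, n_cycles,
            turnover_config=turnover_config, rng=rng, protein_order=protein_order,
        )
    except TrainingUnstableError as err:
        if raise_on_instability:
            raise
        return st, err.trace
    return st, trace


def evaluate_response(
    state: NetworkState, task: TaskGeometry, params: ModelParams
) -> np.ndarray:
    """Free-state target strains of (a copy of) the network.

    Applies the task's source strains, relaxes to mechanical equilibrium
    (no clamp anywhere) and returns the strain at each target edge. This
    is the test-time readout used to compare trained vs untrained networks.
    """
    st = state.copy()
    st.pinned[:] = False
    for e, eps in zip(task.source_edges, task.eps_source):
        apply_source_strain(st, e, eps)
    relaxed = relax(st, params)
    eps = relaxed.strains()
    return eps[np.asarray(task.target_edges, dtype=int)]
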