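"""Coupled node / motor / protein dynamics and the linear-response memory kernel.

The three fields evolve by explicit Euler with a shared time step:

* node positions — overdamped: γ ṙ_j = Σ_k (elastic tension + active force) r̂_{j→k} + f_ext,
* motor density  — ṁ = kb0 + kb1 n − ku m (proteins recruit motors),
* protein density — ṅ = kbn − kun0 e^{−β ϵ̇} n (catch bond: stretching
  lowers unbinding, so n transiently tracks the local strain rate).

Linearising the chain ϵ̇ → n → m shows that the motor density carries an
implicit memory of the local strain, δm(t) = ∫ K(t−t') δϵ(t') dt' with the
zero-mean kernel K(u) = β1 (δ(u) − e^{−u/τk}/τk), τk = ku⁻¹ and
β1 = kb1·β·n0. `estimate_memory_kernel` recovers (τk, β1) from a simulated
single edge and is checked against those identities in the tests.

The active force is measured relative to the chemical steady state,
fa = ξ·(m − m0): the baseline contraction ξ·m0 is balanced by pre-stress
absorbed into the nondimensionalised reference state, so an unperturbed
network is force-free (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .network import NetworkState
from .params import ModelParams, SteadyState, steady_state

__all__ = [
    "EventCounters",
    "MemoryKernelEstimate",
    "edge_tension",
    "active_force",
    "step_nodes",
    "step_motors",
    "step_proteins",
    "simulate_edge_chemistry",
    "estimate_memory_kernel",
]


@dataclass
class EventCounters:
    """Counts of numerical guard events during a run."""

    motor_clips: int = 0
    protein_clips: int = 0
    unbinding_clamps: int = 0   # order-1 factor went negative
    rest_length_floors: int = 0
    stiffness_floors: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def edge_tension(eps, k, k2: float = 0.0, k3: float = 0.0):
    """Elastic restoring magnitude dE/dϵ = k ϵ + k2 ϵ² + k3 ϵ³.

    Positive tension pulls the two end nodes together. Works elementwise
    on arrays.
    """
    return k * eps + k2 * eps**2 + k3 * eps**3


def active_force(motor, params: ModelParams, m0: float | None = None):
    """Contractile active force fa = ξ·(m − m0) on an edge.

    Motor contractility pulls the end nodes together in proportion to the
    bound motor density; the force is measured relative to the resting
    density m0, whose uniform baseline contraction is balanced by the
    reference-state pre-stress. Negative values (motor depletion below
    rest) push the learning signal in the opposite direction.
    """
    if m0 is None:
        m0 = steady_state(params).m0
    return params.xi * (np.asarray(motor) - m0)


def _pair_forces(state: NetworkState, params: ModelParams, m0: float) -> np.ndarray:
    """Scalar pull-together force per edge (0 on severed edges)."""
    eps = state.strains()
    f = edge_tension(eps, state.stiffness, params.k2, params.k3)
    f = f + active_force(state.motor, params, m0)
    f[state.severed] = 0.0
    return f


def net_nodal_forces(
    state: NetworkState,
    params: ModelParams,
    external_forces: np.ndarray | None = None,
    m0: float | None = None,
) -> np.ndarray:
    """(N, 2) net force on every node (elastic + active + external)."""
    if m0 is None:
        m0 = steady_state(params).m0
    f_scalar = _pair_forces(state, params, m0)
    vec = state.edge_vectors()
    L = np.linalg.norm(vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(L[:, None] > 0, vec / L[:, None], 0.0)
    forces = np.zeros_like(state.positions)
    contrib = f_scalar[:, None] * unit
    np.add.at(forces, state.edges[:, 0], contrib)   # pulls node j toward k
    np.add.at(forces, state.edges[:, 1], -contrib)
    if external_forces is not None:
        forces = forces + external_forces
    return forces


def step_nodes(
    state: NetworkState,
    params: ModelParams,
    external_forces: np.ndarray | None = None,
    dt: float | None = None,
    m0: float | None = None,
) -> np.ndarray:
    """One explicit-Euler step of the overdamped node dynamics (in place).

    Pinned nodes do not move. Updates the strain-rate cache: ϵ̇ is the
    backward difference of ϵ = L − L0 over this step. Returns the per-edge
    strain rates.
    """
    dt = params.dt if dt is None else dt
    forces = net_nodal_forces(state, params, external_forces, m0)
    move = ~state.pinned
    state.positions[move] += (dt / params.gamma) * forces[move]
    if not np.all(np.isfinite(state.positions)):
        bad = np.where(~np.isfinite(state.positions).all(axis=1))[0]
        raise FloatingPointError(
            f"non-finite position at node(s) {bad.tolist()} — dynamics unstable, reduce dt"
        )
    eps = state.strains()
    strain_rate = (eps - state.prev_strain) / dt
    state.prev_strain = eps
    return strain_rate


def step_motors(
    state: NetworkState,
    params: ModelParams,
    dt: float | None = None,
    counters: EventCounters | None = None,
) -> np.ndarray:
    """Euler step of ṁ = kb0 + kb1 n − ku m on unsevered edges (in place)."""
    dt = params.dt if dt is None else dt
    if dt * params.ku >= 1.0:
        raise ValueError(
            f"dt*ku = {dt * params.ku:.3g} >= 1: motor update unstable, reduce dt"
        )
    act = state.active_edges()
    m = state.motor
    dm = dt * (params.kb0 + params.kb1 * state.protein[act] - params.ku * m[act])
    new = m[act] + dm
    neg = new < 0
    if neg.any():
        if counters is not None:
            counters.motor_clips += int(neg.sum())
        new = np.maximum(new, 0.0)
    m[act] = new
    return m


def unbinding_factor(strain_rate, params: ModelParams, order,
                     counters: EventCounters | None = None):
    """Multiplier on the protein unbinding rate kun0.

    order = "exact": e^{−β ϵ̇};  order = 1: 1 − β ϵ̇ (clamped at 0);
    order = 3: 1 − β ϵ̇ + (β2/2) ϵ̇² − (β3/6) ϵ̇³ with independently
    configurable β2, β3.
    """
    ed = np.asarray(strain_rate, dtype=float)
    if order == "exact":
        return np.exp(-params.beta * ed)
    if order == 1:
        fac = 1.0 - params.beta * ed
    elif order == 3:
        fac = (1.0 - params.beta * ed + 0.5 * params.beta2 * ed**2
               - params.beta3 / 6.0 * ed**3)
    else:
        raise ValueError("order must be 1, 3 or 'exact'")
    neg = fac < 0
    if np.any(neg):
        if counters is not None:
            counters.unbinding_clamps += int(np.sum(neg))
        fac = np.maximum(fac, 0.0)
    return fac


def step_proteins(
    state: NetworkState,
    params: ModelParams,
    strain_rate: np.ndarray,
    dt: float | None = None,
    order=1,
    counters: EventCounters | None = None,
) -> np.ndarray:
    """Euler step of ṅ = kbn − kun0·u(ϵ̇)·n on unsevered edges (in place)."""
    dt = params.dt if dt is None else dt
    act = state.active_edges()
    fac = unbinding_factor(strain_rate, params, order, counters)
    fac = np.broadcast_to(np.asarray(fac, dtype=float), (state.n_edges,))
    n = state.protein
    dn = dt * (params.kbn - params.kun0 * fac[act] * n[act])
    new = n[act] + dn
    neg = new < 0
    if neg.any():
        if counters is not None:
            counters.protein_clips += int(neg.sum())
        new = np.maximum(new, 0.0)
    n[act] = new
    return n


# ----------------------------------------------------------------------
# memory kernel
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MemoryKernelEstimate:
    """Fitted parameters of K(u) = β1 (δ(u) − e^{−u/τk}/τk)."""

    tau_k: float
    beta1: float
    fit_residual: float

    def __post_init__(self) -> None:
        if self.tau_k <= 0:
            raise ValueError("tau_k must be > 0")


def simulate_edge_chemistry(
    params: ModelParams,
    strain: np.ndarray,
    dt: float | None = None,
    order=1,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a single edge's (n, m) under a prescribed strain series.

    Returns (m(t), n(t)) sampled at the same instants as ``strain``; the
    chemistry starts from its steady state.
    """
    dt = params.dt if dt is None else dt
    ss = steady_state(params)
    nsteps = len(strain)
    m = np.empty(nsteps)
    n = np.empty(nsteps)
    m[0], n[0] = ss.m0, ss.n0
    eps_dot = np.diff(strain) / dt
    fac = np.broadcast_to(unbinding_factor(eps_dot, params, order), (nsteps - 1,))
    kbn, kun0, kb0, kb1, ku = params.kbn, params.kun0, params.kb0, params.kb1, params.ku
    for i in range(1, nsteps):
        n[i] = n[i - 1] + dt * (kbn - kun0 * fac[i - 1] * n[i - 1])
        m[i] = m[i - 1] + dt * (kb0 + kb1 * n[i - 1] - ku * m[i - 1])
    return m, n


def _kernel_response(delta_eps: np.ndarray, dt: float, tau_k: float, beta1: float) -> np.ndarray:
    """δm(t) = β1 [δϵ(t) − (1/τk) ∫ e^{−(t−t')/τk} δϵ(t') dt']."""
    n = len(delta_eps)
    # exact discrete recursion for the exponential moving integral
    decay = np.exp(-dt / tau_k)
    conv = np.empty(n)
    conv[0] = 0.0
    for i in range(1, n):
        conv[i] = decay * conv[i - 1] + (1.0 - decay) * delta_eps[i]
    return beta1 * (delta_eps - conv)


def estimate_memory_kernel(
    params: ModelParams,
    strain_protocol: np.ndarray,
    dt: float | None = None,
    residual_threshold: float = 0.2,
) -> MemoryKernelEstimate:
    """Fit the single-exponential memory kernel to a simulated edge.

    Simulates the order-1 chemistry of one edge under the prescribed
    small-amplitude strain protocol and least-squares fits δm(t) to the
    convolution form with free parameters (τk, β1). The analytic values
    are τk = ku⁻¹ and β1 = kb1·β·n0 (exact in the limit of fast protein
    kinetics, kun0 ≫ ku).
    """
    dt = params.dt if dt is None else dt
    strain = np.asarray(strain_protocol, dtype=float)
    m, _ = simulate_edge_chemistry(params, strain, dt=dt, order=1)
    ss = steady_state(params)
    delta_m = m - ss.m0
    delta_eps = strain - strain[0]
    scale = np.abs(delta_m).max()
    if scale == 0:
        # constant strain: the zero-mean kernel gives no response at all
        return MemoryKernelEstimate(tau_k=1.0 / params.ku,
                                    beta1=params.kb1 * params.beta * ss.n0,
                                    fit_residual=0.0)

    def resid(theta):
        tau_k, beta1 = np.exp(theta[0]), theta[1]
        return (_kernel_response(delta_eps, dt, tau_k, beta1) - delta_m) / scale

    x0 = np.array([np.log(1.0 / params.ku), params.kb1 * params.beta * ss.n0])
    # start the solver away from the analytic answer so the fit is a real test
    sol = least_squares(resid, x0 * [1.5, 0.5], method="lm")
    tau_k, beta1 = float(np.exp(sol.x[0])), float(sol.x[1])
    residual = float(np.sqrt(np.mean(sol.fun**2)))
    if residual > residual_threshold:
        raise RuntimeError(
            f"kernel fit residual {residual:.3g} exceeds {residual_threshold}: "
            "protocol amplitude too large or dt too coarse"
        )
    return MemoryKernelEstimate(tau_k=tau_k, beta1=beta1, fit_residual=residual)
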