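"""Model parameters for the active mechanochemical network.

All quantities are in rescaled (nondimensional) units: the friction
coefficient gamma sets the unit of time together with the edge stiffness
(gamma/k is the local relaxation time), the mean initial rest length sets
the unit of length, and k times the unit length sets the unit of force.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class ModelParams:
    """Rate and mechanics constants of the coupled node/motor/protein dynamics.

    Parameters
    ----------
    gamma : float
        Friction coefficient of the overdamped node dynamics (force·time/length).
    xi : float
        Contractility (activity): active edge force per unit bound-motor density.
    kb0, kb1, ku : float
        Motor bare binding rate, protein-promoted binding coefficient (per unit
        protein density) and unbinding rate (1/time).
    kbn, kun0 : float
        Mechanosensitive-protein bare binding and unbinding rates (1/time).
    beta : float
        Strain-rate sensitivity of protein unbinding (time/length); the
        unbinding rate is kun0·exp(−beta·strain_rate) — a catch bond: faster
        stretching stabilises the bound protein.
    beta2, beta3 : float
        Independent coefficients of the quadratic and cubic terms in the
        third-order expansion of the unbinding factor (default 0 = linear).
    k2, k3 : float
        Nonlinear elastic coefficients: edge energy
        E = k ϵ²/2 + k2 ϵ³/3 + k3 ϵ⁴/4 (default 0 = Hookean).
    dt : float
        Explicit-Euler time step shared by all three fields.
    """

    gamma: float = 1.0
    xi: float = 0.5
    kb0: float = 0.2
    kb1: float = 0.3
    ku: float = 0.5
    kbn: float = 5.0
    kun0: float = 5.0
    beta: float = 0.1
    beta2: float = 0.0
    beta3: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        for name in ("gamma", "ku", "kun0", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("kb0", "kb1", "kbn", "xi", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SteadyState:
    """Resting motor and protein densities (strain rate = 0)."""

    m0: float
    n0: float


def steady_state(params: ModelParams) -> SteadyState:
    """Fixed point of the chemistry at zero strain rate.

    Setting the protein equation to zero gives n0 = kbn/kun0; inserting n0
    into the motor equation gives m0 = (kb0 + kb1·n0)/ku.
    """
    n0 = params.kbn / params.kun0
    m0 = (params.kb0 + params.kb1 * n0) / params.ku
    return SteadyState(m0=m0, n0=n0)
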