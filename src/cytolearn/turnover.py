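"""Stochastic severing and reconnection of edges during training.

Cytoskeletal bundles turn over continuously; here that is caricatured by
two Poisson processes per edge. An intact, unprotected edge with strain
below a critical value ϵ < ϵcrit severs with probability dt/τsev per step
(edges under larger strain are stabilised — catch-bond-like), and a
severed edge reconnects the *same* node pair with probability dt/τcon,
taking the instantaneous node distance as its new rest length (strain
exactly 0 on reconnection). A severed edge exerts no force and its
motor/protein densities are frozen (optionally reset to steady state).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import NetworkState
from .params import ModelParams, steady_state

__all__ = ["TurnoverConfig", "turnover_step"]


@dataclass(frozen=True)
class TurnoverConfig:
    """Severing/reconnection timescales and the critical strain.

    Both timescales must exceed the driving cycle period τcyc — turnover
    faster than the drive destroys learning regardless of their ratio.
    """

    tau_sev: float
    tau_con: float
    eps_crit: float = 0.01
    chemistry_on_sever: str = "freeze"  # or "reset"
    tau_cyc: float | None = None        # if given, validates the timescale ordering
    # which edges are protected from severing: "magnitude" spares every
    # loaded edge (|ϵ| ≥ ϵcrit, tensed or compressed — load stabilises the
    # bond), "signed" spares only tensed edges (ϵ ≥ ϵcrit). Under "signed"
    # the compressed edges that store a contraction-trained network's
    # memory keep severing and learning cannot survive turnover.
    strain_convention: str = "magnitude"

    def __post_init__(self) -> None:
        if self.tau_sev <= 0 or self.tau_con <= 0:
            raise ValueError("tau_sev and tau_con must be > 0")
        if self.eps_crit < 0:
            raise ValueError("eps_crit must be >= 0")
        if self.chemistry_on_sever not in ("freeze", "reset"):
            raise ValueError("chemistry_on_sever must be 'freeze' or 'reset'")
        if self.strain_convention not in ("magnitude", "signed"):
            raise ValueError("strain_convention must be 'magnitude' or 'signed'")
        if self.tau_cyc is not None and min(self.tau_sev, self.tau_con) <= self.tau_cyc:
            raise ValueError(
                "severing and reconnection timescales must exceed the drive period tau_cyc"
            )

    def with_(self, **kwargs) -> "TurnoverConfig":
        return replace(self, **kwargs)


def turnover_step(
    state: NetworkState,
    config: TurnoverConfig,
    dt: float,
    rng: np.random.Generator,
    protected=(),
    params: ModelParams | None = None,
) -> tuple[int, int]:
    """One stochastic turnover update (in place); returns (#sever, #reconnect)."""
    if dt >= min(config.tau_sev, config.tau_con):
        raise ValueError("dt must be smaller than both turnover timescales")
    protected_mask = np.zeros(state.n_edges, dtype=bool)
    if len(protected):
        protected_mask[np.asarray(protected, dtype=int)] = True
    draws = rng.random(state.n_edges)

    eps = state.strains()
    load = np.abs(eps) if config.strain_convention == "magnitude" else eps
    eligible = (~state.severed) & (~protected_mask) & (load < config.eps_crit)
    sever = eligible & (draws < dt / config.tau_sev)
    if sever.any():
        state.severed[sever] = True
        if config.chemistry_on_sever == "reset":
            ss = steady_state(params or ModelParams())
            state.motor[sever] = ss.m0
            state.protein[sever] = ss.n0

    reconnect = state.severed & (~sever) & (draws < dt / config.tau_con)
    if reconnect.any():
        L = state.lengths()[reconnect]
        state.rest_length[reconnect] = np.maximum(L, 1e-12)
        state.severed[reconnect] = False
        state.prev_strain[reconnect] = 0.0  # strain-rate restart: first step uses 0
    return int(sever.sum()), int(reconnect.sum())
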