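"""Jitted inner loop of the training engine.

This mirrors the (reference) numpy loop in `training.run_cycles` operation
for operation; a parity test keeps the two paths consistent. On a single
core the per-step numpy call overhead dominates for the ~10²-edge patches
this package targets, and the compiled loop is ~20× faster.

Stochastic turnover uses numba's legacy np.random stream seeded per run:
deterministic for a fixed seed, but a *different* stream than the numpy
engine path — choose one engine when comparing stochastic runs bit-for-bit.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]

MODE_SUPERVISED = 0
MODE_PULSE_CONST = 1
MODE_PULSE_FEEDBACK = 2
MODE_ADAPTATION = 3

# counter slots
C_MOTOR_CLIP = 0
C_PROTEIN_CLIP = 1
C_UNBIND_CLAMP = 2
C_RL_FLOOR = 3
C_K_FLOOR = 4


@njit(cache=True)
def run_cycles_kernel(
    pos, e0, e1, stiffness, rest_length, motor, protein, prev_strain,
    severed, free_node, floor,
    gamma, xi, kb0, kb1, ku, kbn, kun0, beta, beta2, beta3, k2, k3, dt, m0,
    tau_f, tau_s, lambda_max, mode_id, A0, a0,
    alpha, gc, ldof_is_stiffness, update_every,
    ldof_mask,
    drive_edges, drive_stars,
    record_edges, record_stars,
    turnover_on, p_sev, p_con, eps_crit, magnitude_load, protected_mask,
    n_cycles, steps, protein_order_id, rng_seed,
    errors, strains_out, sever_events, reconnect_events, counters,
):
    ne = e0.shape[0]
    nn = pos.shape[0]
    np.random.seed(rng_seed)
    tau_cyc = tau_f + tau_s
    mob = dt / gamma
    eps = np.zeros(ne)
    unit = np.zeros((ne, 2))
    forces = np.zeros((nn, 2))
    alpha_dt = alpha * dt * update_every
    nonlinear = (k2 != 0.0) or (k3 != 0.0)
    for cycle in range(n_cycles):
        for s in range(steps):
            # geometry + strain rate
            for e in range(ne):
                dx = pos[e1[e], 0] - pos[e0[e], 0]
                dy = pos[e1[e], 1] - pos[e0[e], 1]
                L = np.sqrt(dx * dx + dy * dy)
                if L > 0.0:
                    unit[e, 0] = dx / L
                    unit[e, 1] = dy / L
                else:
                    unit[e, 0] = 0.0
                    unit[e, 1] = 0.0
                eps[e] = L - rest_length[e]
            # forces
            for i in range(nn):
                forces[i, 0] = 0.0
                forces[i, 1] = 0.0
            for e in range(ne):
                if severed[e]:
                    continue
                f = stiffness[e] * eps[e] + xi * (motor[e] - m0)
                if nonlinear:
                    f += k2 * eps[e] * eps[e] + k3 * eps[e] ** 3
                fx = f * unit[e, 0]
                fy = f * unit[e, 1]
                forces[e0[e], 0] += fx
                forces[e0[e], 1] += fy
                forces[e1[e], 0] -= fx
                forces[e1[e], 1] -= fy
            # external drive
            phase = (s * dt) % tau_cyc
            if phase < tau_f:
                ramp01 = phase / tau_f
            else:
                ramp01 = 1.0 - (phase - tau_f) / tau_s
            for t in range(drive_edges.shape[0]):
                e = drive_edges[t]
                L_e = eps[e] + rest_length[e]
                if mode_id == MODE_PULSE_CONST:
                    lam_f = ramp01 * A0
                elif mode_id == MODE_PULSE_FEEDBACK:
                    lam_f = ramp01 * a0 * L_e
                elif mode_id == MODE_ADAPTATION:
                    lam_f = ramp01 * lambda_max * eps[e]
                else:
                    lam_f = ramp01 * lambda_max * (eps[e] - drive_stars[t])
                fx = lam_f * unit[e, 0]
                fy = lam_f * unit[e, 1]
                forces[e0[e], 0] += fx
                forces[e0[e], 1] += fy
                forces[e1[e], 0] -= fx
                forces[e1[e], 1] -= fy
            # node update
            for i in range(nn):
                if free_node[i]:
                    pos[i, 0] += mob * forces[i, 0]
                    pos[i, 1] += mob * forces[i, 1]
            # chemistry (uses the strain rate of the *previous* geometry step,
            # matching the reference engine)
            for e in range(ne):
                rate = (eps[e] - prev_strain[e]) / dt
                prev_strain[e] = eps[e]
                if severed[e]:
                    continue
                if protein_order_id == 0:
                    fac = np.exp(-beta * rate)
                elif protein_order_id == 3:
                    fac = (1.0 - beta * rate + 0.5 * beta2 * rate * rate
                           - beta3 / 6.0 * rate ** 3)
                else:
                    fac = 1.0 - beta * rate
                if protein_order_id != 0 and fac < 0.0:
                    counters[C_UNBIND_CLAMP] += 1
                    fac = 0.0
                n_old = protein[e]
                protein[e] += dt * (kbn - kun0 * fac * n_old)
                if protein[e] < 0.0:
                    counters[C_PROTEIN_CLIP] += 1
                    protein[e] = 0.0
                motor[e] += dt * (kb0 + kb1 * n_old - ku * motor[e])
                if motor[e] < 0.0:
                    counters[C_MOTOR_CLIP] += 1
                    motor[e] = 0.0
            # learning rule
            if alpha != 0.0 and (s + 1) % update_every == 0:
                for e in range(ne):
                    if severed[e] or not ldof_mask[e]:
                        continue
                    fa = xi * (motor[e] - m0)
                    if ldof_is_stiffness:
                        x = eps[e] * fa
                        if x >= gc or x <= -gc:
                            stiffness[e] += alpha_dt * x
                            if stiffness[e] < 0.0:
                                counters[C_K_FLOOR] += 1
                                stiffness[e] = 0.0
                    else:
                        if fa >= gc or fa <= -gc:
                            rest_length[e] += alpha_dt * fa
                            if rest_length[e] < floor[e]:
                                counters[C_RL_FLOOR] += 1
                                rest_length[e] = floor[e]
            # turnover
            if turnover_on:
                for e in range(ne):
                    u = np.random.random()
                    if severed[e]:
                        if u < p_con:
                            dx = pos[e1[e], 0] - pos[e0[e], 0]
                            dy = pos[e1[e], 1] - pos[e0[e], 1]
                            L = np.sqrt(dx * dx + dy * dy)
                            rest_length[e] = L if L > 1e-12 else 1e-12
                            severed[e] = False
                            prev_strain[e] = 0.0
                            reconnect_events[cycle] += 1
                    else:
                        if protected_mask[e]:
                            continue
                        load = abs(eps[e]) if magnitude_load else eps[e]
                        if load < eps_crit and u < p_sev:
                            severed[e] = True
                            sever_events[cycle] += 1
        # cycle end: check stability, record free-point errors
        ok = True
        for i in range(nn):
            if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])):
                ok = False
        if not ok:
            return cycle, 1
        for t in range(record_edges.shape[0]):
            e = record_edges[t]
            dx = pos[e1[e], 0] - pos[e0[e], 0]
            dy = pos[e1[e], 1] - pos[e0[e], 1]
            eps_rec = np.sqrt(dx * dx + dy * dy) - rest_length[e]
            strains_out[cycle, t] = eps_rec
            star = record_stars[t]
            if star == 0.0:
                errors[cycle, t] = abs(eps_rec)
            else:
                errors[cycle, t] = abs(eps_rec - star) / abs(star)
    return n_cycles, 0
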