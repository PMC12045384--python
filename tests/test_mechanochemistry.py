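"""Edge forces, chemical kinetics, invariants, and the memory kernel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cytolearn as cl
from cytolearn.mechanochemistry import (
    net_nodal_forces,
    simulate_edge_chemistry,
    unbinding_factor,
)
from cytolearn.params import steady_state


def elastic_energy(state, params):
    eps = state.strains()[~state.severed]
    k = state.stiffness[~state.severed]
    return float(np.sum(0.5 * k * eps**2 + params.k2 / 3 * eps**3
                        + params.k3 / 4 * eps**4))


class TestEdgeTension:
    @pytest.mark.parametrize(
        "eps,k,k2,k3,expected",
        [
            (0.0, 1.0, 0.0, 0.0, 0.0),
            (0.2, 1.0, 0.0, 0.0, 0.2),
            # cubic-quartic energy: dE/deps at eps=0.5 with k2=-0.1, k3=0.1
            (0.5, 1.0, -0.1, 0.1, 0.4875),
        ],
    )
    def test_tension_values(self, eps, k, k2, k3, expected):
        assert cl.edge_tension(eps, k, k2, k3) == pytest.approx(expected)

    @given(st.floats(-0.5, 0.5), st.floats(0.1, 5.0))
    @settings(deadline=None, max_examples=50)
    def test_hookean_linearity(self, eps, k):
        assert cl.edge_tension(eps, k) == pytest.approx(k * eps)


class TestActiveForce:
    def test_zero_at_rest_density(self):
        p = cl.ModelParams(xi=0.5)
        m0 = steady_state(p).m0
        assert cl.active_force(m0, p) == 0.0

    def test_proportional_to_motor_excess(self):
        # with all binding channels off the resting density is zero
        p = cl.ModelParams(xi=0.5, kb0=0.0, kb1=0.0, kbn=0.0)
        assert cl.active_force(2.0, p) == pytest.approx(1.0)
        assert cl.active_force(0.0, p) == 0.0

    def test_severed_edge_exerts_no_force(self, two_node_state):
        p = cl.ModelParams(xi=1.0, kb0=0.0, kb1=0.0, kbn=0.0)
        two_node_state.motor[0] = 5.0
        two_node_state.severed[0] = True
        f = net_nodal_forces(two_node_state, p)
        np.testing.assert_allclose(f, 0.0)


class TestSteadyState:
    def test_unit_protein_density(self):
        ss = steady_state(cl.ModelParams(kbn=2.0, kun0=2.0))
        assert ss.n0 == pytest.approx(1.0)

    def test_motor_density_from_rate_balance(self):
        # set the motor equation to zero and solve by hand
        ss = steady_state(cl.ModelParams(kb0=0.2, kb1=0.3, kbn=1.0, kun0=1.0, ku=0.5))
        assert ss.m0 == pytest.approx(1.0)

    def test_long_simulation_converges_to_fixed_point(self):
        p = cl.ModelParams(kb0=0.1, kb1=0.7, kbn=3.0, kun0=2.0, ku=0.8, dt=0.01)
        strain = np.zeros(4000)  # constant strain, zero rate
        m, n = simulate_edge_chemistry(p, strain)
        # start the fields away from the fixed point
        ss = steady_state(p)
        m2, n2 = m.copy(), n.copy()
        m2[0], n2[0] = 0.0, 0.0
        for i in range(1, len(strain)):
            n2[i] = n2[i - 1] + p.dt * (p.kbn - p.kun0 * n2[i - 1])
            m2[i] = m2[i - 1] + p.dt * (p.kb0 + p.kb1 * n2[i - 1] - p.ku * m2[i - 1])
        assert m2[-1] == pytest.approx(ss.m0, rel=1e-6)
        assert n2[-1] == pytest.approx(ss.n0, rel=1e-6)


class TestMotorStep:
    def test_fixed_point_is_stationary_to_machine_precision(self, two_node_state):
        p = cl.ModelParams()
        ss = steady_state(p)
        two_node_state.motor[0] = ss.m0
        two_node_state.protein[0] = ss.n0
        for _ in range(100):
            cl.step_motors(two_node_state, p)
            cl.step_proteins(two_node_state, p, np.zeros(1))
        assert two_node_state.motor[0] == pytest.approx(ss.m0, abs=1e-12)
        assert two_node_state.protein[0] == pytest.approx(ss.n0, abs=1e-12)

    def test_pure_decay_geometric(self, two_node_state):
        p = cl.ModelParams(kb0=0.0, kb1=0.0, ku=0.5, dt=0.01)
        two_node_state.motor[0] = 2.0
        two_node_state.protein[0] = 0.0
        cl.step_motors(two_node_state, p)
        assert two_node_state.motor[0] == pytest.approx(2.0 * (1 - 0.5 * 0.01))

    def test_converges_to_forced_fixed_point(self, two_node_state):
        p = cl.ModelParams(kb0=0.2, kb1=0.3, ku=0.5, dt=0.01)
        two_node_state.protein[0] = 3.0  # held constant: n != n0
        two_node_state.motor[0] = 0.0
        for _ in range(5000):
            cl.step_motors(two_node_state, p)
            # protein held fixed
        assert two_node_state.motor[0] == pytest.approx((0.2 + 0.3 * 3.0) / 0.5, rel=1e-5)

    def test_stability_guard(self, two_node_state):
        p = cl.ModelParams(ku=0.5)
        with pytest.raises(ValueError, match="dt"):
            cl.step_motors(two_node_state, p, dt=3.0)


class TestProteinStep:
    def test_catch_bond_unbinding_decreases_with_stretch_rate(self):
        p = cl.ModelParams(beta=0.2)
        assert unbinding_factor(1.0, p, "exact") < unbinding_factor(0.0, p, "exact")

    def test_order3_with_zero_coeffs_equals_order1(self):
        p = cl.ModelParams(beta=0.1, beta2=0.0, beta3=0.0)
        rates = np.linspace(-2, 2, 11)
        np.testing.assert_allclose(
            unbinding_factor(rates, p, 3), unbinding_factor(rates, p, 1))

    def test_exact_and_order1_agree_for_small_rates(self):
        p = cl.ModelParams(beta=0.1)
        rate = 1e-2  # beta*rate = 1e-3
        rel = abs(unbinding_factor(rate, p, 1) / unbinding_factor(rate, p, "exact") - 1)
        assert rel < 1e-5

    def test_order1_clamped_at_zero_for_huge_rates(self, two_node_state):
        p = cl.ModelParams(beta=1.0, kbn=0.0)
        counters = cl.EventCounters()
        fac = unbinding_factor(5.0, p, 1, counters)
        assert fac == 0.0
        assert counters.unbinding_clamps == 1


class TestNodeStep:
    def test_stretched_edge_contracts(self, two_node_state):
        p = cl.ModelParams(xi=0.0)
        d0 = np.linalg.norm(two_node_state.positions[1] - two_node_state.positions[0])
        cl.step_nodes(two_node_state, p)
        d1 = np.linalg.norm(two_node_state.positions[1] - two_node_state.positions[0])
        assert d1 < d0

    def test_pinned_nodes_do_not_move(self, two_node_state):
        two_node_state.pinned[:] = True
        before = two_node_state.positions.copy()
        cl.step_nodes(two_node_state, cl.ModelParams())
        np.testing.assert_array_equal(two_node_state.positions, before)

    def test_newtons_third_law_zero_total_force(self, net8):
        # sum of all internal pair forces vanishes to machine precision
        st = net8.copy()
        rng = np.random.default_rng(3)
        st.positions = st.positions + rng.normal(0, 0.05, st.positions.shape)
        st.motor = st.motor * rng.uniform(0.5, 1.5, st.n_edges)
        f = net_nodal_forces(st, cl.ModelParams(xi=0.7))
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12)

    def test_centroid_fixed_without_pins(self, net8):
        st = net8.copy()
        st.pinned[:] = False
        rng = np.random.default_rng(4)
        st.positions = st.positions + rng.normal(0, 0.05, st.positions.shape)
        c0 = st.positions.mean(axis=0)
        for _ in range(50):
            cl.step_nodes(st, cl.ModelParams(xi=0.3))
        np.testing.assert_allclose(st.positions.mean(axis=0), c0, atol=1e-12)

    def test_elastic_energy_nonincreasing_without_activity(self, net8):
        st = net8.copy()
        rng = np.random.default_rng(5)
        st.positions = st.positions + rng.normal(0, 0.08, st.positions.shape)
        st.prev_strain = st.strains()
        p = cl.ModelParams(xi=0.0, dt=0.01)
        e_prev = elastic_energy(st, p)
        for _ in range(200):
            cl.step_nodes(st, p)
            e = elastic_energy(st, p)
            assert e <= e_prev + 1e-12
            e_prev = e


class TestMemoryKernel:
    def _protocol(self, dt):
        t = np.arange(0, 40, dt)
        return 0.01 * np.sin(0.5 * t)

    @pytest.mark.parametrize("ku", [0.25, 0.5, 1.0])
    def test_timescale_is_inverse_unbinding_rate(self, ku):
        p = cl.ModelParams(ku=ku, kbn=50.0, kun0=50.0, dt=0.002)
        est = cl.estimate_memory_kernel(p, self._protocol(p.dt))
        assert est.tau_k == pytest.approx(1.0 / ku, rel=0.05)

    @pytest.mark.parametrize("kb1,beta", [(0.3, 0.1), (0.5, 0.05)])
    def test_amplitude_is_kb1_beta_n0(self, kb1, beta):
        p = cl.ModelParams(kb1=kb1, beta=beta, kbn=50.0, kun0=50.0, dt=0.002)
        n0 = steady_state(p).n0
        est = cl.estimate_memory_kernel(p, self._protocol(p.dt))
        assert est.beta1 == pytest.approx(kb1 * beta * n0, rel=0.10)

    def test_constant_strain_gives_no_motor_response(self):
        p = cl.ModelParams(dt=0.002)
        m, _ = simulate_edge_chemistry(p, np.full(5000, 0.3))
        np.testing.assert_allclose(m, steady_state(p).m0, atol=1e-10)

    def test_step_strain_response_returns_to_zero(self):
        # zero-mean kernel: after a held step change, delta_m decays away
        p = cl.ModelParams(dt=0.002)
        strain = np.concatenate([np.zeros(500), np.full(20000, 0.01)])
        m, _ = simulate_edge_chemistry(p, strain)
        m0 = steady_state(p).m0
        assert abs(m[700] - m0) > 1e-5          # transient response exists
        assert abs(m[-1] - m0) < 1e-8           # and it is transient
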