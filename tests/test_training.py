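"""Drive schedule, clamp forces, learning rules, and training controls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cytolearn as cl
from cytolearn.params import steady_state
from cytolearn.training import release_source


class TestLambdaSchedule:
    def setup_method(self):
        self.prot = cl.DriveProtocol(tau_f=1.0, tau_s=10.0, lambda_max=0.5)

    def test_zero_at_cycle_start(self):
        assert cl.lambda_of_t(0.0, self.prot) == 0.0

    def test_peak_at_end_of_fast_ramp(self):
        assert cl.lambda_of_t(1.0, self.prot) == pytest.approx(0.5)

    def test_midpoint_of_slow_ramp(self):
        assert cl.lambda_of_t(1.0 + 5.0, self.prot) == pytest.approx(0.25)

    @given(st.floats(0, 200))
    @settings(deadline=None, max_examples=60)
    def test_periodic_and_bounded(self, t):
        lam = cl.lambda_of_t(t, self.prot)
        assert 0.0 <= lam <= 0.5
        assert lam == pytest.approx(
            cl.lambda_of_t(t + self.prot.tau_cyc, self.prot), abs=1e-9)

    def test_symmetric_timescales_warn(self):
        with pytest.warns(UserWarning, match="asymmetry"):
            cl.DriveProtocol(tau_f=5.0, tau_s=5.0)


class TestThreshold:
    @pytest.mark.parametrize("x,gc,expected", [
        (0.05, 0.1, 0.0),
        (-0.2, 0.1, -0.2),
        (0.1, 0.1, 0.1),     # boundary included
        (-0.1, 0.1, -0.1),
    ])
    def test_values(self, x, gc, expected):
        assert cl.threshold_g(x, gc) == expected

    @given(st.floats(-1, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=60)
    def test_odd_and_identity_above_threshold(self, x, gc):
        g = cl.threshold_g(x, gc)
        assert g in (0.0, x)
        assert cl.threshold_g(-x, gc) == -g


class TestClampForce:
    def test_zero_at_set_point(self, two_node_state):
        two_node_state.rest_length[0] = 1.0  # length 1.2, strain 0.2
        ids, f = cl.clamp_force(two_node_state, 0, 0.2, lam=1.0)
        np.testing.assert_allclose(f, 0.0, atol=1e-15)

    def test_horizontal_edge_gradient_by_hand(self, two_node_state):
        # eps - eps* = 0.2 - 0.1 = 0.1, lam=1: magnitude 0.1 along x
        ids, f = cl.clamp_force(two_node_state, 0, 0.1, lam=1.0)
        np.testing.assert_allclose(f[0], [0.1, 0.0], atol=1e-12)
        np.testing.assert_allclose(f[1], [-0.1, 0.0], atol=1e-12)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-15)

    def test_feedback_pulse_magnitude_bounded_by_a0_times_length(self, two_node_state):
        ids, f = cl.clamp_force(two_node_state, 0, 0.0, lam=1.0 * 0.8,
                                mode="pulsation_feedback")
        assert np.linalg.norm(f[0]) == pytest.approx(0.8)

    def test_zero_length_edge_rejected(self, two_node_state):
        two_node_state.positions[1] = two_node_state.positions[0]
        with pytest.raises(ValueError, match="zero length"):
            cl.clamp_force(two_node_state, 0, 0.0, 1.0)


class TestSourceClamp:
    @pytest.mark.parametrize("eps", [0.0, 0.25])
    def test_pinned_edge_carries_exact_strain(self, net8, eps):
        st = net8.copy()
        cl.apply_source_strain(st, 10, eps)
        assert st.strains()[10] == pytest.approx(eps, abs=1e-12)
        a, b = st.edges[10]
        assert st.pinned[a] and st.pinned[b]

    def test_release_round_trip(self, net8):
        st = net8.copy()
        cl.apply_source_strain(st, 10, 0.25)
        release_source(st, 10)
        a, b = st.edges[10]
        assert not st.pinned[a] and not st.pinned[b]


class TestLdofUpdate:
    def _single_edge(self, fa_target, params):
        st = cl.NetworkState(
            positions=np.array([[0.0, 0.0], [1.0, 0.0]]),
            edges=np.array([[0, 1]]),
            stiffness=np.array([1.0]),
            rest_length=np.array([1.0]),
            motor=np.array([steady_state(params).m0 + fa_target / params.xi]),
            protein=np.array([1.0]),
            prev_strain=np.array([0.0]),
            severed=np.array([False]),
            pinned=np.array([True, True]),
            boundary_nodes=np.array([0, 1]),
        )
        return st

    def test_arithmetic_of_rest_length_update(self):
        p = cl.ModelParams(xi=1.0)
        st = self._single_edge(0.2, p)
        cfg = cl.LearningConfig(alpha=1.0, gc=0.1, ldof="rest_length")
        cl.update_ldof(st, cfg, p, dt=0.01)
        assert st.rest_length[0] == pytest.approx(1.0 + 0.002)

    def test_below_threshold_no_change(self):
        p = cl.ModelParams(xi=1.0)
        st = self._single_edge(0.05, p)
        cfg = cl.LearningConfig(alpha=1.0, gc=0.1)
        cl.update_ldof(st, cfg, p, dt=0.01)
        assert st.rest_length[0] == 1.0

    def test_zero_learning_rate_no_change(self):
        p = cl.ModelParams(xi=1.0)
        st = self._single_edge(0.5, p)
        cl.update_ldof(st, cl.LearningConfig(alpha=0.0, gc=0.0), p, dt=0.01)
        assert st.rest_length[0] == 1.0

    def test_stiffness_update_uses_strain_times_force(self):
        p = cl.ModelParams(xi=1.0)
        st = self._single_edge(0.2, p)
        st.rest_length[0] = 0.5  # strain = 0.5
        st.prev_strain[0] = 0.5
        cfg = cl.LearningConfig(alpha=1.0, gc=0.05, ldof="stiffness")
        cl.update_ldof(st, cfg, p, dt=0.01)
        assert st.stiffness[0] == pytest.approx(1.0 + 0.01 * 0.5 * 0.2)


class TestErrorMetric:
    def test_scale_correct(self):
        assert cl.training_error(0.25, 0.25) == 0.0
        assert cl.training_error(0.0, 0.25) == 1.0
        assert cl.training_error(-0.2, -0.25) == pytest.approx(0.2)

    def test_zero_set_point_uses_absolute_strain(self):
        assert cl.training_error(0.03, 0.0) == pytest.approx(0.03)


class TestNoLearningControls:
    """Channels whose removal must exactly freeze the learning DOF."""

    @pytest.mark.parametrize("knockout", [{"xi": 0.0}, {"beta": 0.0}, {"kb1": 0.0}])
    def test_knockout_gives_exactly_zero_ldof_change(self, tiny_bundle, knockout):
        b = tiny_bundle
        params = b.params.with_(**knockout)
        gc = max(b.learning.gc, 1e-12)
        st, trace = cl.train(b.network, b.task, params, b.protocol,
                             b.learning.with_(gc=gc), n_cycles=5, seed=0)
        np.testing.assert_array_equal(trace.dL0, 0.0)
        np.testing.assert_array_equal(trace.dk, 0.0)

    def test_disabled_clamp_no_ldof_drift(self, tiny_bundle):
        b = tiny_bundle
        prot = b.protocol.with_(lambda_max=0.0)
        st, trace = cl.train(b.network, b.task, b.params, prot, b.learning,
                             n_cycles=3, seed=0)
        np.testing.assert_allclose(trace.dL0, 0.0, atol=1e-12)


class TestTrainSmoke:
    def test_trace_shapes_and_reproducibility(self, tiny_bundle):
        b = tiny_bundle
        _, t1 = cl.train(b.network, b.task, b.params, b.protocol, b.learning,
                         n_cycles=4, seed=7)
        _, t2 = cl.train(b.network, b.task, b.params, b.protocol, b.learning,
                         n_cycles=4, seed=7)
        assert t1.errors.shape == (4, 1)
        np.testing.assert_array_equal(t1.errors, t2.errors)
        np.testing.assert_array_equal(t1.dL0, t2.dL0)

    def test_untrained_response_far_from_target(self, tiny_bundle):
        b = tiny_bundle
        resp = cl.evaluate_response(b.network, b.task, b.params)
        assert abs(resp[0] - b.task.eps_target[0]) > 0.1

    def test_zero_source_strain_gives_zero_response(self, net8):
        task = cl.TaskGeometry(source_edges=[0], target_edges=[50],
                               eps_source=[0.0], eps_target=[-0.25])
        resp = cl.evaluate_response(net8, task, cl.ModelParams())
        assert resp[0] == pytest.approx(0.0, abs=1e-6)
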