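"""Classification inputs, phase labelling, and protocol-level contracts."""

import numpy as np
import pytest

import cytolearn as cl
from cytolearn.protocols import classification_accuracy, pulsation_diagnostics


@pytest.fixture(scope="module")
def ctask():
    b = cl.make_fixture("classification", seed=0)
    return b.classification


class TestGradientInput:
    def test_positive_slope_strictly_increasing(self, ctask):
        task = cl.ClassificationTask(**{**ctask.__dict__, "noise_max": 0.0})
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = cl.gradient_input(task, "+", rng)
            assert np.all(np.diff(s) > 0)

    def test_negative_slope_strictly_decreasing(self, ctask):
        task = cl.ClassificationTask(**{**ctask.__dict__, "noise_max": 0.0})
        rng = np.random.default_rng(1)
        for _ in range(20):
            s = cl.gradient_input(task, "-", rng)
            assert np.all(np.diff(s) < 0)

    def test_noise_bounded_by_twenty_percent(self, ctask):
        rng = np.random.default_rng(2)
        noiseless = cl.ClassificationTask(**{**ctask.__dict__, "noise_max": 0.0})
        for _ in range(50):
            state = rng.bit_generator.state
            noisy = cl.gradient_input(ctask, "+", rng)
            rng2 = np.random.default_rng(3)
            rng2.bit_generator.state = state
            base = cl.gradient_input(noiseless, "+", rng2)
            rel = np.abs(noisy / base - 1.0)
            assert np.all(rel <= 0.2 + 1e-12)

    def test_bad_sign_rejected(self, ctask):
        with pytest.raises(ValueError):
            cl.gradient_input(ctask, "x", np.random.default_rng(0))


class TestClassificationContracts:
    def test_accuracy_is_exact_proportion(self, ctask):
        b = cl.make_fixture("classification", seed=0)
        rng = np.random.default_rng(5)
        acc = classification_accuracy(b.network, ctask, b.params, 8, rng)
        assert 0.0 <= acc <= 1.0
        assert acc * 8 == int(round(acc * 8))

    def test_untrained_network_near_zero_accuracy(self, ctask):
        b = cl.make_fixture("classification", seed=0)
        rng = np.random.default_rng(6)
        acc = classification_accuracy(b.network, ctask, b.params, 10, rng)
        assert acc <= 0.2

    def test_zero_tests_rejected(self, ctask):
        b = cl.make_fixture("classification", seed=0)
        with pytest.raises(ValueError, match="n_tests"):
            cl.run_classification(b.network, ctask, b.params, b.protocol,
                                  b.learning, 1, 0)

    def test_overlapping_target_and_source_rejected(self, ctask):
        with pytest.raises(ValueError, match="distinct"):
            cl.ClassificationTask(
                source_edges=ctask.source_edges,
                target_plus=ctask.source_edges[0],
                target_minus=ctask.target_minus,
            )


class TestPhaseClassification:
    thresholds = cl.PhaseThresholds()

    def test_learning_vs_loss(self):
        assert cl.classify_phase({"final_error": 0.05}, self.thresholds) == "learning"
        assert cl.classify_phase({"final_error": 0.8}, self.thresholds) == "loss_of_learning"

    def test_pulsation_labels(self):
        base = {"max_abs_dL0": 0.1, "min_length_frac": 0.8, "max_dL0_frac": 0.2}
        t = self.thresholds
        assert cl.classify_phase(base, t, "pulsation") == "conserved_geometry"
        assert cl.classify_phase({**base, "max_abs_dL0": 1e-5}, t, "pulsation") == "no_learning"
        assert cl.classify_phase({**base, "min_length_frac": 0.05}, t, "pulsation") == "altered_geometry"
        assert cl.classify_phase({**base, "max_dL0_frac": 0.9}, t, "pulsation") == "altered_geometry"

    def test_labels_deterministic_pure_function(self):
        d = {"final_error": 0.19999}
        labels = {cl.classify_phase(d, self.thresholds) for _ in range(5)}
        assert labels == {"learning"}

    def test_aborted_runs_are_labelled(self):
        assert cl.classify_phase({"aborted": True}, self.thresholds) == "loss_of_learning"
        assert cl.classify_phase({"aborted": True}, self.thresholds,
                                 "pulsation") == "altered_geometry"


class TestSweepMachinery:
    def test_grid_and_partial_failure_handling(self):
        calls = []

        def runner(coords, seed):
            calls.append((coords["a"], coords["b"], seed))
            if coords["a"] == 2:
                raise cl.TrainingUnstableError("boom", None)
            return {"final_error": 0.1 * coords["b"]}

        pts = cl.sweep_phase_diagram(("a", [1, 2]), ("b", [1, 3]), runner,
                                     seeds=(0, 1))
        assert len(pts) == 8
        assert len(calls) == 8
        labels = {(p.coords["a"], p.coords["b"]): p.label for p in pts}
        assert labels[(1, 1)] == "learning"
        assert labels[(1, 3)] == "loss_of_learning"
        assert labels[(2, 1)] == "loss_of_learning"  # aborted


class TestAdaptationContracts:
    def test_requires_zero_set_points(self):
        b = cl.make_fixture("adaptation", seed=0)
        bad = cl.TaskGeometry(source_edges=b.task.source_edges,
                              target_edges=b.task.target_edges,
                              eps_source=b.task.eps_source,
                              eps_target=[0.1, 0.0, 0.0])
        with pytest.raises(ValueError, match="zero"):
            cl.run_adaptation(b.network, bad, b.params,
                              b.protocol, b.learning, 1)

    def test_adaptation_fixture_geometry(self):
        b = cl.make_fixture("adaptation", seed=0)
        hull = set(b.network.boundary_nodes.tolist())
        # three targets share an interior hub node
        nodes = [set(map(int, b.network.edges[e])) for e in b.task.target_edges]
        assert len(b.task.target_edges) == 3
        assert set.intersection(*nodes)
        assert all(n not in hull for s in nodes for n in s)
        # sources on the boundary
        for e in b.task.source_edges:
            a, c = b.network.edges[e]
            assert int(a) in hull or int(c) in hull


class TestPulsationContracts:
    def test_mode_required(self):
        b = cl.make_fixture("pulsation", seed=0)
        with pytest.raises(ValueError, match="pulsation"):
            cl.run_pulsation(b.network, b.task, b.params,
                             b.protocol.with_(mode="supervised"),
                             b.learning, 1)

    def test_feedback_amplitude_tracks_length(self, two_node_state):
        # negative feedback: the pulse amplitude is proportional to L
        _, f_long = cl.clamp_force(two_node_state, 0, 0.0, lam=0.6 * 1.2,
                                   mode="pulsation_feedback")
        two_node_state.positions[1, 0] = 0.6
        _, f_short = cl.clamp_force(two_node_state, 0, 0.0, lam=0.6 * 0.6,
                                    mode="pulsation_feedback")
        assert np.linalg.norm(f_short[0]) < np.linalg.norm(f_long[0])
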