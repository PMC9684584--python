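import json

import numpy as np
import pytest

import mdmc
from mdmc.core import default_survival_threshold, run_em
from mdmc.hierarchy import (
    FlowMatrix,
    HierarchyTrace,
    Layer,
    consensus_init,
    detect_layers,
    layer_flows,
    make_schedule,
    run_quasi_static,
    sankey_export,
)


class TestSchedule:
    def test_endpoints(self):
        s = make_schedule(0.01, 1.0, 0, 100)
        assert s.alpha(0) == pytest.approx(0.01)
        assert s.alpha(100) == pytest.approx(1.0)

    def test_midpoint_is_geometric_mean(self):
        s = make_schedule(0.04, 4.0, 0, 200)
        assert s.alpha(100) == pytest.approx(np.sqrt(0.04 * 4.0))

    def test_constant_step_ratio(self):
        s = make_schedule(0.01, 1.0, 0, 100)
        ratios = s.values[1:] / s.values[:-1]
        assert np.allclose(ratios, 100 ** (1 / 100))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(-0.1, 1.0, 0, 10)
        with pytest.raises(ValueError):
            make_schedule(1.0, 0.5, 0, 10)
        with pytest.raises(ValueError):
            make_schedule(0.1, 1.0, 10, 10)

    def test_constant_schedule_allowed(self):
        s = make_schedule(0.5, 0.5, 0, 50)
        assert np.allclose(s.values, 0.5)


class TestConsensusInit:
    def test_single_restart_equals_plain_run(self, small_model):
        best = consensus_init(small_model, K=3, alpha_ini=0.3, n_restarts=1,
                              n_iter=100, base_seed=5)
        plain = run_em(small_model, K=3, alpha=0.3, n_iter=100, seed=5)
        assert np.array_equal(best.state.pi, plain.state.pi)
        assert np.array_equal(best.state.membership, plain.state.membership)

    def test_selects_max_q(self, small_model):
        seeds = [0, 1, 2, 3]
        best = consensus_init(small_model, K=4, alpha_ini=0.2, n_restarts=4,
                              n_iter=150, seeds=seeds)
        qs = [
            run_em(small_model, K=4, alpha=0.2, n_iter=150, seed=s).state.q_tilde
            for s in seeds
        ]
        assert best.state.q_tilde == pytest.approx(max(qs))

    def test_repeat_call_identical(self, small_model):
        a = consensus_init(small_model, K=3, alpha_ini=0.3, n_restarts=3,
                           n_iter=80, base_seed=0)
        b = consensus_init(small_model, K=3, alpha_ini=0.3, n_restarts=3,
                           n_iter=80, base_seed=0)
        assert np.array_equal(a.state.membership, b.state.membership)


class TestQuasiStatic:
    def test_constant_schedule_matches_fixed_alpha_em(self, small_model):
        init = run_em(small_model, K=3, alpha=0.4, n_iter=20, seed=1, tol=0.0)
        sched = make_schedule(0.4, 0.4, 0, 30)
        trace = run_quasi_static(small_model, 3, sched, init.state)
        cont = run_em(small_model, K=3, alpha=0.4, n_iter=30, seed=None,
                      init_state=init.state, tol=0.0)
        assert np.allclose(trace.pis[-1], cont.state.pi, atol=1e-12)

    def test_deterministic_given_init(self, small_model):
        init = run_em(small_model, K=4, alpha=0.1, n_iter=50, seed=2)
        sched = make_schedule(0.1, 1.0, 0, 100)
        t1 = run_quasi_static(small_model, 4, sched, init.state)
        t2 = run_quasi_static(small_model, 4, sched, init.state)
        assert np.array_equal(t1.pis, t2.pis)

    def test_snapshots_recorded(self, small_model):
        init = run_em(small_model, K=3, alpha=0.1, n_iter=50, seed=3)
        sched = make_schedule(0.1, 0.5, 0, 60)
        trace = run_quasi_static(small_model, 3, sched, init.state,
                                 snapshot_steps={0, 30, 60})
        assert set(trace.snapshots) == {0, 30, 60}
        assert np.allclose(trace.snapshots[60].pi, trace.pis[-1])


def synthetic_trace(pis, alpha_ini=0.1, alpha_fin=10.0, K=None):
    n = len(pis) - 1
    sched = make_schedule(alpha_ini, alpha_fin, 0, n)
    pis = np.asarray(pis, dtype=float)
    return HierarchyTrace(
        schedule=sched,
        steps=np.arange(n + 1),
        alphas=sched.values,
        pis=pis,
        survival_threshold=default_survival_threshold(pis.shape[1]),
    )


class TestDetectLayers:
    def test_constant_trajectory_is_one_layer(self):
        pis = np.tile([0.5, 0.5, 0.0], (501, 1))
        layers = detect_layers(synthetic_trace(pis))
        assert len(layers) == 1
        la = layers[0]
        assert la.alpha_range == (pytest.approx(0.1), pytest.approx(10.0))
        assert la.n_survived == 2
        assert la.alpha_center == pytest.approx((0.1 + 10.0) / 2)

    def test_injected_step_change_splits_into_two_layers(self):
        a = np.tile([0.5, 0.3, 0.2], (300, 1))
        b = np.tile([0.7, 0.3, 0.0], (301, 1))
        pis = np.vstack([a, b])
        layers = detect_layers(synthetic_trace(pis))
        assert len(layers) == 2
        assert layers[0].n_survived == 3
        assert layers[1].n_survived == 2
        # the boundary sits at the injected change (step 300 of 600)
        lo, hi = layers[0].alpha_range[1], layers[1].alpha_range[0]
        assert lo == hi
        alphas = synthetic_trace(pis).alphas
        assert abs(np.log(lo) - np.log(alphas[300])) < 0.05

    def test_no_stable_interval_warns_and_returns_empty(self):
        rng = np.random.default_rng(0)
        pis = rng.dirichlet(np.ones(3), size=101)  # pure noise
        with pytest.warns(UserWarning, match="no stable interval"):
            layers = detect_layers(synthetic_trace(pis))
        assert layers == []


class TestLayerFlows:
    def make_layer(self, h, belonging, pi=None):
        K = belonging.shape[0]
        return Layer(
            h=h, alpha_range=(0.1, 1.0), alpha_center=0.5, t_center=0,
            pi=np.full(K, 1 / K) if pi is None else pi,
            n_survived=K, belonging=belonging,
        )

    def test_identical_layers_have_zero_flow(self):
        rng = np.random.default_rng(1)
        B = rng.dirichlet(np.ones(4), size=10).T  # (K, N) columns sum to 1
        fm = layer_flows(self.make_layer(1, B), self.make_layer(2, B),
                         np.full(10, 0.1))
        assert np.all(fm.flows == 0)

    def test_single_node_total_transfer(self):
        B0 = np.array([[1.0], [0.0]])
        B1 = np.array([[0.0], [1.0]])
        fm = layer_flows(self.make_layer(1, B0), self.make_layer(2, B1),
                         np.array([1.0]))
        assert fm.flows[0, 1] == pytest.approx(1.0)
        assert fm.flows.sum() == pytest.approx(1.0)

    def test_per_node_flow_conservation(self):
        rng = np.random.default_rng(2)
        N, K = 30, 5
        B0 = rng.dirichlet(np.ones(K), size=N).T
        B1 = rng.dirichlet(np.ones(K), size=N).T
        p_node = rng.dirichlet(np.ones(N))
        fm = layer_flows(self.make_layer(1, B0), self.make_layer(2, B1), p_node)
        # total marginal flow equals the p(n)-weighted per-node flow-in
        total_in = np.maximum(B1 - B0, 0).sum(axis=0)
        assert fm.flows.sum() == pytest.approx(float(p_node @ total_in), abs=1e-10)
        # and equals the weighted flow-out (mass conservation per node)
        total_out = np.maximum(B0 - B1, 0).sum(axis=0)
        assert fm.flows.sum() == pytest.approx(float(p_node @ total_out), abs=1e-10)


class TestSankeyExport:
    def test_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        B0 = rng.dirichlet(np.ones(3), size=8).T
        B1 = rng.dirichlet(np.ones(3), size=8).T
        mk = TestLayerFlows().make_layer
        l1, l2 = mk(1, B0), mk(2, B1)
        fm = layer_flows(l1, l2, np.full(8, 1 / 8))
        path = tmp_path / "sankey.json"
        doc = sankey_export([l1, l2], [fm], path)
        back = json.loads(path.read_text())
        assert back == doc
        for link in back["links"]:
            assert link["value"] == fm.flows[link["source_k"] - 1, link["target_k"] - 1]

    def test_zero_flows_omitted(self, tmp_path):
        B = np.random.default_rng(4).dirichlet(np.ones(3), size=8).T
        mk = TestLayerFlows().make_layer
        l1, l2 = mk(1, B), mk(2, B)
        fm = layer_flows(l1, l2, np.full(8, 1 / 8))
        doc = sankey_export([l1, l2], [fm], None)
        assert doc["links"] == []

    def test_flow_count_mismatch_rejected(self):
        B = np.random.default_rng(5).dirichlet(np.ones(2), size=4).T
        mk = TestLayerFlows().make_layer
        with pytest.raises(ValueError):
            sankey_export([mk(1, B), mk(2, B)], [], None)
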