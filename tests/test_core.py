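import numpy as np
import pytest

import mdmc
from mdmc.core import (
    MDMCState,
    count_surviving,
    e_step,
    initialize_state,
    m_step,
    q_lower_bound,
    run_em,
)
from mdmc.graph_io import build_transition_model

from conftest import random_undirected_network


class TestInitializeState:
    def test_single_community(self, small_model):
        state = initialize_state(small_model, K=1, alpha=0.3, seed=0)
        assert np.allclose(state.pi, [1.0])
        assert np.allclose(state.resp, 1.0)
        assert state.membership.sum() == pytest.approx(1.0)

    def test_same_seed_bit_identical(self, small_model):
        a = initialize_state(small_model, K=4, alpha=0.2, seed=42)
        b = initialize_state(small_model, K=4, alpha=0.2, seed=42)
        assert np.array_equal(a.pi, b.pi)
        assert np.array_equal(a.membership, b.membership)
        assert np.array_equal(a.resp, b.resp)

    def test_overparameterized_start_warns_but_works(self, karate_model):
        with pytest.warns(UserWarning, match="exceeds"):
            state = initialize_state(karate_model, K=40, alpha=0.5, seed=0)
        assert state.pi.size == 40

    def test_invalid_arguments(self, small_model):
        with pytest.raises(ValueError):
            initialize_state(small_model, K=0, alpha=0.5)
        with pytest.raises(ValueError):
            initialize_state(small_model, K=2, alpha=-0.1)


class TestEStep:
    def test_single_community_responsibility_is_one(self, small_model):
        state = initialize_state(small_model, K=1, alpha=0.3, seed=1)
        assert np.allclose(e_step(state, small_model), 1.0)

    def test_hand_example(self):
        # link a->b with pi=(0.5, 0.5), p(a|1)p(b|1)=0.04, p(a|2)p(b|2)=0.01
        from mdmc.graph_io import Network

        net = Network.from_arrays([0], [1], n_nodes=2, directed=True)
        model = build_transition_model(net, rho=0.2)
        P = np.array([[0.2, 0.2], [0.1, 0.1]])  # products 0.04 and 0.01
        state = MDMCState(
            K=2, alpha=0.5, pi=np.array([0.5, 0.5]),
            membership=P / P.sum(axis=1, keepdims=True) * np.array([[0.4], [0.2]]),
            resp=np.empty((2, 1)),
        )
        state.membership = np.array([[0.2, 0.2], [0.1, 0.1]])  # rows need not sum here
        r = e_step(state, model)
        assert np.allclose(r[:, 0], [0.8, 0.2])

    def test_degenerate_link_gets_uniform_responsibility(self, small_model):
        K = 4
        state = initialize_state(small_model, K=K, alpha=0.3, seed=2)
        state.membership[:, :] = 0.0
        r = e_step(state, small_model)
        assert np.allclose(r, 1.0 / K)


class TestMStep:
    def test_pi_normalized_after_every_call(self, small_model):
        state = initialize_state(small_model, K=5, alpha=0.4, seed=3)
        for _ in range(5):
            resp = e_step(state, small_model)
            pi, P = m_step(state, resp, small_model)
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            state.pi, state.membership, state.resp = pi, P, resp

    def test_large_alpha_limit_is_markov_propagation(self, small_model):
        state = initialize_state(small_model, K=3, alpha=1e9, seed=4)
        resp = e_step(state, small_model)
        _, P = m_step(state, resp, small_model)
        markov = small_model.propagate(state.membership)
        assert np.allclose(P, markov / markov.sum(axis=1, keepdims=True), atol=1e-8)

    def test_alpha_zero_reduction(self, small_model):
        # at alpha = 0 the membership is the responsibility-weighted
        # endpoint mass divided by 2 pi(k)
        net = small_model.network
        state = initialize_state(small_model, K=3, alpha=0.0, seed=5)
        resp = e_step(state, small_model)
        pi, P = m_step(state, resp, small_model)
        w = small_model.p_st_link
        for k in range(3):
            expect = np.zeros(net.n_nodes)
            np.add.at(expect, net.links_from, w * resp[k])
            np.add.at(expect, net.links_to, w * resp[k])
            expect /= 2 * pi[k]
            assert np.allclose(P[k], expect, atol=1e-12)


class TestQLowerBound:
    def test_finite_on_reachable_states(self, small_model):
        state = initialize_state(small_model, K=3, alpha=0.2, seed=6)
        for _ in range(30):
            resp = e_step(state, small_model)
            prev = state.membership
            state.pi, state.membership = m_step(state, resp, small_model)
            state.resp = resp
            q = q_lower_bound(state, small_model, prev_membership=prev)
            assert np.isfinite(q)

    @pytest.mark.parametrize("seed", range(5))
    def test_em_update_never_decreases_fixed_centre_bound(self, seed):
        """Each (E, M) update maximizes Q̃ for the current prior centre
        p_{t-1}, so the bound evaluated at that centre cannot decrease."""
        net = random_undirected_network(20, seed=seed)
        model = build_transition_model(net)
        state = initialize_state(model, K=4, alpha=0.3, seed=seed)
        for _ in range(50):
            prev = state.copy()
            resp = e_step(state, model)
            state.pi, state.membership = m_step(state, resp, model)
            state.resp = resp
            q_before = q_lower_bound(prev, model, prev_membership=prev.membership)
            q_after = q_lower_bound(state, model, prev_membership=prev.membership)
            assert q_after >= q_before - 1e-9


class TestRunEM:
    def test_k1_converges_to_stationary_state(self, small_model):
        res = run_em(small_model, K=1, alpha=0.7, n_iter=2000, seed=0)
        assert np.allclose(res.state.membership[0], small_model.p_st_node, atol=1e-8)

    def test_deterministic(self, karate_model):
        a = run_em(karate_model, K=5, alpha=0.5, n_iter=50, seed=9)
        b = run_em(karate_model, K=5, alpha=0.5, n_iter=50, seed=9)
        assert np.array_equal(a.state.pi, b.state.pi)
        assert np.array_equal(a.state.membership, b.state.membership)
        assert np.array_equal(a.partition, b.partition)

    def test_normalization_invariants_along_run(self, small_model):
        res = run_em(small_model, K=6, alpha=0.2, n_iter=100, seed=1)
        st = res.state
        assert st.pi.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(st.membership.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(st.resp.sum(axis=0), 1.0, atol=1e-10)
        assert res.p_node.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(res.belonging.sum(axis=0), 1.0, atol=1e-10)

    def test_partition_labels_come_from_survivors(self, karate_model):
        res = run_em(karate_model, K=10, alpha=0.5, n_iter=500, seed=0)
        assert set(res.partition) <= set(res.survived.tolist())

    def test_karate_mean_survivors_non_increasing_in_alpha(self, karate_model):
        """The resolution property: averaged over seeds, larger alpha gives
        no more surviving communities.  Holds in the structured regime;
        beyond it the EM settles into the symmetric fixed point where all
        memberships coincide and the count equals K trivially."""
        means = []
        for alpha in (0.1, 0.3, 0.5):
            counts = [
                run_em(karate_model, K=10, alpha=alpha, n_iter=300,
                       seed=s, track_q=False).n_survived
                for s in range(20)
            ]
            means.append(np.mean(counts))
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_invalid_n_iter(self, small_model):
        with pytest.raises(ValueError):
            run_em(small_model, K=2, alpha=0.5, n_iter=0)


class TestCountSurviving:
    def test_examples(self):
        pi = np.array([0.6, 0.4 - 1e-9, 1e-9, 0.0])
        assert count_surviving(pi, 1e-4) == 2
        assert count_surviving(np.full(10, 0.1), 1e-4) == 10
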