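import itertools
import math

import numpy as np
import pytest

from bmrf.mrf_model import ContractViolation, Theta, sigmoid
from bmrf.network_io import NEG, POS, UNKNOWN, ProteinNetwork
from bmrf.samplers import (
    DEFAULT_GAMMA_STEP,
    McmcConfig,
    bmrf,
    demc_propose,
    gibbs_sweep,
    metropolis_accept,
    mrf_deng,
)


def enumerate_fixed_theta_marginals(network, labels, theta):
    """Exact conditional marginals of the unknown nodes at fixed theta.

    The Gibbs conditionals logit = alpha + beta*M1 + gamma*M0 are the full
    conditionals of the joint p(x) ∝ exp(alpha*n1 + beta*n11 - gamma*n00);
    enumerate it over all unknown-label configurations.
    """
    unknown = np.flatnonzero(labels == UNKNOWN)
    weights, configs = [], list(itertools.product([0, 1], repeat=unknown.size))
    for cfg in configs:
        full = labels.copy()
        full[unknown] = cfg
        n1 = int(np.sum(full == POS))
        n11 = n00 = 0
        for u, v in network.edges:
            su, sv = full[network.index[u]], full[network.index[v]]
            n11 += su == POS and sv == POS
            n00 += su == NEG and sv == NEG
        weights.append(math.exp(theta.alpha * n1 + theta.beta * n11 - theta.gamma * n00))
    weights = np.array(weights)
    weights /= weights.sum()
    return np.array(
        [sum(w * cfg[j] for w, cfg in zip(weights, configs)) for j in range(unknown.size)]
    )


class TestGibbsSweep:
    def test_saturated_negative_logit_zeroes_all_targets(self):
        net = ProteinNetwork(["a", "b", "c"], [("a", "b"), ("b", "c")])
        labels = np.array([1, 1, 1], dtype=np.int8)
        new, _ = gibbs_sweep(net, labels, Theta(-50, 0, 0), np.random.default_rng(0))
        assert new.tolist() == [0, 0, 0]

    def test_zero_theta_flips_fairly(self):
        net = ProteinNetwork(["a"], [])
        rng = np.random.default_rng(1)
        draws = [
            gibbs_sweep(net, np.array([0], dtype=np.int8), Theta(0, 0, 0), rng)[0][0]
            for _ in range(4000)
        ]
        assert abs(np.mean(draws) - 0.5) < 3 * math.sqrt(0.25 / 4000)

    def test_conditional_matches_closed_form_with_fixed_neighbor(self):
        net = ProteinNetwork(["a", "b"], [("a", "b")])
        theta = Theta(-0.4, 0.9, -0.3)
        p_expected = sigmoid(theta.alpha + theta.beta)  # neighbor a fixed at 1
        rng = np.random.default_rng(2)
        n = 10000
        hits = 0
        state = np.array([1, 0], dtype=np.int8)
        for _ in range(n):
            state, _ = gibbs_sweep(net, state, theta, rng, targets=np.array([1]))
            hits += int(state[1])
        se = math.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(hits / n - p_expected) < 3 * se

    def test_requires_imputed_labels(self):
        net = ProteinNetwork(["a", "b"], [("a", "b")])
        with pytest.raises(ContractViolation):
            gibbs_sweep(net, np.array([POS, UNKNOWN], dtype=np.int8),
                        Theta(0, 0, 0), np.random.default_rng(0))


class TestDemcPropose:
    def test_degenerate_archive_returns_current_theta(self):
        theta = Theta(0.5, -0.2, 0.1)
        archive = np.tile([1.0, 2.0, 3.0], (5, 1))
        cand = demc_propose(theta, archive, 0.97, 0.0, np.random.default_rng(0))
        assert cand == pytest.approx(theta)

    def test_difference_vector_arithmetic(self):
        theta = Theta(0.0, 0.0, 0.0)
        archive = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        cand = demc_propose(theta, archive, 1.0, 0.0, np.random.default_rng(0))
        # with two archive rows the difference is +/- (1,0,0)
        assert abs(cand.alpha) == pytest.approx(1.0)
        assert cand.beta == 0.0 and cand.gamma == 0.0

    def test_default_step_is_ter_braak_optimum(self):
        assert DEFAULT_GAMMA_STEP == pytest.approx(2.38 / math.sqrt(6))
        assert McmcConfig().gamma_step == pytest.approx(0.9716, abs=1e-4)

    def test_short_archive_rejected(self):
        with pytest.raises(ContractViolation):
            demc_propose(Theta(0, 0, 0), np.zeros((1, 3)), 1.0, 0.0,
                         np.random.default_rng(0))

    def test_distinct_rows_always_selected(self):
        theta = Theta(0.0, 0.0, 0.0)
        archive = np.array([[1.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        rng = np.random.default_rng(3)
        for _ in range(200):
            cand = demc_propose(theta, archive, 1.0, 0.0, rng)
            assert cand.alpha != 0.0  # identical picks would cancel to zero


class TestMetropolisAccept:
    def test_equal_values_always_accept(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-5.0, -5.0, rng) for _ in range(100))

    def test_better_candidate_always_accepted(self):
        rng = np.random.default_rng(0)
        assert metropolis_accept(-1.0, -10.0, rng)

    def test_worse_by_log2_accepts_half_the_time(self):
        rng = np.random.default_rng(4)
        n = 10000
        hits = sum(metropolis_accept(-math.log(2), 0.0, rng) for _ in range(n))
        assert abs(hits / n - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ContractViolation):
            metropolis_accept(float("-inf"), 0.0, np.random.default_rng(0))


class TestMrfDeng:
    def test_no_unknown_gives_empty_posterior_and_nan_acceptance(self, triangle_network):
        labels = np.array([POS, NEG, POS], dtype=np.int8)
        out = mrf_deng(triangle_network, labels, McmcConfig(n_iter=50, burn_in=10))
        assert out.nodes == [] and math.isnan(out.acceptance_rate)

    def test_pinned_zero_theta_gives_half_posteriors(self, six_node_network, six_node_labels):
        out = mrf_deng(six_node_network, six_node_labels,
                       McmcConfig(n_iter=4000, burn_in=500, seed=0),
                       theta_override=Theta(0, 0, 0))
        assert np.allclose(out.probabilities, 0.5, atol=3 * math.sqrt(0.25 / 3500))

    def test_matches_enumeration_oracle_at_fixed_theta(self, six_node_network, six_node_labels):
        theta = Theta(-0.5, 0.8, -0.4)
        exact = enumerate_fixed_theta_marginals(six_node_network, six_node_labels, theta)
        out = mrf_deng(six_node_network, six_node_labels,
                       McmcConfig(n_iter=20000, burn_in=2000, seed=1),
                       theta_override=theta)
        assert np.max(np.abs(out.probabilities - exact)) < 0.02

    def test_zero_coupling_posterior_is_sigmoid_alpha_independent_of_topology(self):
        theta = Theta(-1.3, 0.0, 0.0)
        for edges in ([], [("a", "b"), ("b", "c")]):
            net = ProteinNetwork(["a", "b", "c"], edges)
            labels = np.array([POS, NEG, UNKNOWN], dtype=np.int8)
            out = mrf_deng(net, labels, McmcConfig(n_iter=8000, burn_in=1000, seed=2),
                           theta_override=theta)
            assert out.probabilities[0] == pytest.approx(sigmoid(-1.3), abs=0.02)


@pytest.fixture(scope="module")
def small_run(six_node_network, six_node_labels):
    config = McmcConfig(n_iter=400, burn_in=100, seed=5, theta_bounds=(-3, 3))
    return bmrf(six_node_network, six_node_labels, config), config


class TestBmrf:
    def test_posteriors_in_unit_interval(self, small_run):
        out, _ = small_run
        assert np.all((out.probabilities >= 0) & (out.probabilities <= 1))

    def test_only_unknown_nodes_receive_posteriors(self, small_run):
        out, _ = small_run
        assert out.nodes == ["b", "e"]

    def test_archive_grows_by_one_per_iteration(self, small_run):
        out, config = small_run
        assert out.archive.shape[0] == config.z_init_size + config.n_iter

    def test_acceptance_rate_consistent_with_tallies(self, small_run):
        out, config = small_run
        assert out.n_proposed == config.n_iter
        assert out.acceptance_rate == pytest.approx(out.n_accepted / out.n_proposed)

    def test_input_labels_not_mutated(self, six_node_network, six_node_labels):
        before = six_node_labels.copy()
        bmrf(six_node_network, six_node_labels, McmcConfig(n_iter=60, burn_in=10, seed=0))
        assert np.array_equal(six_node_labels, before)

    def test_same_seed_reproduces_run_exactly(self, six_node_network, six_node_labels):
        config = McmcConfig(n_iter=200, burn_in=50, seed=9)
        a = bmrf(six_node_network, six_node_labels, config)
        b = bmrf(six_node_network, six_node_labels, config)
        assert np.array_equal(a.probabilities, b.probabilities)
        assert a.theta_mean == b.theta_mean
        assert a.acceptance_rate == b.acceptance_rate

    def test_requires_an_unknown_node(self, triangle_network):
        with pytest.raises(ValueError):
            bmrf(triangle_network, np.array([POS, NEG, POS], dtype=np.int8),
                 McmcConfig(n_iter=50, burn_in=10))
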