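import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad

import mimevol as mv
from mimevol.mapping import _sample_bridge
from mimevol.mk import mk_transition_matrix


def bridge_expected_events(q01, q10, t, a, b):
    """Conditional mean event count on [0, t] given endpoints, by quadrature."""
    P = lambda s: mk_transition_matrix(q01, q10, s)
    pab = P(t)[a, b]
    total = 0.0
    for i, j, q in [(0, 1, q01), (1, 0, q10)]:
        total += quad(lambda s: P(s)[a, i] * q * P(t - s)[j, b], 0, t)[0]
    return total / pab


class TestPriorSpec:
    def test_prior_mean_is_multiplier_times_whole_tree_rate(self, yule50, yule50_traits):
        traits, _, _ = yule50_traits
        r = mv.whole_tree_symmetric_rate(yule50, traits)
        spec = mv.PriorSpec.from_whole_tree_rate(yule50, traits)
        assert spec.mean == pytest.approx(10.0 * r, rel=1e-9)

    def test_invalid_root_prior_rejected(self):
        with pytest.raises(ValueError):
            mv.PriorSpec(mean=1.0, root_prior=1.5)


class TestMCMC:
    def test_prior_only_recovers_prior_mean(self, yule50, yule50_traits):
        traits, _, model = yule50_traits
        prior = mv.PriorSpec(mean=0.8)
        post = mv.mcmc_rates(
            yule50, traits, model, prior, n_steps=60000, seed=4,
            use_likelihood=False,
        )
        np.testing.assert_allclose(post.mean(), 0.8, rtol=0.05)

    def test_same_seed_identical_chains(self, yule50, yule50_traits):
        traits, _, model = yule50_traits
        prior = mv.PriorSpec.from_whole_tree_rate(yule50, traits)
        a = mv.mcmc_rates(yule50, traits, model, prior, n_steps=2000, seed=9)
        b = mv.mcmc_rates(yule50, traits, model, prior, n_steps=2000, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_acceptance_rate_adapted(self, yule50, yule50_traits):
        traits, _, model = yule50_traits
        prior = mv.PriorSpec.from_whole_tree_rate(yule50, traits)
        post = mv.mcmc_rates(yule50, traits, model, prior, n_steps=8000, seed=5)
        assert 0.1 < post.acceptance_rate < 0.6


class TestBridge:
    @pytest.mark.parametrize(
        "q01,q10,t,a,b",
        [(0.3, 0.6, 2.0, 0, 0), (0.3, 0.6, 2.0, 0, 1), (1.0, 0.2, 3.0, 1, 0)],
    )
    def test_mean_event_count_matches_quadrature(self, q01, q10, t, a, b):
        rng = np.random.default_rng(17)
        counts = [len(_sample_bridge(q01, q10, t, a, b, rng)) for _ in range(10000)]
        se = np.std(counts) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - bridge_expected_events(q01, q10, t, a, b)) < 3 * se

    def test_endpoint_parity(self):
        rng = np.random.default_rng(3)
        for a, b in itertools.product((0, 1), repeat=2):
            ev = _sample_bridge(0.5, 0.7, 2.0, a, b, rng)
            state = a
            for _, s in ev:
                assert s != state
                state = s
            assert state == b

    def test_zero_rate_identical_endpoints(self):
        rng = np.random.default_rng(0)
        assert _sample_bridge(0.0, 0.0, 5.0, 1, 1, rng) == []


class TestStochasticMap:
    def test_maps_condition_on_tips(self, yule50, yule50_traits):
        traits, _, model = yule50_traits
        ens = mv.sample_map_ensemble(yule50, traits, model, n_maps=50, seed=2)
        for cmap in ens.maps:
            cmap.validate()
            assert cmap.tip_states() == traits

    def test_irreversible_model_only_gains(self, yule50):
        model = mv.PartitionModel([mv.RateMatrix2(0.02, 0.0)])
        traits, _ = mv.simulate_discrete_history(yule50, model, 0.0, seed=6)
        if sum(traits.values()) == 0:  # ensure some 1s for the check to bite
            traits[yule50.tip_labels[0]] = 1
        ens = mv.sample_map_ensemble(yule50, traits, model, root=0.0, n_maps=30, seed=3)
        for cmap in ens.maps:
            for ev in cmap.events.values():
                assert all(s == 1 for _, s in ev)

    def test_root_marginal_matches_analytic(self, yule50, yule50_traits):
        traits, _, model = yule50_traits
        target = mv.root_posterior(yule50, traits, model)
        ens = mv.sample_map_ensemble(yule50, traits, model, n_maps=400, seed=8)
        freq1 = np.mean([m.root_state for m in ens.maps])
        se = math.sqrt(max(target[1] * target[0], 1e-6) / 400)
        assert abs(freq1 - target[1]) < 3.5 * se

    def test_expected_total_events_tiny_tree(self):
        # oracle: enumerate endpoint-state posteriors, quadrature per branch
        tree = mv.parse_newick("((A:1.5,B:1):1,C:2):0;")
        model = mv.PartitionModel([mv.RateMatrix2(0.4, 0.7)])
        traits = {"A": 1, "B": 0, "C": 0}
        pi1 = model.matrices[0].stationary_pi1
        P = {
            v: mk_transition_matrix(0.4, 0.7, float(tree.branch_length[v]))
            for v in range(tree.n_nodes)
            if v != tree.root
        }
        tipst = {i: traits[l] for i, l in enumerate(tree.tip_labels)}
        internals = [v for v in range(tree.n_tips, tree.n_nodes)]
        joint = {}
        Z = 0.0
        for combo in itertools.product((0, 1), repeat=len(internals)):
            st = dict(zip(internals, combo))
            st.update(tipst)
            w = (pi1 if st[tree.root] else 1 - pi1)
            for v, Pv in P.items():
                w *= Pv[st[tree.parent[v]], st[v]]
            joint[combo] = w
            Z += w
        expected = 0.0
        for combo, w in joint.items():
            st = dict(zip(internals, combo))
            st.update(tipst)
            for v in P:
                expected += (w / Z) * bridge_expected_events(
                    0.4, 0.7, float(tree.branch_length[v]),
                    st[tree.parent[v]], st[v],
                )
        ens = mv.sample_map_ensemble(tree, traits, model, n_maps=4000, seed=5)
        totals = ens.per_map_totals().sum(axis=1)
        se = np.std(totals) / math.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) < 3 * se


class TestEnsembleSummary:
    def test_tip_time_frequency_equals_observed(self, yule50, yule50_traits):
        traits, _, model = yule50_traits
        ens = mv.sample_map_ensemble(yule50, traits, model, n_maps=20, seed=4)
        summ = mv.summarize_ensemble(ens, n_time=100)
        assert summ.freq_state1[-1] == pytest.approx(
            np.mean(list(traits.values())), abs=1e-12
        )

    def test_gain_loss_parity_per_branch(self, yule50, yule50_traits):
        traits, _, model = yule50_traits
        ens = mv.sample_map_ensemble(yule50, traits, model, n_maps=10, seed=5)
        for cmap in ens.maps:
            states = cmap.node_states()
            for v in range(yule50.n_nodes):
                if v == yule50.root:
                    continue
                g, l = cmap.branch_gain_loss(v)
                assert g - l == states[v] - states[yule50.parent[v]]

    def test_time_grid_has_requested_rows(self, yule50, yule50_traits):
        traits, _, model = yule50_traits
        ens = mv.sample_map_ensemble(yule50, traits, model, n_maps=5, seed=6)
        summ = mv.summarize_ensemble(ens, n_time=1000)
        assert len(summ.times) == 1000
        assert len(summ.freq_state1) == 1000

    def test_shared_times_stable_under_refinement(self, yule50, yule50_traits):
        traits, _, model = yule50_traits
        ens = mv.sample_map_ensemble(yule50, traits, model, n_maps=5, seed=7)
        coarse = mv.summarize_ensemble(ens, n_time=101)
        fine = mv.summarize_ensemble(ens, n_time=201)
        np.testing.assert_allclose(coarse.freq_state1, fine.freq_state1[::2], atol=1e-12)

    def test_credible_map_is_member(self, yule50, yule50_traits):
        traits, _, model = yule50_traits
        ens = mv.sample_map_ensemble(yule50, traits, model, n_maps=25, seed=8)
        summ = mv.summarize_ensemble(ens, n_time=50)
        assert summ.credible_map is ens.maps[summ.credible_map_index]
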