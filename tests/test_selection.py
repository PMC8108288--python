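"""Candidate screening, enumeration, AIC ranking, edge weights, mediation."""

import itertools

import numpy as np
import pytest

from il23net import ode, selection, synthetic
from il23net.ode import Condition, NetworkConfig
from il23net.selection import (
    CandidateEdgeSet,
    edge_weights,
    enumerate_configurations,
    mediation_analysis,
    rank_models,
    screen_candidate_edges,
)


class TestCandidateScreen:
    def test_self_pairs_never_tested(self, noisy_panel, conditions):
        cand = screen_candidate_edges(noisy_panel, conditions)
        assert all(e.source != e.target for e in cand.edges)

    def test_strong_true_edges_admitted_with_correct_sign(self, noisy_panel,
                                                          conditions):
        cand = screen_candidate_edges(noisy_panel, conditions)
        admitted = {(e.source, e.target): e.sign
                    for e in cand.edges if e.admissible}
        assert admitted.get(("IL1B", "IL23")) == 1
        assert admitted.get(("IL10", "IL23")) == -1
        assert admitted.get(("IL10", "IL1A")) == -1
        assert admitted.get(("IFNG", "IL10")) == -1

    def test_null_panel_admission_rate_controlled(self, null_network,
                                                  conditions):
        """FDR control under the global null: admitted fraction stays below
        alpha (with binomial slack) across replicates."""
        admitted = tested = 0
        for rep in range(200):
            spec = synthetic.CohortSpec(
                n_donors=20, conditions=conditions, noise_sd=0.2,
                donor_effect_sd=0.3, seed=3000 + rep,
            )
            panel = synthetic.simulate_cohort_panel(null_network, spec)
            cand = screen_candidate_edges(panel, conditions, alpha=0.05)
            admitted += cand.n_admissible
            tested += len(cand.edges)
        rate = admitted / tested
        assert rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / tested)

    def test_untested_pairs_not_admissible(self, noisy_panel):
        # only two conditions: no perturbation contrast exists at all
        sub_conditions = [c for c in ode.default_condition_panel()
                          if c.name in ("Ctrl", "LPS")]
        panel = noisy_panel[noisy_panel["condition_id"].isin(["Ctrl", "LPS"])]
        cand = screen_candidate_edges(panel, sub_conditions)
        assert cand.n_admissible == 0


class TestEnumeration:
    def test_analytic_count_at_e31(self):
        edges = [(s, t, 1) for s, t in itertools.product(
            ode.ALL_NODES, ode.MODELLED_NODES) if s != t][:31]
        cand = CandidateEdgeSet.from_edges(edges)
        space = enumerate_configurations(cand)
        assert space.n_admissible == 31
        assert space.total_configurations == 2_147_483_647

    def test_single_edge_space(self):
        cand = CandidateEdgeSet.from_edges([("IL10", "IL23", -1)])
        space = enumerate_configurations(cand)
        assert space.total_configurations == 1
        assert [c.edges for c in space] == [frozenset({("IL10", "IL23", -1)})]

    def test_four_edges_fifteen_configs_by_listing(self):
        edges = [("IL10", "IL23", -1), ("IL1B", "IL23", 1),
                 ("TNF", "IL6", 1), ("IL6", "IL10", 1)]
        space = enumerate_configurations(CandidateEdgeSet.from_edges(edges))
        listed = list(space)
        assert space.total_configurations == 15 == len(listed)
        assert len({c.edges for c in listed}) == 15

    @pytest.mark.parametrize("E", [1, 2, 5, 8, 12])
    def test_count_matches_explicit_subset_listing(self, E):
        pool = [(s, t, 1) for s, t in itertools.product(
            ode.ALL_NODES, ode.MODELLED_NODES) if s != t][:E]
        space = enumerate_configurations(CandidateEdgeSet.from_edges(pool))
        explicit = sum(
            1 for r in range(1, E + 1)
            for _ in itertools.combinations(pool, r)
        )
        assert space.total_configurations == 2**E - 1 == explicit
        assert sum(1 for _ in space) == explicit

    def test_mandatory_edges_always_present(self):
        edges = [("IL10", "IL23", -1), ("IL1B", "IL23", 1), ("TNF", "IL6", 1)]
        cand = CandidateEdgeSet.from_edges(edges, mandatory=[("IL10", "IL23", -1)])
        space = enumerate_configurations(cand)
        configs = list(space)
        assert space.total_configurations == 4 == len(configs)
        assert all(("IL10", "IL23", -1) in c.edges for c in configs)

    def test_max_edges_filter(self):
        edges = [(s, t, 1) for s, t in itertools.product(
            ode.ALL_NODES, ode.MODELLED_NODES) if s != t][:6]
        space = enumerate_configurations(CandidateEdgeSet.from_edges(edges),
                                         max_edges=2)
        configs = list(space)
        assert len(configs) == 6 + 15 == space.total_configurations
        assert all(len(c) <= 2 for c in configs)

    def test_refuses_blowup_iteration_but_still_counts(self):
        edges = [(s, t, 1) for s, t in itertools.product(
            ode.ALL_NODES, ode.MODELLED_NODES) if s != t][:31]
        space = enumerate_configurations(CandidateEdgeSet.from_edges(edges))
        assert space.total_configurations == 2**31 - 1
        with pytest.raises(ValueError, match="refusing"):
            next(iter(space))


def make_decoys(rng, true_edges, n=4):
    """Random admissible decoy edges disjoint from the true ordered pairs."""
    true_pairs = {(s, t) for s, t, *_ in true_edges}
    pool = [(s, t) for s in ode.ALL_NODES for t in ode.MODELLED_NODES
            if s != t and (s, t) not in true_pairs]
    idx = rng.choice(len(pool), size=n, replace=False)
    return [(pool[i][0], pool[i][1], int(rng.choice([1, -1]))) for i in idx]


class TestRankModels:
    def test_exhaustive_recovers_true_config_on_noiseless_panel(
        self, ground_truth, conditions, noiseless_panel
    ):
        rng = np.random.default_rng(0)
        true_edges = sorted(ground_truth.config().edges)
        cand = CandidateEdgeSet.from_edges(
            true_edges + make_decoys(rng, true_edges, n=2))
        rank = rank_models(cand, noiseless_panel, conditions)
        assert rank.best.config.edges == ground_truth.config().edges
        assert rank.table()["delta_aic"].iloc[0] == 0.0
        assert (rank.table()["delta_aic"] >= 0).all()

    def test_noise_candidates_rarely_displace_best_config(
        self, ground_truth, conditions
    ):
        """Adding pure-noise candidate edges leaves the best configuration
        unchanged in most replicates at moderate noise."""
        true_edges = sorted(ground_truth.config().edges)
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            panel = synthetic.simulate_cohort_panel(
                ground_truth,
                synthetic.CohortSpec(n_donors=20, conditions=conditions,
                                     noise_sd=0.1, donor_effect_sd=0.2,
                                     seed=500 + rep),
            )
            cand = CandidateEdgeSet.from_edges(
                true_edges + make_decoys(rng, true_edges, n=2))
            rank = rank_models(cand, panel, conditions)
            hits += rank.best.config.edges == ground_truth.config().edges
        assert hits >= 0.8 * n_rep

    def test_greedy_agrees_with_exhaustive_at_low_noise(
        self, ground_truth, conditions, noiseless_panel
    ):
        rng = np.random.default_rng(7)
        true_edges = sorted(ground_truth.config().edges)
        cand = CandidateEdgeSet.from_edges(
            true_edges + make_decoys(rng, true_edges, n=2))
        ex = rank_models(cand, noiseless_panel, conditions, search="exhaustive")
        gr = rank_models(cand, noiseless_panel, conditions, search="greedy")
        assert ex.best.config.edges == gr.best.config.edges


class TestEdgeWeights:
    def test_single_edge_weight_is_one(self, conditions):
        net = synthetic.GroundTruthNetwork(
            edges=[("IL10", "IL23", -1, 8.0)],
            basal=synthetic.default_ground_truth().basal,
            stimulated=synthetic.default_ground_truth().stimulated,
        )
        panel = synthetic.simulate_cohort_panel(
            net, synthetic.CohortSpec(n_donors=4, conditions=conditions,
                                      noise_sd=0.0, donor_effect_sd=0.0))
        w = edge_weights(net.config(), panel, conditions)
        assert w == {("IL10", "IL23", -1): 1.0}

    def test_weights_sum_to_one_and_strong_edge_dominates(self, conditions):
        """One strong and one near-zero planted edge: the strong edge takes
        nearly all of the fit contribution."""
        gt = synthetic.default_ground_truth()
        net = synthetic.GroundTruthNetwork(
            edges=[("IL1B", "IL23", 1, 20.0), ("TNF", "IL6", 1, 0.001)],
            basal=gt.basal, stimulated=gt.stimulated,
        )
        panel = synthetic.simulate_cohort_panel(
            net, synthetic.CohortSpec(n_donors=4, conditions=conditions,
                                      noise_sd=0.0, donor_effect_sd=0.0))
        w = edge_weights(net.config(), panel, conditions)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)
        assert w[("IL1B", "IL23", 1)] > 0.8

    def test_weights_invariant_to_node_relabelling(self, conditions):
        """Swapping the roles of two interchangeable nodes permutes, but
        does not change, the weight values."""
        gt = synthetic.default_ground_truth()
        basal = dict(gt.basal)
        stim = dict(gt.stimulated)
        # make TNF and IL6 statistically identical so relabelling is a symmetry
        basal["TNF"] = basal["IL6"] = 2.0
        stim["TNF"] = stim["IL6"] = 400.0
        for a, b in ((("TNF", "IL23", 1, 5.0), ("IL6", "IL1A", 1, 3.0)),):
            net1 = synthetic.GroundTruthNetwork(edges=[a, b], basal=basal,
                                                stimulated=stim)
            swapped = [("IL6", "IL23", 1, 5.0), ("TNF", "IL1A", 1, 3.0)]
            net2 = synthetic.GroundTruthNetwork(edges=swapped, basal=basal,
                                                stimulated=stim)
            p1 = synthetic.simulate_cohort_panel(
                net1, synthetic.CohortSpec(n_donors=4, conditions=conditions,
                                           noise_sd=0.0, donor_effect_sd=0.0))
            p2 = synthetic.simulate_cohort_panel(
                net2, synthetic.CohortSpec(n_donors=4, conditions=conditions,
                                           noise_sd=0.0, donor_effect_sd=0.0))
            w1 = edge_weights(net1.config(), p1, conditions)
            w2 = edge_weights(net2.config(), p2, conditions)
            assert w1[("TNF", "IL23", 1)] == pytest.approx(
                w2[("IL6", "IL23", 1)], abs=1e-6)
            assert w1[("IL6", "IL1A", 1)] == pytest.approx(
                w2[("TNF", "IL1A", 1)], abs=1e-6)


class TestMediation:
    def test_mediator_without_path_to_target_mediates_nothing(self):
        gt = synthetic.default_ground_truth()
        cfg = NetworkConfig({("IFNG", "IL10", -1), ("IL1B", "IL23", 1)})
        params = gt.params()
        res = mediation_analysis(
            cfg, params,
            baseline=Condition("LPS", stimulus="LPS"),
            perturbed=Condition("LPS+IFNG", stimulus="LPS",
                                additions=(("IFNG", 1e4),)),
            target="IL23", mediator="IL10",
        )
        # IL-10 has no edge into IL-23 here: clamping it changes nothing
        assert res.mediated_effect == pytest.approx(0.0, abs=1e-6)

    def test_fully_mediated_effect_vanishes_under_clamp(self, ground_truth):
        """IFN-g reaches IL-1a only through IL-10 suppression: clamping
        IL-10 removes essentially the whole effect."""
        cfg, params = ground_truth.config(), ground_truth.params()
        res = mediation_analysis(
            cfg, params,
            baseline=Condition("LPS", stimulus="LPS"),
            perturbed=Condition("LPS+IFNG", stimulus="LPS",
                                additions=(("IFNG", 1e4),)),
            target="IL1A", mediator="IL10",
        )
        assert res.total_effect > 0  # IFN-g amplifies IL-1a
        assert abs(res.direct_effect) < 0.1 * abs(res.total_effect)

    def test_direct_effect_survives_clamp_with_direct_edge(self):
        """With a direct IFN-g -> IL-23 edge alongside IFN-g -| IL-10,
        most of the IL-23 amplification is IL-10-independent."""
        gt = synthetic.default_ground_truth()
        edges = [("IL10", "IL23", -1, 8.0), ("IL1B", "IL23", 1, 20.0),
                 ("IL10", "IL1A", -1, 4.0), ("IFNG", "IL10", -1, 1.0),
                 ("IFNG", "IL23", 1, 6.0)]
        net = synthetic.GroundTruthNetwork(edges=edges, basal=gt.basal,
                                           stimulated=gt.stimulated)
        res = mediation_analysis(
            net.config(), net.params(),
            baseline=Condition("LPS", stimulus="LPS"),
            perturbed=Condition("LPS+IFNG", stimulus="LPS",
                                additions=(("IFNG", 1e4),)),
            target="IL23", mediator="IL10",
        )
        assert res.total_effect > 0
        assert res.direct_effect > 0.5 * res.total_effect

    def test_clamping_the_perturbed_node_rejected(self, ground_truth):
        with pytest.raises(ValueError, match="clamp"):
            mediation_analysis(
                ground_truth.config(), ground_truth.params(),
                baseline=Condition("LPS", stimulus="LPS"),
                perturbed=Condition("LPS+IL10", stimulus="LPS",
                                    additions=(("IL10", 1e4),)),
                target="IL23", mediator="IL10",
            )
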