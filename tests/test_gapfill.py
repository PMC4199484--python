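import pytest

from likfill.exceptions import InfeasibleError, ValidationError
from likfill.fba import apply_media, run_fba, run_fva
from likfill.fixtures import make_small_gapfill_instance, remove_reactions
from likfill.gapfill import (GapfillCosts, Penalties, attach_candidate_gprs,
                             complete_media, compute_costs, gapfill_target,
                             integrate_solution)
from likfill.likelihood import ReactionLikelihoods
from likfill.model_core import (GprExpression, Media, MetabolicModel,
                                Metabolite, Reaction)

from .oracles import enumerate_gapfill


def rxn(rxn_id, stoich, **kw):
    defaults = dict(lower_bound=0.0, upper_bound=1000.0)
    defaults.update(kw)
    return Reaction(rxn_id, stoich, **defaults)


def lik(mapping):
    return ReactionLikelihoods(entries={
        k: (v, GprExpression.empty()) for k, v in mapping.items()})


class TestPenalties:
    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            Penalties(transporter=-1.0)

    def test_direction_surcharge_unknown(self):
        assert Penalties().direction_surcharge(None) == pytest.approx(1.2)

    def test_direction_surcharge_at_10(self):
        assert Penalties().direction_surcharge(10.0) == pytest.approx(3.2)

    def test_negative_opposing_clipped(self):
        assert Penalties().direction_surcharge(-4.0) == pytest.approx(1.2)


class TestComputeCosts:
    def intracellular(self, **kw):
        return rxn("x", {"a_c": -1.0, "b_c": 1.0}, **kw)

    def test_zero_likelihood_favorable(self):
        costs = compute_costs.__wrapped__ if False else None
        c = GapfillCosts(mode="likelihood", penalties=Penalties(),
                         likelihoods=lik({"x": 0.0}))
        assert c.addition_cost(self.intracellular(), "forward") == \
            pytest.approx(1.0)

    def test_high_likelihood_scales_base(self):
        c = GapfillCosts(mode="likelihood", penalties=Penalties(),
                         likelihoods=lik({"x": 0.9}))
        assert c.addition_cost(self.intracellular(), "forward") == \
            pytest.approx(0.1)

    def test_transporter_penalty(self):
        c = GapfillCosts(mode="likelihood", penalties=Penalties(),
                         likelihoods=lik({}))
        t = rxn("x", {"a_e": -1.0, "a_c": 1.0}, is_transporter=True)
        assert c.addition_cost(t, "forward") == pytest.approx(26.0)

    def test_unfavorable_direction_surcharge(self):
        c = GapfillCosts(mode="likelihood", penalties=Penalties(),
                         likelihoods=lik({}))
        r = self.intracellular(delta_g=10.0)
        assert c.addition_cost(r, "forward") == pytest.approx(1.0 + 3.2)
        assert c.addition_cost(r, "reverse") == pytest.approx(1.0)

    def test_surcharge_not_likelihood_scaled(self):
        c = GapfillCosts(mode="likelihood", penalties=Penalties(),
                         likelihoods=lik({"x": 0.9}))
        r = self.intracellular(delta_g=10.0)
        assert c.addition_cost(r, "forward") == pytest.approx(0.1 + 3.2)

    def test_low_confidence_penalty(self):
        c = GapfillCosts(mode="parsimony", penalties=Penalties())
        r = self.intracellular(source_confidence="low")
        assert c.addition_cost(r, "forward") == pytest.approx(6.0)

    def test_reversal_cost_identical_across_modes(self):
        r = self.intracellular(delta_g=-5.0)
        for mode, rl in (("parsimony", None), ("likelihood", lik({"x": 0.9}))):
            c = GapfillCosts(mode=mode, penalties=Penalties(), likelihoods=rl)
            # reverse of a deltaG=-5 reaction: U = (12+10)/10 = 2.2
            assert c.reversal_cost(r, "reverse") == \
                pytest.approx(12.0 * 2.2 / 1.2)

    def test_reversal_cost_unknown_delta_g(self):
        c = GapfillCosts(mode="parsimony", penalties=Penalties())
        assert c.reversal_cost(self.intracellular(), "reverse") == \
            pytest.approx(12.0)

    def test_likelihood_mode_requires_likelihoods(self, universe):
        with pytest.raises(ValidationError):
            compute_costs(universe.universal, universe.gold_model, None,
                          mode="likelihood")


class TestCompleteMedia:
    def test_transported_compounds_listed(self, universe):
        media = complete_media(universe.gold_model)
        assert set(media.uptake_limits) == {"glc_e", "nh4_e", "u_e"}
        assert all(v == 100.0 for v in media.uptake_limits.values())

    def test_no_transporters_empty(self):
        mets = [Metabolite("a_c")]
        m = MetabolicModel("m", mets, [rxn("bio", {"a_c": -1.0})], "bio")
        assert complete_media(m).uptake_limits == {}


class TestGapfillTarget:
    def test_already_active_returns_empty(self, universe, draft):
        media = complete_media(draft)
        costs = compute_costs(universe.universal, draft, None,
                              mode="parsimony")
        sol = gapfill_target(draft, universe.universal, costs, "bio1", media)
        assert sol.is_empty()
        assert sol.objective_value == 0.0

    def test_two_pathway_parsimony(self, universe, two_pathway_draft):
        media = complete_media(two_pathway_draft)
        costs = compute_costs(universe.universal, two_pathway_draft, None,
                              mode="parsimony")
        sol = gapfill_target(two_pathway_draft, universe.universal, costs,
                             "bio1", media)
        assert sorted(a.reaction.id for a in sol.added) == ["S1", "S2"]
        assert sol.objective_value == pytest.approx(2.0, abs=1e-6)

    def test_two_pathway_likelihood(self, universe, two_pathway_draft,
                                    reaction_likelihoods):
        media = complete_media(two_pathway_draft)
        costs = compute_costs(universe.universal, two_pathway_draft,
                              reaction_likelihoods, mode="likelihood")
        sol = gapfill_target(two_pathway_draft, universe.universal, costs,
                             "bio1", media)
        assert sorted(a.reaction.id for a in sol.added) == \
            ["L1", "L2", "L3", "L4"]
        assert sol.objective_value == pytest.approx(0.4, abs=1e-6)

    def test_objective_equals_item_costs(self, universe, two_pathway_draft,
                                         reaction_likelihoods):
        media = complete_media(two_pathway_draft)
        costs = compute_costs(universe.universal, two_pathway_draft,
                              reaction_likelihoods, mode="likelihood")
        sol = gapfill_target(two_pathway_draft, universe.universal, costs,
                             "bio1", media)
        assert sol.objective_value == pytest.approx(
            sum(a.cost for a in sol.added)
            + sum(r.cost for r in sol.reversibility_changes), abs=1e-6)

    def test_missing_target_raises(self, universe, draft):
        costs = compute_costs(universe.universal, draft, None,
                              mode="parsimony")
        with pytest.raises(ValidationError):
            gapfill_target(draft, universe.universal, costs, "nope",
                           complete_media(draft))

    def test_unfillable_precursor_infeasible(self):
        mets = [Metabolite("q_c"), Metabolite("z_c")]
        draft = MetabolicModel(
            "d", mets, [rxn("bio", {"q_c": -1.0})], "bio")
        universal = MetabolicModel(
            "u", mets,
            [rxn("bio", {"q_c": -1.0}), rxn("rz", {"z_c": -1.0})], "bio")
        costs = compute_costs(universal, draft, None, mode="parsimony")
        with pytest.raises(InfeasibleError):
            gapfill_target(draft, universal, costs, "bio",
                           Media("none", {}))

    def test_reversibility_change_used_when_cheapest(self):
        # b_c producible only by reversing the irreversible drain R_drain.
        mets = [Metabolite("s_e", compartment="e"), Metabolite("b_c")]
        draft = MetabolicModel("d", mets, [
            rxn("EX_s_e", {"s_e": -1.0}),
            rxn("R_drain", {"b_c": -1.0, "s_e": 1.0}, is_transporter=True),
            rxn("bio", {"b_c": -1.0}),
        ], "bio")
        universal = MetabolicModel("u", mets, [rxn("bio", {"b_c": -1.0})],
                                   "bio")
        costs = compute_costs(universal, draft, None, mode="parsimony")
        sol = gapfill_target(draft, universal, costs, "bio",
                             Media("s", {"s_e": 10.0}))
        assert [r.reaction_id for r in sol.reversibility_changes] == \
            ["R_drain"]
        assert sol.objective_value == pytest.approx(12.0, abs=1e-6)

    def test_mode_degeneration_with_zero_likelihoods(self, universe,
                                                     two_pathway_draft):
        media = complete_media(two_pathway_draft)
        zero = lik({r.id: 0.0 for r in universe.universal.reactions})
        pars = compute_costs(universe.universal, two_pathway_draft, None,
                             mode="parsimony")
        like = compute_costs(universe.universal, two_pathway_draft, zero,
                             mode="likelihood")
        sol_p = gapfill_target(two_pathway_draft, universe.universal, pars,
                               "bio1", media)
        sol_l = gapfill_target(two_pathway_draft, universe.universal, like,
                               "bio1", media)
        assert sol_p.objective_value == pytest.approx(sol_l.objective_value,
                                                      abs=1e-6)


class TestIntegrateSolution:
    def test_empty_solution_identity(self, universe, draft):
        media = complete_media(draft)
        costs = compute_costs(universe.universal, draft, None,
                              mode="parsimony")
        sol = gapfill_target(draft, universe.universal, costs, "bio1", media)
        assert integrate_solution(draft, sol) == draft

    def test_integration_activates_target(self, universe, two_pathway_draft,
                                          reaction_likelihoods):
        media = complete_media(two_pathway_draft)
        costs = compute_costs(universe.universal, two_pathway_draft,
                              reaction_likelihoods, mode="likelihood")
        sol = gapfill_target(two_pathway_draft, universe.universal, costs,
                             "bio1", media)
        model = integrate_solution(two_pathway_draft, sol,
                                   rxn_lik=reaction_likelihoods,
                                   universal=universe.universal)
        growth = run_fba(apply_media(model, media))
        assert growth.objective_value > 1e-9

    def test_target_no_longer_inactive(self, universe, two_pathway_draft,
                                       reaction_likelihoods):
        from likfill.fba import find_inactive_reactions
        media = complete_media(two_pathway_draft)
        costs = compute_costs(universe.universal, two_pathway_draft,
                              reaction_likelihoods, mode="likelihood")
        sol = gapfill_target(two_pathway_draft, universe.universal, costs,
                             "bio1", media)
        model = integrate_solution(two_pathway_draft, sol,
                                   rxn_lik=reaction_likelihoods,
                                   universal=universe.universal)
        assert "bio1" not in find_inactive_reactions(model, media)

    def test_likelihood_mode_attaches_gprs(self, universe, two_pathway_draft,
                                           reaction_likelihoods):
        media = complete_media(two_pathway_draft)
        costs = compute_costs(universe.universal, two_pathway_draft,
                              reaction_likelihoods, mode="likelihood")
        sol = gapfill_target(two_pathway_draft, universe.universal, costs,
                             "bio1", media)
        model = integrate_solution(two_pathway_draft, sol,
                                   rxn_lik=reaction_likelihoods,
                                   universal=universe.universal)
        assert model.reaction("L1").gpr.to_string() == "gL1"

    def test_parsimony_then_gpr_postprocessing(self, universe,
                                               two_pathway_draft,
                                               reaction_likelihoods):
        media = complete_media(two_pathway_draft)
        costs = compute_costs(universe.universal, two_pathway_draft, None,
                              mode="parsimony")
        sol = gapfill_target(two_pathway_draft, universe.universal, costs,
                             "bio1", media)
        model = integrate_solution(two_pathway_draft, sol,
                                   universal=universe.universal)
        added = {a.reaction.id for a in sol.added}
        assert all(model.reaction(r).gpr.is_empty() for r in added)
        post = attach_candidate_gprs(model, reaction_likelihoods,
                                     only_ids=added)
        # S-path reactions have p=0, so no rules appear even after
        # post-processing; the reaction set is unchanged.
        assert post.reaction_ids == model.reaction_ids
        for r in added:
            expected_empty = reaction_likelihoods.p(r) == 0
            assert post.reaction(r).gpr.is_empty() == expected_empty


# ---------------------------------------------------------------------------
# MILP vs exhaustive enumeration
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("mode", ["parsimony", "likelihood"])
def test_milp_matches_enumeration(seed, mode):
    inst = make_small_gapfill_instance(seed)
    rl = inst.likelihoods if mode == "likelihood" else None
    best_cost, _ = enumerate_gapfill(inst.draft, inst.universal, inst.target,
                                     inst.media, mode, rl)
    costs = compute_costs(inst.universal, inst.draft, rl, mode=mode)
    if best_cost is None:
        with pytest.raises(InfeasibleError):
            gapfill_target(inst.draft, inst.universal, costs, inst.target,
                           inst.media, time_limit=30)
    else:
        sol = gapfill_target(inst.draft, inst.universal, costs, inst.target,
                             inst.media, time_limit=30)
        assert sol.objective_value == pytest.approx(best_cost, abs=1e-6)
        model = integrate_solution(inst.draft, sol, rxn_lik=rl,
                                   universal=inst.universal)
        fva = run_fva(apply_media(model, inst.media), [inst.target])
        assert fva[inst.target][1] >= 1e-5 - 1e-9


def test_monotonicity_cheaper_pathway_never_costlier(universe,
                                                     two_pathway_draft,
                                                     reaction_likelihoods):
    """Raising p on the long path (short fixed) can only lower its cost."""
    media = complete_media(two_pathway_draft)
    entries = {r: (p, g) for r, (p, g)
               in reaction_likelihoods.entries.items()}
    for r in universe.long_path_ids:
        p, g = entries[r]
        entries[r] = (min(p + 0.05, 0.99), g)
    boosted = ReactionLikelihoods(entries=entries)
    base_costs = compute_costs(universe.universal, two_pathway_draft,
                               reaction_likelihoods, mode="likelihood")
    boosted_costs = compute_costs(universe.universal, two_pathway_draft,
                                  boosted, mode="likelihood")
    base_total = sum(base_costs.addition[(r, "forward")]
                     for r in universe.long_path_ids)
    boosted_total = sum(boosted_costs.addition[(r, "forward")]
                        for r in universe.long_path_ids)
    assert boosted_total <= base_total
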