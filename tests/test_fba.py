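"""Flux balance analysis: LP solutions, GPR logic, knockouts, media."""

import numpy as np
import pytest

from promispred.fba import (
    MetabolicModel,
    add_reaction,
    apply_medium,
    essentiality_class,
    evaluate_gpr,
    fba,
    knockout_genes,
)
from promispred.io import ReactionDefinition

R = ReactionDefinition


def chain_model(internal_cap=1000.0):
    """EX_A(<=10 uptake) -> A -> B -> biomass, all 1:1."""
    return MetabolicModel(
        reactions=[
            R("EX_A", {"A": -1.0}, -10.0, 1000.0),
            R("T1", {"A": -1.0, "B": 1.0}, 0.0, internal_cap, gpr="g1"),
            R("BIOMASS", {"B": -1.0}, 0.0, 1000.0),
        ],
        biomass_reaction="BIOMASS",
        media={"M9": {"EX_A": 10.0}, "rich": {"EX_A": 10.0}},
    )


class TestFba:
    def test_linear_chain_objective_equals_uptake(self):
        assert fba(chain_model()).objective == pytest.approx(10.0, abs=1e-9)

    def test_internal_cap_limits_objective(self):
        assert fba(chain_model(4.0)).objective == pytest.approx(4.0, abs=1e-9)

    def test_unproducible_biomass_precursor_gives_zero(self):
        m = MetabolicModel(
            reactions=[
                R("EX_A", {"A": -1.0}, -10.0, 1000.0),
                R("BIOMASS", {"A": -1.0, "Z": -1.0}, 0.0, 1000.0),
            ],
            biomass_reaction="BIOMASS",
            media={"M9": {"EX_A": 10.0}},
        )
        assert fba(m).objective == pytest.approx(0.0, abs=1e-9)

    def test_branched_routes_add_their_capacities(self):
        m = MetabolicModel(
            reactions=[
                R("EX_A", {"A": -1.0}, -10.0, 1000.0),
                R("T1", {"A": -1.0, "B": 1.0}, 0.0, 3.0),
                R("T2", {"A": -1.0, "B": 1.0}, 0.0, 4.0),
                R("BIOMASS", {"B": -1.0}, 0.0, 1000.0),
            ],
            biomass_reaction="BIOMASS",
            media={"M9": {"EX_A": 10.0}},
        )
        assert fba(m).objective == pytest.approx(7.0, abs=1e-9)

    def test_stoichiometric_yield_doubles_objective(self):
        m = MetabolicModel(
            reactions=[
                R("EX_A", {"A": -1.0}, -10.0, 1000.0),
                R("SPLIT", {"A": -1.0, "B": 2.0}, 0.0, 1000.0),
                R("BIOMASS", {"B": -1.0}, 0.0, 1000.0),
            ],
            biomass_reaction="BIOMASS",
            media={"M9": {"EX_A": 10.0}},
        )
        assert fba(m).objective == pytest.approx(20.0, abs=1e-9)

    def test_unbounded_objective_raises(self):
        m = MetabolicModel(
            reactions=[
                R("EX_A", {"A": -1.0}, -np.inf, np.inf),
                R("BIOMASS", {"A": -1.0}, 0.0, np.inf),
            ],
            biomass_reaction="BIOMASS",
            media={"M9": {}},
        )
        with pytest.raises(RuntimeError, match="unbounded"):
            fba(m)

    def test_optimal_solutions_satisfy_mass_balance(self, toy_gem):
        for medium in ("M9", "rich"):
            m = apply_medium(toy_gem.model, medium)
            sol = fba(m)
            S, _ = m.stoichiometric_matrix()
            v = np.array([sol.fluxes[r] for r in m.reaction_ids])
            assert np.abs(S @ v).max() <= 1e-9


class TestGpr:
    @pytest.mark.parametrize(
        "gpr,knocked,expected",
        [
            ("g1 and g2", {"g1"}, False),
            ("g1 and g2", set(), True),
            ("g1 or g2", {"g1"}, True),
            ("g1 or g2", {"g1", "g2"}, False),
            ("(g1 and g2) or g3", {"g1", "g3"}, False),
            ("(g1 and g2) or g3", {"g2"}, True),
            ("(g1 or g2) and (g3 or g4)", {"g1", "g3"}, True),
            ("(g1 or g2) and (g3 or g4)", {"g3", "g4"}, False),
            ("", {"g1"}, True),
            ("G1 AND g2", {"g2"}, False),  # keywords case-insensitive
        ],
    )
    def test_truth_table(self, gpr, knocked, expected):
        assert evaluate_gpr(gpr, knocked) is expected

    def test_unknown_gene_treated_as_present(self):
        assert evaluate_gpr("mystery_gene", {"g1"}) is True

    def test_malformed_expression_rejected(self):
        with pytest.raises(ValueError):
            evaluate_gpr("g1 and", set())


class TestKnockout:
    def test_and_rule_closes_reaction(self):
        m = knockout_genes(chain_model(), {"g1"})
        r = m.reaction("T1")
        assert (r.lower_bound, r.upper_bound) == (0.0, 0.0)
        assert fba(m).objective == pytest.approx(0.0, abs=1e-9)

    def test_empty_knockout_is_identity(self):
        m = chain_model()
        m2 = knockout_genes(m, set())
        assert [
            (r.lower_bound, r.upper_bound) for r in m2.reactions
        ] == [(r.lower_bound, r.upper_bound) for r in m.reactions]

    def test_knockouts_commute(self, toy_gem):
        m = toy_gem.model
        a = knockout_genes(knockout_genes(m, {"eco_g06"}), {"eco_g08"})
        b = knockout_genes(m, {"eco_g08", "eco_g06"})
        assert [
            (r.lower_bound, r.upper_bound) for r in a.reactions
        ] == [(r.lower_bound, r.upper_bound) for r in b.reactions]


class TestMedium:
    def test_unknown_medium_rejected(self, toy_gem):
        with pytest.raises(KeyError, match="unknown medium"):
            apply_medium(toy_gem.model, "broth")

    def test_unlisted_exchanges_closed(self, toy_gem):
        m9 = apply_medium(toy_gem.model, "M9")
        assert m9.reaction("EX_vit").lower_bound == 0.0
        assert m9.reaction("EX_glc").lower_bound == -10.0

    def test_idempotent(self, toy_gem):
        once = apply_medium(toy_gem.model, "M9")
        twice = apply_medium(once, "M9")
        assert [
            (r.lower_bound, r.upper_bound) for r in once.reactions
        ] == [(r.lower_bound, r.upper_bound) for r in twice.reactions]


class TestEssentiality:
    def test_sole_vitamin_route_is_conditionally_essential(self, toy_gem):
        assert (
            essentiality_class(toy_gem.model, "eco_g06")
            == "conditionally_essential"
        )

    def test_redundant_gene_is_nonessential(self, toy_gem):
        # the vitamin transporter is idle on M9 and redundant on rich
        assert essentiality_class(toy_gem.model, "eco_g08") == "nonessential"

    def test_sole_carbon_uptake_is_always_essential(self, toy_gem):
        assert essentiality_class(toy_gem.model, "eco_g07") == "always_essential"

    def test_infeasible_wild_type_baseline_raises(self, toy_gem):
        m = toy_gem.model.copy()
        m.media["M9"] = {}
        with pytest.raises(RuntimeError, match="baseline"):
            essentiality_class(m, "eco_g06")

    def test_invariant_to_reaction_order(self, toy_gem):
        m = toy_gem.model.copy()
        m.reactions = list(reversed(m.reactions))
        assert (
            essentiality_class(m, "eco_g06") == "conditionally_essential"
        )


class TestAddReaction:
    def test_zero_bounded_addition_leaves_objective_unchanged(self):
        m = chain_model()
        m2 = add_reaction(m, R("DEAD", {"A": -1.0, "B": 1.0}, 0.0, 0.0))
        assert fba(m2).objective == pytest.approx(fba(m).objective, abs=1e-9)

    def test_bypass_restores_broken_chain(self):
        broken = knockout_genes(chain_model(), {"g1"})
        fixed = add_reaction(broken, R("BYPASS", {"A": -1.0, "B": 1.0}))
        assert fba(fixed).objective == pytest.approx(10.0, abs=1e-9)

    def test_duplicate_reaction_gets_fresh_id_and_changes_nothing(self):
        m = chain_model()
        m2 = add_reaction(m, m.reaction("T1"))
        assert len(m2.reactions) == 4
        assert "T1_added1" in m2.reaction_ids
        assert fba(m2).objective == pytest.approx(10.0, abs=1e-9)

    def test_unknown_metabolites_listed_in_error(self):
        with pytest.raises(ValueError, match="ghost"):
            add_reaction(chain_model(), R("BAD", {"ghost": 1.0}))

    def test_original_model_unchanged(self):
        m = chain_model()
        add_reaction(m, R("NEW", {"A": -1.0, "B": 1.0}))
        assert len(m.reactions) == 3

    def test_superset_monotonicity_over_random_draws(self):
        """Adding any reaction can only enlarge the feasible region."""
        rng = np.random.default_rng(42)
        mets = ["A", "B", "C", "D"]
        for _ in range(100):
            n_rxn = rng.integers(2, 5)
            reactions = [R("EX_A", {"A": -1.0}, -10.0, 1000.0)]
            for i in range(n_rxn):
                picks = rng.choice(4, size=2, replace=False)
                reactions.append(
                    R(
                        f"r{i}",
                        {mets[picks[0]]: -1.0, mets[picks[1]]: 1.0},
                        0.0,
                        float(rng.integers(0, 20)),
                    )
                )
            reactions.append(R("BIOMASS", {mets[rng.integers(0, 4)]: -1.0}))
            m = MetabolicModel(
                reactions=reactions,
                biomass_reaction="BIOMASS",
                media={"M9": {"EX_A": 10.0}},
                metabolites=list(mets),
            )
            picks = rng.choice(4, size=2, replace=False)
            extra = R(
                "extra",
                {mets[picks[0]]: -1.0, mets[picks[1]]: 1.0},
                0.0,
                float(rng.integers(0, 20)),
            )
            assert (
                fba(add_reaction(m, extra)).objective
                >= fba(m).objective - 1e-9
            )
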