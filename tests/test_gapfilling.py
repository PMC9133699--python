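"""Weighted-pFBA gap filling vs a brute-force subset oracle."""

import itertools

import pytest

from besflux import synthetic_models as sm
from besflux.gapfilling import (
    UnfillableGapError,
    UniversalDB,
    UniversalReaction,
    add_universal_reactions,
    find_unproducible_targets,
    gapfill_all,
    gapfill_substrate,
    gapfill_target,
    parse_equation,
)
from besflux.lp_engine import fba
from besflux.model_core import (
    GLOBAL_BOUND,
    add_exchange,
    add_metabolite,
    add_reaction,
    new_model,
)


def brute_force_minimal_sets(model, universal, target, epsilon=1e-3,
                             max_size=None):
    """Independent oracle: enumerate universal subsets by increasing
    cardinality; return every minimum-cardinality subset that restores
    target producibility."""
    ids = [r.id for r in universal.reactions]
    max_size = len(ids) if max_size is None else max_size

    def feasible(subset):
        work = model.copy()
        from besflux.gapfilling import _resolve_target

        rid = _resolve_target(work, target)
        add_universal_reactions(work, universal.subset(subset))
        state = fba(work, rid, "max")
        return state.ok and state.objective_value >= epsilon

    for size in range(0, max_size + 1):
        hits = [set(c) for c in itertools.combinations(ids, size) if feasible(c)]
        if hits:
            return hits
    return []


class TestEquationParsing:
    @pytest.mark.parametrize("eq,stoich,rev", [
        ("2 A + B -> C", {"A": -2, "B": 1 - 2, "C": 1}, False),
        ("A <-> B", {"A": -1, "B": 1}, True),
        ("A + 0.5 O2 => B", {"A": -1, "O2": -0.5, "B": 1}, False),
    ])
    def test_parse(self, eq, stoich, rev):
        got, reversible = parse_equation(eq)
        if eq.startswith("2 A"):
            stoich = {"A": -2, "B": -1, "C": 1}
        assert got == stoich and reversible == rev

    def test_no_arrow_rejected(self):
        with pytest.raises(ValueError):
            parse_equation("A + B")

    def test_duplicate_ids_rejected(self):
        r = UniversalReaction("U1", {"a": -1, "b": 1})
        with pytest.raises(ValueError, match="duplicate"):
            UniversalDB([r, UniversalReaction("U1", {"c": -1, "d": 1})])

    @pytest.mark.parametrize("via", ["tsv", "json"])
    def test_db_file_round_trip(self, tmp_path, via):
        if via == "tsv":
            path = tmp_path / "u.tsv"
            path.write_text("id\tequation\tlb\tub\tsource\n"
                            "U1\tA_c0 -> B_c0\t0\t1000\tmock\n"
                            "U2\tB_c0 <-> C_c0\t\t\tmock\n")
            db = UniversalDB.from_tsv(path)
        else:
            db = UniversalDB([UniversalReaction("U1", {"A_c0": -1, "B_c0": 1},
                                                0, 1000, "mock"),
                              UniversalReaction("U2", {"B_c0": -1, "C_c0": 1},
                                                -1000, 1000, "mock")])
            db.to_json(tmp_path / "u.json")
            db = UniversalDB.from_json(tmp_path / "u.json")
        assert [r.id for r in db.reactions] == ["U1", "U2"]
        assert db.reactions[1].lower_bound == -GLOBAL_BOUND


class TestBlockedTargets:
    def test_truncated_pathway_is_blocked(self, core_model):
        instance = sm.make_gap_instance(core_model, n_removed=1, seed=1)
        blocked = find_unproducible_targets(
            instance.model, [f"prec{k}_c0" for k in range(1, 5)])
        assert blocked == instance.blocked_targets

    def test_intact_model_has_no_blocked_components(self, core_model):
        assert find_unproducible_targets(
            core_model, [f"prec{k}_c0" for k in range(1, 5)]) == []

    def test_supplied_carbon_source_not_blocked(self, core_model):
        assert find_unproducible_targets(core_model, ["sub_c0"]) == []


class TestGapfillTarget:
    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_exactly_the_hidden_reaction(self, core_model, seed):
        instance = sm.make_gap_instance(core_model, n_removed=1, n_decoys=2,
                                        seed=seed)
        target = instance.blocked_targets[0]
        result = gapfill_target(instance.model, instance.universal, target)
        oracle = brute_force_minimal_sets(instance.model, instance.universal,
                                          target)
        assert oracle == [set(instance.hidden_ids)]  # unique minimum
        assert set(result.added_reactions) == set(instance.hidden_ids)

    def test_producible_target_needs_nothing(self, core_model):
        db = sm.make_gap_instance(core_model, seed=0).universal
        result = gapfill_target(core_model, db, "prec2_c0")
        assert result.added_reactions == []

    def test_prefers_one_step_over_two_step_route(self):
        """Direct and detour routes to the product coexist in the universal
        database; the weighted LP picks the single-reaction route."""
        m = new_model("routes")
        add_metabolite(m, "A_e0", "e0", "C1")
        add_metabolite(m, "A_c0", "c0", "C1")
        add_metabolite(m, "B_c0", "c0", "C1")
        add_exchange(m, "A_e0", -10, GLOBAL_BOUND)
        add_reaction(m, "T_A", {"A_e0": -1, "A_c0": 1})
        db = UniversalDB([
            UniversalReaction("U_direct", {"A_c0": -1, "B_c0": 1}, 0, 1000),
            UniversalReaction("U_step1", {"A_c0": -1, "C_c0": 1}, 0, 1000),
            UniversalReaction("U_step2", {"C_c0": -1, "B_c0": 1}, 0, 1000),
        ], {"C_c0": "C1"})
        result = gapfill_target(m, db, "B_c0")
        assert result.added_reactions == ["U_direct"]
        assert brute_force_minimal_sets(m, db, "B_c0") == [{"U_direct"}]

    def test_unfillable_gap_raises(self, core_model):
        m = core_model.copy()
        add_metabolite(m, "orphan_c0", "c0", "C1")
        with pytest.raises(UnfillableGapError, match="orphan"):
            gapfill_target(m, UniversalDB([]), "orphan_c0")

    def test_objective_monotone_in_database_size(self, core_model):
        instance = sm.make_gap_instance(core_model, n_removed=1, n_decoys=4,
                                        seed=2)
        target = instance.blocked_targets[0]
        small = gapfill_target(instance.model,
                               instance.universal.subset(instance.hidden_ids),
                               target)
        full = gapfill_target(instance.model, instance.universal, target)
        assert full.objective_value <= small.objective_value + 1e-9


class TestGapfillAll:
    def test_shared_missing_reaction_added_once(self, core_model):
        instance = sm.make_gap_instance(core_model, n_removed=1, seed=3)
        # the blocked precursor and the biomass reaction share the same gap
        targets = instance.blocked_targets + ["BIOMASS"]
        augmented, results, failures = gapfill_all(
            instance.model, instance.universal, targets)
        assert not failures
        union = set().union(*(r.added_reactions for r in results.values()))
        assert union == set(instance.hidden_ids)
        assert fba(augmented, "BIOMASS").objective_value > 1e-3

    def test_independent_gaps_all_filled(self, core_model):
        instance = sm.make_gap_instance(core_model, n_removed=3, n_decoys=3,
                                        seed=4)
        augmented, results, failures = gapfill_all(
            instance.model, instance.universal, instance.blocked_targets)
        assert not failures
        assert len(results) == 3
        union = set().union(*(r.added_reactions for r in results.values()))
        assert union == set(instance.hidden_ids)

    def test_partial_failure_recorded(self, core_model):
        instance = sm.make_gap_instance(core_model, n_removed=1, seed=5)
        broken = instance.model.copy()
        add_metabolite(broken, "orphan_c0", "c0", "C1")
        _, results, failures = gapfill_all(
            broken, instance.universal,
            instance.blocked_targets + ["orphan_c0"])
        assert set(results) == set(instance.blocked_targets)
        assert "orphan_c0" in failures

    def test_empty_target_list_rejected(self, core_model):
        with pytest.raises(ValueError):
            gapfill_all(core_model, UniversalDB([]), [])


class TestGapfillSubstrate:
    @pytest.fixture
    def alt_substrate_model(self):
        """Toy with an alternative substrate whose catabolism exists but
        whose exchange/transport is missing; the default substrate is shut
        off so only the alternative can feed ATPM."""
        m = sm.make_core_model(seed=0, ngam=0.0)
        add_metabolite(m, "alt_c0", "c0", "C2H4O2")
        add_reaction(m, "ALT_CAT", {
            "alt_c0": -1, "h2o_c0": -2, "nad_c0": -4,
            "co2_c0": 2, "nadh_c0": 4})
        m.reactions.EX_sub_e0.lower_bound = 0.0
        return m

    def test_missing_exchange_filled_mechanically(self, alt_substrate_model):
        augmented, result = gapfill_substrate(
            alt_substrate_model, UniversalDB([]), "alt_c0", target="ATPM")
        assert result.added_reactions == []
        assert "EX_alt_e0" in result.mechanical_additions
        assert fba(augmented, "ATPM").objective_value > 1e-3

    def test_missing_catabolic_route_filled_from_universal(
            self, alt_substrate_model):
        m = alt_substrate_model.copy()
        cat = m.reactions.get_by_id("ALT_CAT")
        db = UniversalDB([UniversalReaction(
            "U_ALT_CAT", {met.id: c for met, c in cat.metabolites.items()},
            0, GLOBAL_BOUND)])
        m.remove_reactions([cat])
        augmented, result = gapfill_substrate(m, db, "alt_c0", target="ATPM")
        assert result.added_reactions == ["U_ALT_CAT"]
        assert fba(augmented, "ATPM").objective_value > 1e-3

    def test_fully_usable_substrate_needs_nothing(self, core_model):
        augmented, result = gapfill_substrate(
            core_model, UniversalDB([]), "sub_c0", target="BIOMASS")
        assert result.added_reactions == []
        assert result.mechanical_additions == []
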