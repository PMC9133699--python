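"""FBA/pFBA correctness against independent oracles, deletions,
essentiality."""

import numpy as np
import pytest

from besflux.lp_engine import (
    InfeasibleError,
    delete_genes,
    essentiality_screen,
    fba,
    knockout_reactions,
    pfba,
)
from besflux.model_core import GLOBAL_BOUND, add_metabolite, add_reaction

from conftest import reversed_clone


def scipy_fba_optimum(model, objective_id):
    """Independent LP route: assemble S and the bounds by hand and solve
    with scipy's HiGHS instead of GLPK."""
    from scipy.optimize import linprog

    mets = {m.id: i for i, m in enumerate(model.metabolites)}
    rxns = list(model.reactions)
    S = np.zeros((len(mets), len(rxns)))
    for j, rxn in enumerate(rxns):
        for met, coef in rxn.metabolites.items():
            S[mets[met.id], j] = coef
    c = np.zeros(len(rxns))
    c[[r.id for r in rxns].index(objective_id)] = -1.0  # linprog minimizes
    bounds = [(r.lower_bound, r.upper_bound) for r in rxns]
    res = linprog(c, A_eq=S, b_eq=np.zeros(len(mets)), bounds=bounds,
                  method="highs")
    assert res.status == 0, res.message
    return -res.fun


class TestFba:
    def test_single_path_bound_limited(self, chain_model):
        state = fba(chain_model, "DM_B")
        assert state.ok and state.objective_value == pytest.approx(10.0)

    def test_branch_vertex_optimum(self, branch_model):
        # the two pathway vertices give 5 (single) and 10 (doubling)
        state = fba(branch_model, "DM_B")
        assert state.objective_value == pytest.approx(10.0)
        assert state.fluxes["DOUBLE"] == pytest.approx(5.0)
        assert state.fluxes["SINGLE"] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_independent_lp_solver(self, seed):
        from besflux import synthetic_models as sm

        model = sm.make_core_model(seed=seed)
        ours = fba(model, "BIOMASS").objective_value
        assert ours == pytest.approx(scipy_fba_optimum(model, "BIOMASS"), abs=1e-8)

    def test_invariant_under_reaction_permutation(self, core_model):
        ref = fba(core_model, "BIOMASS").objective_value
        perm = fba(reversed_clone(core_model), "BIOMASS").objective_value
        assert perm == pytest.approx(ref, abs=1e-9)

    def test_minimization_sense(self, chain_model):
        assert fba(chain_model, "DM_B", "min").objective_value == pytest.approx(0.0)

    def test_unbounded_reported(self):
        import besflux.model_core as mc

        m = mc.new_model("unb")
        add_metabolite(m, "A_c0", "c0")
        add_reaction(m, "IN", {"A_c0": 1}, -GLOBAL_BOUND, GLOBAL_BOUND)
        add_reaction(m, "OUT", {"A_c0": -1}, -GLOBAL_BOUND, GLOBAL_BOUND)
        m.objective = "OUT"
        for rxn in m.reactions:
            rxn.upper_bound = float("inf")
            rxn.lower_bound = -float("inf")
        state = fba(m, "OUT")
        assert state.status in ("unbounded", "infeasible")
        assert state.status == "unbounded"


class TestPfba:
    def test_futile_loop_suppressed(self, chain_model):
        m = chain_model.copy()
        add_reaction(m, "LOOP_FWD", {"A_c0": -1, "B_c0": 1},
                     -GLOBAL_BOUND, GLOBAL_BOUND)
        # plain FBA tolerates loop flux; pFBA zeroes it
        parsimonious = pfba(m, "DM_B")
        assert parsimonious.objective_value == pytest.approx(10.0)
        assert abs(parsimonious.fluxes["LOOP_FWD"] - parsimonious.fluxes["A2B"]) \
            == pytest.approx(10.0)  # combined they carry exactly the path flux
        assert min(abs(parsimonious.fluxes["LOOP_FWD"]),
                   abs(parsimonious.fluxes["A2B"])) <= 1e-9

    def test_fraction_one_matches_fba_on_unique_optimum(self, chain_model):
        plain = fba(chain_model, "DM_B")
        pars = pfba(chain_model, "DM_B", objective_fraction=1.0)
        for rid, v in plain.fluxes.items():
            assert pars.fluxes[rid] == pytest.approx(v, abs=1e-9)

    def test_total_flux_invariant_on_degenerate_alternatives(self):
        """Two equal-length alternative routes: flux may split but the
        summed |v| equals the single-path total."""
        import besflux.model_core as mc

        m = mc.new_model("alt")
        add_metabolite(m, "A_e0", "e0")
        add_metabolite(m, "A_c0", "c0")
        add_metabolite(m, "B_c0", "c0")
        mc.add_exchange(m, "A_e0", -10, GLOBAL_BOUND)
        add_reaction(m, "T_A", {"A_e0": -1, "A_c0": 1})
        add_reaction(m, "PATH1", {"A_c0": -1, "B_c0": 1})
        add_reaction(m, "PATH2", {"A_c0": -1, "B_c0": 1})
        add_reaction(m, "DM_B", {"B_c0": -1}, artificial=True)
        m.objective = "DM_B"
        pars = pfba(m, "DM_B")
        assert pars.fluxes["PATH1"] + pars.fluxes["PATH2"] == pytest.approx(10.0)
        assert pars.sum_abs_flux == pytest.approx(40.0)  # EX + T + paths + DM

    def test_never_exceeds_fba_total_flux(self, core_model):
        plain = fba(core_model, "BIOMASS")
        pars = pfba(core_model, "BIOMASS")
        assert pars.objective_value == pytest.approx(plain.objective_value, abs=1e-6)
        assert pars.sum_abs_flux <= plain.sum_abs_flux + 1e-6

    def test_bad_fraction_rejected(self, chain_model):
        with pytest.raises(ValueError):
            pfba(chain_model, "DM_B", objective_fraction=0.0)


class TestDeletions:
    def test_isoenzyme_or_semantics(self, core_model):
        # CAT carries an isoenzyme pair "gA or gB"
        g1, g2 = [g.strip() for g in
                  core_model.reactions.CAT.gene_reaction_rule.split("or")]
        aware = delete_genes(core_model, {g1}, mode="gpr_aware")
        assert aware.reactions.CAT.upper_bound > 0
        literal = delete_genes(core_model, {g1}, mode="reaction_removal")
        assert literal.reactions.CAT.bounds == (0.0, 0.0)

    def test_empty_deletion_is_identity(self, core_model):
        out = delete_genes(core_model, set())
        assert all(out.reactions.get_by_id(r.id).bounds == r.bounds
                   for r in core_model.reactions)

    def test_unknown_gene_rejected(self, core_model):
        with pytest.raises(KeyError, match="nope"):
            delete_genes(core_model, {"nope"})

    def test_knockout_reactions(self, core_model):
        out = knockout_reactions(core_model, ["NDH"])
        assert out.reactions.NDH.bounds == (0.0, 0.0)
        assert core_model.reactions.NDH.upper_bound > 0
        same = knockout_reactions(core_model, [])
        assert fba(same, "BIOMASS").objective_value == pytest.approx(
            fba(core_model, "BIOMASS").objective_value)

    def test_alternative_route_carries_flux_after_knockout(self):
        """A parallel NADH->quinol shuttle (lactate-shuttle analogue) keeps
        the objective alive when the dehydrogenase is knocked out; removing
        both routes kills it."""
        from besflux import synthetic_models as sm

        # maintenance off so the double knockout is "no growth", not
        # an infeasible forced-ATPM problem
        m = sm.make_core_model(seed=0, ngam=0.0).copy()
        add_reaction(m, "NDH_ALT", {
            "nadh_c0": -1, "mq_c0": -1, "nad_c0": 1, "mqh2_c0": 1})
        wild = fba(m, "BIOMASS").objective_value
        single = fba(knockout_reactions(m, ["NDH"]), "BIOMASS").objective_value
        assert single > 1e-3  # alternative route carries the electrons
        assert single <= wild + 1e-9
        both = knockout_reactions(m, ["NDH", "NDH_ALT"])
        assert fba(both, "BIOMASS").objective_value == pytest.approx(0.0, abs=1e-6)


class TestEssentiality:
    def test_single_route_gene_essential(self, core_model):
        verdict = essentiality_screen(core_model)
        syn_gene = core_model.reactions.SYN_prec2.gene_reaction_rule
        assert verdict[syn_gene] == "essential"

    def test_isoenzymes_not_essential_gpr_aware(self, core_model):
        verdict = essentiality_screen(core_model, mode="gpr_aware")
        for gid in [g.strip() for g in
                    core_model.reactions.CAT.gene_reaction_rule.split("or")]:
            assert verdict[gid] == "non-essential"

    def test_isoenzymes_overcalled_by_literal_rule(self, core_model):
        verdict = essentiality_screen(core_model, mode="reaction_removal")
        for gid in [g.strip() for g in
                    core_model.reactions.CAT.gene_reaction_rule.split("or")]:
            assert verdict[gid] == "essential"

    def test_dead_end_gene_non_essential(self, core_model):
        m = core_model.copy()
        add_metabolite(m, "dead_c0", "c0", "C1")
        add_reaction(m, "DEADRXN", {"co2_c0": -1, "dead_c0": 1}, gpr="g_dead")
        assert essentiality_screen(m, genes=["g_dead"])["g_dead"] == "non-essential"

    def test_no_growth_wild_type_raises(self, core_model):
        from besflux.model_core import MediumSpec

        with pytest.raises(InfeasibleError):
            essentiality_screen(core_model, MediumSpec())  # everything closed
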