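"""Shared fixtures: toy models and inline micro-networks.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from besflux import synthetic_models as sm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from besflux.model_core import (
    GLOBAL_BOUND,
    add_exchange,
    add_metabolite,
    add_reaction,
    new_model,
)
from besflux.qc_energy import default_dissipation_specs


@pytest.fixture
def core_model():
    return sm.make_core_model(seed=0)


@pytest.fixture
def mfc_model():
    return sm.make_mfc_model(seed=0)


@pytest.fixture
def mes_model():
    return sm.make_mes_model(seed=0)


@pytest.fixture
def dissipation_specs():
    return default_dissipation_specs(sm.default_id_map())


@pytest.fixture
def chain_model():
    """EX_A (>= -10) -> A -> B -> DM_B: a single bound-limited path."""
    m = new_model("chain")
    add_metabolite(m, "A_e0", "e0", "C1")
    add_metabolite(m, "A_c0", "c0", "C1")
    add_metabolite(m, "B_c0", "c0", "C1")
    add_exchange(m, "A_e0", -10.0, GLOBAL_BOUND)
    add_reaction(m, "T_A", {"A_e0": -1, "A_c0": 1})
    add_reaction(m, "A2B", {"A_c0": -1, "B_c0": 1})
    add_reaction(m, "DM_B", {"B_c0": -1}, artificial=True)
    m.objective = "DM_B"
    return m


@pytest.fixture
def branch_model():
    """A -> 2B vs A -> B feeding DM_B at uptake 5: the doubling branch is
    the unique optimum vertex (objective 10)."""
    m = new_model("branch")
    add_metabolite(m, "A_e0", "e0")
    add_metabolite(m, "A_c0", "c0")
    add_metabolite(m, "B_c0", "c0")
    add_exchange(m, "A_e0", -5.0, GLOBAL_BOUND)
    add_reaction(m, "T_A", {"A_e0": -1, "A_c0": 1})
    add_reaction(m, "DOUBLE", {"A_c0": -1, "B_c0": 2})
    add_reaction(m, "SINGLE", {"A_c0": -1, "B_c0": 1})
    add_reaction(m, "DM_B", {"B_c0": -1}, artificial=True)
    m.objective = "DM_B"
    return m


def reversed_clone(model):
    """Same network, reactions registered in reverse order (for
    order-invariance checks)."""
    import cobra

    clone = cobra.Model(model.id + "_rev")
    clone.compartments = dict(model.compartments)
    clone.add_metabolites([m.copy() for m in model.metabolites])
    originals = list(model.reactions)[::-1]
    for rxn in originals:
        new = cobra.Reaction(rxn.id, lower_bound=rxn.lower_bound,
                             upper_bound=rxn.upper_bound)
        clone.add_reactions([new])
        new.add_metabolites({clone.metabolites.get_by_id(m.id): c
                             for m, c in rxn.metabolites.items()})
        new.gene_reaction_rule = rxn.gene_reaction_rule
        new.notes.update(rxn.notes)
    obj = [r.id for r in
           cobra.util.solver.linear_reaction_coefficients(model)]
    if obj:
        clone.objective = obj[0]
    return clone
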