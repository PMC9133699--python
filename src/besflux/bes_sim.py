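"""Bioelectrochemical-system simulation.

MFC mode (outward electron transfer): the anode is modeled as a terminal
electron acceptor through four artificial reactions — an electrode source,
two quinol-oxidizing electrode reductions (each quinol hands 2 electrons to
2 oxidized electrode species, releasing 2 extracellular protons) and an
electrode demand whose flux F counts delivered electrons. Coulombic
efficiency compares F with the electrons available in the substrate, where
the substrate's electron content N is its degree of reduction
(C=4, H=1, O=-2; e.g. lactate C3H6O3 -> 3*4 + 6*1 + 3*(-2) = 12).

Two CE accountings are provided and never silently merged:

* ``strict``: CE = F*100 / (uptake*N). With the printed 1-electron
  Reduced_Electrode stoichiometry this is the conservation-consistent form
  (100% when every substrate electron reaches the anode).
* ``paired``:    CE = F*2*100 / (uptake*N), the field's printed formula kept
  verbatim; under the same stoichiometry it double-counts by a factor 2.

MES mode (inward electron transfer): cathodic electrons enter as an
electron source (Sink_e-) feeding NADH regeneration
(2 e- + H+_p + NAD+ -> NADH); growth is switched off and a product demand
is maximized. The theoretical maximum yield from electron balance alone is
the degree-of-reduction ratio N/M (substrate over product).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from cobra import Model

from .model_core import (
    EXTRACELLULAR,
    GLOBAL_BOUND,
    PERIPLASM,
    add_metabolite,
    add_reaction,
    parse_formula,
)
from .lp_engine import fba, pfba

# degree of reduction per atom; unknown elements raise rather than count 0
DEFAULT_DEGREES: dict[str, float] = {
    "C": 4.0, "H": 1.0, "O": -2.0,   # the core convention
    "N": -3.0, "S": 6.0, "P": 5.0,   # common extensions
}


@dataclass
class ReductionDegreeConvention:
    degrees: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DEGREES))


def degree_of_reduction(formula: str | Mapping[str, float],
                        convention: ReductionDegreeConvention | None = None) -> float:
    """Available electrons per mole: sum over elements of count * degree."""
    conv = (convention or ReductionDegreeConvention()).degrees
    counts = parse_formula(formula)
    if not counts:
        raise ValueError("empty formula has no degree of reduction")
    unknown = sorted(set(counts) - set(conv))
    if unknown:
        raise ValueError(f"no reduction degree defined for element(s) {unknown}")
    return sum(n * conv[e] for e, n in counts.items())


def theoretical_max_yield(substrate_formula: str | Mapping[str, float],
                          product_formula: str | Mapping[str, float],
                          convention: ReductionDegreeConvention | None = None) -> float:
    """Electron-balance yield ceiling N/M (mol product per mol substrate)."""
    n = degree_of_reduction(substrate_formula, convention)
    m = degree_of_reduction(product_formula, convention)
    if m <= 0:
        raise ValueError(f"product degree of reduction {m} is not positive")
    if n <= 0:
        raise ValueError(f"substrate degree of reduction {n} is not positive")
    return n / m


def coulombic_efficiency(electrode_flux: float, uptake: float, n_electrons: float,
                         accounting: str = "paired") -> float:
    """CE%% from the electrode demand flux F, the substrate uptake rate and
    the substrate's electron content N. ``accounting="paired"`` applies the
    printed formula F*2*100/(uptake*N); ``"strict"`` drops the factor 2."""
    if uptake <= 0:
        raise ZeroDivisionError("substrate uptake rate must be positive")
    if n_electrons <= 0:
        raise ZeroDivisionError("substrate electron content N must be positive")
    if accounting == "paired":
        return electrode_flux * 2.0 * 100.0 / (uptake * n_electrons)
    if accounting == "strict":
        return electrode_flux * 100.0 / (uptake * n_electrons)
    raise ValueError("accounting must be 'paired' or 'strict'")


# ---------------------------------------------------------------------------
# electrode augmentation (MFC)
# ---------------------------------------------------------------------------

OXIDIZED_ELECTRODE = "Oxidated_Electrode_e0"
REDUCED_ELECTRODE = "Reduced_Electrode_e0"
ELECTRODE_SINK = "Electrode_Sink"
ELECTRODE_DEMAND = "Electrode_Demand"


@dataclass
class ElectrodeSpec:
    """Metabolite-id map for the electrode pseudo-reactions.

    quinol/quinone: the menaquinol-7/menaquinone-7 pool ids; a second
    (methyl-) pair is optional. h_e: extracellular proton id.
    """

    quinol: str
    quinone: str
    h_e: str
    quinol2: str | None = None
    quinone2: str | None = None


def add_electrode(model: Model, spec: ElectrodeSpec) -> Model:
    """Attach the four electrode pseudo-reactions to a model copy. The
    electrode species carry no formula and the reactions are flagged
    artificial, so they are exempt from mass-balance audits."""
    pairs = [(spec.quinol, spec.quinone)]
    if spec.quinol2 and spec.quinone2:
        pairs.append((spec.quinol2, spec.quinone2))
    missing = [m for pair in pairs for m in pair if m not in model.metabolites]
    if spec.h_e not in model.metabolites:
        missing.append(spec.h_e)
    if missing:
        raise KeyError(f"electrode augmentation: metabolites not in model: {missing}")
    if ELECTRODE_DEMAND in model.reactions:
        raise ValueError("model already carries the electrode pseudo-reactions")

    out = model.copy()
    add_metabolite(out, OXIDIZED_ELECTRODE, EXTRACELLULAR, name="oxidized electrode")
    add_metabolite(out, REDUCED_ELECTRODE, EXTRACELLULAR, name="reduced electrode")
    add_reaction(out, ELECTRODE_SINK, {OXIDIZED_ELECTRODE: 1.0},
                 0.0, GLOBAL_BOUND, artificial=True)
    for i, (quinol, quinone) in enumerate(pairs, start=1):
        add_reaction(out, f"Electrode_Reduction_{i}", {
            OXIDIZED_ELECTRODE: -2.0, quinol: -1.0,
            REDUCED_ELECTRODE: 2.0, quinone: 1.0, spec.h_e: 2.0,
        }, 0.0, GLOBAL_BOUND, artificial=True)
    add_reaction(out, ELECTRODE_DEMAND, {REDUCED_ELECTRODE: -1.0},
                 0.0, GLOBAL_BOUND, artificial=True)
    return out


def simulate_electron_generation(
    model: Model,
    substrate_exchange: str,
    substrate_formula: str | Mapping[str, float],
    biomass_id: str,
    uptake: float = 4.06,
    biomass_fraction: float = 0.10,
    convention: ReductionDegreeConvention | None = None,
) -> dict[str, float]:
    """MFC electron-generation simulation.

    The substrate uptake is fixed, the growth rate is pinned at
    ``biomass_fraction`` of its (anaerobic) maximum, and the electrode
    demand is maximized. Reports the electrode flux F, the electron rate
    per C-mole of substrate, and CE under both accountings. The caller is
    responsible for an anaerobic medium (O2 exchange closed) with the
    substrate as sole carbon source.
    """
    if ELECTRODE_DEMAND not in model.reactions:
        raise KeyError("model lacks the electrode pseudo-reactions; run add_electrode")
    counts = parse_formula(substrate_formula)
    n_electrons = degree_of_reduction(counts, convention)
    carbons = counts.get("C", 0.0)

    work = model.copy()
    work.reactions.get_by_id(substrate_exchange).bounds = (-uptake, -uptake)
    growth_state = fba(work, biomass_id, "max")
    mu_max = growth_state.objective_value if growth_state.ok else 0.0
    if mu_max <= 1e-9:
        mu_max = 0.0  # no anaerobic growth: pin biomass at zero
    work.reactions.get_by_id(biomass_id).bounds = (
        biomass_fraction * mu_max, biomass_fraction * mu_max)
    state = pfba(work, ELECTRODE_DEMAND, objective_fraction=1.0)
    f_flux = state.objective_value
    return {
        "F": f_flux,
        "growth_rate": biomass_fraction * mu_max,
        "uptake": uptake,
        "n_electrons": n_electrons,
        "electrons_per_cmol": f_flux / (uptake * carbons) if carbons else float("nan"),
        "ce_strict": coulombic_efficiency(f_flux, uptake, n_electrons, "strict"),
        "ce_paired": coulombic_efficiency(f_flux, uptake, n_electrons, "paired"),
    }


# ---------------------------------------------------------------------------
# microbial electrosynthesis (MES)
# ---------------------------------------------------------------------------

ELECTRON_MET = "e_inward_p0"
NADH_R = "NADH_R"
SINK_E = "Sink_e"


@dataclass
class MESSpec:
    """Id map for the inward-electron machinery: NADH regeneration from
    cathodic electrons (2 e- + H+_p + NAD+ -> NADH) plus an electron
    source. With ``inward_electron`` False the electron source is closed."""

    nad: str
    nadh: str
    h_p: str
    inward_electron: bool = True


def add_mes(model: Model, spec: MESSpec) -> Model:
    missing = [m for m in (spec.nad, spec.nadh, spec.h_p) if m not in model.metabolites]
    if missing:
        raise KeyError(f"MES augmentation: metabolites not in model: {missing}")
    if NADH_R in model.reactions:
        raise ValueError("model already carries the MES pseudo-reactions")
    out = model.copy()
    add_metabolite(out, ELECTRON_MET, PERIPLASM, name="inward electron")
    add_reaction(out, NADH_R, {
        ELECTRON_MET: -2.0, spec.h_p: -1.0, spec.nad: -1.0, spec.nadh: 1.0,
    }, 0.0, GLOBAL_BOUND, artificial=True)
    sink_ub = GLOBAL_BOUND if spec.inward_electron else 0.0
    add_reaction(out, SINK_E, {ELECTRON_MET: 1.0}, 0.0, sink_ub, artificial=True)
    return out


def simulate_mes_yield(
    model: Model,
    product_demand: str,
    substrate_exchange: str,
    biomass_id: str,
    uptake: float = 4.06,
    inward: bool = True,
    atpm_id: str | None = None,
) -> dict[str, float]:
    """MES product-yield simulation.

    Growth is forced to zero (and the maintenance lower bound dropped, since
    a non-growing cell without a terminal acceptor has no energy source for
    it), the substrate uptake is fixed, CO2 supply is left to the medium
    (keep its exchange unbounded), and the product demand is maximized.
    Yield = demand flux / uptake (mol/mol); the inward electron flux is the
    electron-source flux.
    """
    if NADH_R not in model.reactions:
        raise KeyError("model lacks the MES pseudo-reactions; run add_mes")
    work = model.copy()
    work.reactions.get_by_id(biomass_id).bounds = (0.0, 0.0)
    if atpm_id is not None:
        atpm = work.reactions.get_by_id(atpm_id)
        atpm.bounds = (0.0, atpm.upper_bound)
    work.reactions.get_by_id(substrate_exchange).bounds = (-uptake, 0.0)
    work.reactions.get_by_id(SINK_E).bounds = (0.0, GLOBAL_BOUND if inward else 0.0)
    state = pfba(work, product_demand, objective_fraction=1.0)
    if not state.ok or state.objective_value < 1e-9:
        blocked = _blocked_precursors(work, product_demand)
        return {"yield": 0.0, "production": 0.0, "inward_flux": 0.0,
                "blocked_precursors": blocked}
    return {
        "yield": state.objective_value / uptake,
        "production": state.objective_value,
        "inward_flux": state.fluxes.get(SINK_E, 0.0),
    }


def _blocked_precursors(model: Model, demand_id: str) -> list[str]:
    """Diagnostic: which substrates of an unreachable demand cannot be
    produced at all."""
    from .gapfilling import find_unproducible_targets

    demand = model.reactions.get_by_id(demand_id)
    precursors = [m.id for m, c in demand.metabolites.items() if c < 0]
    return find_unproducible_targets(model, precursors)
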