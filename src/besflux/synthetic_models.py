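"""Seed-controlled generators of small electron-balanced toy models.

The core toy emulates, at ~20-40 reactions, the architecture of a
respiring Gram-negative electroactive cell: substrate uptake (periplasmic
symport), full catabolic oxidation harvesting electrons as NADH, a
menaquinone pool, a proton-pumping respiratory chain with a configurable
stoichiometric P/O ratio, ATP synthase, ATP maintenance, and a
multi-precursor biomass reaction with GAM/NGAM. Pseudo-elements keep every
internal reaction exactly element-balanced: the NAD(H) core is element
``X`` (NADH = XH2), the menaquinone core is ``Y`` (menaquinol = YH2) and
the adenosine core is ``Z`` (ATP = ZHPO3, ADP = Z, Pi = H3PO4), so a
substrate CcHhOo is oxidized as

    substrate + (2c-o) H2O + d/2 NAD+  ->  c CO2 + d/2 NADH

with d = 4c + h - 2o its degree of reduction — electron bookkeeping is
exact by construction.

Corruption injectors produce ground-truthed QC and gap-filling fixtures:
``inject_egc`` flips one reaction direction to create an ATP-type or
PMF-type energy-generating cycle; ``make_gap_instance`` hides essential
biosynthesis steps in a decoy-padded universal database. Dedicated builders
derive MFC, MES and FSEOF fixtures from the same chemistry. All generators
are deterministic per seed (the seed permutes gene-id assignment).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from cobra import Model

from .model_core import (
    CYTOSOL,
    EXTRACELLULAR,
    GLOBAL_BOUND,
    PERIPLASM,
    BiomassSpec,
    add_demand,
    add_exchange,
    add_metabolite,
    add_reaction,
    new_model,
    parse_formula,
)
from .gapfilling import UniversalDB, UniversalReaction

DEFAULT_UPTAKE_BOUND = 10.0


@dataclass
class ToyConfig:
    seed: int = 0
    n_biomass_precursors: int = 4
    p_o_ratio: float = 1.5
    include_periplasm: bool = True
    substrate_formula: str = "C3H6O3"
    byproduct_leak: bool = False
    acceptors: tuple[str, ...] = ("oxygen",)  # subset of {"oxygen", "fumarate"}
    gam: float = 2.0   # placeholder growth-associated maintenance, mmol ATP/gDW
    ngam: float = 0.1  # placeholder non-growth maintenance, mmol/gDW/h
    formate_release: bool = False  # catabolism loses 2 e- as a formate analogue
    leak_rate: float = 0.5  # forced byproduct secretion, mmol/gDW/h

    def __post_init__(self) -> None:
        if self.n_biomass_precursors < 1:
            raise ValueError("need at least one biomass precursor")
        if self.p_o_ratio < 0.5:
            raise ValueError("p_o_ratio below 0.5 cannot be realized by this chain")
        bad = set(self.acceptors) - {"oxygen", "fumarate"}
        if bad:
            raise ValueError(f"unknown acceptors: {sorted(bad)}")


# metabolite id shorthand used by all fixtures
IDS = {
    "sub_c": "sub_c0", "sub_p": "sub_p0", "sub_e": "sub_e0",
    "h2o_c": "h2o_c0", "h2o_e": "h2o_e0",
    "co2_c": "co2_c0", "co2_e": "co2_e0",
    "o2_c": "o2_c0", "o2_e": "o2_e0",
    "h_c": "h_c0", "h_p": "h_p0", "h_e": "h_e0",
    "nad": "nad_c0", "nadh": "nadh_c0",
    "mq": "mq_c0", "mqh2": "mqh2_c0",
    "adp": "adp_c0", "atp": "atp_c0", "pi": "pi_c0",
    "fum_c": "fum_c0", "fum_e": "fum_e0",
    "suc_c": "suc_c0", "suc_e": "suc_e0",
    "byp_c": "byp_c0", "byp_e": "byp_e0",
    "for_c": "for_c0", "for_e": "for_e0",
}

ATP_EGC_CANDIDATE = "R_atp_prec1"
PMF_EGC_CANDIDATE = "T_sub_pc_sym"


def default_id_map(include_periplasm: bool = True) -> dict[str, str]:
    """Metabolite-id map for QC/electrode/MES wiring of the toy models."""
    return {
        "atp": IDS["atp"], "adp": IDS["adp"], "pi": IDS["pi"],
        "h2o": IDS["h2o_c"], "h_c": IDS["h_c"],
        "h_p": IDS["h_p"] if include_periplasm else IDS["h_e"],
        "h_e": IDS["h_e"],
        "nad": IDS["nad"], "nadh": IDS["nadh"],
        "quinol": IDS["mqh2"], "quinone": IDS["mq"],
    }


def _gene_names(rng: random.Random, n: int) -> list[str]:
    nums = rng.sample(range(1000, 9999), n)
    return [f"SO_t{num}" for num in nums]


def make_core_model(config: ToyConfig | None = None, **overrides) -> Model:
    """Build the deterministic core toy model for a configuration."""
    config = replace(config or ToyConfig(), **overrides)
    rng = random.Random(config.seed)
    sub = parse_formula(config.substrate_formula)
    c, h, o = sub.get("C", 0.0), sub.get("H", 0.0), sub.get("O", 0.0)
    degree = 4 * c + h - 2 * o
    n_nadh, n_h2o = degree / 2.0, 2 * c - o
    if degree <= 0 or n_h2o < 0 or c <= 0:
        raise ValueError(f"substrate {config.substrate_formula!r} cannot drive the toy")

    model = new_model(f"toy_core_seed{config.seed}", config.include_periplasm)
    proton_out = IDS["h_p"] if config.include_periplasm else IDS["h_e"]

    # -- metabolites -------------------------------------------------------
    add_metabolite(model, IDS["sub_c"], CYTOSOL, config.substrate_formula)
    add_metabolite(model, IDS["sub_e"], EXTRACELLULAR, config.substrate_formula)
    add_metabolite(model, IDS["h2o_c"], CYTOSOL, "H2O")
    add_metabolite(model, IDS["h2o_e"], EXTRACELLULAR, "H2O")
    add_metabolite(model, IDS["co2_c"], CYTOSOL, "CO2")
    add_metabolite(model, IDS["co2_e"], EXTRACELLULAR, "CO2")
    add_metabolite(model, IDS["h_c"], CYTOSOL, "H")
    add_metabolite(model, IDS["h_e"], EXTRACELLULAR, "H")
    add_metabolite(model, IDS["nad"], CYTOSOL, "X")
    add_metabolite(model, IDS["nadh"], CYTOSOL, "XH2")
    add_metabolite(model, IDS["mq"], CYTOSOL, "Y")
    add_metabolite(model, IDS["mqh2"], CYTOSOL, "YH2")
    add_metabolite(model, IDS["adp"], CYTOSOL, "Z")
    add_metabolite(model, IDS["atp"], CYTOSOL, "ZHPO3")
    add_metabolite(model, IDS["pi"], CYTOSOL, "H3PO4")
    if config.include_periplasm:
        add_metabolite(model, IDS["sub_p"], PERIPLASM, config.substrate_formula)
        add_metabolite(model, IDS["h_p"], PERIPLASM, "H")
    precursors = []
    for k in range(1, config.n_biomass_precursors + 1):
        precursors.append(add_metabolite(
            model, f"prec{k}_c0", CYTOSOL, config.substrate_formula).id)

    # -- exchanges and transport ------------------------------------------
    add_exchange(model, IDS["sub_e"], -DEFAULT_UPTAKE_BOUND, GLOBAL_BOUND)
    add_exchange(model, IDS["co2_e"], -GLOBAL_BOUND, GLOBAL_BOUND)
    add_exchange(model, IDS["h2o_e"], -GLOBAL_BOUND, GLOBAL_BOUND)
    add_exchange(model, IDS["h_e"], -GLOBAL_BOUND, GLOBAL_BOUND)
    if config.include_periplasm:
        add_reaction(model, "T_sub_ep", {IDS["sub_e"]: -1, IDS["sub_p"]: 1},
                     -GLOBAL_BOUND, GLOBAL_BOUND)
        # proton symport (the PMF-cycle injection candidate) plus a plain
        # uniporter — a redundancy typical of merged draft reconstructions
        add_reaction(model, PMF_EGC_CANDIDATE,
                     {IDS["sub_p"]: -1, IDS["h_p"]: -1, IDS["sub_c"]: 1, IDS["h_c"]: 1})
        add_reaction(model, "T_sub_pc_uni", {IDS["sub_p"]: -1, IDS["sub_c"]: 1})
        add_reaction(model, "T_h_pe", {IDS["h_p"]: -1, IDS["h_e"]: 1},
                     -GLOBAL_BOUND, GLOBAL_BOUND)
    else:
        add_reaction(model, "T_sub", {IDS["sub_e"]: -1, IDS["sub_c"]: 1})
    add_reaction(model, "T_co2", {IDS["co2_c"]: -1, IDS["co2_e"]: 1},
                 -GLOBAL_BOUND, GLOBAL_BOUND)
    add_reaction(model, "T_h2o", {IDS["h2o_c"]: -1, IDS["h2o_e"]: 1},
                 -GLOBAL_BOUND, GLOBAL_BOUND)

    # -- catabolism --------------------------------------------------------
    if config.formate_release:
        # oxidation stops at a formate analogue (CH2O2, 2 electrons) that
        # the toy cannot re-assimilate: (d-2)/2 NADH per substrate
        if not (c >= 2 and degree > 2):
            raise ValueError("formate_release needs a >=C2 substrate")
        add_metabolite(model, IDS["for_c"], CYTOSOL, "CH2O2")
        add_metabolite(model, IDS["for_e"], EXTRACELLULAR, "CH2O2")
        add_exchange(model, IDS["for_e"], 0.0, GLOBAL_BOUND)
        add_reaction(model, "T_for", {IDS["for_c"]: -1, IDS["for_e"]: 1})
        n_f = (degree - 2) / 2.0
        w_f = 2 * (c - 1) - (o - 2)
        add_reaction(model, "CAT", {
            IDS["sub_c"]: -1, IDS["h2o_c"]: -w_f, IDS["nad"]: -n_f,
            IDS["co2_c"]: c - 1, IDS["for_c"]: 1, IDS["nadh"]: n_f,
        })
    else:
        add_reaction(model, "CAT", {
            IDS["sub_c"]: -1, IDS["h2o_c"]: -n_h2o, IDS["nad"]: -n_nadh,
            IDS["co2_c"]: c, IDS["nadh"]: n_nadh,
        })

    # -- anabolism ---------------------------------------------------------
    add_reaction(model, "R_free_prec1", {IDS["sub_c"]: -1, precursors[0]: 1})
    # ATP-coupled duplicate route (the ATP-cycle injection candidate)
    add_reaction(model, ATP_EGC_CANDIDATE, {
        IDS["sub_c"]: -1, IDS["atp"]: -1, IDS["h2o_c"]: -1,
        precursors[0]: 1, IDS["adp"]: 1, IDS["pi"]: 1,
    })
    for k, prec in enumerate(precursors[1:], start=2):
        add_reaction(model, f"SYN_prec{k}", {
            IDS["sub_c"]: -1, IDS["atp"]: -1, IDS["h2o_c"]: -1,
            prec: 1, IDS["adp"]: 1, IDS["pi"]: 1,
        })

    # -- respiratory chain: P/O realized as proton stoichiometry -----------
    # per NADH the chain pumps 4*P/O protons; ATP synthase uses 4 per ATP
    ndh_pump = 4 * config.p_o_ratio - 2 if "oxygen" in config.acceptors else 4 * config.p_o_ratio
    add_reaction(model, "NDH", {
        IDS["nadh"]: -1, IDS["mq"]: -1, IDS["h_c"]: -ndh_pump,
        IDS["nad"]: 1, IDS["mqh2"]: 1, proton_out: ndh_pump,
    })
    if "oxygen" in config.acceptors:
        add_metabolite(model, IDS["o2_c"], CYTOSOL, "O2")
        add_metabolite(model, IDS["o2_e"], EXTRACELLULAR, "O2")
        add_exchange(model, IDS["o2_e"], -GLOBAL_BOUND, GLOBAL_BOUND)
        add_reaction(model, "T_o2", {IDS["o2_e"]: -1, IDS["o2_c"]: 1})
        add_reaction(model, "CYO", {
            IDS["mqh2"]: -1, IDS["o2_c"]: -0.5, IDS["h_c"]: -2,
            IDS["mq"]: 1, IDS["h2o_c"]: 1, proton_out: 2,
        })
    if "fumarate" in config.acceptors:
        add_metabolite(model, IDS["fum_c"], CYTOSOL, "C4H4O4")
        add_metabolite(model, IDS["fum_e"], EXTRACELLULAR, "C4H4O4")
        add_metabolite(model, IDS["suc_c"], CYTOSOL, "C4H6O4")
        add_metabolite(model, IDS["suc_e"], EXTRACELLULAR, "C4H6O4")
        add_exchange(model, IDS["fum_e"], -GLOBAL_BOUND, GLOBAL_BOUND)
        add_exchange(model, IDS["suc_e"], 0.0, GLOBAL_BOUND)
        add_reaction(model, "T_fum", {IDS["fum_e"]: -1, IDS["fum_c"]: 1})
        add_reaction(model, "T_suc", {IDS["suc_c"]: -1, IDS["suc_e"]: 1})
        add_reaction(model, "FRD", {
            IDS["fum_c"]: -1, IDS["mqh2"]: -1, IDS["suc_c"]: 1, IDS["mq"]: 1,
        })
    add_reaction(model, "ATPS", {
        IDS["adp"]: -1, IDS["pi"]: -1, proton_out: -4,
        IDS["atp"]: 1, IDS["h2o_c"]: 1, IDS["h_c"]: 4,
    })
    add_reaction(model, "ATPM", {
        IDS["atp"]: -1, IDS["h2o_c"]: -1, IDS["adp"]: 1, IDS["pi"]: 1,
    }, lower_bound=config.ngam)

    # -- byproduct leak ----------------------------------------------------
    if config.byproduct_leak:
        add_metabolite(model, IDS["byp_c"], CYTOSOL, "C3H8O3")
        add_metabolite(model, IDS["byp_e"], EXTRACELLULAR, "C3H8O3")
        # forced secretion: a free optimizer would never leak electrons
        add_exchange(model, IDS["byp_e"], config.leak_rate, GLOBAL_BOUND)
        add_reaction(model, "T_byp", {IDS["byp_c"]: -1, IDS["byp_e"]: 1})
        add_reaction(model, "BYP_SYN", {
            IDS["sub_c"]: -1, IDS["nadh"]: -1, IDS["byp_c"]: 1, IDS["nad"]: 1,
        })

    # -- biomass -----------------------------------------------------------
    biomass_stoich: dict[str, float] = {p: -1.0 for p in precursors}
    biomass_stoich.update({
        IDS["atp"]: -config.gam, IDS["h2o_c"]: -config.gam,
        IDS["adp"]: config.gam, IDS["pi"]: config.gam,
    })
    add_reaction(model, "BIOMASS", biomass_stoich, 0.0, GLOBAL_BOUND,
                 artificial=True)
    model.objective = "BIOMASS"

    # -- seed-permuted gene assignment ------------------------------------
    gpr_slots = [
        ("CAT", "iso"), ("NDH", "complex"), ("ATPS", "single"),
        ("ATPM", "single"), ("R_free_prec1", "single"),
        (ATP_EGC_CANDIDATE, "single"),
    ]
    gpr_slots += [(f"SYN_prec{k}", "single")
                  for k in range(2, config.n_biomass_precursors + 1)]
    if "oxygen" in config.acceptors:
        gpr_slots.append(("CYO", "single"))
    if "fumarate" in config.acceptors:
        gpr_slots.append(("FRD", "single"))
    needed = sum(2 if kind != "single" else 1 for _, kind in gpr_slots)
    pool = iter(_gene_names(rng, needed))
    for rxn_id, kind in gpr_slots:
        rxn = model.reactions.get_by_id(rxn_id)
        if kind == "iso":
            rxn.gene_reaction_rule = f"{next(pool)} or {next(pool)}"
        elif kind == "complex":
            rxn.gene_reaction_rule = f"{next(pool)} and {next(pool)}"
        else:
            rxn.gene_reaction_rule = next(pool)
    return model


def biomass_spec(model: Model) -> BiomassSpec:
    """Read the biomass bookkeeping back out of a generated toy."""
    biomass = model.reactions.get_by_id("BIOMASS")
    precursors = {m.id: -c for m, c in biomass.metabolites.items()
                  if c < 0 and m.id.startswith("prec")}
    gam = -biomass.metabolites.get(model.metabolites.get_by_id(IDS["atp"]), 0.0)
    return BiomassSpec(precursors=precursors, gam=float(gam),
                       ngam=float(model.reactions.get_by_id("ATPM").lower_bound),
                       atpm_reaction_id="ATPM")


# ---------------------------------------------------------------------------
# corruption injectors
# ---------------------------------------------------------------------------

def inject_egc(model: Model, seed: int = 0,
               currency: str | None = None) -> tuple[Model, str, str]:
    """Flip one reaction direction to create an energy-generating cycle.

    ATP-type: the ATP-coupled duplicate biosynthesis route is made
    reversible, closing a net-ATP loop with its ATP-free twin. PMF-type:
    the proton symporter is made reversible, closing a proton-pumping loop
    with the uniporter. Returns (corrupted copy, flipped id, currency).
    """
    candidates = {}
    if ATP_EGC_CANDIDATE in model.reactions:
        candidates["ATP"] = ATP_EGC_CANDIDATE
    if PMF_EGC_CANDIDATE in model.reactions:
        candidates["PMF"] = PMF_EGC_CANDIDATE
    if not candidates:
        raise ValueError("model has no energy-coupled injection candidate")
    if currency is None:
        currency = random.Random(seed).choice(sorted(candidates))
    if currency not in candidates:
        raise ValueError(f"no {currency}-type candidate in this model")
    target = candidates[currency]
    out = model.copy()
    out.reactions.get_by_id(target).lower_bound = -GLOBAL_BOUND
    return out, target, currency


@dataclass
class GapInstance:
    """A ground-truthed gap-filling fixture."""

    model: Model
    universal: UniversalDB
    hidden_ids: list[str]        # universal ids of the removed reactions
    blocked_targets: list[str]   # metabolite ids that became unproducible
    decoy_ids: list[str] = field(default_factory=list)


def make_gap_instance(model: Model, n_removed: int = 1, n_decoys: int = 2,
                      seed: int = 0) -> GapInstance:
    """Remove essential biosynthesis steps and hide them (among balanced but
    disconnected decoys) in a universal database."""
    rng = random.Random(seed)
    candidates = sorted(r.id for r in model.reactions if r.id.startswith("SYN_prec"))
    if n_removed > len(candidates):
        raise ValueError(
            f"cannot remove {n_removed} reactions: only {len(candidates)} "
            "essential single-route steps available")
    removed = sorted(rng.sample(candidates, n_removed))

    corrupted = model.copy()
    hidden, blocked = [], []
    formulas: dict[str, str] = {}
    universal_rxns: list[UniversalReaction] = []
    for rid in removed:
        rxn = corrupted.reactions.get_by_id(rid)
        stoich = {m.id: c for m, c in rxn.metabolites.items()}
        universal_rxns.append(UniversalReaction(
            f"U_{rid}", stoich, rxn.lower_bound, rxn.upper_bound, source="hidden"))
        hidden.append(f"U_{rid}")
        blocked.extend(m.id for m, c in rxn.metabolites.items()
                       if c > 0 and m.id.startswith("prec"))
        corrupted.remove_reactions([rxn], remove_orphans=False)

    decoys = []
    for i in range(n_decoys):
        a, b = f"dmetA{i}_c0", f"dmetB{i}_c0"
        formulas[a] = formulas[b] = "C2H4O2"
        rid = f"U_decoy{i}"
        universal_rxns.append(UniversalReaction(
            rid, {a: -1.0, b: 1.0}, -GLOBAL_BOUND, GLOBAL_BOUND, source="decoy"))
        decoys.append(rid)
    rng.shuffle(universal_rxns)
    return GapInstance(model=corrupted,
                       universal=UniversalDB(universal_rxns, formulas),
                       hidden_ids=hidden, blocked_targets=sorted(set(blocked)),
                       decoy_ids=decoys)


# ---------------------------------------------------------------------------
# BES fixtures
# ---------------------------------------------------------------------------

def make_mfc_model(seed: int = 0, byproduct_leak: bool = False,
                   p_o_ratio: float = 1.5, **overrides) -> Model:
    """Anaerobic core toy wired for electrode attachment: no soluble
    terminal acceptor, so the quinol pool can only discharge at the anode."""
    from .bes_sim import ElectrodeSpec, add_electrode

    base = make_core_model(ToyConfig(
        seed=seed, acceptors=(), byproduct_leak=byproduct_leak,
        p_o_ratio=p_o_ratio, **overrides))
    spec = ElectrodeSpec(quinol=IDS["mqh2"], quinone=IDS["mq"], h_e=IDS["h_e"])
    return add_electrode(base, spec)


def make_mes_model(seed: int = 0, inward: bool = True, **overrides) -> Model:
    """Anaerobic toy for electrosynthesis: catabolism releases an
    unrecoverable formate analogue (the redox/carbon loss that holds the
    no-inward yield below N/M), a 2-NADH reduction step makes the product
    (C3H10O3, degree 16), and the inward-electron machinery is attached.
    The product demand is ``DM_prod_c0``."""
    from .bes_sim import MESSpec, add_mes

    base = make_core_model(ToyConfig(
        seed=seed, acceptors=(), formate_release=True, ngam=0.0, **overrides))
    add_metabolite(base, "prod_c0", CYTOSOL, "C3H10O3")
    add_reaction(base, "R_PROD", {
        IDS["sub_c"]: -1, IDS["nadh"]: -2, "prod_c0": 1, IDS["nad"]: 2,
    })
    add_demand(base, "prod_c0")
    spec = MESSpec(nad=IDS["nad"], nadh=IDS["nadh"], h_p=IDS["h_p"],
                   inward_electron=inward)
    return add_mes(base, spec)


FSEOF_NADH_BRANCH = "R_mdh_like"
FSEOF_NEUTRAL_BRANCH = "R_isomerase"
# the full NADH-producing route: the oxidizing step plus its obligate
# oxidized-waste export and the drain's proton efflux
FSEOF_TARGET_BRANCH = frozenset({FSEOF_NADH_BRANCH, "T_waste", "T_h"})


def make_fseof_toy(seed: int = 0) -> Model:
    """Two-branch toy for FSEOF ground-truth recovery.

    The redox-neutral branch isomerizes the substrate straight into the
    biomass precursor; the NADH branch (malate-dehydrogenase analogue)
    oxidizes it to an exported waste product, releasing 2 NADH. With no
    other NADH sink the oxidizing branch is exactly zero at maximal growth
    and must carry all flux at maximal NADH drain, so the amplification set
    is the known :data:`FSEOF_TARGET_BRANCH` for every seed.
    """
    rng = random.Random(seed)
    model = new_model(f"toy_fseof_seed{seed}", include_periplasm=False)
    add_metabolite(model, IDS["sub_c"], CYTOSOL, "C3H6O3")
    add_metabolite(model, IDS["sub_e"], EXTRACELLULAR, "C3H6O3")
    add_metabolite(model, "bpre_c0", CYTOSOL, "C3H6O3")
    add_metabolite(model, "waste_c0", CYTOSOL, "C3H2O3")
    add_metabolite(model, "waste_e0", EXTRACELLULAR, "C3H2O3")
    add_metabolite(model, IDS["nad"], CYTOSOL, "X")
    add_metabolite(model, IDS["nadh"], CYTOSOL, "XH2")
    add_metabolite(model, IDS["h_c"], CYTOSOL, "H")
    add_metabolite(model, IDS["h_e"], EXTRACELLULAR, "H")

    add_exchange(model, IDS["sub_e"], -DEFAULT_UPTAKE_BOUND, GLOBAL_BOUND)
    add_exchange(model, "waste_e0", 0.0, GLOBAL_BOUND)
    add_exchange(model, IDS["h_e"], -GLOBAL_BOUND, GLOBAL_BOUND)
    add_reaction(model, "T_sub", {IDS["sub_e"]: -1, IDS["sub_c"]: 1})
    add_reaction(model, "T_waste", {"waste_c0": -1, "waste_e0": 1})
    add_reaction(model, "T_h", {IDS["h_c"]: -1, IDS["h_e"]: 1},
                 -GLOBAL_BOUND, GLOBAL_BOUND)
    genes = iter(_gene_names(rng, 2))
    add_reaction(model, FSEOF_NADH_BRANCH, {
        IDS["sub_c"]: -1, IDS["nad"]: -2,
        "waste_c0": 1, IDS["nadh"]: 2,
    }, gpr=next(genes))
    add_reaction(model, FSEOF_NEUTRAL_BRANCH, {IDS["sub_c"]: -1, "bpre_c0": 1},
                 gpr=next(genes))
    add_reaction(model, "BIOMASS", {"bpre_c0": -1}, 0.0, GLOBAL_BOUND,
                 artificial=True)
    model.objective = "BIOMASS"
    return model


def nadh_drain_stoichiometry(include_periplasm: bool = True) -> dict[str, float]:
    """Stoichiometry of the canonical NADH regeneration drain
    (NADH -> NAD+ + H+)."""
    return {IDS["nadh"]: -1.0, IDS["nad"]: 1.0, IDS["h_c"]: 1.0}
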