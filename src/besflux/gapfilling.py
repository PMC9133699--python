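"""Weight-added parsimonious-FBA gap filling.

The gap filler merges the model with a universal reaction database and
solves one LP:

    min   sum_i (1/W) |v_i|  +  sum_j |y_j|
    s.t.  S v + U y = 0
          eps <= v_target <= 10
          lb <= v, y <= ub

where v are fluxes through the model's own reactions (cheap, weight W =
1000 by default) and y are fluxes through universal candidate reactions
(expensive, weight 1). Minimizing the weighted absolute flux sum drives the
solution to activate as few universal reactions as possible while still
letting the existing network carry flux freely — an LP relaxation of
minimum-cardinality gap filling ("weight-added pFBA"). Absolute values use
the solver's non-negative forward/reverse split variables; the strict
demand ``0 < v_target`` is realized as ``v_target >= eps`` (default 1e-3).

Every result is verified by re-solving the model augmented with only the
returned reactions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from cobra import Model
from optlang.symbolics import Zero

from .model_core import (
    CYTOSOL,
    EXTRACELLULAR,
    GLOBAL_BOUND,
    add_demand,
    add_exchange,
    add_metabolite,
    add_reaction,
)
from .lp_engine import fba

DEFAULT_WEIGHT = 1000.0
DEFAULT_EPSILON = 1e-3
TARGET_UPPER = 10.0
ACTIVE_TOL = 1e-6
BLOCKED_TOL = 1e-6


class UnfillableGapError(RuntimeError):
    """The target stays blocked even with the full universal database."""


# ---------------------------------------------------------------------------
# universal database
# ---------------------------------------------------------------------------

_ARROW_RE = re.compile(r"<->|<=>|->|=>")


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A + B -> C"`` into a stoichiometry map; ``<->``/``<=>``
    marks a reversible reaction."""
    arrow = _ARROW_RE.search(equation)
    if not arrow:
        raise ValueError(f"no reaction arrow in equation {equation!r}")
    reversible = arrow.group(0) in ("<->", "<=>")
    lhs, rhs = equation[:arrow.start()], equation[arrow.end():]
    stoich: dict[str, float] = {}

    def _side(side: str, sign: float) -> None:
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split(None, 1)
            if len(parts) == 2 and re.fullmatch(r"\d*\.?\d+", parts[0]):
                coef, met = float(parts[0]), parts[1].strip()
            else:
                coef, met = 1.0, term
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    _side(lhs, -1.0)
    _side(rhs, +1.0)
    return {m: c for m, c in stoich.items() if c != 0.0}, reversible


@dataclass
class UniversalReaction:
    """One candidate reaction in the universal database."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -GLOBAL_BOUND
    upper_bound: float = GLOBAL_BOUND
    source: str = ""

    @classmethod
    def from_equation(cls, rxn_id: str, equation: str,
                      lower_bound: float | None = None,
                      upper_bound: float | None = None,
                      source: str = "") -> "UniversalReaction":
        stoich, reversible = parse_equation(equation)
        lb = lower_bound if lower_bound is not None else (-GLOBAL_BOUND if reversible else 0.0)
        ub = upper_bound if upper_bound is not None else GLOBAL_BOUND
        return cls(rxn_id, stoich, lb, ub, source)


@dataclass
class UniversalDB:
    """Candidate reactions for gap filling, with optional formulas for
    metabolites the model does not yet contain."""

    reactions: list[UniversalReaction] = field(default_factory=list)
    metabolite_formulas: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate universal reaction ids: {dupes}")

    def __len__(self) -> int:
        return len(self.reactions)

    def subset(self, ids: set[str] | list[str]) -> "UniversalDB":
        keep = set(ids)
        return UniversalDB([r for r in self.reactions if r.id in keep],
                           dict(self.metabolite_formulas))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "UniversalDB":
        """Columns: id, equation, lb, ub, source (header optional)."""
        reactions = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("id", "reaction_id"):
                continue
            rid, eq = parts[0], parts[1]
            lb = float(parts[2]) if len(parts) > 2 and parts[2] else None
            ub = float(parts[3]) if len(parts) > 3 and parts[3] else None
            src = parts[4] if len(parts) > 4 else ""
            reactions.append(UniversalReaction.from_equation(rid, eq, lb, ub, src))
        return cls(reactions)

    @classmethod
    def from_json(cls, path: str | Path) -> "UniversalDB":
        data = json.loads(Path(path).read_text())
        reactions = [
            UniversalReaction(
                r["id"], {m: float(c) for m, c in r["stoichiometry"].items()},
                float(r.get("lower_bound", -GLOBAL_BOUND)),
                float(r.get("upper_bound", GLOBAL_BOUND)),
                r.get("source", ""))
            for r in data["reactions"]
        ]
        return cls(reactions, {k: str(v) for k, v in data.get("metabolite_formulas", {}).items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "reactions": [
                {"id": r.id, "stoichiometry": r.stoichiometry,
                 "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
                 "source": r.source}
                for r in self.reactions
            ],
            "metabolite_formulas": self.metabolite_formulas,
        }, indent=1))


def _compartment_of(met_id: str) -> str:
    for suffix, comp in (("_c0", CYTOSOL), ("_p0", "p0"), ("_e0", EXTRACELLULAR)):
        if met_id.endswith(suffix):
            return comp
    return CYTOSOL


def add_universal_reactions(model: Model, universal: UniversalDB) -> list[str]:
    """Graft the universal reactions onto a model in place, creating any
    metabolites the model lacks. Returns the added reaction ids."""
    clash = [r.id for r in universal.reactions if r.id in model.reactions]
    if clash:
        raise ValueError(f"universal reaction ids already in model: {clash}")
    added = []
    for urxn in universal.reactions:
        for met_id in urxn.stoichiometry:
            if met_id not in model.metabolites:
                add_metabolite(model, met_id, _compartment_of(met_id),
                               formula=universal.metabolite_formulas.get(met_id))
        add_reaction(model, urxn.id, urxn.stoichiometry,
                     urxn.lower_bound, urxn.upper_bound)
        added.append(urxn.id)
    return added


# ---------------------------------------------------------------------------
# blocked-target discovery
# ---------------------------------------------------------------------------

def find_unproducible_targets(model: Model, component_ids: list[str],
                              threshold: float = BLOCKED_TOL) -> list[str]:
    """For each component, add a demand reaction, maximize it, and report
    the components whose maximal demand flux is below threshold (blocked).
    Demands are removed afterwards."""
    blocked = []
    for met_id in component_ids:
        with model as m:
            dm = add_demand(m, met_id, rxn_id=f"DM_probe_{met_id}")
            state = fba(m, dm.id, "max")
        if (not state.ok) or state.objective_value < threshold:
            blocked.append(met_id)
    return blocked


# ---------------------------------------------------------------------------
# the weighted-pFBA gap fill LP
# ---------------------------------------------------------------------------

@dataclass
class GapfillResult:
    target: str
    added_reactions: list[str]
    fluxes: dict[str, float]
    objective_value: float
    mechanical_additions: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "target": self.target,
            "added_reactions": self.added_reactions,
            "mechanical_additions": self.mechanical_additions,
            "objective_value": self.objective_value,
        }


def _resolve_target(model: Model, target: str) -> str:
    """Target may be a reaction id or a metabolite id (for which a demand
    reaction is ensured). Returns the target reaction id."""
    if target in model.reactions:
        return target
    if target in model.metabolites:
        rxn_id = f"DM_{target}"
        if rxn_id not in model.reactions:
            add_demand(model, target, rxn_id=rxn_id)
        return rxn_id
    raise KeyError(f"gap-fill target {target!r} is neither a reaction nor a metabolite")


def gapfill_target(
    model: Model,
    universal: UniversalDB,
    target: str,
    weight: float = DEFAULT_WEIGHT,
    epsilon: float = DEFAULT_EPSILON,
    target_upper: float = TARGET_UPPER,
    verify: bool = True,
) -> GapfillResult:
    """Fill the gaps blocking one target via the weighted-pFBA LP.

    ``target`` is a reaction id (demand/exchange/biomass) or a metabolite id
    (a demand is created). Returns the universal reactions carrying flux
    above tolerance at the optimum.
    """
    if weight < 1:
        raise ValueError("weight W must be >= 1")
    work = model.copy()
    target_rxn_id = _resolve_target(work, target)
    model_rxn_ids = {r.id for r in work.reactions}
    added_ids = add_universal_reactions(work, universal)

    trxn = work.reactions.get_by_id(target_rxn_id)
    trxn.bounds = (epsilon, min(target_upper, max(trxn.upper_bound, epsilon)))

    # feasibility with the full universal database
    probe = fba(work, target_rxn_id, "max")
    if not probe.ok:
        raise UnfillableGapError(
            f"target {target!r} is unfillable even with the full universal database")

    # min sum (1/W)|v_i| + sum |y_j| over forward/reverse split variables
    work.objective = work.problem.Objective(Zero, direction="min", sloppy=True)
    coefs = {}
    for rxn in work.reactions:
        c = 1.0 if rxn.id in set(added_ids) else 1.0 / weight
        coefs[rxn.forward_variable] = c
        coefs[rxn.reverse_variable] = c
    work.objective.set_linear_coefficients(coefs)
    solution = work.optimize(raise_error=False)
    if solution.status != "optimal":
        raise UnfillableGapError(
            f"gap-fill LP for target {target!r} ended with status {solution.status!r}")

    fluxes = {r: float(v) for r, v in solution.fluxes.items()}
    added = sorted(rid for rid in added_ids if abs(fluxes[rid]) > ACTIVE_TOL)
    objective_value = sum(abs(fluxes[r]) / weight for r in model_rxn_ids) + \
        sum(abs(fluxes[r]) for r in added_ids)

    if verify:
        check = model.copy()
        _resolve_target(check, target)
        add_universal_reactions(check, universal.subset(added))
        state = fba(check, target_rxn_id, "max")
        if (not state.ok) or state.objective_value < epsilon:
            raise UnfillableGapError(
                f"verification re-solve failed for target {target!r}: "
                f"added set {added} does not restore producibility")

    return GapfillResult(target=target, added_reactions=added,
                         fluxes=fluxes, objective_value=objective_value)


def gapfill_all(
    model: Model,
    universal: UniversalDB,
    targets: list[str],
    weight: float = DEFAULT_WEIGHT,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[Model, dict[str, GapfillResult], dict[str, str]]:
    """Gap-fill every target, apply the union of additions once, and verify
    each target in the augmented model. Unfillable targets are recorded and
    the rest proceed. Returns (augmented model, results, failures)."""
    if not targets:
        raise ValueError("no gap-fill targets given")
    results: dict[str, GapfillResult] = {}
    failures: dict[str, str] = {}
    union: set[str] = set()
    for target in targets:
        try:
            res = gapfill_target(model, universal, target,
                                 weight=weight, epsilon=epsilon)
        except (UnfillableGapError, KeyError) as exc:
            failures[target] = str(exc)
            continue
        results[target] = res
        union.update(res.added_reactions)
    augmented = model.copy()
    add_universal_reactions(augmented, universal.subset(union))
    for target in results:
        rid = _resolve_target(augmented, target)
        state = fba(augmented, rid, "max")
        if (not state.ok) or state.objective_value < epsilon:
            failures[target] = "target not producible after union of additions"
    return augmented, results, failures


# ---------------------------------------------------------------------------
# substrate-utilization gap filling
# ---------------------------------------------------------------------------

def gapfill_substrate(
    model: Model,
    universal: UniversalDB,
    substrate_id: str,
    target: str,
    uptake: float = 4.06,
    weight: float = DEFAULT_WEIGHT,
    epsilon: float = DEFAULT_EPSILON,
    threshold: float = BLOCKED_TOL,
) -> tuple[Model, GapfillResult]:
    """Enable utilization of a substrate.

    Two gap categories: (1) a missing exchange/transport into the cell is
    created mechanically; (2) a missing catabolic route is filled with the
    weighted-pFBA gap filler against the downstream ``target`` reaction
    (biomass or ATPM). ``substrate_id`` is the cytosolic metabolite id.
    Returns the augmented model and the result (empty additions when the
    substrate is already fully usable).
    """
    cyto = model.metabolites.get_by_id(substrate_id)
    work = model.copy()
    mechanical: list[str] = []

    base = substrate_id[:-len("_c0")] if substrate_id.endswith("_c0") else substrate_id
    ext_id = f"{base}_e0"
    if ext_id not in work.metabolites:
        add_metabolite(work, ext_id, EXTRACELLULAR, formula=cyto.formula,
                       charge=cyto.charge or 0)
    if f"EX_{ext_id}" not in work.reactions:
        add_exchange(work, ext_id)
        mechanical.append(f"EX_{ext_id}")
    work.reactions.get_by_id(f"EX_{ext_id}").lower_bound = -uptake
    # transport gap: the supplied substrate cannot reach the cytosol
    if find_unproducible_targets(work, [substrate_id], threshold):
        transporter = f"T_{base}_gf"
        add_reaction(work, transporter, {ext_id: -1.0, substrate_id: 1.0},
                     -GLOBAL_BOUND, GLOBAL_BOUND)
        mechanical.append(transporter)

    state = fba(work, target, "max")
    if state.ok and state.objective_value >= threshold:
        return work, GapfillResult(target=target, added_reactions=[],
                                   fluxes=state.fluxes, objective_value=0.0,
                                   mechanical_additions=mechanical)
    result = gapfill_target(work, universal, target, weight=weight, epsilon=epsilon)
    result.mechanical_additions = mechanical
    add_universal_reactions(work, universal.subset(result.added_reactions))
    return work, result
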