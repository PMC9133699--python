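"""FBA, parsimonious FBA and deletion analysis.

Thin, deterministic layer over cobra's optlang/GLPK solver interface. All
entry points leave the input model untouched (work happens inside cobra
model contexts) and return :class:`FluxState` records.

pFBA is the standard two-stage LP: fix the objective at a fraction of its
optimum, then minimize total absolute flux via the solver's non-negative
forward/reverse split variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
from cobra import Model

from .model_core import MediumSpec, apply_medium

DEFAULT_GROWTH_THRESHOLD = 1e-6
FEASIBILITY_TOL = 1e-9


class InfeasibleError(RuntimeError):
    """The LP has no feasible point under the given constraints."""


@dataclass
class FluxState:
    """Solver outcome: status, the objective reaction's flux, and the full
    flux vector (mmol/gDW/h)."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    sum_abs_flux: float | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _solve(model: Model) -> FluxState:
    try:
        solution = model.optimize(raise_error=False)
        status = solution.status
    except Exception:  # cobra raises on e.g. unbounded regardless of flag
        status = str(model.solver.status)
    if status not in ("optimal",):
        # optlang reports GLPK unbounded problems as "unbounded" or
        # "undefined"; normalize anything else to infeasible.
        status = "unbounded" if status in ("unbounded", "undefined") else "infeasible"
        return FluxState(status=status, objective_value=float("nan"))
    fluxes = {r: float(v) for r, v in solution.fluxes.items()}
    return FluxState(
        status="optimal",
        objective_value=float(solution.objective_value),
        fluxes=fluxes,
        sum_abs_flux=sum(abs(v) for v in fluxes.values()),
    )


def fba(model: Model, objective_id: str | None = None, sense: str = "max") -> FluxState:
    """Flux balance analysis: optimize one reaction's flux over S v = 0 and
    the bounds. ``objective_id`` defaults to the model's current objective."""
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    with model as m:
        if objective_id is not None:
            m.objective = m.reactions.get_by_id(objective_id)
        m.objective_direction = sense
        state = _solve(m)
    if objective_id is not None and state.ok:
        state.objective_value = state.fluxes[objective_id]
    return state


def pfba(model: Model, objective_id: str | None = None,
         objective_fraction: float = 1.0) -> FluxState:
    """Parsimonious FBA: fix the objective at ``objective_fraction`` of its
    FBA optimum, then minimize the summed absolute flux."""
    if not 0.0 < objective_fraction <= 1.0:
        raise ValueError("objective_fraction must be in (0, 1]")
    with model as m:
        if objective_id is not None:
            m.objective = m.reactions.get_by_id(objective_id)
        m.objective_direction = "max"
        obj_rxn_id = objective_id or str(
            next(iter(cobra.util.solver.linear_reaction_coefficients(m))).id)
        try:
            solution = cobra.flux_analysis.pfba(
                m, fraction_of_optimum=objective_fraction)
        except cobra.exceptions.Infeasible as exc:
            raise InfeasibleError(
                f"pFBA infeasible after fixing {obj_rxn_id} at fraction "
                f"{objective_fraction} of its optimum") from exc
    fluxes = {r: float(v) for r, v in solution.fluxes.items()}
    return FluxState(
        status="optimal",
        objective_value=fluxes[obj_rxn_id],
        fluxes=fluxes,
        sum_abs_flux=sum(abs(v) for v in fluxes.values()),
    )


# ---------------------------------------------------------------------------
# deletions
# ---------------------------------------------------------------------------

def _disable_genes(model: Model, genes: set[str], mode: str) -> None:
    """Disable reactions inside an open cobra context."""
    unknown = [g for g in genes if g not in model.genes]
    if unknown:
        raise KeyError(f"unknown gene ids: {unknown}")
    if mode == "gpr_aware":
        # GPR boolean evaluation: a reaction dies only if its rule is false
        # with the deleted genes set false (OR = isoenzymes survive).
        for gid in genes:
            model.genes.get_by_id(gid).knock_out()
    elif mode == "reaction_removal":
        # literal rule: any reaction mentioning a deleted gene is disabled
        for rxn in model.reactions:
            if any(g.id in genes for g in rxn.genes):
                rxn.bounds = (0.0, 0.0)
    else:
        raise ValueError("mode must be 'gpr_aware' or 'reaction_removal'")


def delete_genes(model: Model, genes: set[str] | list[str],
                 mode: str = "gpr_aware") -> Model:
    """Return a copy of the model with the given genes deleted."""
    out = model.copy()
    _disable_genes(out, set(genes), mode)
    return out


def knockout_reactions(model: Model, reaction_ids: list[str] | set[str]) -> Model:
    """Return a copy with the given reactions' bounds set to zero."""
    out = model.copy()
    for rid in reaction_ids:
        out.reactions.get_by_id(rid).bounds = (0.0, 0.0)
    return out


def essentiality_screen(
    model: Model,
    medium: MediumSpec | None = None,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    mode: str = "gpr_aware",
    genes: list[str] | None = None,
) -> dict[str, str]:
    """Single-gene deletion screen against the biomass objective.

    A gene is essential iff the maximal growth after its deletion falls
    below ``growth_threshold``. Raises :class:`InfeasibleError` when the
    wild type itself does not grow (the screen would be meaningless).
    """
    work = apply_medium(model, medium) if medium is not None else model.copy()
    wild = fba(work)
    if not wild.ok or wild.objective_value < growth_threshold:
        raise InfeasibleError(
            f"wild-type growth {wild.objective_value!r} below threshold; "
            "essentiality screen is meaningless")
    gene_ids = genes if genes is not None else [g.id for g in work.genes]
    verdict: dict[str, str] = {}
    for gid in gene_ids:
        with work as m:
            _disable_genes(m, {gid}, mode)
            state = _solve(m)
        growth = state.objective_value if state.ok else 0.0
        verdict[gid] = "essential" if growth < growth_threshold else "non-essential"
    return verdict
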