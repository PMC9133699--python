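"""Core data model for constraint-based metabolic networks.

The in-memory container is :class:`cobra.Model`; this module adds the
conventions the rest of the package relies on:

* three compartments — cytosol ``c0``, periplasm ``p0``, extracellular
  ``e0`` (the compartment layout of Gram-negative electroactive bacteria,
  where the periplasm hosts the electrode-facing respiratory chains);
* exchange reactions are boundary reactions on a single ``e0`` metabolite,
  conventionally prefixed ``EX_``, with uptake negative and secretion
  positive;
* *artificial* reactions (electrode pseudo-reactions, NADH drains, demand
  sinks) are tagged in ``Reaction.notes`` so that mass-balance audits and
  medium handling can exempt them;
* media are plain tables of exchange-reaction bounds.

Flux units are mmol/gDW/h throughout; growth is h^-1. The default global
bound magnitude is 1000.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import cobra
import yaml
from cobra import Metabolite, Model, Reaction

GLOBAL_BOUND = 1000.0

CYTOSOL = "c0"
PERIPLASM = "p0"
EXTRACELLULAR = "e0"
COMPARTMENTS = {CYTOSOL: "cytosol", PERIPLASM: "periplasm", EXTRACELLULAR: "extracellular"}

_ARTIFICIAL_KEY = "artificial"


class ModelValidationError(ValueError):
    """A model violates a structural invariant (bad compartment, dangling
    metabolite reference, missing objective...)."""


class MediumError(ValueError):
    """A medium refers to a reaction that is not an exchange reaction."""


# ---------------------------------------------------------------------------
# artificial / exchange conventions
# ---------------------------------------------------------------------------

def mark_artificial(reaction: Reaction) -> Reaction:
    """Tag a reaction as artificial (electrode pseudo-reaction, drain,
    demand...). Artificial reactions are exempt from mass-balance audits and
    are never treated as medium exchanges."""
    reaction.notes[_ARTIFICIAL_KEY] = "true"
    return reaction


def is_artificial(reaction: Reaction) -> bool:
    return str(reaction.notes.get(_ARTIFICIAL_KEY, "")).lower() == "true"


def is_exchange(reaction: Reaction) -> bool:
    """Exchange reactions touch exactly one metabolite, in ``e0``, and are
    not artificial sinks/demands."""
    if is_artificial(reaction) or len(reaction.metabolites) != 1:
        return False
    met = next(iter(reaction.metabolites))
    return met.compartment == EXTRACELLULAR and reaction.boundary


def exchanges(model: Model) -> list[Reaction]:
    return [r for r in model.reactions if is_exchange(r)]


# ---------------------------------------------------------------------------
# model construction helpers
# ---------------------------------------------------------------------------

def new_model(model_id: str, include_periplasm: bool = True) -> Model:
    model = Model(model_id)
    comps = dict(COMPARTMENTS)
    if not include_periplasm:
        comps.pop(PERIPLASM)
    model.compartments = comps
    return model


def add_metabolite(
    model: Model,
    met_id: str,
    compartment: str,
    formula: str | None = None,
    charge: int = 0,
    name: str | None = None,
) -> Metabolite:
    if compartment not in COMPARTMENTS:
        raise ModelValidationError(
            f"metabolite {met_id!r}: unknown compartment {compartment!r} "
            f"(expected one of {sorted(COMPARTMENTS)})"
        )
    met = Metabolite(met_id, formula=formula, name=name or met_id,
                     compartment=compartment, charge=charge)
    model.add_metabolites([met])
    return met


def add_reaction(
    model: Model,
    rxn_id: str,
    stoichiometry: Mapping[str, float],
    lower_bound: float = 0.0,
    upper_bound: float = GLOBAL_BOUND,
    gpr: str = "",
    name: str | None = None,
    artificial: bool = False,
) -> Reaction:
    """Add a reaction from a {metabolite_id: coefficient} map (negative =
    consumed). All metabolites must already exist in the model."""
    if lower_bound > upper_bound:
        raise ModelValidationError(
            f"reaction {rxn_id!r}: lower bound {lower_bound} > upper bound {upper_bound}"
        )
    missing = [m for m in stoichiometry if m not in model.metabolites]
    if missing:
        raise ModelValidationError(
            f"reaction {rxn_id!r} references undeclared metabolites: {missing}"
        )
    rxn = Reaction(rxn_id, name=name or rxn_id,
                   lower_bound=lower_bound, upper_bound=upper_bound)
    model.add_reactions([rxn])
    rxn.add_metabolites({model.metabolites.get_by_id(m): c
                         for m, c in stoichiometry.items()})
    if gpr:
        rxn.gene_reaction_rule = gpr
    if artificial:
        mark_artificial(rxn)
    return rxn


def add_exchange(model: Model, met_id: str,
                 lower_bound: float = 0.0,
                 upper_bound: float = GLOBAL_BOUND) -> Reaction:
    met = model.metabolites.get_by_id(met_id)
    if met.compartment != EXTRACELLULAR:
        raise ModelValidationError(
            f"exchange target {met_id!r} is in {met.compartment!r}, not {EXTRACELLULAR!r}"
        )
    return add_reaction(model, f"EX_{met_id}", {met_id: -1.0},
                        lower_bound=lower_bound, upper_bound=upper_bound)


def add_demand(model: Model, met_id: str, rxn_id: str | None = None,
               upper_bound: float = GLOBAL_BOUND) -> Reaction:
    """Irreversible artificial demand (met ->), used to probe producibility."""
    rxn_id = rxn_id or f"DM_{met_id}"
    return add_reaction(model, rxn_id, {met_id: -1.0}, 0.0, upper_bound,
                        artificial=True)


# ---------------------------------------------------------------------------
# validation and I/O
# ---------------------------------------------------------------------------

def validate_model(model: Model) -> None:
    """Check structural invariants; raise :class:`ModelValidationError`."""
    for met in model.metabolites:
        if met.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {met.id!r}: unknown compartment {met.compartment!r}"
            )
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r}: lower bound exceeds upper bound"
            )


def read_model(path: str | Path, fmt: str | None = None) -> Model:
    """Read an SBML (L3 + FBC) or JSON model. Format inferred from the
    suffix when not given. Raises :class:`ModelValidationError` on files
    that parse but violate the package's structural invariants."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "sbml")
    try:
        if fmt == "json":
            model = cobra.io.load_json_model(str(path))
        elif fmt == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            raise ValueError(f"unknown model format {fmt!r}")
    except (KeyError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown model format" in str(exc):
            raise
        raise ModelValidationError(
            f"malformed {fmt} model {path}: offending entity {exc}") from exc
    validate_model(model)
    return model


def write_model(model: Model, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "sbml")
    if fmt == "json":
        cobra.io.save_json_model(model, str(path), sort=True)
    elif fmt == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def sbml_bytes(model: Model) -> bytes:
    """Serialize to SBML in memory (used for determinism checks)."""
    buf = io.StringIO()
    cobra.io.write_sbml_model(model, buf)
    return buf.getvalue().encode()


# ---------------------------------------------------------------------------
# biomass / medium specifications
# ---------------------------------------------------------------------------

@dataclass
class BiomassSpec:
    """Biomass formulation bookkeeping.

    gam: growth-associated ATP maintenance (mmol ATP per gDW), embedded in
    the biomass reaction's ATP stoichiometry. ngam: non-growth maintenance
    flux (mmol/gDW/h), enforced as the ATPM lower bound.
    """

    precursors: dict[str, float]
    gam: float
    ngam: float
    atpm_reaction_id: str
    biomass_reaction_id: str = "BIOMASS"

    def __post_init__(self) -> None:
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("GAM and NGAM must be non-negative")


@dataclass
class MediumSpec:
    """Exchange-reaction bounds defining a growth medium."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    name: str = "medium"

    @classmethod
    def from_file(cls, path: str | Path) -> "MediumSpec":
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            data = yaml.safe_load(path.read_text())
            bounds = {k: (float(v[0]), float(v[1])) for k, v in data.get("bounds", data).items()
                      if k != "name"}
            name = data.get("name", path.stem) if isinstance(data, dict) else path.stem
            return cls(bounds=bounds, name=str(name))
        # 3-column TSV: reaction_id, lb, ub
        bounds = {}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, lb, ub = line.split("\t")[:3]
            if rid.lower() in ("reaction_id", "id"):
                continue
            bounds[rid] = (float(lb), float(ub))
        return cls(bounds=bounds, name=path.stem)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {"name": self.name, "bounds": {k: list(v) for k, v in self.bounds.items()}}))


def apply_medium(model: Model, medium: MediumSpec, inplace: bool = False) -> Model:
    """Set exchange bounds from a medium. Non-listed exchange reactions get
    their uptake closed (lower bound 0); listed ones get exactly the given
    bounds. Idempotent. Only exchange reactions may be listed."""
    target = model if inplace else model.copy()
    ex_ids = {r.id for r in exchanges(target)}
    bad = [rid for rid in medium.bounds if rid not in ex_ids]
    if bad:
        raise MediumError(f"medium {medium.name!r} lists non-exchange reactions: {bad}")
    for rxn in exchanges(target):
        if rxn.id in medium.bounds:
            lb, ub = medium.bounds[rxn.id]
            rxn.bounds = (lb, ub)
        else:
            rxn.bounds = (0.0, rxn.upper_bound)
    return target


# ---------------------------------------------------------------------------
# elemental bookkeeping
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str | Mapping[str, float]) -> dict[str, float]:
    """Parse ``"C3H6O3"`` into ``{"C": 3, "H": 6, "O": 3}``. Accepts a
    ready-made element map unchanged."""
    if isinstance(formula, Mapping):
        return {str(k): float(v) for k, v in formula.items()}
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*\.?\d*)+", formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    counts: dict[str, float] = {}
    for elem, num in _FORMULA_RE.findall(formula):
        if not elem:
            continue
        counts[elem] = counts.get(elem, 0.0) + (float(num) if num else 1.0)
    return counts


@dataclass
class BalanceReport:
    """Outcome of a mass/charge audit: per-reaction element and charge
    residuals for internal reactions; exchanges, artificial reactions and
    the biomass reaction are open systems and excluded."""

    imbalanced: dict[str, dict[str, float]]
    unverifiable: list[str]
    checked: int

    @property
    def clean(self) -> bool:
        return not self.imbalanced


def check_mass_charge_balance(model: Model,
                              biomass_id: str | None = None,
                              tol: float = 1e-9) -> BalanceReport:
    imbalanced: dict[str, dict[str, float]] = {}
    unverifiable: list[str] = []
    checked = 0
    for rxn in model.reactions:
        if rxn.boundary or is_exchange(rxn) or is_artificial(rxn):
            continue
        if biomass_id is not None and rxn.id == biomass_id:
            continue
        if any(not met.formula for met in rxn.metabolites):
            unverifiable.append(rxn.id)
            continue
        checked += 1
        residual: dict[str, float] = {}
        for met, coef in rxn.metabolites.items():
            for elem, n in parse_formula(met.formula).items():
                residual[elem] = residual.get(elem, 0.0) + coef * n
            residual["charge"] = residual.get("charge", 0.0) + coef * (met.charge or 0)
        residual = {k: v for k, v in residual.items() if abs(v) > tol}
        if residual:
            imbalanced[rxn.id] = residual
    return BalanceReport(imbalanced=imbalanced, unverifiable=unverifiable, checked=checked)
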