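"""Phenotype screening: substrate-utilization and terminal-electron-acceptor
simulation, Biolog endpoint classification, and model-vs-experiment scoring.

Biolog phenotype microarrays report respiration as OmniLog units (OU); the
endpoint rule classifies a well as positive at >= 1.5x the control, negative
at <= 0.8x, and ambiguous in between. In-silico screening swaps the sole
source of a nutrient class (uptake 4.06 mmol/gDW/h) and calls growth above
threshold a positive prediction; acceptor screening opens one terminal
acceptor at a time and reads the maximal ATP-maintenance flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from cobra import Model

from .lp_engine import DEFAULT_GROWTH_THRESHOLD, fba

POSITIVE_FOLD = 1.5
NEGATIVE_FOLD = 0.8
DEFAULT_UPTAKE = 4.06


def classify_biolog(treatment_ou: float, control_ou: float) -> str:
    """Endpoint classification of one well against its control."""
    if control_ou <= 0:
        raise ValueError("control OU must be positive")
    ratio = treatment_ou / control_ou
    if ratio >= POSITIVE_FOLD:
        return "positive"
    if ratio <= NEGATIVE_FOLD:
        return "negative"
    return "ambiguous"


@dataclass
class PhenotypeObservation:
    substrate: str
    nutrient_class: str  # C | N | P | S | acceptor
    observed: str        # positive | negative | ambiguous
    exchange_id: str | None = None
    ou_treatment: float | None = None
    ou_control: float | None = None

    def __post_init__(self) -> None:
        if self.observed not in ("positive", "negative", "ambiguous"):
            raise ValueError(f"observed must be positive/negative/ambiguous, "
                             f"got {self.observed!r}")

    @classmethod
    def from_ou(cls, substrate: str, nutrient_class: str,
                ou_treatment: float, ou_control: float,
                exchange_id: str | None = None) -> "PhenotypeObservation":
        return cls(substrate, nutrient_class,
                   classify_biolog(ou_treatment, ou_control),
                   exchange_id, ou_treatment, ou_control)


def read_observations(path: str | Path) -> list[PhenotypeObservation]:
    """TSV: substrate, class, observed[, exchange_id[, OU_treatment, OU_control]]."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() == "substrate":
            continue
        ex = parts[3] if len(parts) > 3 and parts[3] else None
        out.append(PhenotypeObservation(parts[0], parts[1], parts[2], ex,
                                        float(parts[4]) if len(parts) > 5 else None,
                                        float(parts[5]) if len(parts) > 5 else None))
    return out


def screen_substrates(
    model: Model,
    observations: list[PhenotypeObservation],
    nutrient_class: str,
    class_exchanges: list[str],
    biomass_id: str,
    uptake: float = DEFAULT_UPTAKE,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
) -> dict[str, str]:
    """Predict utilization per substrate of one nutrient class.

    ``class_exchanges`` lists every exchange reaction supplying that class;
    for each observed substrate, all of them are closed except the
    substrate's own (opened at the uptake rate), and biomass is maximized.
    Substrates with no mappable exchange are predicted negative (the
    missing-transport case). Order-independent and deterministic.
    """
    predictions: dict[str, str] = {}
    for obs in observations:
        if obs.nutrient_class != nutrient_class:
            continue
        if obs.exchange_id is None or obs.exchange_id not in model.reactions:
            predictions[obs.substrate] = "negative"
            continue
        with model as m:
            for ex_id in class_exchanges:
                if ex_id in m.reactions:
                    rxn = m.reactions.get_by_id(ex_id)
                    rxn.bounds = (0.0, rxn.upper_bound)
            m.reactions.get_by_id(obs.exchange_id).lower_bound = -uptake
            state = fba(m, biomass_id, "max")
        grows = state.ok and state.objective_value > growth_threshold
        predictions[obs.substrate] = "positive" if grows else "negative"
    return predictions


def screen_acceptors(
    model: Model,
    acceptor_exchanges: list[str],
    atpm_id: str,
    substrate_exchange: str | None = None,
    uptake: float = DEFAULT_UPTAKE,
) -> dict[str, float]:
    """Per terminal electron acceptor, open only its exchange among the
    acceptor set and maximize the ATP maintenance flux. A positive flux
    means the acceptor supports respiration."""
    fluxes: dict[str, float] = {}
    for chosen in acceptor_exchanges:
        with model as m:
            for ex_id in acceptor_exchanges:
                if ex_id in m.reactions:
                    rxn = m.reactions.get_by_id(ex_id)
                    rxn.bounds = (0.0, rxn.upper_bound)
            if chosen in m.reactions:
                m.reactions.get_by_id(chosen).lower_bound = -1000.0
            if substrate_exchange is not None:
                m.reactions.get_by_id(substrate_exchange).lower_bound = -uptake
            state = fba(m, atpm_id, "max")
        fluxes[chosen] = state.objective_value if state.ok else 0.0
    return fluxes


@dataclass
class AgreementSummary:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    excluded: int = 0
    details: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def agreement_percent(self) -> float:
        if self.total == 0:
            raise ValueError("empty overlap between predictions and observations")
        return 100.0 * (self.tp + self.tn) / self.total


def agreement(predictions: dict[str, str],
              observations: list[PhenotypeObservation]) -> AgreementSummary:
    """Confusion-matrix summary of predicted vs observed utilization.
    Ambiguous observations are excluded from the denominator."""
    summary = AgreementSummary()
    for obs in observations:
        if obs.substrate not in predictions:
            continue
        if obs.observed == "ambiguous":
            summary.excluded += 1
            continue
        pred = predictions[obs.substrate]
        key = {
            ("positive", "positive"): "tp",
            ("negative", "negative"): "tn",
            ("positive", "negative"): "fp",
            ("negative", "positive"): "fn",
        }[(pred, obs.observed)]
        setattr(summary, key, getattr(summary, key) + 1)
        summary.details[obs.substrate] = key.upper()
    if summary.total == 0:
        raise ValueError("empty overlap between predictions and observations")
    return summary


def agreement_from_counts(tp: int, tn: int, total: int) -> float:
    """Agreement %% from confusion counts: 100*(TP+TN)/total."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * (tp + tn) / total
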