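"""Flux Scanning based on Enforced Objective Flux (FSEOF).

The scan drives an enforced reaction (canonically an NADH drain,
NADH_c -> NAD+_c + H+_c, standing in for NADH regeneration demand) from its
level at maximal growth (baseline) up to its own maximum (ceiling) in
``n_steps`` increments. At each step the enforced flux is pinned and a
parsimonious FBA maximizing biomass is solved; pFBA keeps the per-step flux
vectors out of degenerate-optimum noise. Reactions whose absolute flux
rises monotonically with enforcement, keeps its sign, and gains at least
max(10% of baseline, an absolute floor) are amplification (overexpression)
candidates; monotone decreases are attenuated. Exchange and artificial
reactions (including the enforced drain itself) are never targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from cobra import Model

from .model_core import GLOBAL_BOUND, add_reaction, is_artificial, is_exchange
from .lp_engine import fba, pfba


def add_drain(model: Model, drain_id: str, stoichiometry: Mapping[str, float]) -> Model:
    """Add an irreversible artificial drain (e.g. NADH_G) to a model copy."""
    if drain_id in model.reactions:
        raise ValueError(f"drain {drain_id!r} already present")
    out = model.copy()
    add_reaction(out, drain_id, dict(stoichiometry), 0.0, GLOBAL_BOUND,
                 artificial=True)
    return out


@dataclass
class FseofConfig:
    enforced_id: str = "NADH_G"
    biomass_id: str = "BIOMASS"
    n_steps: int = 10
    tolerance: float = 1e-6
    min_relative_gain: float = 0.10
    min_absolute_gain: float = 1e-4
    pdh_off: bool = False
    pdh_reaction_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_steps < 3:
            raise ValueError("n_steps must be >= 3")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class FseofResult:
    enforced_levels: list[float]
    trajectories: dict[str, list[float]]
    classification: dict[str, str]  # amplification | attenuated | unchanged
    skipped_steps: list[int] = field(default_factory=list)
    note: str = ""

    @property
    def targets(self) -> list[str]:
        return sorted(r for r, c in self.classification.items() if c == "amplification")


def _classify(traj: list[float], tol: float, rel: float, abs_floor: float) -> str:
    absolute = [abs(v) for v in traj]
    base, final = absolute[0], absolute[-1]
    signs = {1 if v > tol else -1 for v in traj if abs(v) > tol}
    sign_stable = len(signs) <= 1
    mono_up = all(b >= a - tol for a, b in zip(absolute, absolute[1:]))
    mono_down = all(b <= a + tol for a, b in zip(absolute, absolute[1:]))
    if sign_stable and mono_up and (final - base) >= max(rel * base, abs_floor):
        return "amplification"
    if mono_down and (base - final) > max(rel * final, abs_floor):
        return "attenuated"
    return "unchanged"


def fseof(model: Model, config: FseofConfig) -> FseofResult:
    """Run the FSEOF scan and classify every scannable reaction."""
    work = model.copy()
    if config.pdh_off:
        for rid in config.pdh_reaction_ids:
            work.reactions.get_by_id(rid).bounds = (0.0, 0.0)
    enforced = work.reactions.get_by_id(config.enforced_id)

    baseline_state = pfba(work, config.biomass_id, objective_fraction=1.0)
    baseline = baseline_state.fluxes[config.enforced_id]
    ceiling_state = fba(work, config.enforced_id, "max")
    if not ceiling_state.ok:
        raise RuntimeError("maximizing the enforced reaction failed")
    ceiling = ceiling_state.objective_value
    if ceiling - baseline <= config.tolerance:
        return FseofResult([], {}, {},
                           note="enforced flux cannot rise above its baseline")

    scannable = [r.id for r in work.reactions
                 if not (is_exchange(r) or is_artificial(r) or r.id == config.enforced_id)]
    levels: list[float] = []
    trajectories: dict[str, list[float]] = {rid: [] for rid in scannable}
    skipped: list[int] = []
    orig_bounds = enforced.bounds
    for k in range(config.n_steps + 1):
        level = baseline + k / config.n_steps * (ceiling - baseline)
        enforced.bounds = (level, level)
        try:
            state = pfba(work, config.biomass_id, objective_fraction=1.0)
        except Exception:
            skipped.append(k)
            continue
        levels.append(level)
        for rid in scannable:
            trajectories[rid].append(state.fluxes[rid])
    enforced.bounds = orig_bounds
    if not levels:
        raise RuntimeError("every FSEOF step was infeasible")

    classification = {
        rid: _classify(traj, config.tolerance, config.min_relative_gain,
                       config.min_absolute_gain)
        for rid, traj in trajectories.items()
    }
    return FseofResult(levels, trajectories, classification, skipped)
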