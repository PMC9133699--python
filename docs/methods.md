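# Methods

## Scope and model conventions

All analyses operate on constraint-based metabolic models in the standard
steady-state formalism: fluxes `v` (mmol/gDW/h) satisfy `S·v = 0` within
bounds, growth in h⁻¹, default global bound magnitude 1000. Models carry
three compartments — cytosol `c0`, periplasm `p0`, extracellular `e0` —
the layout of Gram-negative electroactive bacteria, whose periplasm hosts
the electrode-facing respiratory machinery. Exchange reactions are
boundary reactions on a single `e0` metabolite (uptake negative, secretion
positive); artificial constructs (electrode pseudo-reactions, drains,
demands) are tagged in reaction notes and exempted from mass-balance
audits and medium handling. `cobra` is the in-memory container and I/O
layer (SBML L3+FBC and JSON); GLPK via optlang is the LP solver. LP
solutions at degenerate optima are disambiguated with parsimonious FBA
wherever a flux *vector* (rather than an optimum value) is reported.

## Energy-generating-cycle QC

A draft reconstruction with wrong reaction directions can manufacture ATP
or proton-motive force out of nothing. The test is the closed-model
dissipation assay: close every exchange completely, relax forced lower
bounds (e.g. the maintenance flux — otherwise the closed model is
trivially infeasible and the verdict is masked), add an irreversible
dissipation reaction for the currency (ATP hydrolysis; periplasm→cytosol
proton re-entry; NADH oxidation), and maximize it. Any optimum above 1e-6
demonstrates an internal cycle; an optimum at ≥ 0.999 × the global bound
is reported at severity "unbounded" (an LP under finite bounds cannot
return literal infinity). The reported active set is the pFBA-minimal flux
state at the dissipation optimum — a cheap compact witness, documented as
a heuristic rather than a guaranteed minimal cut set. Choosing *which*
direction to flip remains a curation decision; fixes are consumed as
4-column tables (reaction, new bounds, note).

## Weight-added pFBA gap filling

The gap filler merges the model stoichiometry `S` with a universal
candidate database `U` and solves a single LP,

    min  Σᵢ (1/W)·|vᵢ| + Σⱼ |yⱼ|
    s.t. S·v + U·y = 0,   ε ≤ v_target ≤ 10,   bounds on v and y,

with `W = 1000` by default: model fluxes are three orders of magnitude
cheaper than database fluxes, so the optimum activates as few universal
reactions as possible while the native network routes freely. This is an
LP relaxation of minimum-cardinality gap filling ("weight-added pFBA");
absolute values use the solver's non-negative forward/reverse split
variables, and the strict demand `0 < v_target` is realized as
`v_target ≥ ε` with ε = 1e-3 (configurable; the window's upper value 10
caps the forced demand). Every result is verified by re-solving the model
augmented with only the returned reactions. The weighting admits a second
reading in which `W` scales the mass-balance of the native matrix itself;
that form is dimensionally inert (any feasible `v` rescales) and was
rejected in favor of the cost interpretation, which matches the method's
purpose of minimizing introduced reactions. On every fixture in the test
suite the LP answer coincides with a brute-force minimum-cardinality
subset search over the database; instances where an LP relaxation could
split flux across a cheaper multi-reaction combination are possible in
principle and would be reported by the verification step's flux pattern.

The three-step procedure is: (1) probe each biomass component with a
temporary demand reaction (maximum < 1e-6 ⇒ blocked); (2) fill each
blocked target; (3) apply the union of additions once and re-verify every
target. Substrate-utilization gaps are handled in two categories: a
missing exchange/transport into the cell is created mechanically, a
missing catabolic route goes through the LP with biomass or the ATP
maintenance reaction as the downstream target.

## Phenotype and essentiality screens

Biolog-style endpoint calls: positive at ≥ 1.5× the control signal,
negative at ≤ 0.8×, ambiguous in between (ambiguous wells are excluded
from agreement denominators). In-silico utilization: the sole source of
the nutrient class is swapped at an uptake of 4.06 mmol/gDW/h and growth
above 1e-6 is a positive prediction; substrates with no mappable exchange
are predicted negative. The 4.06 bound is applied uniformly to all
nutrient classes, and non-carbon screens keep the default carbon source
open (growth needs carbon regardless of which nitrogen source is being
probed). Acceptor screens open one terminal-acceptor exchange at a time
and read the maximal ATP-maintenance flux; any positive flux means the
acceptor supports respiration.

Gene deletions default to GPR-aware semantics (a reaction dies only when
its boolean gene rule evaluates false, so isoenzymes survive), with a
literal `reaction_removal` switch that disables every reaction mentioning
a deleted gene — the latter intentionally overcalls essentiality for
isoenzyme pairs and exists for comparability with that simpler published
rule. Essentiality threshold: maximal growth < 1e-6 after deletion.

## MFC electron generation and Coulombic efficiency

The anode enters the model as four irreversible artificial reactions: an
electrode source (→ oxidized electrode), two electrode reductions
(2 oxidized + quinol → 2 reduced + quinone + 2 H⁺_e0, for the menaquinol
and methylmenaquinol pools) and an electrode demand (reduced electrode →)
whose flux `F` is the electron current. The simulation fixes substrate
uptake, pins growth at 10% of its anaerobic maximum (electroactive
bacteria grow slowly on anodes; fraction configurable), and maximizes the
demand. The substrate's electron content `N` is its degree of reduction
(C=4, H=1, O=−2, with configurable extensions N=−3, S=+6, P=+5; unknown
elements raise). Two CE accountings are reported side by side:

* `strict`: `CE = F·100/(uptake·N)` — conservation-consistent with the
  printed one-electron-per-reduced-electrode stoichiometry; 100% when
  every substrate electron reaches the anode.
* `paired`: `CE = F·2·100/(uptake·N)` — the field's printed formula kept
  verbatim. Under the stoichiometry above the factor 2 double-counts
  (each quinol already yields two reduced-electrode species), so this
  accounting reads 200% at full transfer. Neither form is silently
  "corrected"; `coulombic_efficiency()` defaults to the verbatim form,
  simulations report both, and the test suite asserts conservation on the
  strict form.

## MES yields and the N/M ceiling

Inward electrons enter as an electron source (`Sink_e⁻`, → e⁻) feeding
NADH regeneration (`NADH_R`, 2 e⁻ + H⁺_p + NAD⁺ → NADH). Growth is forced
to zero (non-growing biocathodes), and — a package decision — the
maintenance lower bound is dropped for the simulation, since a non-growing
cell without a terminal acceptor has no energy source to pay it; CO₂
supply is left to the medium and should be unbounded. The product demand
is maximized under pFBA; yield = demand flux / nominal uptake. The
electron-balance ceiling without external electrons is `N/M`, the
substrate/product degree-of-reduction ratio; with inward electrons the
ceiling no longer binds (external reducing power can fix CO₂ and
re-assimilate otherwise lost intermediates), so inward yields at or above
`N/M` are expected, and relaxing the electron source can never lower the
optimum (tested as a monotonicity invariant).

## FSEOF

The scan computes the enforced reaction's level at maximal growth
(baseline, under pFBA) and its own maximum (ceiling), then pins it at
`n_steps = 10` evenly spaced levels, maximizing biomass by pFBA at each
(pFBA suppresses degenerate-optimum noise in the trajectories; maximizing
biomass at intermediate steps is the package's reading of "from optimal
growth to optimal enforcement"). A reaction is an amplification target
when its |flux| is monotone non-decreasing across steps (within tolerance
1e-6), sign-stable, and gains at least max(10% of baseline, 1e-4) — the
"significant change" rule, with both knobs in the configuration. Exchange
and artificial reactions (including the enforced drain) are never
targets. The canonical enforced reaction is an NADH drain
(NADH → NAD⁺ + H⁺), and reactions with no measurable activity under the
scan's condition (e.g. pyruvate dehydrogenase under anaerobiosis) can be
listed as temporarily off.

## Synthetic fixtures: what they emulate and what they do not

The core toy (~20–40 reactions) reproduces the *architecture* of a
respiring electroactive cell with exact electron bookkeeping:
pseudo-elements make every internal reaction element-balanced (NAD(H)
core `X`, quinone core `Y`, adenosine core `Z` with ATP = `ZHPO3`,
Pi = `H3PO4`), and a substrate CcHhOo is oxidized as
`substrate + (2c−o) H₂O + d/2 NAD⁺ → c CO₂ + d/2 NADH` with
`d = 4c + h − 2o`, so conservation checks are sharp to 1e-6. The
respiratory chain realizes the P/O ratio stoichiometrically: per NADH the
chain pumps `4·P/O` protons and ATP synthase consumes 4 per ATP, making
the ATP audit exactly linear in P/O. GAM/NGAM default to placeholder
values (2 mmol ATP/gDW, 0.1 mmol/gDW/h) chosen for a toy that grows at
O(0.1–2) h⁻¹; they are configuration, not literature values. Uptake bound
10 mmol/gDW/h by default; seeds permute gene-id assignment (one isoenzyme
pair, one two-subunit complex) and fix everything else, so identical
seeds give byte-identical SBML.

Deliberate idealizations: single lumped catabolic reaction (no pathway
intermediates, no substrate-level phosphorylation), no NADPH/quinol
distinction beyond one pool each, no thermodynamics or regulation, and
corruption injectors flip exactly one reaction. Passing tests therefore
demonstrate the *algorithms* (detection, filling, scanning, accounting)
against known ground truth — not predictive accuracy on real organisms,
which requires a curated genome-scale model.

Fixture-specific choices:

* the EGC injector relies on route redundancies the core toy carries on
  purpose (an ATP-coupled duplicate of a free biosynthesis step; a proton
  symporter next to a uniporter) — the same redundancies through which
  direction errors create cycles in merged draft reconstructions;
* the MFC byproduct leak forces secretion of a reduced compound
  (C₃H₈O₃, 14 e⁻) through a positive exchange lower bound
  (0.5 mmol/gDW/h), because a free optimizer maximizing electrode current
  would never leak electrons voluntarily;
* the MES toy's catabolism stops at a formate analogue (CH₂O₂, 2 of the
  substrate's 12 electrons) that the network cannot re-assimilate, which
  pins the no-inward yield at exactly 5/7 ≈ 0.714 — strictly below the
  N/M ceiling of 0.75 — while inward electrons lift it to 1.0;
* the FSEOF toy's NADH branch diverts carbon to an exported oxidized
  waste, so at maximal growth it is exactly silent and the amplification
  ground truth (the oxidizing step, its waste export, and the drain's
  proton efflux) is unique for every seed.

## Numerical choices

Feasibility/optimality at solver defaults (GLPK); flux activity threshold
1e-6; blocked-target threshold 1e-6; growth/essentiality threshold 1e-6;
gap-fill ε 1e-3; EGC "unbounded" severity at 0.999 × global bound; pFBA
via forward/reverse split variables (LP, never MILP). Degenerate optima:
pFBA flux vectors are used for all reported flux states; optimum *values*
are solver-order independent (tested by reaction-permutation
invariance). Problem sizes in the test suite: toys of ≤ 40 reactions,
≤ 20 seeds per property, brute-force gap-filling oracles over databases of
≤ 10 candidates — chosen so each property runs in seconds while still
covering both cycle types, both deletion modes and 1–2-reaction gaps.

## Known limitations

No MILP-based loopless analysis, flux sampling or thermodynamic
constraints; no automatic direction repair (curation chooses the flip);
the minimal-cycle witness and the LP gap-fill relaxation are heuristics
with the caveats noted above; the Coulombic-efficiency factor-2
discrepancy is surfaced, not resolved; genome-scale validations require
supplying the published reconstruction file, which is not bundled.
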