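# Methods

## Scope and model class

`commflux` implements constraint-based (stoichiometric) analysis of
single-species metabolic models and of compartmentalized multi-species
communities. All computation reduces to linear programs over the
steady-state polytope `{v : S·v = 0, LB ≤ v ≤ UB}`; there are no kinetic,
thermodynamic (ΔG) or regulatory terms. Flux units are mmol/gDW/h
throughout. The flux of a biomass pseudo-reaction is reported as a growth
rate in h⁻¹; community-modelling literature sometimes prints growth in
mmol/gDW/h, but dimensionally the biomass flux is per-hour once the biomass
equation is normalized to one gram of dry weight, and we label it so.

## Conventions

* Stoichiometric coefficients: negative = consumed, positive = produced.
* Exchange reactions touch exactly one metabolite in an extracellular
  compartment (`e` or `e0`); negative exchange flux is uptake, positive is
  secretion (BiGG convention).
* Unconstrained bounds default to ±1000 mmol/gDW/h. "Hitting a bound" in
  cycle detection requires the bound magnitude to be ≥ 1000 so that
  deliberately user-constrained reactions are never flagged.
* Row/column order of the stoichiometric matrix is sorted by id, so flux
  vectors from different runs are directly comparable.

## LP backend and numerical choices

All LPs go through one seam (`fba._solve_lp`) backed by SciPy's HiGHS
interface with primal/dual feasibility tolerances of 1e-9. Validation
(steady-state residual, bound satisfaction, oracle agreement) uses 1e-6.
The test suite cross-checks FBA objectives and FVA ranges against GLPK
(through cobrapy) — a genuinely independent simplex implementation — on
random networks; observed disagreement is at the 1e-12 level.

FBA optima are usually degenerate. Reported flux distributions therefore
default to parsimonious FBA: the objective is pinned at its optimum and
total absolute flux Σ|v| is minimized via a forward/reverse split of each
net flux. The pin uses an absolute slack of 1e-7 (well above the solver's
feasibility tolerance) because re-solving with a width-zero box at the
reported optimum can be declared infeasible by the solver; the *reported*
objective value is the untouched FBA optimum. In FVA the near-optimality
constraint `v_obj ≥ γ·Z*` is imposed with no slack: `Z*` is read off the
returned solution vertex itself, so the constraint is feasible at that
vertex by construction. γ defaults to 1.0 ("objective held at its optimal
value"); it is a parameter because relaxed settings (e.g. 0.9) are common.

Flux-space comparison classifies a reaction as decreased/increased only
when its width changes by more than a relative tolerance of 1e-4, keeping
solver jitter out of the summary fractions. A reaction with zero reference
width but positive width in the other condition has no defined percent
change and is excluded from the fractions (flagged "undefined").

## Curation diagnostics

* **Balance**: per element, imbalance = Σ_j coeff_j · count_j; a reaction is
  balanced iff all element imbalances and the charge difference are zero.
  Any participant without a formula makes the verdict *indeterminate* —
  missing data is never treated as evidence either way. Exchange and
  biomass pseudo-reactions are exempt. A pure proton imbalance (n in H and
  the same n in charge) is repairable by shifting the H⁺ coefficient.
* **Unbound reactions / thermodynamically infeasible cycles**: all exchange
  lower bounds are closed and FVA is run without an optimality constraint;
  reactions still reaching a default big bound can only be running around
  an internal loop.
* **Dead ends**: ignoring exchange reactions, a metabolite only produced,
  only consumed, or never referenced. Metabolites that have an exchange
  reaction are skipped outright: the boundary supplies their missing role
  by construction, and without this rule every secreted extracellular
  metabolite of a perfectly functional model would be flagged. A reversible
  reaction counts as both producer and consumer (conservative).
* **Blocked reactions**: FVA range {0} under a stated media, again without
  an optimality constraint, so blockage reflects network structure rather
  than competition with the objective. The media is an explicit argument —
  blockage is only defined relative to a nutrient environment.
* Gap candidates are the dead-end metabolites adjacent to blocked
  reactions. Detection is as far as the package goes: filling gaps is a
  curation decision made against reference databases, not a solver output.

## Biomass sensitivity

Each consumed precursor of the objective reaction is scaled by (1 + δ) one
at a time (default |δ| = 0.20, the conventional ±20% integrity check;
product-side pseudo-species are skipped) and FBA is re-run from the
pristine model. When one precursor is strictly limiting, growth follows
1/(1 + δ) exactly; insensitive precursors indicate surplus supply routes.
The scan reports the full table, per-precursor growth extremes, and the
maximum |percent change| as the headline robustness number.

## Community construction

Members are merged by namespace tagging: every internal metabolite,
reaction and compartment id gets a `_tag` suffix; extracellular metabolites
are renamed into the shared compartment `e0` (id rewritten `x_e → x_e0`).
Member exchange reactions are dropped and exactly one fully open community
exchange is created per pooled metabolite. Each member's biomass reaction
additionally produces one unit of a `biomass_tag` species whose only drain
is the community biomass reaction `Σ_k a_k · biomass_k → ∅`. This makes the
abundance-weighted community growth a literal stoichiometric statement and
yields two exact contracts asserted in the tests: a community with
abundances (1, 0) grows exactly like the lone member, and scaling all a_k
by c scales the optimum by 1/c.

Two modelling consequences are worth knowing. First, abundances are used
as given (an optional flag renormalizes to sum 1). Second, the coupling is
rigid: member growth must occur in exact abundance ratio, with no dilution
term and no per-member uptake scaling — members compete freely for the
shared pool. This is the formulation's strongest assumption; a community
whose abundance ratio demands more growth from a member than its substrate
supply permits is simply infeasible above zero growth.

## Synthetic data

The generator emulates the functional roles of curated gut GEMs — a
glucose fermenter secreting acetate, an acetate consumer producing
butyrate, chains and branches of substrate→product conversions — at ≤ ~30
reactions, where optima have closed forms (growth = uptake · ATP yield /
ATP cost for a single pathway) or are checkable by the independent solver.
Stoichiometry is integer and media limits are round numbers so expected
values are analytic rather than regression snapshots. ATP is an
energy-accounting token, not a mass-balanced species; generated metabolites
carry no formulas, so balance checks return "indeterminate" rather than
false findings.

Scenario species secrete two units of byproduct per unit of growth-coupled
conversion. The factor-2 headroom exists because of the rigid abundance
coupling above: a consumer can demand up to twice its supplier's
growth-coupled output before the transfer becomes limiting, so seeded
abundance jitter (±10% around uniform) never collapses community growth to
zero. The surplus leaves through the community exchange. The default
"disease" profile rescales one species — the terminal fermenter — by 0.5,
emulating the depletion of a downstream short-chain-fatty-acid producer in
dysbiosis; the perturbed species and factor are parameters. Structure is
never random; the seed only drives abundance jitter, and a scenario is a
pure function of its arguments (byte-identical files per seed).

Broken fixtures isolate one defect each. The dead-end fixture uses an
orphan (declared, never referenced) rather than an only-produced
metabolite, because a produced-but-unconsumed species necessarily blocks
its producing reaction too and would trigger a second finding; the
only-produced/only-consumed logic is exercised by unit tests directly.

What passing on synthetic data does **not** show: behaviour on real GEMs
with thousands of reactions (solver scaling, degenerate-optimum breadth),
curation noise (wrong formulas rather than missing ones), or biological
fidelity of any particular abundance table or diet. The pipeline's numbers
on real inputs inherit all assumptions above, especially the rigid
community-biomass coupling.

## File formats

SBML Level-3 + FBC (bounds as shared parameters, one maximization
objective, gene rules as infix association text, subsystems in reaction
notes) and a JSON dialect mirroring the same content one-to-one so that
fixtures are hand-writable:

```json
{
  "id": "ToyA", "objective": "BIOMASS",
  "compartments": {"c": "cytosol", "e": "extracellular"},
  "metabolites": [{"id": "glc_c", "name": "glucose", "compartment": "c",
                    "formula": {"C": 6, "H": 12, "O": 6}, "charge": 0}],
  "reactions": [{"id": "FERM", "stoichiometry": {"glc_c": -1, "ac_c": 2},
                  "lower_bound": 0, "upper_bound": 1000,
                  "gene_rule": "", "subsystem": ""}]
}
```

Media are two-column TSVs (`exchange_id`, `max_uptake ≥ 0`, `#` comments);
applying a media sets each listed exchange's lower bound to −max_uptake and
(by default) closes every unlisted uptake, never touching secretion bounds.
Abundance tables are three-column TSVs (`species_tag`, `condition`,
`abundance`). Reports are TSVs with stable ordering; the cross-feeding
network also exports to GraphML.

## Known limitations

* No loopless FBA/FVA, flux sampling, dynamic FBA, or quadratic objectives.
* No growth-rate coupling constraints beyond the weighted objective (no
  SteadyCom-style formulation), no host compartment, no spatial structure.
* Gap detection without gap filling; no cofactor-specificity curation.
* Pairwise cross-feeding transfers are attributed proportionally to
  producer/consumer shares of the pooled metabolite; net species fluxes do
  not determine pairwise flows uniquely, so any attribution rule is a
  convention and this one is recorded in the output metadata.
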