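"""Model-refinement diagnostics for draft metabolic reconstructions.

Draft reconstructions typically carry four classes of defects that degrade
flux predictions:

* mass/charge-imbalanced reactions (wrong formulas or missing protons),
* "unbound" reactions participating in thermodynamically infeasible cycles
  (TICs) — loops that carry arbitrary flux even with every nutrient uptake
  closed, detected when unconstrained FVA drives a reaction to its default
  big bound,
* dead-end and orphan metabolites (only produced, only consumed, or never
  referenced), and
* blocked reactions whose flux range is {0} under a stated media, usually
  downstream of a network gap.

This module detects all four; it deliberately does not auto-fill gaps —
fixing a reconstruction is a curation decision, not a solver output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .fva import flux_variability
from .model import Media, MetabolicModel, Metabolite, Reaction, apply_media

__all__ = [
    "BalanceResult",
    "QCReport",
    "check_balance",
    "rebalance_protons",
    "find_unbound_reactions",
    "find_dead_end_metabolites",
    "find_blocked_reactions",
    "qc_report",
]

DEFAULT_TOL = 1e-6
DEFAULT_BIG_BOUND = 1000.0


@dataclass
class BalanceResult:
    element_imbalance: dict[str, float]
    charge_imbalance: float | None
    status: str  # balanced | imbalanced | indeterminate | exempt


@dataclass
class QCReport:
    """Aggregated curation diagnostics for one model."""

    model_id: str
    imbalanced: list[tuple[str, dict[str, float], float | None]] = field(default_factory=list)
    unbound: list[tuple[str, float]] = field(default_factory=list)
    dead_end: list[tuple[str, str]] = field(default_factory=list)
    blocked: list[str] = field(default_factory=list)
    gap_candidates: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.imbalanced or self.unbound or self.dead_end
                    or self.blocked or self.gap_candidates)

    def to_tsv(self, path: str | Path) -> None:
        """One finding per row: category, id, detail — in stable order."""
        rows = ["category\tid\tdetail"]
        for rid, elems, charge in self.imbalanced:
            detail = ",".join(f"{e}:{v:g}" for e, v in sorted(elems.items()))
            if charge:
                detail += f";charge:{charge:g}"
            rows.append(f"imbalanced\t{rid}\t{detail}")
        for rid, bound in self.unbound:
            rows.append(f"unbound\t{rid}\tattained:{bound:g}")
        for mid, reason in self.dead_end:
            rows.append(f"dead_end\t{mid}\t{reason}")
        for rid in self.blocked:
            rows.append(f"blocked\t{rid}\t")
        for mid in self.gap_candidates:
            rows.append(f"gap_candidate\t{mid}\t")
        Path(path).write_text("\n".join(rows) + "\n")


def _is_pseudo(reaction: Reaction, objective_id: str | None) -> bool:
    # biomass and exchange pseudo-reactions are not chemical conversions
    return reaction.is_exchange or reaction.id == objective_id \
        or "biomass" in reaction.id.lower()


def check_balance(
    reaction: Reaction,
    metabolites: dict[str, Metabolite],
    objective_id: str | None = None,
) -> BalanceResult:
    """Elemental and charge balance of one reaction.

    The imbalance of element e is sum_j coeff_j * count_j(e) over all
    participants (products minus reactants); a balanced conversion has every
    imbalance and the charge difference equal to zero. Any participant with
    an unknown formula makes the verdict "indeterminate" — never a guess.
    Exchange and biomass pseudo-reactions are exempt.
    """
    if _is_pseudo(reaction, objective_id):
        return BalanceResult({}, 0.0, "exempt")

    elements: dict[str, float] = {}
    charge: float | None = 0.0
    indeterminate = False
    for met_id, coeff in reaction.stoichiometry.items():
        met = metabolites[met_id]
        if not met.formula:
            indeterminate = True
            continue
        for el, n in met.formula.items():
            elements[el] = elements.get(el, 0.0) + coeff * n
        if met.charge is None:
            charge = None
        elif charge is not None:
            charge += coeff * met.charge
    elements = {e: v for e, v in elements.items() if v != 0.0}
    if indeterminate:
        return BalanceResult(elements, charge, "indeterminate")
    balanced = not elements and (charge == 0.0 or charge is None)
    return BalanceResult(elements, charge, "balanced" if balanced else "imbalanced")


def rebalance_protons(
    reaction: Reaction,
    metabolites: dict[str, Metabolite],
    proton_id: str,
) -> Reaction | None:
    """Fix a pure proton imbalance by adjusting the H+ coefficient.

    When the only imbalance is n in hydrogen and the same n in charge, the
    reaction is repaired by shifting the proton coefficient by -n (protons
    added to whichever side is short). Returns a balanced copy, the original
    (copied) if already balanced, or None when the imbalance is not
    proton-fixable. The input reaction is never modified.
    """
    if proton_id not in metabolites:
        raise KeyError(f"proton metabolite {proton_id!r} not in model")
    proton = metabolites[proton_id]
    if proton.formula != {"H": 1}:
        raise ValueError(f"{proton_id!r} does not have formula H")

    result = check_balance(reaction, metabolites)
    if result.status == "balanced":
        return reaction.copy()
    if result.status in ("indeterminate", "exempt"):
        return None
    non_h = {e: v for e, v in result.element_imbalance.items() if e != "H"}
    h = result.element_imbalance.get("H", 0.0)
    if non_h or result.charge_imbalance is None or result.charge_imbalance != h or h == 0.0:
        return None
    fixed = reaction.copy()
    fixed.stoichiometry[proton_id] = fixed.stoichiometry.get(proton_id, 0.0) - h
    if fixed.stoichiometry[proton_id] == 0.0:
        del fixed.stoichiometry[proton_id]
    return fixed


def find_unbound_reactions(
    model: MetabolicModel,
    big_bound: float = DEFAULT_BIG_BOUND,
    tol: float = DEFAULT_TOL,
) -> list[tuple[str, float]]:
    """Detect thermodynamically infeasible cycles by closed-uptake FVA.

    All exchange lower bounds are set to 0 (no nutrient can enter) and FVA
    is run with no optimality constraint. Any reaction still able to reach a
    default big bound (|bound| >= big_bound) is flagged with the bound it
    attains: with nothing coming in, the only way to carry that much flux is
    around an internal loop.
    """
    closed = model.copy()
    for rxn in closed.exchanges:
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
    ranges = flux_variability(closed, fraction_of_optimum=None)
    flagged: list[tuple[str, float]] = []
    for rid in sorted(ranges.ranges):
        rxn = closed.reactions[rid]
        lo, hi = ranges[rid]
        if abs(rxn.lower_bound) >= big_bound and lo <= rxn.lower_bound + tol * abs(rxn.lower_bound):
            flagged.append((rid, rxn.lower_bound))
        elif abs(rxn.upper_bound) >= big_bound and hi >= rxn.upper_bound - tol * abs(rxn.upper_bound):
            flagged.append((rid, rxn.upper_bound))
    return flagged


def find_dead_end_metabolites(model: MetabolicModel) -> list[tuple[str, str]]:
    """Metabolites that are only produced, only consumed, or never referenced.

    Exchange reactions are ignored (the boundary is not a pathway), and
    metabolites that have an exchange reaction are skipped outright — the
    boundary provides their missing role by construction. A reversible
    reaction (LB < 0 < UB) counts as both producer and consumer of every
    participant, which is conservative: it can only un-flag.
    """
    producers: dict[str, int] = {m: 0 for m in model.metabolites}
    consumers: dict[str, int] = {m: 0 for m in model.metabolites}
    touched: set[str] = set()
    boundary: set[str] = set()
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            boundary.update(rxn.stoichiometry)
            continue
        forward = rxn.upper_bound > 0
        backward = rxn.lower_bound < 0
        for met_id, coeff in rxn.stoichiometry.items():
            touched.add(met_id)
            produces = (coeff > 0 and forward) or (coeff < 0 and backward)
            consumes = (coeff < 0 and forward) or (coeff > 0 and backward)
            if produces:
                producers[met_id] += 1
            if consumes:
                consumers[met_id] += 1
    findings = []
    for met_id in sorted(model.metabolites):
        if met_id in boundary:
            continue
        if met_id not in touched:
            findings.append((met_id, "orphan"))
        elif producers[met_id] and not consumers[met_id]:
            findings.append((met_id, "only-produced"))
        elif consumers[met_id] and not producers[met_id]:
            findings.append((met_id, "only-consumed"))
    return findings


def find_blocked_reactions(
    model: MetabolicModel, media: Media, tol: float = DEFAULT_TOL
) -> list[str]:
    """Reactions whose FVA range is {0} under the given media.

    Run with no optimality constraint so a reaction is blocked only when the
    network structure itself — not competition with the objective — pins its
    flux to zero.
    """
    constrained = apply_media(model, media, closed_default=True)
    ranges = flux_variability(constrained, fraction_of_optimum=None)
    return sorted(
        rid for rid, (lo, hi) in ranges.ranges.items()
        if abs(lo) <= tol and abs(hi) <= tol
    )


def qc_report(model: MetabolicModel, media: Media) -> QCReport:
    """Run all diagnostics; gap candidates are dead-ends touching blocked reactions."""
    report = QCReport(model.id)
    for rid in sorted(model.reactions):
        result = check_balance(model.reactions[rid], model.metabolites,
                               model.objective_id)
        if result.status == "imbalanced":
            report.imbalanced.append((rid, result.element_imbalance,
                                      result.charge_imbalance))
    report.unbound = find_unbound_reactions(model)
    report.dead_end = find_dead_end_metabolites(model)
    report.blocked = find_blocked_reactions(model, media)
    blocked_mets = {
        met_id for rid in report.blocked
        for met_id in model.reactions[rid].stoichiometry
    }
    dead_ids = {mid for mid, _ in report.dead_end}
    report.gap_candidates = sorted(blocked_mets & dead_ids)
    return report
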