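"""Biomass-composition sensitivity: perturb precursor coefficients, re-run FBA.

The biomass reaction consumes precursor metabolites in fixed stoichiometric
coefficients d_n meant to reflect cellular composition. Because those
coefficients are measured (or borrowed), it matters how strongly the
predicted growth rate depends on each one. The scan perturbs each precursor
coefficient by +/- delta one at a time (d*_n = d_n * (1 + delta)), re-solves
FBA, and tabulates the growth change. When a single precursor is strictly
limiting, growth scales exactly as 1/(1 + delta); a robust network
re-routes flux and moves much less.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fba import optimize
from .model import MetabolicModel

__all__ = ["SensitivityResult", "SensitivityScan",
           "perturb_biomass_coefficient", "sensitivity_scan"]

DEFAULT_DELTA = 0.20


@dataclass
class SensitivityResult:
    precursor_id: str
    delta: float            # signed perturbation fraction
    coefficient: float      # perturbed (consumption-side, positive magnitude)
    growth: float           # h^-1
    pct_change: float       # vs unperturbed growth


@dataclass
class SensitivityScan:
    baseline_growth: float
    results: list[SensitivityResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.precursor_id, r.delta, r.coefficient, r.growth, r.pct_change)
             for r in self.results],
            columns=["precursor", "delta", "coefficient", "growth", "pct_change"],
        )

    def summary(self) -> pd.DataFrame:
        """Per precursor: lowest and highest growth attained over the scan."""
        df = self.to_frame()
        agg = df.groupby("precursor")["growth"].agg(["min", "max"])
        agg.columns = ["lowest_growth", "highest_growth"]
        return agg.reset_index()

    @property
    def max_abs_pct_change(self) -> float:
        return max((abs(r.pct_change) for r in self.results), default=0.0)


def perturb_biomass_coefficient(
    model: MetabolicModel, precursor_id: str, delta: float
) -> MetabolicModel:
    """Copy of *model* with one biomass-precursor coefficient scaled by (1 + delta).

    Only reactants (consumed species, negative coefficient) of the objective
    reaction qualify as precursors.
    """
    if delta <= -1.0:
        raise ValueError(f"delta must be > -1, got {delta}")
    objective = model.objective
    coeff = objective.stoichiometry.get(precursor_id)
    if coeff is None or coeff >= 0:
        raise KeyError(
            f"{precursor_id!r} is not a consumed precursor of {objective.id}"
        )
    out = model.copy()
    out.reactions[model.objective_id].stoichiometry[precursor_id] = coeff * (1.0 + delta)
    return out


def sensitivity_scan(
    model: MetabolicModel, delta_magnitude: float = DEFAULT_DELTA
) -> SensitivityScan:
    """Perturb every biomass precursor by +/- delta_magnitude, FBA each time.

    The input model is never modified; each perturbation starts from the
    pristine baseline. Raises if the baseline itself is infeasible or has
    zero growth (percent changes would be meaningless).
    """
    base = optimize(model)
    if not base.optimal:
        raise RuntimeError(f"baseline FBA is {base.status} on model {model.id}")
    if base.objective_value <= 0:
        raise RuntimeError(
            f"baseline growth is {base.objective_value}; nothing to perturb against"
        )
    precursors = sorted(
        met_id for met_id, coeff in model.objective.stoichiometry.items() if coeff < 0
    )
    results: list[SensitivityResult] = []
    for met_id in precursors:
        for delta in (+delta_magnitude, -delta_magnitude):
            perturbed = perturb_biomass_coefficient(model, met_id, delta)
            state = optimize(perturbed)
            growth = state.objective_value if state.optimal else 0.0
            results.append(SensitivityResult(
                precursor_id=met_id,
                delta=delta,
                coefficient=abs(perturbed.reactions[model.objective_id]
                                .stoichiometry[met_id]),
                growth=growth,
                pct_change=100.0 * (growth - base.objective_value) / base.objective_value,
            ))
    return SensitivityScan(base.objective_value, results)
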