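"""Flux variability analysis and condition-wise flux-space comparison.

FVA computes, for every reaction, the minimum and maximum flux it can carry
while the network stays at steady state within bounds and — when a fraction
of optimum gamma is given — while the objective flux stays at or above
gamma * Z*. The interval [min, max] is the reaction's flux space; its width
shrinks or grows between conditions (for instance healthy vs disease
abundance weightings of a community), and the fraction of reactions whose
flux space shrinks or grows is a compact signature of metabolic
reprogramming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba import _lp_arrays, _solve_lp, optimize
from .model import MetabolicModel

__all__ = [
    "FluxRange",
    "FluxSpaceComparison",
    "flux_variability",
    "compare_flux_spaces",
    "aggregate_by_subsystem",
]

#: Relative tolerance separating "decreased"/"increased" from solver jitter.
DEFAULT_REL_TOL = 1e-4


@dataclass
class FluxRange:
    """Per-reaction [min, max] flux intervals at a stated optimality fraction."""

    ranges: dict[str, tuple[float, float]]
    objective_id: str | None = None
    fraction_of_optimum: float | None = None
    objective_optimum: float | None = None

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        return self.ranges[reaction_id]

    def width(self, reaction_id: str) -> float:
        lo, hi = self.ranges[reaction_id]
        return hi - lo

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, lo, hi) for r, (lo, hi) in sorted(self.ranges.items())],
            columns=["reaction_id", "min", "max"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **context) -> "FluxRange":
        ranges = {
            str(row.reaction_id): (float(row.min), float(row.max))
            for row in frame.itertuples(index=False)
        }
        return cls(ranges, **context)


@dataclass
class FluxSpaceComparison:
    """Reaction-level change of flux-space width between two conditions."""

    table: pd.DataFrame  # reaction_id, width_a, width_b, pct_change, class
    fraction_decreased: float
    fraction_increased: float
    only_in_a: list[str] = field(default_factory=list)
    only_in_b: list[str] = field(default_factory=list)


def flux_variability(
    model: MetabolicModel,
    objective_id: str | None = None,
    fraction_of_optimum: float | None = 1.0,
    reactions: list[str] | None = None,
) -> FluxRange:
    """Min/max feasible flux per reaction, optionally at near-optimal growth.

    With ``fraction_of_optimum=None`` the objective constraint is dropped and
    the ranges describe the whole feasible flux cone under the bounds.
    """
    objective_id = objective_id or model.objective_id
    gamma = fraction_of_optimum
    if gamma is not None and not (0.0 <= gamma <= 1.0):
        raise ValueError(f"fraction_of_optimum must be in [0, 1] or None, got {gamma}")

    rxn_ids, S, lb, ub = _lp_arrays(model)
    z_opt = None
    if gamma is not None:
        base = optimize(model, objective_id, "max")
        if not base.optimal:
            raise RuntimeError(
                f"model {model.id} is {base.status}; cannot run FVA at an optimality fraction"
            )
        z_opt = base.objective_value
        j_obj = rxn_ids.index(objective_id)
        lb = lb.copy()
        # v_obj >= gamma * Z*; no slack is needed because Z* is read off the
        # solution vertex itself, so the constraint is feasible at that vertex
        lb[j_obj] = max(lb[j_obj], gamma * z_opt)

    targets = reactions if reactions is not None else rxn_ids
    index = {r: j for j, r in enumerate(rxn_ids)}
    ranges: dict[str, tuple[float, float]] = {}
    n = len(rxn_ids)
    for rid in targets:
        j = index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo_res = _solve_lp(c, S, lb, ub)
        c[j] = -1.0
        hi_res = _solve_lp(c, S, lb, ub)
        if not (lo_res.success and hi_res.success):
            raise RuntimeError(f"FVA LP failed for reaction {rid}")
        lo, hi = float(lo_res.x[j]), float(hi_res.x[j])
        if lo > hi:  # solver jitter on a fully determined flux
            lo = hi = 0.5 * (lo + hi)
        ranges[rid] = (lo, hi)
    return FluxRange(ranges, objective_id, gamma, z_opt)


def compare_flux_spaces(
    ranges_a: FluxRange,
    ranges_b: FluxRange,
    rel_tol: float = DEFAULT_REL_TOL,
) -> FluxSpaceComparison:
    """Classify every shared reaction by flux-space width change A -> B.

    Percent change is 100 * (w_B - w_A) / w_A, relative to condition A (the
    reference, e.g. healthy). A reaction with zero width in A but positive
    width in B has no defined percent change and is classed "undefined";
    undefined reactions are excluded from the summary fractions.
    """
    ids_a, ids_b = set(ranges_a.ranges), set(ranges_b.ranges)
    shared = sorted(ids_a & ids_b)
    if not shared:
        raise ValueError("flux ranges have no reactions in common")

    rows = []
    n_dec = n_inc = n_classified = 0
    for rid in shared:
        w_a, w_b = ranges_a.width(rid), ranges_b.width(rid)
        if w_a == 0.0:
            if w_b == 0.0:
                cls, pct = "unchanged", 0.0
                n_classified += 1
            else:
                cls, pct = "undefined", float("nan")
        else:
            pct = 100.0 * (w_b - w_a) / w_a
            if w_b < w_a * (1.0 - rel_tol):
                cls = "decreased"
                n_dec += 1
            elif w_b > w_a * (1.0 + rel_tol):
                cls = "increased"
                n_inc += 1
            else:
                cls = "unchanged"
            n_classified += 1
        rows.append((rid, w_a, w_b, pct, cls))

    table = pd.DataFrame(
        rows, columns=["reaction_id", "width_a", "width_b", "pct_change", "class"]
    )
    frac_dec = n_dec / n_classified if n_classified else 0.0
    frac_inc = n_inc / n_classified if n_classified else 0.0
    return FluxSpaceComparison(
        table, frac_dec, frac_inc,
        only_in_a=sorted(ids_a - ids_b), only_in_b=sorted(ids_b - ids_a),
    )


def aggregate_by_subsystem(
    comparison: FluxSpaceComparison, model: MetabolicModel
) -> pd.DataFrame:
    """Pathway-level view: mean percent change and class counts per subsystem.

    Reactions without a subsystem label fall into "unassigned". Subsystems
    whose reactions are all "undefined" report a NaN mean.
    """
    sub = {
        rid: (model.reactions[rid].subsystem or "unassigned")
        if rid in model.reactions else "unassigned"
        for rid in comparison.table["reaction_id"]
    }
    df = comparison.table.copy()
    df["subsystem"] = df["reaction_id"].map(sub)
    out = []
    for name, group in df.groupby("subsystem", sort=True):
        defined = group["pct_change"].dropna()
        counts = group["class"].value_counts()
        out.append({
            "subsystem": name,
            "n_reactions": len(group),
            "mean_pct_change": float(defined.mean()) if len(defined) else float("nan"),
            "n_decreased": int(counts.get("decreased", 0)),
            "n_increased": int(counts.get("increased", 0)),
            "n_unchanged": int(counts.get("unchanged", 0)),
            "n_undefined": int(counts.get("undefined", 0)),
        })
    return pd.DataFrame(out)
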