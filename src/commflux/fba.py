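"""Flux balance analysis: linear programming over the stoichiometric network.

FBA maximizes (or minimizes) the flux of one objective reaction subject to
steady-state mass balance S.v = 0 and per-reaction bounds LB <= v <= UB.
The optimum Z of a biomass objective is the specific growth rate.

Because an FBA optimum is usually degenerate (many flux vectors attain the
same Z), :func:`parsimonious_fluxes` re-solves with the objective pinned at
its optimum while minimizing total absolute flux, which makes the reported
flux distribution well-defined up to any remaining degeneracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .model import MetabolicModel, stoichiometric_matrix

__all__ = ["FluxState", "optimize", "parsimonious_fluxes",
           "FEASIBILITY_TOL", "VALIDATION_TOL"]

#: Tolerance passed to the LP solver for primal feasibility.
FEASIBILITY_TOL = 1e-9
#: Tolerance used when validating S.v = 0 and bound satisfaction afterwards.
VALIDATION_TOL = 1e-6


@dataclass
class FluxState:
    """One FBA solution: objective value Z plus a flux per reaction."""

    objective_id: str
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    status: str = "optimal"  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def _solve_lp(c, S, lb, ub):
    """Single seam to the LP backend: minimize c.v s.t. S.v = 0, lb <= v <= ub."""
    res = scipy.optimize.linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )
    return res


def _lp_arrays(model: MetabolicModel):
    rxn_ids = model.reaction_ids()
    S = stoichiometric_matrix(model)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    return rxn_ids, S, lb, ub


def optimize(
    model: MetabolicModel,
    objective_id: str | None = None,
    direction: str = "max",
) -> FluxState:
    """Solve the FBA linear program and return one optimal flux vertex.

    Parameters
    ----------
    model:
        A validated metabolic model.
    objective_id:
        Reaction whose flux to optimize; defaults to the model's objective.
    direction:
        "max" (default) or "min".
    """
    objective_id = objective_id or model.objective_id
    if objective_id not in model.reactions:
        raise KeyError(f"objective reaction {objective_id!r} not in model {model.id}")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")

    rxn_ids, S, lb, ub = _lp_arrays(model)
    sign = -1.0 if direction == "max" else 1.0
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = sign

    res = _solve_lp(c, S, lb, ub)
    if res.status == 2:
        return FluxState(objective_id, float("nan"), {}, "infeasible")
    if res.status == 3:
        return FluxState(objective_id, sign * -float("inf"), {}, "unbounded")
    if not res.success:
        raise RuntimeError(f"LP solver failed on model {model.id}: {res.message}")
    fluxes = dict(zip(rxn_ids, (float(v) for v in res.x)))
    return FluxState(objective_id, fluxes[objective_id], fluxes, "optimal")


def parsimonious_fluxes(
    model: MetabolicModel, objective_id: str | None = None, tol: float = 1e-9
) -> FluxState:
    """FBA followed by total-flux minimization at the fixed optimum (pFBA).

    The objective flux is constrained to its FBA optimum (within *tol*), then
    sum(|v_j|) is minimized by splitting each net flux into forward and
    reverse non-negative parts. The objective value is unchanged; the flux
    vector is unique up to any degeneracy that survives the minimization.
    """
    objective_id = objective_id or model.objective_id
    base = optimize(model, objective_id, "max")
    if not base.optimal:
        return base

    rxn_ids, S, lb, ub = _lp_arrays(model)
    j_obj = rxn_ids.index(objective_id)
    z = base.objective_value
    # pin slack well above the solver's feasibility tolerance, else re-solving
    # at the reported (slightly inexact) optimum can come back infeasible
    slack = max(1e-7, abs(z) * tol)
    lb = lb.copy()
    ub = ub.copy()
    lb[j_obj] = z - slack
    ub[j_obj] = z + slack

    # v = p - n with p, n >= 0; minimize sum(p + n)
    n_rxn = len(rxn_ids)
    S2 = sp.hstack([S, -S]).tocsr()
    lb2 = np.concatenate([np.maximum(lb, 0.0), np.maximum(-ub, 0.0)])
    ub2 = np.concatenate([np.maximum(ub, 0.0), np.maximum(-lb, 0.0)])
    c2 = np.ones(2 * n_rxn)

    res = _solve_lp(c2, S2, lb2, ub2)
    if not res.success:
        raise RuntimeError(
            f"pFBA minimization failed on model {model.id}: {res.message}"
        )
    v = res.x[:n_rxn] - res.x[n_rxn:]
    fluxes = dict(zip(rxn_ids, (float(x) for x in v)))
    return FluxState(objective_id, z, fluxes, "optimal")


def steady_state_residual(model: MetabolicModel, state: FluxState) -> float:
    """max_i |sum_j S_ij v_j| — the mass-balance residual of a solution."""
    rxn_ids, S, _, _ = _lp_arrays(model)
    v = np.array([state.fluxes[r] for r in rxn_ids])
    return float(np.abs(S @ v).max()) if len(v) else 0.0
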