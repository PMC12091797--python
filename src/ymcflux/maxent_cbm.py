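"""Transcriptome-conditioned maximum-entropy flux inference.

Given the flux polytope P = {v >= 0 | Sv = 0, LB <= v <= UB} on the split
(all-nonnegative) network and expression weights g, the inferred fluxome is

    argmax_v  Hg(v) = - sum_i (v_i/V) log( (v_i/V) / (g_i/G) ),

with V = sum_j v_j and G = sum_j g_j, i.e. the flux vector whose fraction
distribution is closest in Kullback-Leibler divergence to the expression
distribution.  The objective depends only on flux fractions; absolute scale
is pinned by fixing the biomass flux to the observed growth rate and by the
physiology ratio constraint

    v_mu - (w_mu / w_o2) * v_o2 = 0,

where v_o2 is the uptake-direction (reverse) component of the oxygen
exchange reaction, so that v_o2 equals the measured uptake magnitude w_o2.

The program is solved with an interior trust-region method (scipy
``trust-constr``) with an analytic gradient:

    d KL / d v_k = (1/V) [ log(p_k / q_k) - KL ],   p = v/V, q = g/G.

Infeasibility is diagnosed by staged linear-program relaxation: first the
stoichiometric polytope alone, then with the physiology constraints added.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, linprog, minimize

from .model_io import ExpressionWeights, IrreversibleNetwork

__all__ = [
    "PhysiologyConstraint",
    "FluxProblem",
    "FluxSolution",
    "InfeasibleProblemError",
    "SolverError",
    "objective_value",
    "solve_maxent",
    "solve_series",
]


class InfeasibleProblemError(RuntimeError):
    """The flux polytope (or its physiology-constrained section) is empty."""


class SolverError(RuntimeError):
    """The optimizer failed to converge to the stated tolerances."""


@dataclass(frozen=True)
class PhysiologyConstraint:
    """Observed growth rate w_mu (1/h) and O2 uptake magnitude w_o2
    (mmol/gDW/h); with ``fix_growth`` the biomass flux is pinned to w_mu."""

    w_mu: float
    w_o2: float
    fix_growth: bool = True

    def __post_init__(self) -> None:
        if self.w_mu <= 0 or self.w_o2 <= 0:
            raise ValueError("w_mu and w_o2 must be strictly positive")


@dataclass
class FluxProblem:
    irr: IrreversibleNetwork
    weights: ExpressionWeights
    physiology: Optional[PhysiologyConstraint] = None
    feasibility_tol: float = 1e-9
    optimality_tol: float = 1e-8
    flux_floor: float = 1e-10

    def __post_init__(self) -> None:
        if len(self.weights.g) != self.irr.n_components:
            raise ValueError("weights length must equal the component count")


@dataclass
class FluxSolution:
    v: np.ndarray
    component_ids: List[str]
    objective_value: float  # Hg(v), in nats, <= 0
    net_fluxes: Dict[str, float]
    max_sv_residual: float
    status: str
    n_iterations: int
    diagnostics: Dict[str, float] = field(default_factory=dict)


def objective_value(v: np.ndarray, g: np.ndarray, floor: float = 0.0) -> float:
    """Hg(v) = -KL(v/sum(v) || g/sum(g)) in nats, with 0 log 0 = 0."""
    v = np.asarray(v, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(v < -1e-12):
        raise ValueError("fluxes must be nonnegative")
    if np.any(g <= 0):
        raise ValueError("weights must be strictly positive")
    total = v.sum()
    if total <= 0:
        raise ValueError("total flux is zero; fractions undefined")
    p = np.clip(v, 0.0, None) / total
    q = g / g.sum()
    mask = p > max(floor, 0.0)
    kl = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    return -kl


def _kl_and_grad(v: np.ndarray, q: np.ndarray, floor: float):
    total = v.sum()
    p = v / total
    pf = np.maximum(p, floor)
    logratio = np.log(pf / q)
    kl = float(np.sum(p * logratio))
    grad = (logratio - kl) / total
    return kl, grad


def _stage_feasible(A_eq, b_eq, lb, ub) -> bool:
    res = linprog(
        c=np.zeros(len(lb)),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res.status == 0


def _physiology_rows(problem: FluxProblem):
    """Equality rows for v_mu - (w_mu/w_o2) v_o2 = 0 (+ fixed growth)."""
    irr, phys = problem.irr, problem.physiology
    net = irr.parent
    if net.biomass_reaction_id is None or net.oxygen_exchange_id is None:
        raise ValueError(
            "physiology constraint requires biomass_reaction_id and "
            "oxygen_exchange_id on the network"
        )
    cidx = irr.component_index
    i_mu = cidx[net.biomass_reaction_id]
    # uptake magnitude = the consuming (reverse) component of the exchange
    rev_id = net.oxygen_exchange_id + "__rev"
    if rev_id not in cidx:
        raise ValueError(
            f"oxygen exchange {net.oxygen_exchange_id!r} has no uptake "
            "(reverse) component; its lower bound is nonnegative"
        )
    i_o2 = cidx[rev_id]
    row = np.zeros(irr.n_components)
    row[i_mu] = 1.0
    row[i_o2] = -phys.w_mu / phys.w_o2
    return row, i_mu, i_o2


def solve_maxent(problem: FluxProblem, x0: Optional[np.ndarray] = None) -> FluxSolution:
    """Solve the maximum-entropy flux program for one time point.

    Returns the unique maximizer of the strictly convex objective over the
    (physiology-constrained) polytope.  Deterministic: the default initial
    point is the expression vector scaled into the bounds.
    """
    irr = problem.irr
    S = irr.S
    K = irr.n_components
    lb = irr.lb.copy()
    ub = irr.ub.copy()
    if np.any(lb > ub):
        bad = [irr.component_ids[i] for i in np.nonzero(lb > ub)[0]]
        raise InfeasibleProblemError(f"LB > UB on components {bad}")
    g = problem.weights.g
    q = g / g.sum()

    # stage 1: stoichiometry + bounds
    if not _stage_feasible(S, np.zeros(S.shape[0]), lb, ub):
        raise InfeasibleProblemError(
            "stoichiometric constraints (Sv=0 with bounds) are infeasible"
        )

    A_rows = [S]
    b_rows = [np.zeros(S.shape[0])]
    if problem.physiology is not None:
        row, i_mu, _ = _physiology_rows(problem)
        A_rows.append(row[np.newaxis, :])
        b_rows.append(np.zeros(1))
        if problem.physiology.fix_growth:
            lb[i_mu] = ub[i_mu] = problem.physiology.w_mu
        if not _stage_feasible(np.vstack(A_rows), np.concatenate(b_rows), lb, ub):
            raise InfeasibleProblemError(
                "physiological constraints (growth/oxygen ratio with fixed "
                "growth) are infeasible on the stoichiometric polytope"
            )
    A_eq = np.vstack(A_rows)
    b_eq = np.concatenate(b_rows)

    if x0 is None:
        mid = 0.5 * (lb + np.minimum(ub, np.quantile(ub, 0.5) + 1.0))
        scale = float(np.mean(mid)) / float(np.mean(g))
        x0 = np.clip(scale * g, lb, ub)
    x0 = np.clip(np.asarray(x0, dtype=float), lb, ub)

    floor = problem.flux_floor

    def fun(v):
        kl, _ = _kl_and_grad(np.maximum(v, 0.0) + floor, q, floor)
        return kl

    def grad(v):
        _, gr = _kl_and_grad(np.maximum(v, 0.0) + floor, q, floor)
        return gr

    res = minimize(
        fun,
        x0,
        jac=grad,
        method="trust-constr",
        bounds=list(zip(lb, ub)),
        constraints=[LinearConstraint(A_eq, b_eq, b_eq)],
        options={
            "gtol": problem.optimality_tol,
            "xtol": 1e-12,
            "maxiter": 3000,
            "verbose": 0,
        },
    )
    v = np.clip(res.x, lb, ub)
    # polish: minimum-norm projection onto the equality constraints (the
    # correction is within the optimizer's tolerance, so bounds stay intact)
    defect = A_eq @ v - b_eq
    if np.any(defect):
        correction, *_ = np.linalg.lstsq(A_eq, defect, rcond=None)
        v = np.clip(v - correction, lb, ub)
    residual = float(np.max(np.abs(A_eq @ v - b_eq))) if A_eq.size else 0.0
    if residual > max(1e-6, problem.feasibility_tol * 1e3):
        raise SolverError(
            f"solver returned an infeasible point (max residual {residual:.2e}, "
            f"status {res.status})"
        )
    if not res.success and res.status not in (1, 2):
        raise SolverError(f"optimizer did not converge: {res.message}")

    v_report = v.copy()
    v_report[v_report < floor] = 0.0
    return FluxSolution(
        v=v_report,
        component_ids=list(irr.component_ids),
        objective_value=objective_value(np.maximum(v, floor), g),
        net_fluxes=irr.net_fluxes(v_report),
        max_sv_residual=float(np.max(np.abs(S @ v))),
        status="optimal",
        n_iterations=int(res.niter),
        diagnostics={"kl": float(res.fun), "constraint_residual": residual},
    )


def solve_series(problems: Sequence[FluxProblem]) -> List[FluxSolution]:
    """Solve one problem per time point (shared network), in order."""
    if not problems:
        return []
    net0 = problems[0].irr.parent
    if any(p.irr.parent is not net0 for p in problems[1:]):
        raise ValueError("all problems in a series must share one network")
    solutions = []
    for t, prob in enumerate(problems):
        try:
            solutions.append(solve_maxent(prob))
        except (InfeasibleProblemError, SolverError) as exc:
            raise type(exc)(f"time point {t}: {exc}") from exc
    return solutions
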