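"""Flux balance analysis and parsimonious refinement.

FBA maximizes the biomass objective c·v subject to the steady-state
constraint S·v = 0 and flux bounds lb ≤ v ≤ ub (linear program, solved with
HiGHS through :func:`scipy.optimize.linprog`).  Because the FBA optimum is
generally degenerate, per-replicate point estimates come from parsimonious
FBA (pFBA): biomass is pinned at the FBA optimum and total absolute flux
Σ|v| is minimized via the standard flux-splitting reformulation, yielding a
unique, deterministic flux vector suitable for downstream per-reaction
statistics.

``replicate_flux_matrix`` runs the full model-construction chain
(medium → thermodynamic directions → per-replicate capacity bounds) and
collects one pFBA flux vector per expression replicate into a
condition-labeled matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .constraints import (
    ConstraintConfig,
    ExpressionProfile,
    MediumTable,
    apply_medium,
    attach_annotations,
    capacity_bounds,
    thermodynamic_directions,
)
from .network import MetabolicNetwork, stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "solve_fba",
    "solve_pfba",
    "replicate_flux_matrix",
    "write_flux_matrix",
    "read_flux_matrix",
]

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-7

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


@dataclass(frozen=True)
class FluxSolution:
    """Outcome of one LP solve: status, objective value, flux vector."""

    status: str
    objective_value: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _lp_arrays(network: MetabolicNetwork):
    sm = stoichiometric_matrix(network)
    lb = np.array([r.lower_bound for r in network.reactions])
    ub = np.array([r.upper_bound for r in network.reactions])
    c = np.zeros(len(network.reactions))
    c[list(network.reaction_ids).index(network.objective_id)] = 1.0
    return sm, lb, ub, c


_HIGHS_OPTS = {"presolve": True, "primal_feasibility_tolerance": FEASIBILITY_TOL * 10,
               "dual_feasibility_tolerance": OPTIMALITY_TOL}


def solve_fba(network: MetabolicNetwork) -> FluxSolution:
    """Maximize the biomass objective over the flux polytope.

    An empty-interior bound pair (lb > ub) yields ``infeasible`` status, not
    an exception.
    """
    sm, lb, ub, c = _lp_arrays(network)
    rids = list(sm.col_ids)
    if np.any(lb > ub):
        return FluxSolution("infeasible", float("nan"), {})
    res = linprog(
        -c,
        A_eq=sp.csr_matrix(sm.S),
        b_eq=np.zeros(sm.S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_HIGHS_OPTS,
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FluxSolution(status, float("nan"), {})
    v = np.asarray(res.x)
    return FluxSolution("optimal", float(c @ v), dict(zip(rids, v.tolist())))


def solve_pfba(
    network: MetabolicNetwork, optimality_fraction: float = 1.0
) -> FluxSolution:
    """Parsimonious FBA: minimal total |v| at (a fraction of) the FBA optimum.

    The flux vector is split v = p − n with p, n ≥ 0 and Σ(p + n) is
    minimized subject to S·v = 0, the original bounds, and
    c·v ≥ optimality_fraction × FBA optimum (within 1e−9); the reported
    objective_value is the biomass actually attained.
    """
    if not 0 < optimality_fraction <= 1:
        raise ValueError(f"optimality_fraction must be in (0, 1], got {optimality_fraction}")
    base = solve_fba(network)
    if not base.optimal:
        return base
    target = optimality_fraction * base.objective_value

    sm, lb, ub, c = _lp_arrays(network)
    n_rxn = sm.S.shape[1]
    rids = list(sm.col_ids)
    # variables x = [p, n], v = p - n
    p_ub = np.maximum(ub, 0.0)
    n_ub = np.maximum(-lb, 0.0)
    bounds = np.column_stack(
        [np.zeros(2 * n_rxn), np.concatenate([p_ub, n_ub])]
    )
    A_eq = sp.hstack([sm.S, -sm.S], format="csr")
    b_eq = np.zeros(sm.S.shape[0])
    # inequality rows: biomass floor, plus per-reaction rows where the
    # original interval excludes zero (strictly positive lb / negative ub)
    rows = [np.concatenate([-c, c])]
    rhs = [-(target - FEASIBILITY_TOL)]
    for i in range(n_rxn):
        unit = np.zeros(2 * n_rxn)
        if lb[i] > 0:
            unit[i], unit[n_rxn + i] = -1.0, 1.0  # -(p - n) <= -lb
            rows.append(unit)
            rhs.append(-lb[i])
        elif ub[i] < 0:
            unit[i], unit[n_rxn + i] = 1.0, -1.0  # p - n <= ub
            rows.append(unit)
            rhs.append(ub[i])
    res = linprog(
        np.ones(2 * n_rxn),
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options=_HIGHS_OPTS,
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FluxSolution(status, float("nan"), {})
    x = np.asarray(res.x)
    v = x[:n_rxn] - x[n_rxn:]
    return FluxSolution("optimal", float(c @ v), dict(zip(rids, v.tolist())))


def replicate_flux_matrix(
    network: MetabolicNetwork,
    profiles: list[ExpressionProfile],
    medium: MediumTable,
    config: ConstraintConfig = ConstraintConfig(),
    kcat: dict[str, float] | None = None,
    delta_g_prime: dict[str, float] | None = None,
    optimality_fraction: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """One pFBA flux vector per expression replicate, as a labeled matrix.

    Returns ``(matrix, report)``: the matrix has reaction ids as rows and a
    ``(condition, replicate)`` MultiIndex on columns, ordered condition-major
    in input order; the report records per-replicate solver status and
    objective, and lists any non-optimal replicates (excluded from the
    matrix).
    """
    if kcat or delta_g_prime:
        network = attach_annotations(network, kcat=kcat, delta_g_prime=delta_g_prime)
    base = thermodynamic_directions(apply_medium(network, medium, config), config)

    conditions: list[str] = []
    for p in profiles:
        if p.condition not in conditions:
            conditions.append(p.condition)
    ordered = [p for cond in conditions for p in profiles if p.condition == cond]

    columns: dict[tuple[str, str], list[float]] = {}
    report: dict = {"replicates": {}, "excluded": []}
    rids = network.reaction_ids
    for p in ordered:
        label = (p.condition, p.replicate)
        if label in columns:
            raise ValueError(f"duplicate replicate label {label}")
        model = capacity_bounds(base, p, config)
        sol = solve_pfba(model, optimality_fraction)
        report["replicates"][f"{p.condition}:{p.replicate}"] = {
            "status": sol.status,
            "objective_value": None if not sol.optimal else sol.objective_value,
        }
        if sol.optimal:
            columns[label] = [sol.fluxes[rid] for rid in rids]
        else:
            report["excluded"].append(f"{p.condition}:{p.replicate}")
    matrix = pd.DataFrame(
        columns, index=pd.Index(rids, name="reaction_id"),
    )
    matrix.columns = pd.MultiIndex.from_tuples(
        matrix.columns, names=["condition", "replicate"]
    )
    return matrix, report


def write_flux_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write the flux matrix as TSV with ``condition:replicate`` headers."""
    flat = matrix.copy()
    flat.columns = [f"{c}:{r}" for c, r in matrix.columns]
    flat.to_csv(path, sep="\t", index=True)


def read_flux_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="reaction_id")
    df.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split(":", 1)) for c in df.columns], names=["condition", "replicate"]
    )
    return df


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=1) + "\n")
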