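"""Constraint-based analyses: FBA, FVA, doubling time, function tasks.

Flux balance analysis (FBA) solves

    max  c·v   s.t.  S·v = 0,  lb <= v <= ub

where S is the stoichiometric matrix and c selects the objective
(typically biomass).  The optimum is unique; the flux vector generally is
not.  Because every downstream comparison in this package depends on the
particular flux vector, a deterministic variant is provided that returns
the minimum-L1-norm vector among the optima (a secondary LP at the fixed
optimum) — the parsimonious choice used throughout the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

from .lp import OPTIMAL, solve_lp
from .model import MetabolicModel

__all__ = [
    "FluxDistribution",
    "FVAResult",
    "FunctionTask",
    "TaskResult",
    "fba",
    "fva",
    "doubling_time",
    "run_function_task",
    "FLUX_EPS",
]

#: fluxes with |v| below this are treated as zero throughout the pipeline
FLUX_EPS = 1e-6

# relative slack when pinning the objective at its optimum in secondary LPs
_PIN_TOL = 1e-9


@dataclass(frozen=True)
class FluxDistribution:
    """One LP solution: reaction id -> flux, plus objective value and status."""

    fluxes: Dict[str, float]
    objective_value: Optional[float]
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass(frozen=True)
class FVAResult:
    ranges: Dict[str, Tuple[float, float]]
    optimality_fraction: float

    def __getitem__(self, rxn_id: str) -> Tuple[float, float]:
        return self.ranges[rxn_id]


def _objective_vector(model: MetabolicModel, objective: Optional[str]) -> Tuple[np.ndarray, str]:
    obj_id = objective or model.objective_reaction_id
    if obj_id is None:
        raise ValueError(f"model {model.id!r} has no objective reaction and none was given")
    c = np.zeros(len(model.reactions))
    c[model.reaction_index(obj_id)] = 1.0
    return c, obj_id


def fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
    minimize_l1: bool = False,
) -> FluxDistribution:
    """Flux balance analysis.

    With ``minimize_l1=True`` the objective is first optimised, then the
    total flux Σ|v| is minimised at the pinned optimum, giving a unique,
    solver-order-independent flux vector.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    c, _ = _objective_vector(model, objective)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    n = len(model.reactions)
    bounds = list(zip(lb, ub))
    res = solve_lp(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, maximize=(sense == "max"))
    if res.status != OPTIMAL:
        return FluxDistribution({}, None, res.status)
    opt = res.objective
    if not minimize_l1:
        fluxes = {r.id: float(res.x[j]) for j, r in enumerate(model.reactions)}
        return FluxDistribution(fluxes, float(opt), OPTIMAL)

    # secondary LP: min Σ t_i with t_i >= ±v_i, objective pinned at opt
    slack = _PIN_TOL * max(1.0, abs(opt))
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([S, np.zeros((S.shape[0], n))])
    # t >= v  and  t >= -v   <=>   v - t <= 0  and  -v - t <= 0
    I = np.eye(n)
    A_ub = np.vstack(
        [
            np.hstack([I, -I]),
            np.hstack([-I, -I]),
        ]
    )
    b_ub = np.zeros(2 * n)
    # pin the objective: c·v >= opt - slack (max) or c·v <= opt + slack (min)
    if sense == "max":
        A_ub = np.vstack([A_ub, np.hstack([-c, np.zeros(n)])])
        b_ub = np.append(b_ub, -(opt - slack))
    else:
        A_ub = np.vstack([A_ub, np.hstack([c, np.zeros(n)])])
        b_ub = np.append(b_ub, opt + slack)
    big = max(np.max(np.abs(lb)), np.max(np.abs(ub)), 1.0)
    bounds2 = bounds + [(0.0, big)] * n
    res2 = solve_lp(c2, A_eq=A_eq, b_eq=np.zeros(S.shape[0]), A_ub=A_ub, b_ub=b_ub, bounds=bounds2)
    if res2.status != OPTIMAL:  # pragma: no cover - pinned problem is feasible by construction
        return FluxDistribution({}, None, res2.status)
    v = res2.x[:n]
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    return FluxDistribution(fluxes, float(opt), OPTIMAL)


def fva(
    model: MetabolicModel,
    optimality_fraction: float = 0.9,
    reactions: Optional[Iterable[str]] = None,
    objective: Optional[str] = None,
) -> FVAResult:
    """Flux variability analysis.

    For each reaction, minimise and maximise its flux subject to the
    objective retaining at least ``optimality_fraction`` of the FBA
    optimum (fraction 0 releases the objective entirely, the setting used
    for blocked-reaction detection).
    """
    if not 0 <= optimality_fraction <= 1:
        raise ValueError("optimality_fraction must be in [0, 1]")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    bounds = list(zip(lb, ub))
    b_eq = np.zeros(S.shape[0])
    A_ub = None
    b_ub = None
    if optimality_fraction > 0:
        c, _ = _objective_vector(model, objective)
        base = solve_lp(c, A_eq=S, b_eq=b_eq, bounds=bounds, maximize=True)
        if base.status != OPTIMAL:
            raise RuntimeError(f"base FBA not optimal (status {base.status}); cannot run FVA")
        floor = optimality_fraction * base.objective
        A_ub = -c.reshape(1, -1)
        b_ub = np.array([-floor + _PIN_TOL * max(1.0, abs(floor))])

    ids = [r.id for r in model.reactions] if reactions is None else list(reactions)
    ranges: Dict[str, Tuple[float, float]] = {}
    n = len(model.reactions)
    for rxn_id in ids:
        cj = np.zeros(n)
        cj[model.reaction_index(rxn_id)] = 1.0
        lo = solve_lp(cj, A_eq=S, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds, maximize=False)
        hi = solve_lp(cj, A_eq=S, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds, maximize=True)
        if lo.status != OPTIMAL or hi.status != OPTIMAL:
            raise RuntimeError(f"FVA subproblem for {rxn_id} not optimal")
        vmin, vmax = float(lo.objective), float(hi.objective)
        ranges[rxn_id] = (min(vmin, vmax), max(vmin, vmax))
    return FVAResult(ranges, optimality_fraction)


def doubling_time(mu: float) -> float:
    """Doubling time in hours from a growth rate mu (h⁻¹): ln(2)/mu."""
    if mu <= 0:
        raise ValueError(f"growth rate must be positive, got {mu}")
    return math.log(2.0) / mu


# ---------------------------------------------------------------------------
# Liver-function feasibility tasks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FunctionTask:
    """A metabolic capability test: force some exchange bounds, then check
    the model can push at least ``min_target_flux`` through a target
    reaction (e.g. lactate in -> glucose out for gluconeogenesis)."""

    name: str
    forced_exchanges: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    target_reaction: str = ""
    min_target_flux: float = FLUX_EPS


@dataclass(frozen=True)
class TaskResult:
    name: str
    passed: bool
    achieved_flux: Optional[float]
    status: str


def run_function_task(model: MetabolicModel, task: FunctionTask) -> TaskResult:
    """Run one feasibility task; the input model is never mutated."""
    for rxn_id in list(task.forced_exchanges) + [task.target_reaction]:
        if not model.has_reaction(rxn_id):
            raise ValueError(f"task {task.name!r}: unknown reaction {rxn_id!r}")
    constrained = model.with_bounds(dict(task.forced_exchanges))
    sol = fba(constrained, objective=task.target_reaction, sense="max")
    if not sol.optimal:
        return TaskResult(task.name, False, None, sol.status)
    achieved = sol.objective_value
    return TaskResult(task.name, achieved >= task.min_target_flux, achieved, sol.status)
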