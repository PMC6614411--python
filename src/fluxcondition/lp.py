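"""Thin linear-programming layer over scipy's HiGHS interface.

All constraint-based computations in the package funnel through
:func:`solve_lp` so that solver options (tolerances, determinism) are set
in one place.  HiGHS with fixed options is deterministic for a fixed
problem, which the pipeline relies on for byte-reproducible outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

__all__ = ["LPResult", "solve_lp", "OPTIMAL", "INFEASIBLE", "UNBOUNDED"]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

# feasibility / optimality tolerances used for every solve
FEAS_TOL = 1e-9
OPT_TOL = 1e-9


@dataclass(frozen=True)
class LPResult:
    status: str
    x: Optional[np.ndarray]
    objective: Optional[float]


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[np.ndarray] = None,
    b_eq: Optional[np.ndarray] = None,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    maximize: bool = False,
) -> LPResult:
    """Solve min (or max) c·x subject to A_eq x = b_eq, A_ub x <= b_ub, bounds."""
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": FEAS_TOL,
            "dual_feasibility_tolerance": OPT_TOL,
        },
    )
    if res.status == 0:
        return LPResult(OPTIMAL, res.x, sign * res.fun)
    if res.status == 2:
        return LPResult(INFEASIBLE, None, None)
    if res.status == 3:
        return LPResult(UNBOUNDED, None, None)
    raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")
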