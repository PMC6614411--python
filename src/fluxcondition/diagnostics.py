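"""Structural network diagnostics that need an LP: blocked reactions and
gap filling.

A reaction is *blocked* when no feasible steady state can carry flux
through it in either direction; blocked reactions and their companion
dead-end metabolites are the usual symptoms of missing reactions in a
draft reconstruction, which gap filling repairs by importing a
minimal-cardinality set of reactions from a universal reaction database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .analysis import FLUX_EPS, fva
from .model import MetabolicModel, Reaction

__all__ = ["find_blocked_reactions", "gap_fill", "GapFillResult"]

logger = logging.getLogger(__name__)


def find_blocked_reactions(model: MetabolicModel, eps: float = FLUX_EPS) -> List[str]:
    """Reactions whose flux range is [0, 0] (within eps) in every steady
    state, with the objective constraint fully released (FVA at
    optimality fraction 0)."""
    result = fva(model, optimality_fraction=0.0)
    blocked = [
        rxn_id
        for rxn_id, (lo, hi) in result.ranges.items()
        if max(abs(lo), abs(hi)) < eps
    ]
    return sorted(blocked)


@dataclass(frozen=True)
class GapFillResult:
    added: List[str]
    unfillable: List[str]

    @property
    def complete(self) -> bool:
        return not self.unfillable


def gap_fill(
    model: MetabolicModel,
    universal: MetabolicModel,
    targets: Sequence[str],
    eps: float = FLUX_EPS,
) -> GapFillResult:
    """Minimal set of universal reactions whose addition unblocks every target.

    Solved as one MILP with a binary indicator per candidate reaction and
    an independent flux vector per target, each forced to carry at least
    ``eps`` flux through its target; the indicators are shared, so the
    optimum is the smallest set unblocking all targets simultaneously.
    Ties in cardinality are broken lexicographically by reaction id via a
    tiny secondary weight.  Targets that stay blocked even with the whole
    universal database added are reported as unfillable and excluded from
    the MILP.
    """
    candidates = [r for r in universal.reactions if not model.has_reaction(r.id)]
    candidates.sort(key=lambda r: r.id)
    augmented = model.with_reactions_added(candidates)

    fillable: List[str] = []
    unfillable: List[str] = []
    relaxed = find_blocked_reactions(augmented, eps=eps)
    still_blocked = set(relaxed)
    already_ok = set(find_blocked_reactions(model, eps=eps))
    for t in targets:
        if not model.has_reaction(t):
            raise ValueError(f"gap_fill target {t!r} not in model")
        if t not in already_ok:
            # target already carries flux; nothing to do for it
            continue
        if t in still_blocked:
            unfillable.append(t)
        else:
            fillable.append(t)
    if not fillable:
        return GapFillResult([], sorted(unfillable))

    added = _gapfill_milp(augmented, len(model.reactions), candidates, fillable, eps)
    return GapFillResult(added, sorted(unfillable))


def _gapfill_milp(
    augmented: MetabolicModel,
    n_base: int,
    candidates: List[Reaction],
    targets: List[str],
    eps: float,
) -> List[str]:
    S = sp.csr_matrix(augmented.stoichiometric_matrix())
    lb, ub = augmented.bounds()
    n = len(augmented.reactions)
    u = len(candidates)
    T = len(targets)
    # variable layout: [v^t for each target t] then [y]
    n_var = T * n + u
    cost = np.zeros(n_var)
    # cardinality + tiny lexicographic tie-break (earlier ids preferred)
    tie = 1e-6 / max(u, 1)
    cost[T * n:] = 1.0 + tie * np.arange(u)

    constraints = []
    m = S.shape[0]
    for t in range(T):
        block = sp.hstack(
            [sp.csr_matrix((m, t * n)), S, sp.csr_matrix((m, (T - 1 - t) * n + u))]
        )
        constraints.append(LinearConstraint(block, 0.0, 0.0))
        # candidate coupling: lb_k*y_k <= v^t_k <= ub_k*y_k
        rows_lo, rows_hi = [], []
        for k in range(u):
            j = n_base + k
            row = sp.lil_matrix((1, n_var))
            row[0, t * n + j] = 1.0
            row[0, T * n + k] = -ub[j]
            rows_hi.append(row)
            row2 = sp.lil_matrix((1, n_var))
            row2[0, t * n + j] = -1.0
            row2[0, T * n + k] = lb[j]
            rows_lo.append(row2)
        if rows_hi:
            constraints.append(LinearConstraint(sp.vstack(rows_hi).tocsr(), -np.inf, 0.0))
            constraints.append(LinearConstraint(sp.vstack(rows_lo).tocsr(), -np.inf, 0.0))

    var_lb = np.concatenate([np.tile(lb, T), np.zeros(u)])
    var_ub = np.concatenate([np.tile(ub, T), np.ones(u)])
    for t, target in enumerate(targets):
        j = augmented.reaction_index(target)
        # force flux through the target in its feasible direction; the
        # forcing level sits well above the MIP feasibility tolerance
        # (1e-6), below which HiGHS would accept a zero-flux "solution"
        if ub[j] >= eps:
            force = max(eps, min(1e-3, 0.5 * ub[j]))
            var_lb[t * n + j] = max(var_lb[t * n + j], force)
        else:
            force = max(eps, min(1e-3, 0.5 * abs(lb[j])))
            var_ub[t * n + j] = min(var_ub[t * n + j], -force)

    integrality = np.concatenate([np.zeros(T * n), np.ones(u)])
    res = milp(
        c=cost,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
    )
    if res.status != 0:  # pragma: no cover - fillability pre-checked
        raise RuntimeError(f"gap-fill MILP failed: {res.message}")
    y = res.x[T * n:]
    return sorted(candidates[k].id for k in range(u) if y[k] > 0.5)
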