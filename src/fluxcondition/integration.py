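"""Transcriptome integration: map expression onto reactions and build
condition-specific models with GIMME and E-flux.

Both algorithms start from the same reaction-level expression score
(GPR-mapped: min over AND, max over OR, on linear abundance) but use it
differently:

* **GIMME** keeps the network intact and asks for the flux state that
  achieves a required fraction of the maximal objective while paying the
  least penalty for using reactions whose expression falls below a
  threshold; the total penalty is the *inconsistency score* between the
  transcriptome and the demanded functionality.
* **E-flux** shrinks each internal reaction's flux bounds in proportion
  to its relative expression, so poorly expressed enzymes become narrow
  pipes; the medium (exchange bounds) is left untouched so that diet
  enters through the transcriptome only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .analysis import FluxDistribution, fba
from .lp import OPTIMAL, solve_lp
from .model import MetabolicModel

__all__ = [
    "ExpressionMatrix",
    "ReactionExpression",
    "ConditionModel",
    "reaction_expression",
    "gimme",
    "eflux",
    "GIMME_REQUIRED_FRACTION",
    "GIMME_THRESHOLD_PERCENTILE",
]

logger = logging.getLogger(__name__)

#: default fraction of the maximal objective GIMME must retain
GIMME_REQUIRED_FRACTION = 0.9
#: default GIMME threshold: percentile of the reaction-expression distribution
GIMME_THRESHOLD_PERCENTILE = 25.0


class ExpressionMatrix:
    """Genes × samples matrix of normalized log2 intensities with sample
    metadata (group 1–5, day 4/14, replicate).

    Groups follow the diet-restriction design: 1 = ad libitum,
    2 = ad libitum + overnight fast (the control), 3 = −15%, 4 = −30%,
    5 = −60% food.
    """

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame):
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in expression matrix: {dupes[:5]}")
        required = {"group", "day", "replicate"}
        missing = required - set(sample_meta.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        meta = sample_meta.copy()
        if "sample" in meta.columns:
            meta = meta.set_index("sample")
        absent = [s for s in values.columns if s not in meta.index]
        if absent:
            raise ValueError(f"samples without metadata: {absent[:5]}")
        self.values = values
        self.sample_meta = meta.loc[values.columns]

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    def samples_for(self, group: int, day: Optional[int] = None) -> List[str]:
        meta = self.sample_meta
        mask = meta["group"] == group
        if day is not None:
            mask &= meta["day"] == day
        return list(meta.index[mask])

    def condition_mean(self, group: int, day: Optional[int] = None) -> Dict[str, float]:
        """Per-gene linear-scale abundance for one condition.

        Log2 values are un-logged (2**x) per sample and then averaged
        over the condition's replicates, so the GPR min/max rules and the
        E-flux scaling operate on linear abundance.
        """
        samples = self.samples_for(group, day)
        if not samples:
            raise ValueError(f"no samples for group={group}, day={day}")
        linear = np.power(2.0, self.values[samples].to_numpy(dtype=float))
        return dict(zip(self.values.index, linear.mean(axis=1)))

    # -- I/O -------------------------------------------------------------
    @classmethod
    def read_tsv(cls, values_path, meta_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        return cls(values, meta)

    def write_tsv(self, values_path, meta_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


#: reaction id -> linear-scale expression score; None = no evidence
ReactionExpression = Dict[str, Optional[float]]


def reaction_expression(
    model: MetabolicModel, gene_scores: Mapping[str, float]
) -> ReactionExpression:
    """GPR-evaluate per-gene abundances into per-reaction scores.

    Scores must be non-negative (linear scale).  Reactions with an empty
    GPR, or whose every informative gene is unmeasured, score None
    ("absent" — no transcriptomic evidence either way).
    """
    neg = [g for g, v in gene_scores.items() if v < 0]
    if neg:
        raise ValueError(
            f"gene scores must be non-negative linear abundances; got negatives for {neg[:5]}"
        )
    return {rxn.id: rxn.gpr.score(gene_scores) for rxn in model.reactions}


@dataclass(frozen=True)
class ConditionModel:
    """A condition-specific model: the base model plus modified bounds."""

    base_model_id: str
    condition: str
    method: str  # "GIMME" or "E-flux"
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    inconsistency: Optional[float] = None

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        return model.with_bounds(self.bounds)


def gimme_threshold(
    rxn_expr: ReactionExpression, percentile: float = GIMME_THRESHOLD_PERCENTILE
) -> float:
    """Expression threshold as a percentile of the scored reactions."""
    scores = np.array([v for v in rxn_expr.values() if v is not None], dtype=float)
    if scores.size == 0:
        raise ValueError("no scored reactions; cannot derive a GIMME threshold")
    return float(np.percentile(scores, percentile))


def gimme(
    model: MetabolicModel,
    rxn_expr: ReactionExpression,
    threshold: float,
    required_fraction: float = GIMME_REQUIRED_FRACTION,
    condition: str = "",
) -> Tuple[ConditionModel, FluxDistribution]:
    """Gene Inactivity Moderated by Metabolism and Expression.

    Minimises sum over below-threshold reactions of
    ``(threshold - x_i) * |v_i|`` subject to steady state, bounds, and
    the objective achieving ``required_fraction`` of its FBA maximum.
    Reactions without expression evidence carry no penalty.  Returns the
    condition model (carrying the inconsistency score) and the optimal
    flux distribution.
    """
    if not 0 < required_fraction <= 1:
        raise ValueError("required_fraction must be in (0, 1]")
    base = fba(model)
    if not base.optimal:
        raise RuntimeError(f"base FBA is {base.status}; GIMME needs an optimal base state")
    if base.objective_value <= 0:
        raise RuntimeError(
            "base FBA optimum is not positive; GIMME's required functionality "
            "constraint would be vacuous"
        )
    floor = required_fraction * base.objective_value

    penalties: Dict[int, float] = {}
    for j, rxn in enumerate(model.reactions):
        x = rxn_expr.get(rxn.id)
        if x is not None and x < threshold:
            penalties[j] = threshold - x

    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    n = len(model.reactions)
    obj_j = model.reaction_index(model.objective_reaction_id)

    pen_idx = sorted(penalties)
    k = len(pen_idx)
    # variables: v (n) then t (k) with t_i >= |v_{pen_i}|
    c = np.concatenate([np.zeros(n), np.array([penalties[j] for j in pen_idx])])
    A_eq = np.hstack([S, np.zeros((S.shape[0], k))]) if k else S
    rows = []
    for i, j in enumerate(pen_idx):
        r1 = np.zeros(n + k)
        r1[j] = 1.0
        r1[n + i] = -1.0
        rows.append(r1)
        r2 = np.zeros(n + k)
        r2[j] = -1.0
        r2[n + i] = -1.0
        rows.append(r2)
    # objective floor: -v_obj <= -floor
    r_obj = np.zeros(n + k)
    r_obj[obj_j] = -1.0
    rows.append(r_obj)
    A_ub = np.vstack(rows)
    b_ub = np.zeros(len(rows))
    b_ub[-1] = -floor + 1e-9 * max(1.0, abs(floor))
    big = max(np.max(np.abs(lb)), np.max(np.abs(ub)), 1.0)
    bounds = list(zip(lb, ub)) + [(0.0, big)] * k

    res = solve_lp(c, A_eq=A_eq, b_eq=np.zeros(S.shape[0]), A_ub=A_ub, b_ub=b_ub, bounds=bounds)
    if res.status != OPTIMAL:
        raise RuntimeError(
            f"GIMME LP is {res.status}: required_fraction={required_fraction} "
            f"(objective floor {floor:g}) cannot be met"
        )
    v = res.x[:n]
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    dist = FluxDistribution(fluxes, float(v[obj_j]), OPTIMAL)
    cond = ConditionModel(
        base_model_id=model.id,
        condition=condition,
        method="GIMME",
        bounds={},
        inconsistency=float(res.objective),
    )
    return cond, dist


def eflux(
    model: MetabolicModel,
    rxn_expr: ReactionExpression,
    condition: str = "",
) -> ConditionModel:
    """E-flux: scale internal reaction bounds by relative expression.

    Each scored internal reaction gets scale factor
    ``f = x / max(x)`` in [0, 1]; its upper bound becomes ``f*|ub|``
    (never exceeding the original) and, if reversible, its lower bound
    becomes ``-f*|lb|``.  Unscored reactions and boundary (exchange or
    demand) reactions keep their original bounds.
    """
    internal_scores = {
        rxn.id: rxn_expr.get(rxn.id)
        for rxn in model.reactions
        if not rxn.boundary and rxn_expr.get(rxn.id) is not None
    }
    if not internal_scores:
        raise ValueError("all reactions are unscored; E-flux has nothing to scale")
    xmax = max(internal_scores.values())
    if xmax <= 0:
        raise ValueError("maximum expression score is 0; E-flux scale undefined")

    new_bounds: Dict[str, Tuple[float, float]] = {}
    for rxn in model.reactions:
        x = internal_scores.get(rxn.id)
        if x is None:
            continue
        f = x / xmax
        ub = min(f * abs(rxn.upper_bound), rxn.upper_bound)
        if rxn.lower_bound < 0:
            lb = max(-f * abs(rxn.lower_bound), rxn.lower_bound)
        else:
            lb = min(rxn.lower_bound, ub)
        new_bounds[rxn.id] = (lb, ub)
    return ConditionModel(
        base_model_id=model.id,
        condition=condition,
        method="E-flux",
        bounds=new_bounds,
    )
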