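"""Cross-condition flux comparison.

Given per-condition flux vectors from two integration methods, this
module extracts the high-confidence *consensus* set of reactions active
under a majority of conditions in both methods, aggregates their
absolute fluxes to subsystem level, subtracts the control condition, and
normalizes the resulting subsystems × conditions table by projective
decomposition — a scale-invariant factorization X = D_r · core · D_c
with positive row/column factors and a core whose every row and column
has unit root-mean-square.  The normalized core is what gets clustered
and drawn as a clustergram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .analysis import FLUX_EPS
from .model import MetabolicModel

__all__ = [
    "active_reactions",
    "consensus_active_set",
    "ConsensusSet",
    "subsystem_flux_table",
    "projective_decompose",
    "ProjectiveDecompositionResult",
    "cluster_subsystems",
    "ClusterResult",
]

logger = logging.getLogger(__name__)


def active_reactions(table: pd.DataFrame, eps: float = FLUX_EPS) -> pd.Series:
    """Per-reaction count of conditions with |v| >= eps.

    ``table`` is reactions × conditions.  Fluxes below eps are noise at
    solver precision and count as zero.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    return (table.abs() >= eps).sum(axis=1)


@dataclass(frozen=True)
class ConsensusSet:
    reactions: List[str]
    gimme_counts: Dict[str, int]
    eflux_counts: Dict[str, int]
    n_conditions: int
    eps: float
    majority: int  # strict minimum count for inclusion (count > majority fails -> count >= majority+... )

    def __len__(self) -> int:
        return len(self.reactions)

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in set(self.reactions)


def consensus_active_set(
    gimme_counts: pd.Series,
    eflux_counts: pd.Series,
    n_conditions: int,
    eps: float = FLUX_EPS,
) -> ConsensusSet:
    """Reactions active in a strict majority of conditions under *both*
    methods — the intersection of the two per-method majority sets."""
    if set(gimme_counts.index) != set(eflux_counts.index):
        raise ValueError("GIMME and E-flux counts cover different reaction universes")
    cutoff = n_conditions / 2.0
    g_set = set(gimme_counts.index[gimme_counts > cutoff])
    e_set = set(eflux_counts.index[eflux_counts > cutoff])
    members = sorted(g_set & e_set)
    return ConsensusSet(
        reactions=members,
        gimme_counts={r: int(gimme_counts[r]) for r in members},
        eflux_counts={r: int(eflux_counts[r]) for r in members},
        n_conditions=n_conditions,
        eps=eps,
        majority=int(np.floor(cutoff)),
    )


def subsystem_flux_table(
    model: MetabolicModel,
    consensus: ConsensusSet,
    table: pd.DataFrame,
    control: str,
) -> pd.DataFrame:
    """Subsystems × conditions table of control-differenced mean |flux|.

    Per subsystem and condition: mean of |v| over the consensus reactions
    assigned to that subsystem; the control column is then subtracted
    element-wise and dropped.  Subsystems with no consensus reaction are
    dropped (logged).
    """
    if control not in table.columns:
        raise ValueError(f"control condition {control!r} not in flux table columns")
    members = [r for r in consensus.reactions if r in table.index]
    by_subsystem: Dict[str, List[str]] = {}
    for rxn_id in members:
        sub = model.reaction(rxn_id).subsystem or "(unassigned)"
        by_subsystem.setdefault(sub, []).append(rxn_id)
    dropped = set(model.subsystems) - set(by_subsystem)
    if dropped:
        logger.info("subsystems with no consensus reaction dropped: %s", sorted(dropped))
    rows = {
        sub: table.loc[rxns].abs().mean(axis=0) for sub, rxns in sorted(by_subsystem.items())
    }
    means = pd.DataFrame(rows).T
    diff = means.sub(means[control], axis=0)
    return diff.drop(columns=[control])


# ---------------------------------------------------------------------------
# Projective decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProjectiveDecompositionResult:
    core: pd.DataFrame
    row_factors: pd.Series
    col_factors: pd.Series
    iterations: int
    converged: bool


def projective_decompose(
    X: pd.DataFrame,
    tol: float = 1e-9,
    max_iter: int = 10000,
) -> ProjectiveDecompositionResult:
    """Scale-invariant normalization by alternating row/column RMS scaling.

    Factorizes X into row_factors · core · col_factors with every row and
    column of |core| having root-mean-square 1 at convergence.  The
    algorithm is Sinkhorn-like: repeatedly divide each row of |X| by its
    RMS, then each column, accumulating the divisors.  Signs of X are
    reattached to the core afterwards.  All-zero rows/columns must be
    removed beforehand (their RMS cannot be scaled to 1).
    """
    A = X.abs().to_numpy(dtype=float)
    if A.size == 0:
        raise ValueError("empty matrix")
    if (A.sum(axis=1) == 0).any() or (A.sum(axis=0) == 0).any():
        raise ValueError("all-zero rows/columns must be removed before decomposition")
    n_rows, n_cols = A.shape
    row_f = np.ones(n_rows)
    col_f = np.ones(n_cols)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = np.sqrt(np.mean(A**2, axis=1))
        if not (np.isfinite(A).all() and np.isfinite(r).all()):
            # alternating scaling can diverge on adversarial zero patterns
            break
        A /= r[:, None]
        row_f *= r
        c = np.sqrt(np.mean(A**2, axis=0))
        A /= c[None, :]
        col_f *= c
        r_now = np.sqrt(np.mean(A**2, axis=1))
        c_now = np.sqrt(np.mean(A**2, axis=0))
        if np.all(np.abs(r_now - 1) < tol) and np.all(np.abs(c_now - 1) < tol):
            converged = True
            break
    core = pd.DataFrame(np.sign(X.to_numpy()) * A, index=X.index, columns=X.columns)
    return ProjectiveDecompositionResult(
        core=core,
        row_factors=pd.Series(row_f, index=X.index),
        col_factors=pd.Series(col_f, index=X.columns),
        iterations=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterResult:
    order: List[str]
    linkage: np.ndarray
    newick: str


def cluster_subsystems(normalized: pd.DataFrame) -> ClusterResult:
    """Average-linkage hierarchical clustering (Euclidean) of rows.

    Rows are sorted by id before linkage so the result is independent of
    input order; the tree is also rendered as Newick text.
    """
    X = normalized.sort_index()
    labels = list(X.index)
    if len(labels) == 1:
        return ClusterResult(order=labels, linkage=np.empty((0, 4)), newick=f"{labels[0]};")
    Z = hierarchy.linkage(pdist(X.to_numpy(dtype=float), metric="euclidean"), method="average")
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    newick = _to_newick(hierarchy.to_tree(Z), labels)
    return ClusterResult(order=order, linkage=Z, newick=newick)


def _to_newick(node, labels: List[str]) -> str:
    def walk(nd, parent_dist: float) -> str:
        length = max(parent_dist - nd.dist, 0.0)
        if nd.is_leaf():
            return f"{labels[nd.id]}:{length:g}"
        left = walk(nd.left, nd.dist)
        right = walk(nd.right, nd.dist)
        return f"({left},{right}):{length:g}"

    return walk(node, node.dist) + ";"
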