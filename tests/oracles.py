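"""Independent brute-force oracles used by the test suite.

Each function here recomputes a quantity by exhaustive enumeration or a
closed form, deliberately avoiding the code paths (and, where possible,
the libraries) used by the implementation under test.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb, inf
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np


def lp_max_by_vertex_enumeration(
    c: np.ndarray,
    A_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    tol: float = 1e-9,
) -> float:
    """Maximize c·x s.t. A_eq x = 0, lb <= x <= ub by vertex enumeration.

    Every vertex of the polytope has at least n - rank(A_eq) variables at
    a bound; enumerate all choices of which variables sit at which bound,
    solve the resulting square-ish linear system for the rest, and keep
    the feasible points.  Exponential, so only for tiny models.
    """
    n = len(c)
    A = np.asarray(A_eq, dtype=float)
    rank = np.linalg.matrix_rank(A) if A.size else 0
    n_fix = n - rank
    best = -inf
    for fixed_vars in itertools.combinations(range(n), n_fix):
        free_vars = [j for j in range(n) if j not in fixed_vars]
        for bounds_choice in itertools.product([0, 1], repeat=n_fix):
            x = np.zeros(n)
            for j, side in zip(fixed_vars, bounds_choice):
                x[j] = lb[j] if side == 0 else ub[j]
            if free_vars:
                Af = A[:, free_vars]
                rhs = -A[:, fixed_vars] @ x[list(fixed_vars)] if fixed_vars else np.zeros(A.shape[0])
                sol, residuals, rk, _ = np.linalg.lstsq(Af, rhs, rcond=None)
                x[free_vars] = sol
            if np.max(np.abs(A @ x)) > 1e-7:
                continue
            if np.any(x < lb - 1e-7) or np.any(x > ub + 1e-7):
                continue
            best = max(best, float(c @ x))
    return best


def brute_force_edge_betweenness(
    edges: Iterable[Tuple[str, str]], fractional: bool = True
) -> Dict[Tuple[str, str], float]:
    """Edge betweenness by explicit enumeration of all shortest paths.

    BFS from each node gives distances; all shortest paths between a pair
    are enumerated by walking predecessor links.  With ``fractional``
    each of a pair's sigma shortest paths contributes 1/sigma per edge,
    otherwise 1.
    """
    adj: Dict[str, set] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    nodes = sorted(adj)

    def norm(e):
        return (e[0], e[1]) if e[0] <= e[1] else (e[1], e[0])

    counts: Dict[Tuple[str, str], float] = {}
    for a in adj:
        for b in adj[a]:
            counts[norm((a, b))] = 0.0

    def all_shortest_paths(s: str, t: str) -> List[List[str]]:
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        if t not in dist:
            return []
        paths: List[List[str]] = []

        def extend(path: List[str]) -> None:
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in adj[u]:
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    path.append(v)
                    extend(path)
                    path.pop()

        extend([s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            weight = 1.0 / len(paths) if fractional else 1.0
            for path in paths:
                for u, v in zip(path, path[1:]):
                    counts[norm((u, v))] += weight
    return counts


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration of tables with the
    observed margins, using the point-probability rule."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_prob(x: int) -> float:
        # hypergeometric: P(first cell = x)
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def bh_step_up(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg adjusted p-values computed directly from the
    step-up definition: q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        q[i] = min(running, 1.0)
    return q


def minimal_gapfill_sets(
    is_fixed: "callable", candidates: Sequence[str], max_size: int | None = None
) -> List[frozenset]:
    """All minimum-cardinality subsets of candidates for which
    ``is_fixed(subset)`` is True, by exhaustive subset enumeration."""
    max_size = len(candidates) if max_size is None else max_size
    for size in range(0, max_size + 1):
        hits = [
            frozenset(combo)
            for combo in itertools.combinations(candidates, size)
            if is_fixed(set(combo))
        ]
        if hits:
            return hits
    return []
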