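"""Weighted minimum vertex cover over the conflict graph, and variant
assignment to the surviving (evolutionarily compatible) patterns.

The integer program is

    minimize   sum_i c_i x_i
    subject to x_i + x_j >= 1   for every edge (i, j)
               x_i in {0, 1}

solved with HiGHS through :func:`scipy.optimize.milp`.  The kept patterns are
the complement of the optimal cover.  Nodes with (numerically) zero weight
are not sent to the solver: they can cover their edges at no cost, and are
afterwards greedily re-admitted to the kept set whenever compatible, so the
kept set is a maximal conflict-free family at the optimal objective.

Ties between equal-objective covers are broken deterministically towards
covers that remove fewer nodes via a tiny per-node penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse

from phyloseed.bayes import PresenceTable
from phyloseed.patterns import ConflictGraph, log_likelihood_matrix

__all__ = ["CoverSolution", "solve_min_vertex_cover", "assign_variants"]

_COUNT_PENALTY = 1e-9


@dataclass
class CoverSolution:
    """Result of the minimum vertex cover MILP.

    ``removed``/``kept`` are sets of pattern bitmasks; ``objective`` is the
    summed reliability weight of the removed patterns (true weights, without
    the tie-break penalty).
    """

    removed: set
    kept: set
    objective: float
    proven_optimal: bool
    n_milp_nodes: int = 0

    def is_cover(self, graph: ConflictGraph) -> bool:
        masks = graph.masks
        for i, j in zip(*graph.edges):
            if masks[int(i)] not in self.removed and masks[int(j)] not in self.removed:
                return False
        return True


def _greedy_complete_kept(kept_idx: set, candidates, neighbors) -> set:
    """Add zero-weight candidate node indices back to ``kept_idx`` whenever
    none of their graph neighbors is kept (order: larger subsets first)."""
    kept_idx = set(kept_idx)
    for i in candidates:
        if not neighbors[i] & kept_idx:
            kept_idx.add(i)
    return kept_idx


def solve_min_vertex_cover(graph: ConflictGraph, zero_weight_tol: float = 0.0, time_limit: float | None = None) -> CoverSolution:
    """Solve the weighted minimum vertex cover on a conflict graph.

    Parameters
    ----------
    graph : ConflictGraph
    zero_weight_tol : float
        Nodes with weight <= this are treated as free-to-remove and excluded
        from the MILP (variable reduction); 0 keeps the program exact.
    time_limit : float, optional
        Solver wall-clock limit in seconds; exceeding it raises RuntimeError.
    """
    masks = np.asarray(graph.masks)
    weights = np.asarray(graph.weights, dtype=float)
    if not np.isfinite(weights).all():
        raise ValueError("node weights must be finite")
    ei, ej = graph.edges
    ei = np.asarray(ei, dtype=np.int64)
    ej = np.asarray(ej, dtype=np.int64)

    conflicted = np.zeros(len(masks), dtype=bool)
    conflicted[ei] = True
    conflicted[ej] = True

    free = conflicted & (weights <= zero_weight_tol)
    milp_nodes = np.flatnonzero(conflicted & ~free)

    # edges between two positive nodes go to the MILP; edges touching a free
    # node are covered by removing the free node at zero cost
    pos = np.zeros(len(masks), dtype=bool)
    pos[milp_nodes] = True
    both_pos = pos[ei] & pos[ej]
    mei, mej = ei[both_pos], ej[both_pos]

    removed_idx: set[int] = set(np.flatnonzero(free))
    proven = True
    if len(milp_nodes) and len(mei):
        remap = -np.ones(len(masks), dtype=np.int64)
        remap[milp_nodes] = np.arange(len(milp_nodes))
        rows = np.repeat(np.arange(len(mei)), 2)
        cols = np.concatenate([remap[mei][:, None], remap[mej][:, None]], axis=1).ravel()
        A = sparse.csr_matrix((np.ones(2 * len(mei)), (rows, cols)), shape=(len(mei), len(milp_nodes)))
        c = weights[milp_nodes] + _COUNT_PENALTY * (1.0 + weights[milp_nodes].max())
        constraints = optimize.LinearConstraint(A, lb=1.0, ub=np.inf)
        options = {}
        if time_limit is not None:
            options["time_limit"] = time_limit
        res = optimize.milp(
            c=c,
            integrality=np.ones(len(milp_nodes)),
            bounds=optimize.Bounds(0, 1),
            constraints=constraints,
            options=options,
        )
        if res.status == 1:
            raise RuntimeError(
                "MILP solver hit the iteration/time limit; "
                f"best bound so far: {getattr(res, 'mip_dual_bound', float('nan'))}"
            )
        if not res.success:
            raise RuntimeError(f"MILP solver failed: {res.message}")
        x = np.round(res.x).astype(bool)
        removed_idx.update(milp_nodes[x].tolist())
        proven = res.status == 0

    neighbors: dict[int, set] = {i: set() for i in range(len(masks))}
    for a, bb in zip(ei, ej):
        neighbors[int(a)].add(int(bb))
        neighbors[int(bb)].add(int(a))
    kept_idx = {i for i in range(len(masks)) if i not in removed_idx}
    # re-admit free nodes whose neighbors were all removed anyway
    free_candidates = sorted(
        (i for i in removed_idx if free[i]),
        key=lambda i: (-bin(int(masks[i])).count("1"), int(masks[i])),
    )
    kept_idx = _greedy_complete_kept(kept_idx, free_candidates, neighbors)
    removed_masks = {int(masks[i]) for i in range(len(masks)) if i not in kept_idx}
    kept_masks = {int(masks[i]) for i in kept_idx}
    objective = float(sum(weights[i] for i in range(len(masks)) if i not in kept_idx))
    return CoverSolution(
        removed=removed_masks,
        kept=kept_masks,
        objective=objective,
        proven_optimal=proven,
        n_milp_nodes=len(milp_nodes),
    )


def assign_variants(solution: CoverSolution, table: PresenceTable, loglik: np.ndarray | None = None, kept_masks: np.ndarray | None = None) -> np.ndarray:
    """Assign each variant to its most likely kept (compatible) pattern.

    Returns an array of pattern bitmasks, one per variant.  Ties are broken
    towards larger sample subsets, then smaller bitmask value.
    """
    if kept_masks is None:
        kept_masks = np.array(sorted(solution.kept), dtype=np.int64)
    if len(kept_masks) == 0:
        raise ValueError("kept pattern set is empty")
    if loglik is None:
        loglik = log_likelihood_matrix(table, kept_masks)
    popcount = np.array([bin(int(m)).count("1") for m in kept_masks])
    # tie-break: among equal log-likelihoods prefer larger sample subsets,
    # then the smaller bitmask; realized by column ordering + first-max scan
    order = np.lexsort((kept_masks, -popcount))
    ll = loglik[:, order]
    out = np.empty(table.n_variants, dtype=np.int64)
    for i in range(ll.shape[0]):
        row = ll[i]
        top = row.max()
        cand = np.flatnonzero(row >= top - 1e-12)
        out[i] = kept_masks[order[cand[0]]]
    return out
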