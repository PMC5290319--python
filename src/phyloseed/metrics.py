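"""Benchmark error metrics against simulated ground truth, plus a
neighbour-joining baseline on thresholded binary profiles."""

from __future__ import annotations

import numpy as np

from phyloseed.bayes import PresenceTable
from phyloseed.tree import Phylogeny

__all__ = [
    "branching_error",
    "mutation_matrix_error",
    "ancestry_matrix",
    "fill_missing_pairs",
    "neighbour_joining_baseline",
]


def _clades(tree_or_clades) -> set:
    if isinstance(tree_or_clades, Phylogeny):
        return tree_or_clades.clades()
    return {frozenset(c) for c in tree_or_clades}


def _leaves(tree_or_clades, other) -> None:
    if isinstance(tree_or_clades, Phylogeny) and isinstance(other, Phylogeny):
        if set(tree_or_clades.samples) != set(other.samples):
            raise ValueError("trees must share an identical leaf set")


def branching_error(true_tree, inferred_tree) -> float:
    """Fraction of true coalescent events (non-root, non-leaf clades) missing
    from the inferred tree; 0 when the true tree has no internal clades."""
    _leaves(true_tree, inferred_tree)
    true_clades = _clades(true_tree)
    inferred_clades = _clades(inferred_tree)
    if not true_clades:
        return 0.0
    missed = len(true_clades - inferred_clades)
    return missed / len(true_clades)


def mutation_matrix_error(true_A: np.ndarray, inferred_A: np.ndarray) -> float:
    """Normalized ancestry disagreement: mean |A_hat - A| over ordered
    off-diagonal pairs.  A tool with no output for a pair should have been
    filled with A - 0.5 (see :func:`fill_missing_pairs`), making total
    ignorance score exactly 0.5."""
    A = np.asarray(true_A, dtype=float)
    Ah = np.asarray(inferred_A, dtype=float)
    if A.shape != Ah.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    k = A.shape[0]
    if k < 2:
        raise ValueError("need at least two mutations")
    off = ~np.eye(k, dtype=bool)
    return float(np.abs(Ah - A)[off].sum() / (k * (k - 1)))


def fill_missing_pairs(true_A: np.ndarray, inferred_A: np.ndarray, known: np.ndarray) -> np.ndarray:
    """Apply the no-information fill rule A_hat := A - 0.5 outside ``known``
    (boolean mask of pairs the tool reported)."""
    A = np.asarray(true_A, dtype=float)
    out = np.asarray(inferred_A, dtype=float).copy()
    out[~known] = A[~known] - 0.5
    return out


def ancestry_matrix(assignment_masks, known: np.ndarray | None = None) -> np.ndarray:
    """Ancestry matrix implied by per-variant pattern assignments.

    Within a compatible (laminar) pattern family, variant i is ancestral to
    variant j iff i's sample set properly contains j's; equal non-empty
    patterns put the pair on one branch (0.5).  Variants assigned the empty
    pattern (``known`` False) carry no information and should be filled with
    :func:`fill_missing_pairs`.
    """
    masks = np.asarray(assignment_masks, dtype=np.int64)
    k = len(masks)
    A = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            mi, mj = int(masks[i]), int(masks[j])
            if mi == 0 or mj == 0:
                continue
            if mi == mj:
                A[i, j] = 0.5
            elif (mi & mj) == mj:
                A[i, j] = 1.0
    return A


def neighbour_joining_baseline(table: PresenceTable, threshold: float = 0.5):
    """Neighbour joining on Hamming distances of thresholded presence
    profiles, rooted at an all-absent germline profile.

    Returns the set of clades (frozensets of sample names, root and leaves
    excluded) and the Newick string.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    n = table.n_samples
    if n < 3:
        raise ValueError("neighbour joining needs at least three samples")
    profiles = (table.p > threshold).astype(int)
    labels = list(table.samples) + ["__germline__"]
    mat = np.concatenate([profiles, np.zeros((table.n_variants, 1), dtype=int)], axis=1)
    dm = np.zeros((n + 1, n + 1))
    for a in range(n + 1):
        for b in range(a + 1, n + 1):
            dist = int((mat[:, a] != mat[:, b]).sum())
            dm[a, b] = dm[b, a] = dist
    tree = nj(DistanceMatrix(dm, ids=labels))
    germ = tree.find("__germline__")
    rooted = tree.root_at(germ.parent) if germ.parent is not None else tree
    clades = set()
    for node in rooted.non_tips(include_self=False):
        names = frozenset(t.name for t in node.tips() if t.name != "__germline__")
        if 1 < len(names) < n:
            clades.add(names)
    return clades, str(rooted)
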