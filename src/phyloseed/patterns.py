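"""Mutation patterns, reliability scores, and the evolutionary conflict graph.

A mutation pattern is the subset of samples carrying a variant, encoded as a
bitmask over the n samples (bit s set = present in sample s).  Two patterns
are evolutionarily incompatible iff a perfect-and-persistent phylogeny cannot
hold both, i.e. iff they properly intersect: u\\v, v\\u and u&v all non-empty.

For n samples all 2^n patterns are enumerated (up to a configurable limit);
beyond it a restricted node set is used: the maximum-likelihood pattern of
each variant, every pattern within Hamming distance 1 of those, and the empty
and full patterns.

Node weights are reliability scores in nats,

    omega_v = -(1/m) * sum_mu log(1 - L_mu(v)),

where L_mu(v) = prod_s (p_mu_s if v_s else q_mu_s) is the likelihood that
variant mu exhibits pattern v.  Likelihoods are capped at 1 - 1e-12 before
the log so scores stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from phyloseed.bayes import PresenceTable

__all__ = [
    "ConflictGraph",
    "incompatible",
    "pattern_likelihood",
    "log_likelihood_matrix",
    "reliability_score",
    "reliability_scores",
    "build_conflict_graph",
    "mask_to_bits",
    "bits_to_mask",
]

LIKELIHOOD_CAP = 1.0 - 1e-12


def bits_to_mask(bits) -> int:
    """Binary vector (v_0, ..., v_{n-1}) -> integer bitmask."""
    mask = 0
    for s, b in enumerate(bits):
        if b:
            mask |= 1 << s
    return mask


def mask_to_bits(mask: int, n: int) -> np.ndarray:
    return np.array([(mask >> s) & 1 for s in range(n)], dtype=np.int8)


def incompatible(u: int, v: int, n: int | None = None) -> bool:
    """True iff patterns u and v cannot coexist on one perfect phylogeny.

    Accepts bitmasks (with ``n`` optional) or equal-length binary sequences.
    """
    if not isinstance(u, (int, np.integer)):
        if len(u) != len(v):
            raise ValueError("patterns must cover identical sample sets")
        u, v = bits_to_mask(u), bits_to_mask(v)
    elif isinstance(v, (int, np.integer)) is False:
        raise ValueError("patterns must both be bitmasks or both vectors")
    return bool(u & ~v) and bool(v & ~u) and bool(u & v)


def pattern_likelihood(variant_index: int, pattern, table: PresenceTable) -> float:
    """L_mu(v): product over samples of p (if present in v) or q (absent)."""
    n = table.n_samples
    mask = pattern if isinstance(pattern, (int, np.integer)) else bits_to_mask(pattern)
    p_row = table.p[variant_index]
    q_row = table.q[variant_index]
    like = 1.0
    for s in range(n):
        like *= p_row[s] if (mask >> s) & 1 else q_row[s]
    return float(like)


def log_likelihood_matrix(table: PresenceTable, masks: np.ndarray) -> np.ndarray:
    """m x |masks| matrix of log L_mu(v), vectorized.

    log L = sum_s log q + sum_{s in v} (log p - log q).
    """
    n = table.n_samples
    with np.errstate(divide="ignore"):
        logp = np.log(np.clip(table.p, 1e-300, 1.0))
        logq = np.log(np.clip(table.q, 1e-300, 1.0))
    bits = ((masks[:, None] >> np.arange(n)[None, :]) & 1).astype(float)  # |masks| x n
    return logq.sum(axis=1)[:, None] + (logp - logq) @ bits.T


def reliability_scores(table: PresenceTable, masks: np.ndarray, loglik: np.ndarray | None = None, variant_subset: np.ndarray | None = None) -> np.ndarray:
    """Reliability score omega_v for every mask, in nats.

    ``variant_subset`` (indices, possibly with repeats) supports bootstrap
    resampling on a precomputed ``loglik`` matrix.
    """
    if loglik is None:
        loglik = log_likelihood_matrix(table, masks)
    if variant_subset is not None:
        loglik = loglik[variant_subset]
    like = np.minimum(np.exp(loglik), LIKELIHOOD_CAP)
    m = like.shape[0]
    return -np.log1p(-like).sum(axis=0) / m


def reliability_score(pattern, table: PresenceTable) -> float:
    """omega_v = -(1/m) log prod_mu (1 - L_mu(v)) for a single pattern."""
    mask = pattern if isinstance(pattern, (int, np.integer)) else bits_to_mask(pattern)
    masks = np.array([mask], dtype=np.int64)
    return float(reliability_scores(table, masks)[0])


@lru_cache(maxsize=8)
def _full_edge_set(n: int) -> tuple:
    """Upper-triangle index pairs of incompatible patterns among all 2^n."""
    masks = np.arange(2**n, dtype=np.int64)
    return _edges_for_masks(masks, n)


def _edges_for_masks(masks: np.ndarray, n: int) -> tuple:
    full = (1 << n) - 1
    a = masks[:, None]
    b = masks[None, :]
    conflict = ((a & ~b & full) != 0) & ((b & ~a & full) != 0) & ((a & b) != 0)
    iu, ju = np.triu_indices(len(masks), k=1)
    sel = conflict[iu, ju]
    return iu[sel], ju[sel]


@dataclass
class ConflictGraph:
    """Weighted conflict graph over mutation patterns.

    ``masks`` are pattern bitmasks, ``weights`` their reliability scores, and
    ``edges`` index pairs (i, j) of incompatible patterns.
    """

    n_samples: int
    masks: np.ndarray
    weights: np.ndarray
    edges: tuple
    restricted: bool = False
    samples: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.masks)

    @property
    def n_edges(self) -> int:
        return len(self.edges[0])

    def index_of(self, mask: int) -> int:
        idx = np.flatnonzero(self.masks == mask)
        if len(idx) == 0:
            raise KeyError(f"pattern {mask:b} not in graph")
        return int(idx[0])

    def degree(self, i: int) -> int:
        return int((self.edges[0] == i).sum() + (self.edges[1] == i).sum())

    def write_edge_list(self, path) -> None:
        """Export nodes and adjacency as TSV (bitstring, weight, neighbors)."""
        neighbors: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for i, j in zip(*self.edges):
            neighbors[int(i)].append(int(j))
            neighbors[int(j)].append(int(i))
        with open(path, "w") as fh:
            fh.write("pattern\tweight_nats\tneighbors\n")
            for i in range(self.n_nodes):
                bits = format(int(self.masks[i]), f"0{self.n_samples}b")[::-1]
                nb = ",".join(format(int(self.masks[j]), f"0{self.n_samples}b")[::-1] for j in sorted(neighbors[i]))
                fh.write(f"{bits}\t{self.weights[i]:.10g}\t{nb}\n")


def _restricted_masks(table: PresenceTable) -> np.ndarray:
    """ML pattern per variant, Hamming-1 neighborhood, empty and full."""
    n = table.n_samples
    full = (1 << n) - 1
    ml = (table.p > 0.5).astype(np.int64)
    base = set()
    for row in ml:
        mask = int(bits_to_mask(row))
        base.add(mask)
        for s in range(n):
            base.add(mask ^ (1 << s))
    base.add(0)
    base.add(full)
    return np.array(sorted(base), dtype=np.int64)


def build_conflict_graph(table: PresenceTable, max_enumeration_samples: int = 14, restricted: bool | None = None, samples: list[str] | None = None) -> ConflictGraph:
    """Build the conflict graph from a presence table.

    Enumerates all 2^n patterns when n <= ``max_enumeration_samples`` unless
    ``restricted`` forces either mode.  Node weights are reliability scores;
    edges join exactly the incompatible pairs.
    """
    n = table.n_samples
    if restricted is None:
        restricted = n > max_enumeration_samples
    if not restricted and n > max_enumeration_samples:
        raise ValueError(
            f"full enumeration of 2^{n} patterns exceeds the limit "
            f"({max_enumeration_samples} samples); pass restricted=True"
        )
    if restricted:
        masks = _restricted_masks(table)
        edges = _edges_for_masks(masks, n)
    else:
        masks = np.arange(2**n, dtype=np.int64)
        edges = _full_edge_set(n)
    weights = reliability_scores(table, masks)
    return ConflictGraph(
        n_samples=n,
        masks=masks,
        weights=weights,
        edges=edges,
        restricted=restricted,
        samples=list(samples or table.samples),
    )
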