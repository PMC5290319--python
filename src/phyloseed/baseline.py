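"""Conventional binary present/absent classification and the classical
maximum-compatibility conflict count it implies.

Each cell gets a one-tailed binomial p-value under the null that the variant
is absent and supporting reads are false positives arriving at rate p_fpr;
the pooled per-patient p-values are corrected with the Benjamini-Hochberg
step-up procedure.  Rejected cells are classified present.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from phyloseed.datamodel import PatientConfig, VariantCallMatrix

__all__ = [
    "binomial_pvalue",
    "fdr_step_up",
    "binary_classification",
    "bh_critical_value",
    "count_incompatible_variants",
]


def binomial_pvalue(K: int, N: int, p_fpr: float) -> float:
    """P(X >= K) for X ~ Binomial(N, p_fpr); K = 0 gives 1."""
    if K < 0 or N < 0 or K > N:
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if K == 0:
        return 1.0
    return float(stats.binom.sf(K - 1, N, p_fpr))


def fdr_step_up(pvalues, fdr: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean rejection flags.

    Rejects hypotheses 1..k* in p-value order where k* is the largest k with
    p_(k) <= k/M * fdr.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    M = p.size
    if M == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = (np.arange(1, M + 1) / M) * fdr
    passing = np.flatnonzero(ranked <= thresholds)
    reject = np.zeros(M, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


def bh_critical_value(pvalues, fdr: float) -> float:
    """Largest rejected p-value (realized BH cutoff); 0 if nothing rejected."""
    p = np.asarray(pvalues, dtype=float).ravel()
    reject = fdr_step_up(p, fdr)
    return float(p[reject].max()) if reject.any() else 0.0


def binary_pvalues(matrix: VariantCallMatrix, config: PatientConfig | None = None) -> np.ndarray:
    config = config or PatientConfig()
    m, n = matrix.n_variants, matrix.n_samples
    pv = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            pv[i, j] = binomial_pvalue(int(matrix.mut_reads[i, j]), int(matrix.coverage[i, j]), config.p_fpr)
    return pv


def binary_classification(matrix: VariantCallMatrix, config: PatientConfig | None = None) -> np.ndarray:
    """m x n boolean presence matrix from the pooled binomial/BH test."""
    config = config or PatientConfig()
    pv = binary_pvalues(matrix, config)
    reject = fdr_step_up(pv.ravel(), config.fdr)
    return reject.reshape(pv.shape)


def count_incompatible_variants(binary: np.ndarray, return_detail: bool = False):
    """Number of variants whose observed binary patterns are evolutionarily
    incompatible under the classical maximum-compatibility criterion.

    Observed patterns become conflict-graph nodes weighted by the number of
    variants exhibiting them; the minimum vertex cover removes the smallest
    number of variants such that the remaining patterns are conflict-free.
    """
    from phyloseed.cover import solve_min_vertex_cover
    from phyloseed.patterns import ConflictGraph, _edges_for_masks

    binary = np.asarray(binary, dtype=bool)
    m, n = binary.shape
    masks = np.zeros(m, dtype=np.int64)
    for s in range(n):
        masks |= binary[:, s].astype(np.int64) << s
    uniq, counts = np.unique(masks, return_counts=True)
    edges = _edges_for_masks(uniq, n)
    graph = ConflictGraph(
        n_samples=n,
        masks=uniq,
        weights=counts.astype(float),
        edges=edges,
    )
    solution = solve_min_vertex_cover(graph)
    removed = solution.removed
    incompatible_variants = int(sum(c for u, c in zip(uniq, counts) if int(u) in removed))
    if return_detail:
        per_variant = np.array([int(mk) in removed for mk in masks])
        return incompatible_variants, per_variant, solution
    return incompatible_variants
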