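"""Rooted perfect-and-persistent phylogeny from compatible mutation patterns,
sequencing-artifact classification, and bootstrap branch support."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from phyloseed.bayes import PresenceTable, _theta_params
from phyloseed.datamodel import PatientConfig, VariantCallMatrix

__all__ = ["PhyloNode", "Phylogeny", "ArtifactReport", "build_tree", "classify_artifacts", "bootstrap_support"]


@dataclass
class PhyloNode:
    """One branch of the phylogeny; ``mask`` is the sample subset below it."""

    mask: int
    variants: list[int] = field(default_factory=list)
    children: list["PhyloNode"] = field(default_factory=list)
    support: float | None = None

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Phylogeny:
    """Rooted sample tree; the root branch descends from the germline.

    Internal branches carry the sample-subset pattern they introduce and the
    indices of variants acquired on them.  Variants assigned to the empty
    pattern are collected in ``unplaced`` (putative false-positive set).
    """

    root: PhyloNode
    samples: list[str]
    unplaced: list[int] = field(default_factory=list)
    variant_names: list[str] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def branch_masks(self) -> set:
        return {node.mask for node in self.root.walk()}

    def clades(self, include_root: bool = False, include_leaves: bool = False) -> set:
        """Sample subsets of the tree's branches, as frozensets of names."""
        out = set()
        full = (1 << self.n_samples) - 1
        for node in self.root.walk():
            size = bin(node.mask).count("1")
            if node.mask == full and not include_root:
                continue
            if size == 1 and not include_leaves:
                continue
            if size == 0:
                continue
            out.add(frozenset(self.samples[s] for s in range(self.n_samples) if (node.mask >> s) & 1))
        return out

    def presence_matrix(self, n_variants: int) -> np.ndarray:
        """m x n boolean matrix implied by the branch placements."""
        present = np.zeros((n_variants, self.n_samples), dtype=bool)
        for node in self.root.walk():
            bits = [(node.mask >> s) & 1 for s in range(self.n_samples)]
            for v in node.variants:
                present[v] |= np.array(bits, dtype=bool)
        return present

    def newick(self, with_support: bool = True, branch_length: str = "variants") -> str:
        """Newick string; internal node labels carry bootstrap support."""

        def fmt(node: PhyloNode) -> str:
            length = f":{len(node.variants)}" if branch_length == "variants" else ""
            if not node.children:
                names = [self.samples[s] for s in range(self.n_samples) if (node.mask >> s) & 1]
                label = "_".join(names[0].split()) if names else ""
                return f"{label}{length}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.2f}"
            return f"({inner}){label}{length}"

        return fmt(self.root) + ";"


def build_tree(assignments, n_samples: int, samples: list[str] | None = None, variant_names: list[str] | None = None) -> Phylogeny:
    """Construct the unique phylogeny from pairwise-compatible patterns.

    ``assignments`` is one pattern bitmask per variant.  The distinct
    non-empty patterns, ordered by containment, become the internal branches;
    the full pattern is the trunk; singleton patterns are leaf branches.
    Samples without a private pattern still receive a (variant-free) leaf.
    Raises ``ValueError`` if any two patterns are incompatible.
    """
    assignments = np.asarray(assignments, dtype=np.int64)
    samples = list(samples) if samples is not None else [f"S{i+1}" for i in range(n_samples)]
    full = (1 << n_samples) - 1
    distinct = sorted({int(m) for m in assignments if m != 0})
    for a in range(len(distinct)):
        for b in range(a + 1, len(distinct)):
            u, v = distinct[a], distinct[b]
            if (u & ~v) and (v & ~u) and (u & v):
                raise ValueError(
                    f"patterns {u:0{n_samples}b} and {v:0{n_samples}b} are "
                    "evolutionarily incompatible; resolve conflicts first"
                )
    variants_of: dict[int, list[int]] = {m: [] for m in distinct}
    unplaced = []
    for idx, m in enumerate(assignments):
        if m == 0:
            unplaced.append(idx)
        else:
            variants_of[int(m)].append(idx)

    node_masks = set(distinct)
    node_masks.add(full)  # germline root / trunk
    for s in range(n_samples):
        node_masks.add(1 << s)
    nodes = {m: PhyloNode(mask=m, variants=variants_of.get(m, [])) for m in node_masks}

    # parent = smallest strict superset among node masks (laminar family)
    ordered = sorted(node_masks, key=lambda m: (bin(m).count("1"), m))
    for m in ordered:
        if m == full:
            continue
        best = None
        for cand in node_masks:
            if cand != m and (cand & m) == m:
                if best is None or bin(cand).count("1") < bin(best).count("1"):
                    best = cand
        nodes[best].children.append(nodes[m])
    for node in nodes.values():
        node.children.sort(key=lambda c: (-bin(c.mask).count("1"), c.mask))
    return Phylogeny(root=nodes[full], samples=samples, unplaced=unplaced, variant_names=variant_names)


CONCORDANT = "concordant"
FALSE_POSITIVE = "putative false-positive"
FN_UNDERPOWERED = "under-powered false-negative"
FN_WELLPOWERED = "well-powered false-negative"


@dataclass
class ArtifactReport:
    """Per-cell comparison of inferred vs binary-baseline classifications."""

    classification: np.ndarray  # m x n array of strings
    counts: dict

    @property
    def n_artifacts(self) -> int:
        return int(sum(v for k, v in self.counts.items() if k != CONCORDANT))

    @property
    def n_false_negatives(self) -> int:
        return int(self.counts.get(FN_UNDERPOWERED, 0) + self.counts.get(FN_WELLPOWERED, 0))

    def to_frame(self, matrix: VariantCallMatrix):
        import pandas as pd

        rows = []
        m, n = self.classification.shape
        for i in range(m):
            for j in range(n):
                if self.classification[i, j] != CONCORDANT:
                    rows.append(
                        {
                            "variant": matrix.variants[i],
                            "sample": matrix.samples[j],
                            "mut_reads": int(matrix.mut_reads[i, j]),
                            "coverage": int(matrix.coverage[i, j]),
                            "classification": self.classification[i, j],
                        }
                    )
        return pd.DataFrame(rows, columns=["variant", "sample", "mut_reads", "coverage", "classification"])


def _detection_read_threshold(N: int, alpha: float, p_fpr: float, min_reads: int) -> int:
    """Smallest K whose one-tailed binomial p-value clears alpha, floored at
    the minimum supporting-read filter."""
    if N == 0:
        return max(min_reads, 1)
    k = int(stats.binom.isf(alpha, N, p_fpr))  # P(X > k) <= alpha
    while k >= 1 and stats.binom.sf(k - 1, N, p_fpr) <= alpha:
        k -= 1
    k += 1
    return max(k, min_reads)


def classify_artifacts(assignments, baseline: np.ndarray, matrix: VariantCallMatrix, config: PatientConfig | None = None, bh_alpha: float | None = None) -> ArtifactReport:
    """Compare inferred pattern presence against the binary baseline.

    A cell is an artifact when the two disagree: baseline present + inferred
    absent = putative false-positive; baseline absent + inferred present =
    false-negative, split by detection power.  The power of a cell is the
    probability that a clonal variant (expected VAF gamma_s/2) would have
    reached the detection read threshold at the cell's coverage; below 50%
    the false-negative is called under-powered.
    """
    config = config or PatientConfig()
    if matrix.purity is None:
        raise ValueError("matrix must carry purities")
    assignments = np.asarray(assignments, dtype=np.int64)
    m, n = matrix.n_variants, matrix.n_samples
    inferred = np.zeros((m, n), dtype=bool)
    for i in range(m):
        for s in range(n):
            inferred[i, s] = bool((assignments[i] >> s) & 1)
    baseline = np.asarray(baseline, dtype=bool)
    if baseline.shape != (m, n):
        raise ValueError("baseline shape mismatch")

    alpha = bh_alpha if bh_alpha is not None else config.fdr
    theta0, slope = _theta_params(config.e, config.error_channel)
    median_cov = np.median(matrix.coverage, axis=0)
    out = np.full((m, n), CONCORDANT, dtype=object)
    counts = {CONCORDANT: 0, FALSE_POSITIVE: 0, FN_UNDERPOWERED: 0, FN_WELLPOWERED: 0}
    for i in range(m):
        for j in range(n):
            b, t = baseline[i, j], inferred[i, j]
            if b == t:
                counts[CONCORDANT] += 1
                continue
            if b and not t:
                out[i, j] = FALSE_POSITIVE
            else:
                gamma = float(matrix.purity[j])
                N = int(matrix.coverage[i, j])
                min_reads = config.min_variant_reads_low_cov if median_cov[j] <= 25 else config.min_variant_reads
                k_min = _detection_read_threshold(N, alpha, config.p_fpr, min_reads)
                theta_clonal = theta0 + slope * (gamma / 2.0)
                power = float(stats.binom.sf(k_min - 1, N, theta_clonal)) if N > 0 else 0.0
                out[i, j] = FN_UNDERPOWERED if power < 0.5 else FN_WELLPOWERED
            counts[out[i, j]] += 1
    return ArtifactReport(classification=out, counts=counts)


def bootstrap_support(matrix: VariantCallMatrix, config: PatientConfig | None = None, reps: int | None = None, table: PresenceTable | None = None) -> dict:
    """Bootstrap branch support: resample variants with replacement, rerun
    scoring -> vertex cover -> tree, and count branch recurrence.

    Returns ``{mask: support_fraction}`` over the branches of the original
    tree.  Purities are held fixed across replicates.
    """
    from phyloseed.bayes import presence_table as _presence_table
    from phyloseed.cover import assign_variants, solve_min_vertex_cover
    from phyloseed.patterns import build_conflict_graph, log_likelihood_matrix, reliability_scores

    config = config or PatientConfig()
    reps = config.bootstrap_reps if reps is None else reps
    if reps < 1:
        raise ValueError("bootstrap requires at least one replicate")
    table = table if table is not None else _presence_table(matrix, config)
    graph = build_conflict_graph(table, config.max_enumeration_samples)
    loglik = log_likelihood_matrix(table, graph.masks)

    base_sol = solve_min_vertex_cover(graph, zero_weight_tol=1e-10)
    base_assign = assign_variants(base_sol, table)
    base_tree = build_tree(base_assign, table.n_samples, table.samples)
    branch_hits = {mask: 0 for mask in base_tree.branch_masks()}

    rng = np.random.default_rng(config.rng_seed)
    m = table.n_variants
    from dataclasses import replace as _dc_replace

    for _ in range(reps):
        idx = rng.integers(0, m, size=m)
        weights = reliability_scores(table, graph.masks, loglik=loglik, variant_subset=idx)
        rep_graph = _dc_replace(graph, weights=weights)
        sol = solve_min_vertex_cover(rep_graph, zero_weight_tol=1e-10)
        sub = PresenceTable(
            p=table.p[idx],
            q=table.q[idx],
            samples=list(table.samples),
            variants=[table.variants[i] for i in idx],
        )
        rep_assign = assign_variants(sol, sub)
        rep_masks = set(build_tree(rep_assign, table.n_samples, table.samples).branch_masks())
        for mask in branch_hits:
            if mask in rep_masks:
                branch_hits[mask] += 1
    return {mask: hits / reps for mask, hits in branch_hits.items()}
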