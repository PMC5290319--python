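"""Detection of polyphyletic (mixed) samples and separation into subclones.

Evolutionary conflicts whose reliability score exceeds what presence-noise
alone produces may indicate that a sample harbours two subclones with
distinct evolutionary trajectories.  The noise threshold is the 95th
percentile of the top conflicted-pattern score under a permutation null in
which each variant's per-sample presence probabilities are shuffled across
samples.  A flagged conflict splits every witness sample (confidently
carrying both sides of the conflict) into two pseudo-samples and reassigns
the conflicting pattern to the second one.

This module is an admissible reconstruction of the original procedure, whose
exact iteration rules are not published; defaults are conservative (at most
two subclones per sample, five iterations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from phyloseed.bayes import PresenceTable
from phyloseed.cover import CoverSolution
from phyloseed.datamodel import PatientConfig
from phyloseed.patterns import ConflictGraph, log_likelihood_matrix, reliability_scores

__all__ = ["SubcloneSplit", "detect_subclones", "conflict_noise_threshold"]

MAX_ITERATIONS = 5


@dataclass
class SubcloneSplit:
    """Result of subclone separation.

    ``pseudo_samples`` maps each original sample to its pseudo-sample names
    (one entry = no split); ``assignments`` are pattern bitmasks over the
    pseudo-sample columns ``columns``.
    """

    pseudo_samples: dict
    columns: list
    assignments: np.ndarray
    noise_threshold: float
    split_events: list = field(default_factory=list)
    unresolved: list = field(default_factory=list)

    @property
    def any_split(self) -> bool:
        return any(len(v) > 1 for v in self.pseudo_samples.values())


def conflict_noise_threshold(graph: ConflictGraph, table: PresenceTable, config: PatientConfig, percentile: float = 95.0) -> float:
    """Permutation-null threshold for conflicted-pattern reliability scores.

    Each permutation shuffles every variant's presence probabilities across
    samples independently, recomputes the scores of the conflicted patterns,
    and records the maximum; the threshold is the given percentile over
    permutations.
    """
    rng = np.random.default_rng(config.rng_seed + 101)
    conflicted = np.zeros(graph.n_nodes, dtype=bool)
    ei, ej = graph.edges
    conflicted[np.asarray(ei, dtype=np.int64)] = True
    conflicted[np.asarray(ej, dtype=np.int64)] = True
    if not conflicted.any():
        return np.inf
    masks = graph.masks[conflicted]
    stats = np.empty(config.subclone_permutations)
    m, n = table.p.shape
    for it in range(config.subclone_permutations):
        perm_p = table.p.copy()
        for i in range(m):
            perm_p[i] = perm_p[i, rng.permutation(n)]
        perm_table = PresenceTable(p=perm_p, q=1.0 - perm_p, samples=list(table.samples), variants=list(table.variants))
        stats[it] = reliability_scores(perm_table, masks).max()
    return float(np.percentile(stats, percentile))


def _compatible_family(masks, n_cols: int) -> bool:
    distinct = sorted({int(m) for m in masks if m})
    for a in range(len(distinct)):
        for b in range(a + 1, len(distinct)):
            u, v = distinct[a], distinct[b]
            if (u & ~v) and (v & ~u) and (u & v):
                return False
    return True


def detect_subclones(graph: ConflictGraph, solution: CoverSolution, table: PresenceTable, config: PatientConfig | None = None, threshold: float | None = None) -> SubcloneSplit:
    """Split mixed samples indicated by high-reliability removed patterns.

    Removed (covered) patterns are visited in decreasing reliability; one
    whose score exceeds the noise threshold is matched with its strongest
    kept conflictor, and every sample confidently carrying both sides is
    split into two pseudo-samples.  Variants whose maximum-likelihood pattern
    is the conflicting one move to the second pseudo-sample.
    """
    config = config or PatientConfig()
    n = table.n_samples
    if threshold is None:
        threshold = conflict_noise_threshold(graph, table, config)

    mask_index = {int(m): i for i, m in enumerate(graph.masks)}
    weights = graph.weights
    loglik = log_likelihood_matrix(table, graph.masks)
    ml_pattern = graph.masks[np.argmax(loglik, axis=1)]

    # start from the conflict-free assignment of the cover solution
    from phyloseed.cover import assign_variants

    base_assign = assign_variants(solution, table)

    pseudo: dict[str, list[str]] = {s: [s] for s in table.samples}
    # per variant: current mask over pseudo columns; columns start as originals
    columns = list(table.samples)
    assignments = base_assign.copy()
    split_events: list[dict] = []
    unresolved: list[int] = []

    removed_sorted = sorted(
        (int(m) for m in solution.removed if int(m) in mask_index),
        key=lambda m: -weights[mask_index[m]],
    )
    split_samples: set[int] = set()
    iterations = 0
    for v in removed_sorted:
        if iterations >= MAX_ITERATIONS:
            unresolved.extend(m for m in removed_sorted if weights[mask_index[m]] > threshold and m != v)
            break
        w_v = weights[mask_index[v]]
        if w_v <= threshold:
            continue
        # strongest kept conflictor
        conflictors = [
            int(k)
            for k in solution.kept
            if (v & ~int(k)) and (int(k) & ~v) and (v & int(k)) and int(k) in mask_index
        ]
        if not conflictors:
            continue
        w = max(conflictors, key=lambda k: weights[mask_index[k]])
        supporters_v = np.flatnonzero(ml_pattern == v)
        supporters_w = np.flatnonzero(ml_pattern == w)
        witness = []
        for s in range(n):
            if not ((v >> s) & 1 and (w >> s) & 1) or s in split_samples:
                continue
            conf_v = any(table.p[i, s] > config.subclone_presence_threshold for i in supporters_v)
            conf_w = any(table.p[i, s] > config.subclone_presence_threshold for i in supporters_w)
            if conf_v and conf_w:
                witness.append(s)
        if not witness:
            unresolved.append(v)
            continue
        iterations += 1
        # restore the conflicting pattern for its supporters before moving
        # the witness-sample bits to the new pseudo-sample columns
        for i in supporters_v:
            assignments[i] = v
        for s in witness:
            split_samples.add(s)
            name = table.samples[s]
            pseudo[name] = [f"{name} SC 1", f"{name} SC 2"]
            new_col = len(columns)
            columns.append(f"{name} SC 2")
            columns[s] = f"{name} SC 1"
            s_bit = 1 << s
            new_bit = 1 << new_col
            for i in range(len(assignments)):
                mask = int(assignments[i])
                if not mask & s_bit:
                    continue
                if ml_pattern[i] == v:
                    # the conflicting lineage lives in the second subclone
                    assignments[i] = (mask & ~s_bit) | new_bit
                elif (mask & v) == v:
                    # ancestors (supersets of v) span both subclones
                    assignments[i] = mask | new_bit
            split_events.append({"sample": name, "removed_pattern": int(v), "kept_pattern": int(w)})

    if not _compatible_family(assignments, len(columns)):
        # conservative fallback: report the attempt but keep original masks
        unresolved.append(-1)
        assignments = base_assign.copy()
        columns = list(table.samples)
        pseudo = {s: [s] for s in table.samples}
        split_events = []
    return SubcloneSplit(
        pseudo_samples=pseudo,
        columns=columns,
        assignments=assignments,
        noise_threshold=float(threshold),
        split_events=split_events,
        unresolved=unresolved,
    )
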