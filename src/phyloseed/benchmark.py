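"""Benchmark driver: simulate, sequence, run the pipeline, score.

Replicates where some true branch received no detected variant are excluded
from the error statistics (and counted), mirroring the conditioning used in
the simulation benchmarks.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from phyloseed.datamodel import PatientConfig
from phyloseed.metrics import ancestry_matrix, branching_error, fill_missing_pairs, mutation_matrix_error, neighbour_joining_baseline
from phyloseed.pipeline import run_analysis
from phyloseed.simulate import SimParams, sequence_samples, simulate_tumor
from phyloseed.tree import build_tree

__all__ = ["run_replicate", "run_grid", "score_reconstruction"]


def _mask_to_clades(masks, samples) -> set:
    n = len(samples)
    out = set()
    for mask in {int(m) for m in masks}:
        size = bin(mask).count("1")
        if 1 < size < n:
            out.add(frozenset(samples[s] for s in range(n) if (mask >> s) & 1))
    return out


def score_reconstruction(tumor, matrix, truth, result, include_nj: bool = False) -> dict:
    """Branching error and mutation-matrix error for one replicate."""
    samples = truth["samples"]
    n = len(samples)
    clonal = tumor.clonal_masks()
    full = (1 << n) - 1

    true_tree = build_tree(
        [int(m) for m in clonal if m], n, samples
    )
    true_clades = true_tree.clades()

    # conditioning: every true branch must carry >= 1 detected variant
    detected_ids = set(truth["mutation_ids"])
    branch_variant_masks = {int(clonal[mu]) for mu in detected_ids}
    informative_branches = {int(m) for m in clonal if 0 < int(m) < full}
    conditioned = informative_branches <= branch_variant_masks

    be = branching_error(true_clades, result.tree.clades())

    # mutation matrix error over truth's parsimony-informative mutations
    informative = [mu for mu in range(tumor.n_mutations) if 0 < int(clonal[mu]) < full and tumor.mutation_kind[mu] == "snv"]
    out = {
        "branching_error": be,
        "conditioned": conditioned,
        "n_variants_detected": matrix.n_variants,
        "n_informative": len(informative),
    }
    if len(informative) >= 2:
        A = tumor.parental_matrix(informative)
        name_to_row = {v: i for i, v in enumerate(matrix.variants)}
        k = len(informative)
        masks_hat = np.zeros(k, dtype=np.int64)
        known = np.zeros((k, k), dtype=bool)
        has_info = np.zeros(k, dtype=bool)
        for a, mu in enumerate(informative):
            row = name_to_row.get(f"m{mu}")
            if row is not None and int(result.assignments[row]) != 0:
                masks_hat[a] = int(result.assignments[row])
                has_info[a] = True
        known = has_info[:, None] & has_info[None, :]
        A_hat = ancestry_matrix(masks_hat)
        A_hat = fill_missing_pairs(A, A_hat, known)
        out["mutation_matrix_error"] = mutation_matrix_error(A, A_hat)
    else:
        out["mutation_matrix_error"] = np.nan
    if include_nj:
        nj_clades, _ = neighbour_joining_baseline(result.table)
        out["nj_branching_error"] = branching_error(true_clades, nj_clades)
    return out


def run_replicate(params: SimParams, config: PatientConfig | None = None, include_nj: bool = False, tumor=None) -> dict:
    """Simulate one tumour (unless provided), sequence it and run the
    pipeline; returns the metric row."""
    if tumor is None:
        tumor = simulate_tumor(params)
    rng = np.random.default_rng(params.rng_seed + 7)
    matrix, truth = sequence_samples(tumor, params, rng)
    config = config or PatientConfig(e=params.e_seq, rng_seed=params.rng_seed)
    result = run_analysis(matrix, config, bootstrap=0)
    row = score_reconstruction(tumor, matrix, truth, result, include_nj=include_nj)
    row.update(
        {
            "depth": params.mean_depth,
            "purity": params.purity,
            "m_mets": params.m_mets,
            "polyphyletic": params.polyphyletic_count,
            "seed": params.rng_seed,
        }
    )
    return row


def run_grid(depths, purities, reps: int, base_params: SimParams | None = None, seed: int = 0, include_nj: bool = False, reuse_tumors: bool = True) -> pd.DataFrame:
    """Run a (depth x purity) benchmark grid.

    With ``reuse_tumors`` the same simulated tumour per replicate index is
    re-sequenced under every scenario, which isolates the effect of depth and
    purity and keeps desk-scale runtimes low.
    """
    base = base_params or SimParams()
    rows = []
    tumors = {}
    for rep in range(reps):
        rep_seed = seed + 1000 * rep
        if reuse_tumors:
            tumors[rep] = simulate_tumor(replace(base, rng_seed=rep_seed))
        for depth in depths:
            for purity in purities:
                params = replace(base, mean_depth=depth, purity=purity, rng_seed=rep_seed)
                tumor = tumors.get(rep)
                row = run_replicate(params, include_nj=include_nj, tumor=tumor)
                row["replicate"] = rep
                rows.append(row)
    return pd.DataFrame(rows)
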