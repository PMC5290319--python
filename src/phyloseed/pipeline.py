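"""End-to-end orchestration: counts -> purity -> posteriors -> conflict graph
-> vertex cover -> tree -> artifacts -> bootstrap -> (optional) subclones."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from phyloseed.baseline import (
    bh_critical_value,
    binary_classification,
    binary_pvalues,
    count_incompatible_variants,
)
from phyloseed.bayes import PresenceTable, presence_table
from phyloseed.cover import CoverSolution, assign_variants, solve_min_vertex_cover
from phyloseed.datamodel import PatientConfig, VariantCallMatrix, estimate_purity
from phyloseed.patterns import ConflictGraph, build_conflict_graph
from phyloseed.tree import ArtifactReport, Phylogeny, bootstrap_support, build_tree, classify_artifacts

__all__ = ["AnalysisResult", "run_analysis", "write_outputs"]

# conflicted patterns with reliability below this are freely removable in the
# MILP (variable reduction; see cover.solve_min_vertex_cover)
ZERO_WEIGHT_TOL = 1e-10


@dataclass
class AnalysisResult:
    matrix: VariantCallMatrix
    config: PatientConfig
    table: PresenceTable
    graph: ConflictGraph
    solution: CoverSolution
    assignments: np.ndarray
    tree: Phylogeny
    baseline: np.ndarray
    baseline_incompatible: int
    artifact_report: ArtifactReport
    branch_support: dict | None = None
    subclone_split: object | None = None
    purity_estimated: bool = False

    def summary(self) -> dict:
        counts = {k: int(v) for k, v in sorted(self.artifact_report.counts.items())}
        support = None
        if self.branch_support is not None:
            support = {
                format(mask, f"0{self.matrix.n_samples}b")[::-1]: round(val, 6)
                for mask, val in sorted(self.branch_support.items())
            }
        return {
            "patient": self.matrix.patient_id,
            "n_samples": self.matrix.n_samples,
            "n_variants": self.matrix.n_variants,
            "samples": list(self.matrix.samples),
            "purity": [round(float(g), 6) for g in self.matrix.purity],
            "purity_estimated": self.purity_estimated,
            "config": {
                "c0": self.config.c0,
                "e": self.config.e,
                "f_absent": self.config.f_absent,
                "p_fpr": self.config.p_fpr,
                "fdr": self.config.fdr,
                "rng_seed": self.config.rng_seed,
                "error_channel": self.config.error_channel,
            },
            "conflict_graph": {
                "n_nodes": int(self.graph.n_nodes),
                "n_edges": int(self.graph.n_edges),
                "restricted": bool(self.graph.restricted),
            },
            "vertex_cover": {
                "objective_nats": round(float(self.solution.objective), 10),
                "n_removed": len(self.solution.removed),
                "proven_optimal": bool(self.solution.proven_optimal),
            },
            "baseline_incompatible_variants": int(self.baseline_incompatible),
            "artifacts": counts,
            "n_artifacts": int(self.artifact_report.n_artifacts),
            "branch_support": support,
            "subclones": None
            if self.subclone_split is None
            else {
                "splits": self.subclone_split.split_events,
                "noise_threshold": self.subclone_split.noise_threshold,
                "pseudo_samples": self.subclone_split.pseudo_samples,
            },
            "newick": self.tree.newick(),
        }


def run_analysis(
    matrix: VariantCallMatrix,
    config: PatientConfig | None = None,
    bootstrap: int | None = None,
    subclones: bool = False,
) -> AnalysisResult:
    """Run the full inference pipeline on a variant call matrix.

    ``bootstrap`` overrides ``config.bootstrap_reps`` (0 disables support
    estimation); ``subclones`` enables polyphyletic-sample separation.
    Purities are estimated from founder variants when absent.
    """
    config = config or PatientConfig()
    matrix = matrix.filter_samples(config.min_median_coverage)
    purity_estimated = False
    if matrix.purity is None:
        matrix.purity = estimate_purity(matrix, config)
        purity_estimated = True

    table = presence_table(matrix, config)
    graph = build_conflict_graph(table, config.max_enumeration_samples)
    solution = solve_min_vertex_cover(graph, zero_weight_tol=ZERO_WEIGHT_TOL)
    assignments = assign_variants(solution, table)
    tree = build_tree(assignments, matrix.n_samples, matrix.samples, matrix.variants)

    baseline = binary_classification(matrix, config)
    baseline_incompatible = count_incompatible_variants(baseline)
    alpha = bh_critical_value(binary_pvalues(matrix, config).ravel(), config.fdr)
    report = classify_artifacts(assignments, baseline, matrix, config, bh_alpha=alpha if alpha > 0 else config.fdr)

    support = None
    reps = config.bootstrap_reps if bootstrap is None else bootstrap
    if reps and reps > 0:
        support = bootstrap_support(matrix, config, reps=reps, table=table)
        _annotate_support(tree, support)

    split = None
    if subclones:
        from phyloseed.subclones import detect_subclones

        split = detect_subclones(graph, solution, table, config)

    return AnalysisResult(
        matrix=matrix,
        config=config,
        table=table,
        graph=graph,
        solution=solution,
        assignments=assignments,
        tree=tree,
        baseline=baseline,
        baseline_incompatible=baseline_incompatible,
        artifact_report=report,
        branch_support=support,
        subclone_split=split,
        purity_estimated=purity_estimated,
    )


def _annotate_support(tree: Phylogeny, support: dict) -> None:
    for node in tree.root.walk():
        if node.mask in support:
            node.support = support[node.mask]


def write_outputs(result: AnalysisResult, outdir, prefix: str = "phyloseed") -> dict:
    """Write Newick, JSON summary, artifact TSV, baseline TSV and presence TSV.

    Returns the paths written.  Summaries are deterministic (sorted keys) so
    identical inputs and seeds produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["newick"] = outdir / f"{prefix}_tree.nwk"
    paths["newick"].write_text(result.tree.newick() + "\n")

    paths["summary"] = outdir / f"{prefix}_summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(result.summary(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    paths["artifacts"] = outdir / f"{prefix}_artifacts.tsv"
    result.artifact_report.to_frame(result.matrix).to_csv(paths["artifacts"], sep="\t", index=False)

    import pandas as pd

    paths["baseline"] = outdir / f"{prefix}_baseline.tsv"
    pd.DataFrame(
        result.baseline.astype(int), index=result.matrix.variants, columns=result.matrix.samples
    ).rename_axis("variant").to_csv(paths["baseline"], sep="\t")

    paths["presence"] = outdir / f"{prefix}_presence.tsv"
    result.table.to_frame().rename_axis("variant").round(6).to_csv(paths["presence"], sep="\t")

    paths["conflicts"] = outdir / f"{prefix}_conflict_graph.tsv"
    result.graph.write_edge_list(paths["conflicts"])

    variant_rows = []
    n = result.matrix.n_samples
    for i, mask in enumerate(result.assignments):
        variant_rows.append(
            {
                "variant": result.matrix.variants[i],
                "pattern": format(int(mask), f"0{n}b")[::-1],
                "samples": ";".join(
                    result.matrix.samples[s] for s in range(n) if (int(mask) >> s) & 1
                ),
            }
        )
    paths["patterns"] = outdir / f"{prefix}_variant_patterns.tsv"
    pd.DataFrame(variant_rows).to_csv(paths["patterns"], sep="\t", index=False)
    return paths
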