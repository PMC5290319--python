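# phyloseed

Reconstruction of metastatic seeding phylogenies from multi-sample tumour
sequencing read counts.

Given per-variant / per-sample counts of variant-supporting reads (K) and
total coverage (N) from spatially distinct tumour samples, phyloseed:

1. computes Bayesian posterior probabilities that each variant is present or
   absent in each sample, under a binomial read-error model with a
   spike-and-slab prior whose support scales with the sample's neoplastic
   cell content (purity);
2. scores every candidate mutation pattern (sample subset) with a
   reliability weight aggregating the evidence of all variants, and builds
   the evolutionary conflict graph whose edges join pattern pairs that
   cannot coexist on one perfect-and-persistent phylogeny;
3. removes the minimum-weight set of conflicting patterns via an exact
   weighted minimum-vertex-cover integer program (HiGHS through SciPy), and
   assigns each variant to its most likely surviving pattern;
4. derives the unique rooted phylogeny, flags putative sequencing artifacts
   (false-positives, under-/well-powered false-negatives) by comparison with
   a conventional binomial-test + Benjamini–Hochberg baseline, and estimates
   branch support by bootstrapping variants;
5. optionally detects polyphyletic (mixed) samples from high-reliability
   conflicts and splits them into subclones.

A stochastic multi-type branching-process simulator of primary growth,
metastatic seeding and in-silico sequencing, plus benchmarking error metrics
(branching error, mutation-matrix error score, neighbour-joining baseline),
are included for validation.

## CLI

```sh
# full analysis from a TSV pair (first column = variant key, remaining
# columns = samples); writes Newick tree, JSON summary, artifact report,
# baseline/presence matrices and the conflict-graph edge list
phyloseed run --mut-reads mut.tsv --coverage cov.tsv \
    --purity-file purity.tsv --boot 1000 --seed 1 --outdir out/

# from matched tumour(-normal) VCFs with AD fields
phyloseed run --vcf t1.vcf --vcf t2.vcf --normal-sample NORMAL --outdir out/

# simulate a metastatic tumour; writes the same TSV pair + ground-truth JSON
phyloseed simulate --depth 200 --purity 0.55 --mets 6 --seed 7 --outdir sim/

# scaled-down benchmark grid; tidy metrics TSV
phyloseed benchmark --depths 25,400 --purities 0.15,0.55,0.95 --reps 5 \
    --out benchmark.tsv
```

Useful `run` flags: `--fpr` (baseline per-read false-positive rate, default
0.005), `--fdr` (0.05), `--f-absent` (0.05), `--c0`, `--error-rate`,
`--min-median-coverage`, `--subclones`, `--plots`. Without a purity file,
purities are estimated as 2× the median VAF of founder variants per sample.

## Package layout

| module | role |
| --- | --- |
| `phyloseed.datamodel` | count-table / VCF / purity I/O, `VariantCallMatrix`, `PatientConfig` |
| `phyloseed.bayes` | per-cell presence posteriors (`PresenceTable`) |
| `phyloseed.patterns` | pattern likelihoods, reliability scores, conflict graph |
| `phyloseed.cover` | weighted minimum-vertex-cover MILP, variant assignment |
| `phyloseed.tree` | phylogeny construction, artifact classification, bootstrap |
| `phyloseed.subclones` | polyphyletic-sample detection and splitting |
| `phyloseed.baseline` | binomial test + BH step-up, binary compatibility count |
| `phyloseed.simulate` | branching-process metastasis simulator + in-silico sequencing |
| `phyloseed.metrics` / `phyloseed.benchmark` | error metrics, NJ baseline, grid driver |
| `phyloseed.pipeline` / `phyloseed.cli` | orchestration, report files, CLI |
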