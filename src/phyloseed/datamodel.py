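"""Data model and I/O for multi-sample variant read-count data.

Variant identity is ``(chrom, pos, ref, alt)`` with 1-based positions (VCF
convention).  Count tables are tab-separated with a header row of sample names
and one row per variant; the first column holds the variant key.  Extra,
non-numeric annotation columns (e.g. a gene-name column) are tolerated and
carried along as metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VariantCallMatrix",
    "PatientConfig",
    "ParseError",
    "read_count_tables",
    "read_vcf_pair",
    "read_purity_table",
    "estimate_purity",
]


class ParseError(ValueError):
    """Structured error for malformed or inconsistent input tables."""


@dataclass(frozen=True)
class PatientConfig:
    """Analysis parameters.

    Attributes
    ----------
    c0 : float
        Prior probability that the variant allele frequency is exactly zero.
    e : float
        Sequencing error rate per read.
    f_absent : float
        Maximal VAF still considered "absent".
    p_fpr : float
        Per-read false-positive rate of the binary baseline's binomial test.
    fdr : float
        Target false-discovery rate for the pooled step-up correction.
    min_median_coverage : int
        Samples whose median coverage falls below this are dropped (0 = off).
    bootstrap_reps : int
        Number of bootstrap replicates for branch support.
    rng_seed : int
        Seed for every stochastic step.
    error_channel : str
        ``"third"``: an erroneous read shows the specific alternate base with
        probability e/3; ``"full"``: with probability e.
    prior_eps : float
        Guard added to ``f_absent`` for the minimal support of the presence
        prior in very low-purity samples.
    max_enumeration_samples : int
        Full 2^n pattern enumeration is used up to this many samples.
    subclone_presence_threshold : float
        Posterior presence needed in a sample for subclone splitting.
    subclone_permutations : int
        Permutations for the subclone noise-threshold null.
    min_variant_reads : int
        Supporting reads deemed necessary for confident detection (used for
        the under/well-powered false-negative split); relaxed to
        ``min_variant_reads_low_cov`` when a sample's median coverage is <= 25.
    """

    c0: float = 0.5
    e: float = 0.005
    f_absent: float = 0.05
    p_fpr: float = 0.005
    fdr: float = 0.05
    min_median_coverage: int = 0
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    error_channel: str = "third"
    prior_eps: float = 0.01
    max_enumeration_samples: int = 14
    subclone_presence_threshold: float = 0.8
    subclone_permutations: int = 100
    min_variant_reads: int = 4
    min_variant_reads_low_cov: int = 2

    def __post_init__(self) -> None:
        for name in ("c0", "e", "f_absent", "p_fpr", "fdr"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if self.error_channel not in ("third", "full"):
            raise ValueError(f"unknown error_channel {self.error_channel!r}")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be non-negative")


@dataclass
class VariantCallMatrix:
    """Per-patient matrix of variant-supporting reads and total coverage.

    ``mut_reads`` (K) and ``coverage`` (N) are m x n integer matrices over m
    variants and n samples; ``purity`` maps each sample to its neoplastic cell
    content in (0, 1].
    """

    patient_id: str
    samples: list[str]
    variants: list[str]
    mut_reads: np.ndarray
    coverage: np.ndarray
    purity: np.ndarray | None = None
    gene_names: list[str] | None = None
    annotations: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mut_reads = np.asarray(self.mut_reads, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        m, n = self.mut_reads.shape
        if self.coverage.shape != (m, n):
            raise ValueError("mut_reads and coverage must share dimensions")
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError("label lengths must match matrix dimensions")
        if n < 2:
            raise ValueError("at least two samples are required")
        if m < 1:
            raise ValueError("at least one variant is required")
        if (self.mut_reads < 0).any() or (self.coverage < 0).any():
            raise ValueError("read counts must be non-negative")
        if (self.mut_reads > self.coverage).any():
            i, j = np.argwhere(self.mut_reads > self.coverage)[0]
            raise ValueError(
                f"mut_reads exceeds coverage for variant {self.variants[i]!r} "
                f"in sample {self.samples[j]!r}"
            )
        if self.purity is not None:
            self.purity = np.asarray(self.purity, dtype=float)
            if self.purity.shape != (n,):
                raise ValueError("purity must have one entry per sample")
            if ((self.purity <= 0) | (self.purity > 1)).any():
                raise ValueError("purity values must lie in (0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def vaf(self) -> np.ndarray:
        """Observed variant allele frequencies (0 where coverage is 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.coverage > 0, self.mut_reads / np.maximum(self.coverage, 1), 0.0)
        return f

    def filter_samples(self, min_median_coverage: int) -> "VariantCallMatrix":
        """Drop samples with median coverage below the threshold."""
        if min_median_coverage <= 0:
            return self
        keep = [j for j in range(self.n_samples) if np.median(self.coverage[:, j]) >= min_median_coverage]
        if len(keep) == self.n_samples:
            return self
        if len(keep) < 2:
            raise ValueError("fewer than two samples pass the median-coverage filter")
        return replace(
            self,
            samples=[self.samples[j] for j in keep],
            mut_reads=self.mut_reads[:, keep],
            coverage=self.coverage[:, keep],
            purity=None if self.purity is None else self.purity[keep],
        )

    def write_count_tables(self, mut_reads_path, coverage_path) -> None:
        """Write the K and N matrices as the same TSV layout we read."""
        for path, mat in ((mut_reads_path, self.mut_reads), (coverage_path, self.coverage)):
            df = pd.DataFrame(mat, index=self.variants, columns=self.samples)
            df.index.name = "variant"
            df.to_csv(path, sep="\t")


def _read_count_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a variant-key column plus sample columns")
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated variant key {dup!r}")
    # annotation columns are those that fail to parse as integers in any row
    numeric = {}
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.notna().all():
            numeric[col] = parsed.astype(np.int64)
    ann_cols = [c for c in df.columns if c not in numeric]
    counts = pd.DataFrame(numeric, index=df.index)
    if counts.shape[1] < 2:
        raise ParseError(f"{path}: fewer than two parseable sample columns")
    counts.attrs["annotations"] = df[ann_cols] if ann_cols else None
    return counts


def read_count_tables(mut_reads_path, coverage_path, patient_id: str = "patient") -> VariantCallMatrix:
    """Load a mut-reads/coverage TSV pair into a :class:`VariantCallMatrix`.

    Both files must carry identical variant keys and sample columns; rows with
    unparseable cells in sample columns are rejected by the integer parse.
    """
    kdf = _read_count_tsv(mut_reads_path)
    ndf = _read_count_tsv(coverage_path)
    if list(kdf.columns) != list(ndf.columns):
        missing = set(kdf.columns).symmetric_difference(ndf.columns)
        raise ParseError(
            f"sample columns differ between {mut_reads_path} and {coverage_path}: "
            f"{sorted(missing)}"
        )
    if list(kdf.index) != list(ndf.index):
        missing = set(kdf.index).symmetric_difference(ndf.index)
        offender = sorted(missing)[0] if missing else "(ordering)"
        raise ParseError(
            f"variant keys differ between {mut_reads_path} and {coverage_path}: "
            f"first offender {offender!r}"
        )
    ann = kdf.attrs.get("annotations")
    gene_names = None
    if ann is not None:
        for col in ann.columns:
            if col.lower() in ("gene", "gene_name", "genename"):
                gene_names = ann[col].tolist()
                break
    return VariantCallMatrix(
        patient_id=patient_id,
        samples=list(kdf.columns),
        variants=list(kdf.index),
        mut_reads=kdf.to_numpy(),
        coverage=ndf.to_numpy(),
        gene_names=gene_names,
        annotations=ann,
    )


def read_vcf_pair(vcf_paths, patient_id: str = "patient", normal_sample: str | None = None) -> VariantCallMatrix:
    """Merge matched tumour(-normal) VCFs into a :class:`VariantCallMatrix`.

    Each VCF contributes one tumour sample (or several, for multi-sample
    VCFs).  Variants are identified by ``(chrom, pos, ref, alt)``; the same
    locus with different alternate alleles yields distinct rows.  Allelic
    depths are taken from the per-sample ``AD`` field.  If ``normal_sample``
    is given, variants with any supporting read in that sample are dropped
    (somatic filter) and the normal column is excluded from the matrix.
    Missing (variant, sample) entries get coverage 0.
    """
    from cyvcf2 import VCF

    counts: dict[tuple[str, int, str, str], dict[str, tuple[int, int]]] = {}
    ref_seen: dict[tuple[str, int], str] = {}
    sample_order: list[str] = []
    for path in vcf_paths:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        if not samples:
            raise ParseError(f"{path}: VCF has no sample columns")
        for s in samples:
            if s not in sample_order:
                sample_order.append(s)
        for rec in vcf:
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            if ad is None:
                raise ParseError(f"{path}: record {rec.CHROM}:{rec.POS} lacks the AD allelic-depth field")
            locus = (rec.CHROM, rec.POS)
            if locus in ref_seen and ref_seen[locus] != rec.REF:
                raise ParseError(
                    f"inconsistent reference alleles at {rec.CHROM}:{rec.POS}: "
                    f"{ref_seen[locus]!r} vs {rec.REF!r}"
                )
            ref_seen[locus] = rec.REF
            for ai, alt in enumerate(rec.ALT):
                key = (rec.CHROM, rec.POS, rec.REF, alt)
                row = counts.setdefault(key, {})
                for si, s in enumerate(samples):
                    depths = ad[si]
                    k = int(depths[1 + ai]) if len(depths) > 1 + ai and depths[1 + ai] >= 0 else 0
                    n = int(sum(d for d in depths if d >= 0))
                    if s in row:
                        k0, n0 = row[s]
                        row[s] = (k0 + k, n0 + n)
                    else:
                        row[s] = (k, n)
    if normal_sample is not None:
        if normal_sample not in sample_order:
            raise ParseError(f"normal sample {normal_sample!r} not found in the VCFs")
        counts = {
            key: row
            for key, row in counts.items()
            if row.get(normal_sample, (0, 0))[0] == 0
        }
        sample_order = [s for s in sample_order if s != normal_sample]
    if not counts:
        raise ParseError("no somatic variants remain after filtering")
    keys = sorted(counts, key=lambda k: (k[0], k[1], k[2], k[3]))
    m, n = len(keys), len(sample_order)
    K = np.zeros((m, n), dtype=np.int64)
    N = np.zeros((m, n), dtype=np.int64)
    for i, key in enumerate(keys):
        for j, s in enumerate(sample_order):
            k, nn = counts[key].get(s, (0, 0))
            K[i, j], N[i, j] = k, nn
    variants = [f"{c}:{p}:{r}>{a}" for c, p, r, a in keys]
    return VariantCallMatrix(patient_id, sample_order, variants, K, N)


def read_purity_table(path, samples: list[str]) -> np.ndarray:
    """Read a two-column sample/purity TSV aligned to ``samples``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "purity"], comment="#", dtype={0: str})
    mapping = dict(zip(df["sample"].astype(str), df["purity"].astype(float)))
    missing = [s for s in samples if s not in mapping]
    if missing:
        raise ParseError(f"purity table {path} lacks samples: {missing}")
    return np.array([mapping[s] for s in samples], dtype=float)


def estimate_purity(matrix: VariantCallMatrix, config: PatientConfig | None = None) -> np.ndarray:
    """Estimate per-sample neoplastic cell content from founder variants.

    A variant is a putative founder when the binary baseline classifies it
    present in every sample; under a heterozygous-diploid assumption the
    clonal VAF is purity/2, so the estimator is ``min(1, 2 * median founder
    VAF)`` per sample.  With no founders it falls back to all variants and
    warns.
    """
    from phyloseed.baseline import binary_classification

    config = config or PatientConfig()
    present = binary_classification(matrix, config)
    founders = present.all(axis=1)
    vaf = matrix.vaf()
    if founders.any():
        rows = vaf[founders]
    else:
        warnings.warn(
            "no founder variants found; estimating purity from all variants",
            stacklevel=2,
        )
        rows = vaf
    gamma = np.minimum(1.0, 2.0 * np.median(rows, axis=0))
    return np.clip(gamma, 1e-3, 1.0)
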