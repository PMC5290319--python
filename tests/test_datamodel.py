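import numpy as np
import pytest

from phyloseed import PatientConfig, VariantCallMatrix, estimate_purity, read_count_tables, read_vcf_pair
from phyloseed.datamodel import ParseError, read_purity_table


def write_pair(tmp_path, variants, samples, K, N):
    mut, cov = tmp_path / "mut.tsv", tmp_path / "cov.tsv"
    header = "variant\t" + "\t".join(samples)
    mut.write_text("\n".join([header] + [v + "\t" + "\t".join(str(x) for x in row) for v, row in zip(variants, K)]) + "\n")
    cov.write_text("\n".join([header] + [v + "\t" + "\t".join(str(x) for x in row) for v, row in zip(variants, N)]) + "\n")
    return mut, cov


class TestCountTables:
    def test_round_trip_2x2(self, tmp_path):
        mut, cov = write_pair(tmp_path, ["1:5:A>T", "2:9:C>G"], ["S1", "S2"], [[3, 0], [5, 7]], [[10, 11], [12, 13]])
        mat = read_count_tables(mut, cov)
        assert mat.samples == ["S1", "S2"]
        assert mat.variants == ["1:5:A>T", "2:9:C>G"]
        np.testing.assert_array_equal(mat.mut_reads, [[3, 0], [5, 7]])
        np.testing.assert_array_equal(mat.coverage, [[10, 11], [12, 13]])
        out_m, out_c = tmp_path / "o1.tsv", tmp_path / "o2.tsv"
        mat.write_count_tables(out_m, out_c)
        again = read_count_tables(out_m, out_c)
        np.testing.assert_array_equal(again.mut_reads, mat.mut_reads)
        np.testing.assert_array_equal(again.coverage, mat.coverage)
        assert again.variants == mat.variants and again.samples == mat.samples

    def test_missing_sample_column_rejected(self, tmp_path):
        mut, _ = write_pair(tmp_path, ["v1"], ["S1", "S2"], [[1, 2]], [[5, 5]])
        cov = tmp_path / "cov2.tsv"
        cov.write_text("variant\tS1\nv1\t5\n")
        with pytest.raises(ParseError, match="S2|sample"):
            read_count_tables(mut, cov)

    def test_key_mismatch_names_offender(self, tmp_path):
        mut, cov = write_pair(tmp_path, ["v1", "v2"], ["S1", "S2"], [[1, 2], [0, 1]], [[5, 5], [9, 9]])
        cov.write_text("variant\tS1\tS2\nv1\t5\t5\nvX\t9\t9\n")
        with pytest.raises(ParseError, match="v2|vX"):
            read_count_tables(mut, cov)

    def test_annotation_columns_tolerated(self, tmp_path):
        mut = tmp_path / "mut.tsv"
        cov = tmp_path / "cov.tsv"
        mut.write_text("variant\tGene\tS1\tS2\nv1\tKRAS\t3\t4\n")
        cov.write_text("variant\tGene\tS1\tS2\nv1\tKRAS\t8\t9\n")
        mat = read_count_tables(mut, cov)
        assert mat.samples == ["S1", "S2"]
        assert mat.gene_names == ["KRAS"]

    def test_mut_reads_exceeding_coverage_rejected(self):
        with pytest.raises(ValueError, match="exceeds coverage"):
            VariantCallMatrix("p", ["a", "b"], ["v"], [[5, 0]], [[3, 1]])


class TestVcf:
    def write_vcf(self, path, sample, records):
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT", sample]),
        ]
        for chrom, pos, ref, alt, ad in records:
            lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t0/1:{ad}")
        path.write_text("\n".join(lines) + "\n")

    def test_ad_extraction(self, tmp_path):
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        self.write_vcf(a, "T1", [("1", 100, "A", "T", "3,7")])
        self.write_vcf(b, "T2", [("1", 100, "A", "T", "9,1")])
        mat = read_vcf_pair([a, b], patient_id="p")
        # AD=3,7 -> K=7 (alt depth), N=10 (total depth)
        assert mat.mut_reads[0, 0] == 7
        assert mat.coverage[0, 0] == 10

    def test_two_vcfs_disjoint_union(self, tmp_path):
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        self.write_vcf(a, "T1", [("1", 100, "A", "T", "3,7")])
        self.write_vcf(b, "T2", [("2", 200, "C", "G", "10,5")])
        mat = read_vcf_pair([a, b])
        assert mat.variants == ["1:100:A>T", "2:200:C>G"]
        np.testing.assert_array_equal(mat.mut_reads, [[7, 0], [0, 5]])
        np.testing.assert_array_equal(mat.coverage, [[10, 0], [0, 15]])

    def test_same_locus_distinct_alts(self, tmp_path):
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        self.write_vcf(a, "T1", [("1", 100, "A", "T", "3,7")])
        self.write_vcf(b, "T2", [("1", 100, "A", "G", "4,6")])
        mat = read_vcf_pair([a, b])
        assert sorted(mat.variants) == ["1:100:A>G", "1:100:A>T"]

    def test_inconsistent_ref_rejected(self, tmp_path):
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        self.write_vcf(a, "T1", [("1", 100, "A", "T", "3,7")])
        self.write_vcf(b, "T2", [("1", 100, "C", "T", "4,6")])
        with pytest.raises(ParseError, match="reference"):
            read_vcf_pair([a, b])

    def test_missing_ad_rejected(self, tmp_path):
        v = tmp_path / "noad.vcf"
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tT1",
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1",
        ]
        v.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="AD"):
            read_vcf_pair([v])


class TestPurity:
    def make(self, K, N):
        K, N = np.asarray(K), np.asarray(N)
        return VariantCallMatrix("p", [f"S{j}" for j in range(K.shape[1])], [f"v{i}" for i in range(K.shape[0])], K, N)

    def test_definitional(self):
        # all founder VAFs 0.25 -> gamma 0.5
        mat = self.make(np.full((6, 2), 50), np.full((6, 2), 200))
        gamma = estimate_purity(mat)
        np.testing.assert_allclose(gamma, [0.5, 0.5], atol=1e-12)

    def test_median_arithmetic(self):
        # founder VAFs 0.1/0.2/0.3 in sample 1 -> gamma 0.4
        N = np.full((3, 2), 1000)
        K = np.array([[100, 300], [200, 300], [300, 300]])
        gamma = estimate_purity(self.make(K, N))
        assert gamma[0] == pytest.approx(0.4)
        assert gamma[1] == pytest.approx(0.6)

    def test_row_order_invariance(self, rng):
        N = rng.integers(100, 400, size=(12, 3))
        K = (N * rng.uniform(0.1, 0.35)).astype(int)
        mat = self.make(K, N)
        perm = rng.permutation(12)
        mat2 = self.make(K[perm], N[perm])
        np.testing.assert_allclose(estimate_purity(mat), estimate_purity(mat2))

    def test_no_founders_warns(self):
        K = np.array([[50, 0], [0, 50]])
        N = np.full((2, 2), 200)
        with pytest.warns(UserWarning, match="founder"):
            estimate_purity(self.make(K, N))

    def test_user_purity_table(self, tmp_path):
        p = tmp_path / "purity.tsv"
        p.write_text("S1\t0.3\nS2\t0.45\n")
        np.testing.assert_allclose(read_purity_table(p, ["S2", "S1"]), [0.45, 0.3])


class TestSampleFilter:
    def test_min_median_coverage(self):
        N = np.array([[100, 5], [100, 5], [100, 300], [90, 4]])
        K = np.zeros_like(N)
        mat = VariantCallMatrix("p", ["hi", "lo"], [f"v{i}" for i in range(4)], K, N)
        same = mat.filter_samples(0)
        assert same.samples == ["hi", "lo"]
        with pytest.raises(ValueError):
            mat.filter_samples(50)  # would leave a single sample


def test_config_validation():
    with pytest.raises(ValueError):
        PatientConfig(c0=0.0)
    with pytest.raises(ValueError):
        PatientConfig(e=1.5)
    with pytest.raises(ValueError):
        PatientConfig(error_channel="bogus")
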