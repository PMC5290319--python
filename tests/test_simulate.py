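import numpy as np
import pytest

from phyloseed.simulate import (
    SimParams,
    SimulatedTumor,
    _Site,
    fit_log_growth_rate,
    primary_growth_trajectory,
    sequence_samples,
    simulate_tumor,
    single_lineage_survival,
)

FAST = dict(M=1e6, m_mets=3, mean_depth=100, purity=0.75)


def test_param_validation():
    with pytest.raises(ValueError):
        SimParams(b=0.1, d=0.2)
    with pytest.raises(ValueError):
        SimParams(u=1.5)
    with pytest.raises(ValueError):
        SimParams(M=0)


def test_no_migration_means_no_metastases():
    params = SimParams(q_mig=0.0, m_mets=1, M=1e5, max_steps=2000, rng_seed=5)
    with pytest.raises(RuntimeError, match="max_steps"):
        simulate_tumor(params)


def test_survival_fraction_closed_form():
    b, d = 0.16, 0.1555
    frac = single_lineage_survival(b, d, reps=20_000, seed=11)
    target = 1 - d / b
    se = np.sqrt(target * (1 - target) / 20_000)
    assert abs(frac - target) < 4 * se


def test_growth_rate_matches_b_minus_d():
    params = SimParams(rng_seed=0)
    slopes = [fit_log_growth_rate(primary_growth_trajectory(params, seed=s)) for s in range(20)]
    assert abs(np.mean(slopes) / (params.b - params.d) - 1) < 0.1


def test_seeded_runs_reproducible():
    params = SimParams(rng_seed=42, **FAST)
    t1 = simulate_tumor(params)
    t2 = simulate_tumor(params)
    assert t1.met_sites == t2.met_sites
    assert t1.n_mutations == t2.n_mutations
    m1, tr1 = sequence_samples(t1, params, np.random.default_rng(1))
    m2, tr2 = sequence_samples(t2, params, np.random.default_rng(1))
    assert m1.variants == m2.variants
    np.testing.assert_array_equal(m1.mut_reads, m2.mut_reads)
    np.testing.assert_array_equal(m1.coverage, m2.coverage)


def test_simulated_tumor_structure():
    params = SimParams(rng_seed=7, **FAST)
    tumor = simulate_tumor(params)
    assert len(tumor.met_sites) == 3
    for site_id in tumor.met_sites:
        assert tumor.sites[site_id].total >= params.M
    # genealogy is a tree rooted at genotype 0
    for g, parent in enumerate(tumor.genotype_parent):
        if g == 0:
            assert parent is None
        else:
            assert 0 <= parent < g
    # seeding order is chronological
    seed_times = [tumor.sites[s].seed_time for s in tumor.met_sites]
    assert seed_times == sorted(seed_times)


def test_parental_matrix_properties():
    params = SimParams(rng_seed=7, **FAST)
    tumor = simulate_tumor(params)
    clonal = tumor.clonal_masks()
    full = (1 << len(tumor.met_sites)) - 1
    informative = [m for m in range(tumor.n_mutations) if 0 < int(clonal[m]) < full][:25]
    if len(informative) < 2:
        pytest.skip("run produced too few informative mutations")
    A = tumor.parental_matrix(informative)
    assert set(np.unique(A)) <= {0.0, 0.5, 1.0}
    # parental implies not-parental in reverse; same-branch cells symmetric
    k = len(informative)
    for i in range(k):
        for j in range(k):
            if A[i, j] == 1.0:
                assert A[j, i] == 0.0
            if A[i, j] == 0.5:
                assert A[j, i] == 0.5


def _one_clone_tumor(size=1e6, n_mets=2, purity=0.75):
    """Hand-built tumour: one genotype carrying one mutation, two met sites."""
    params = SimParams(m_mets=n_mets, purity=purity, mean_depth=400, n_founder_mutations=1)
    sites = [_Site(site_id=0, parent_site=None, founder_genotype=0, seed_time=0.0)]
    for i in range(n_mets):
        s = _Site(site_id=i + 1, parent_site=0, founder_genotype=0, seed_time=10.0 * (i + 1))
        s.genotypes = [0]
        s.sizes = np.array([size])
        sites.append(s)
    sites[0].genotypes = [0]
    sites[0].sizes = np.array([size])
    return SimulatedTumor(
        params=params,
        genotype_parent=[None],
        genotype_mutations=[[0]],
        mutation_genotype=[0],
        mutation_kind=["snv"],
        mutation_chrom=np.array([0]),
        mutation_pos=np.array([100]),
        mutation_haplotype=np.array([0]),
        mutation_cnv_length=np.array([0]),
        mutation_cnv_delta=np.array([0]),
        sites=sites,
        met_sites=[1, 2],
        primary_trajectory=[],
        attempts=1,
    )


def test_clonal_het_vaf_expectation():
    # clonal heterozygous SNV at purity 0.75 in diploid cells: VAF 0.375
    tumor = _one_clone_tumor(purity=0.75)
    matrix, truth = sequence_samples(tumor, rng=np.random.default_rng(3))
    vaf = np.array(truth["true_vaf"]["m0"])
    np.testing.assert_allclose(vaf, 0.375, atol=1e-12)
    obs = matrix.mut_reads.sum() / matrix.coverage.sum()
    e = tumor.params.e_seq
    expected_read_fraction = 0.375 * (1 - e) + (1 - 0.375) * e / 3
    assert obs == pytest.approx(expected_read_fraction, abs=0.01)


def test_depth_distribution_and_filter_thresholds():
    tumor = _one_clone_tumor()
    params_lo = SimParams(m_mets=2, mean_depth=25.0, n_founder_mutations=1)
    # at mean depth 25 the supporting-read filter drops to 2
    assert params_lo.min_variant_reads_low_cov == 2
    matrix, _ = sequence_samples(tumor, params_lo, np.random.default_rng(5))
    assert abs(matrix.coverage.mean() - 25) < 8
    params_hi = SimParams(m_mets=2, mean_depth=400.0, n_founder_mutations=1)
    matrix_hi, _ = sequence_samples(tumor, params_hi, np.random.default_rng(5))
    # negative binomial with variance 2x mean
    assert abs(matrix_hi.coverage.mean() - 400) < 25


def test_error_channel_on_absent_locus():
    # a mutation confined to the primary has true VAF 0 in the mets; reads
    # supporting it arise only through the e/3 error channel
    tumor = _one_clone_tumor()
    tumor.genotype_parent.append(0)
    tumor.genotype_mutations.append([1])
    tumor.mutation_genotype.append(1)
    tumor.mutation_kind.append("snv")
    tumor.mutation_chrom = np.array([0, 1])
    tumor.mutation_pos = np.array([100, 5000])
    tumor.mutation_haplotype = np.array([0, 0])
    tumor.mutation_cnv_length = np.array([0, 0])
    tumor.mutation_cnv_delta = np.array([0, 0])
    matrix, truth = sequence_samples(tumor, rng=np.random.default_rng(9))
    assert truth["true_vaf"].get("m1", [0, 0]) == [0.0, 0.0] or "m1" not in truth["true_vaf"]


def test_mutation_rate_per_division():
    # SNV events per division = u: compare recorded mutations against the
    # realized division integral of the tracked phase
    params = SimParams(rng_seed=1, mutation_track_limit=2000.0, switch_size=2500.0)
    from phyloseed.simulate import _SimState, _step_site

    total_snvs = 0
    total_divisions = 0.0
    for s in range(200):
        rng_local = np.random.default_rng(1000 + s)
        if rng_local.random() >= 1 - params.d / params.b:
            continue
        state = _SimState(params, rng_local)
        t = 0.0
        while not state.sites[0].deterministic and not state.sites[0].dead:
            _step_site(state, state.sites[0], t, params.time_step, seeding_open=False)
            t += params.time_step
        total_snvs += sum(1 for k in state.mutation_kind if k == "snv") - params.n_founder_mutations
        total_divisions += state.tracked_division_integral
    rate = total_snvs / total_divisions
    se = np.sqrt(params.u / total_divisions)
    assert abs(rate - params.u) < 5 * se


def test_polyphyletic_sampling_mixes_two_sites():
    params = SimParams(rng_seed=3, polyphyletic_count=1, **FAST)
    tumor = simulate_tumor(params)
    matrix, truth = sequence_samples(tumor, params, np.random.default_rng(4))
    assert len(truth["polyphyletic_samples"]) == 1
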