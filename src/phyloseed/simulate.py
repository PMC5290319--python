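"""Stochastic multi-type branching-process simulator of metastatic progression
with in-silico multi-sample sequencing.

Cells divide at rate ``b`` and die at rate ``d``; a dividing cell acquires a
point mutation with probability ``u`` and a copy-number event with probability
``cnv_rate``, and a daughter cell migrates to found a new anatomic site with
probability ``q_mig`` per division.  Seeding from established metastases is
allowed.  The run stops once ``m_mets`` metastases have reached the detection
size ``M``.

The implementation is a clone-level hybrid: while a site is below a size
threshold its genotype populations evolve by the exact linear birth-death
transition law (sampled per time step), with mutation/migration events
Poissonized at the realized division rate; above the threshold growth is
deterministic exponential with frozen genotype frequencies and Poissonized
migration.  New mutations stop being tracked once a site outgrows
``mutation_track_limit`` cells: later mutations cannot reach a detectable cell
fraction at the final size.

Two exact-in-distribution devices keep the run tractable.  First, each
migrant lineage's ultimate survival is decided up front (probability
1 - d/b); doomed migrants are never instantiated (a doomed lineage re-seeding
before dying has probability ~ q_mig * d/(b-d), negligible), and surviving
lineages evolve under the birth-death law conditioned on non-extinction,
realized by resampling any step that would end at zero cells -- for a
permanently absorbing state this stepwise rejection equals conditioning on
survival.  Second, seeding stops ``grace_window`` time units after ``m_mets``
surviving candidate sites exist: with growth rate b - d, later seeds trail by
more than the stochastic-lag variability and cannot reach the detection size
first.

Sequencing draws one million cells per detected metastasis, dilutes them with
variant-free normal cells to the target purity, mixes two sites for
polyphyletic samples, draws coverage from a negative binomial
(variance = 2 x mean) and variant reads from a binomial with the read-error
channel theta(f) = f(1-e) + (1-f)e/3.  Only variants with VAF >= 5% and
enough supporting reads (4; 2 when the mean depth is <= 25) in at least one
sample are emitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from phyloseed.datamodel import VariantCallMatrix

__all__ = [
    "SimParams",
    "SimulatedTumor",
    "simulate_tumor",
    "sequence_samples",
    "single_lineage_survival",
    "fit_log_growth_rate",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the branching-process simulation and in-silico sequencing."""

    b: float = 0.16
    d: float = 0.1555
    q_mig: float = 1e-9
    u: float = 0.145
    cnv_rate: float = 0.001
    M: float = 1e8
    m_mets: int = 6
    purity: float = 0.75
    mean_depth: float = 400.0
    e_seq: float = 0.005
    polyphyletic_count: int = 0
    rng_seed: int = 0
    n_founder_mutations: int = 10
    genome_size: int = 45_000_000
    n_chromosomes: int = 22
    sample_cells: int = 1_000_000
    vaf_threshold: float = 0.05
    min_variant_reads: int = 4
    min_variant_reads_low_cov: int = 2
    low_cov_mean: float = 25.0
    switch_size: float = 1e4
    mutation_track_limit: float = 4e3
    late_site_track_limit: float = 300.0
    grace_window: float = 500.0
    time_step: float = 10.0
    cnv_length_mu: float = np.log(1e5)
    cnv_length_sigma: float = 1.0
    max_retries: int = 2000
    max_steps: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.d < self.b:
            raise ValueError("require 0 <= d < b")
        for name in ("q_mig", "u", "cnv_rate", "purity", "e_seq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.M < 1:
            raise ValueError("detection size M must be >= 1")


@dataclass
class _Site:
    site_id: int
    parent_site: int | None
    founder_genotype: int
    seed_time: float
    genotypes: list = field(default_factory=list)  # genotype ids
    sizes: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    deterministic: bool = False
    dead: bool = False
    detect_time: float | None = None
    track_limit: float = 4e3

    @property
    def total(self) -> float:
        return float(self.sizes.sum())


@dataclass
class SimulatedTumor:
    """Ground truth of one simulated tumour.

    ``genotype_parent``/``genotype_mutations`` encode the clone genealogy
    (genotype 0 is the founding clone carrying the founder mutations);
    ``mutation_genotype`` maps each mutation to the genotype that acquired it.
    ``sites`` lists all seeded sites; ``met_sites`` the detected metastases in
    chronological order of their seeding.
    """

    params: SimParams
    genotype_parent: list
    genotype_mutations: list  # list of lists of mutation ids
    mutation_genotype: list
    mutation_kind: list  # "snv" | "cnv"
    mutation_chrom: np.ndarray
    mutation_pos: np.ndarray
    mutation_haplotype: np.ndarray
    mutation_cnv_length: np.ndarray
    mutation_cnv_delta: np.ndarray
    sites: list
    met_sites: list
    primary_trajectory: list  # (time, size) while the primary was stochastic
    attempts: int

    @property
    def n_mutations(self) -> int:
        return len(self.mutation_genotype)

    def genotype_lineage(self, g: int) -> list:
        """Mutation ids carried by genotype g (root-to-genotype order)."""
        path = []
        while g is not None:
            path.append(g)
            g = self.genotype_parent[g]
        muts: list[int] = []
        for gg in reversed(path):
            muts.extend(self.genotype_mutations[gg])
        return muts

    def is_ancestral_genotype(self, a: int, g: int) -> bool:
        """True iff genotype a is an ancestor of (or equal to) genotype g."""
        while g is not None:
            if g == a:
                return True
            g = self.genotype_parent[g]
        return False

    def clonal_masks(self) -> np.ndarray:
        """Per-mutation bitmask of metastases carrying it clonally.

        A mutation is clonal in a metastasis iff the site's founding cell
        carried it, i.e. it lies on the founder genotype's lineage.
        """
        masks = np.zeros(self.n_mutations, dtype=np.int64)
        for j, site_id in enumerate(self.met_sites):
            founder = self.sites[site_id].founder_genotype
            for mu in self.genotype_lineage(founder):
                masks[mu] |= 1 << j
        return masks

    def parental_matrix(self, mutation_ids) -> np.ndarray:
        """True ancestry matrix A over the given mutations.

        A[i, j] = 1 if mutation i is parental to mutation j, 0.5 if the two
        mutations sit on the same branch (identical clonal sample patterns),
        0 otherwise.
        """
        ids = list(mutation_ids)
        k = len(ids)
        masks = self.clonal_masks()
        A = np.zeros((k, k))
        for a in range(k):
            for bb in range(k):
                if a == bb:
                    continue
                i, j = ids[a], ids[bb]
                gi, gj = self.mutation_genotype[i], self.mutation_genotype[j]
                if masks[i] == masks[j] and masks[i] != 0:
                    A[a, bb] = 0.5
                elif gi != gj and self.is_ancestral_genotype(gi, gj):
                    A[a, bb] = 1.0
                elif gi == gj:
                    A[a, bb] = 0.5  # co-acquired in one clone
        return A

    def truth_dict(self) -> dict:
        """JSON-serializable ground-truth summary."""
        masks = self.clonal_masks()
        return {
            "n_mutations": self.n_mutations,
            "met_sites": [int(s) for s in self.met_sites],
            "site_parents": {str(s.site_id): (None if s.parent_site is None else int(s.parent_site)) for s in self.sites},
            "seed_times": {str(s.site_id): float(s.seed_time) for s in self.sites},
            "clonal_masks": [int(m) for m in masks],
            "mutation_kind": list(self.mutation_kind),
            "attempts": int(self.attempts),
        }


def _bd_transition(sizes: np.ndarray, b: float, d: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Exact linear birth-death transition over dt for integer clone sizes."""
    r = b - d
    ert = np.exp(r * dt)
    denom = b * ert - d
    alpha = d * (ert - 1.0) / denom  # extinction probability of one cell
    beta = b * (ert - 1.0) / denom
    k = sizes.astype(np.int64)
    survivors = rng.binomial(k, 1.0 - alpha)
    out = survivors.astype(np.int64).copy()
    pos = survivors > 0
    if pos.any():
        out[pos] += rng.negative_binomial(survivors[pos], 1.0 - beta)
    return out


def _place_snv(params: SimParams, rng: np.random.Generator) -> tuple:
    pos = int(rng.integers(0, params.genome_size))
    chrom = pos * params.n_chromosomes // params.genome_size
    hap = int(rng.integers(0, 2))
    return chrom, pos, hap


class _SimState:
    """Mutable state of one simulation attempt."""

    def __init__(self, params: SimParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.genotype_parent: list = [None]
        self.genotype_mutations: list = [list(range(params.n_founder_mutations))]
        self.mutation_genotype: list = [0] * params.n_founder_mutations
        self.mutation_kind: list = ["snv"] * params.n_founder_mutations
        self.mut_chrom: list = []
        self.mut_pos: list = []
        self.mut_hap: list = []
        self.mut_len: list = []
        self.mut_delta: list = []
        for _ in range(params.n_founder_mutations):
            c, p, h = _place_snv(params, rng)
            self.mut_chrom.append(c)
            self.mut_pos.append(p)
            self.mut_hap.append(h)
            self.mut_len.append(0)
            self.mut_delta.append(0)
        primary = _Site(
            site_id=0,
            parent_site=None,
            founder_genotype=0,
            seed_time=0.0,
            track_limit=params.mutation_track_limit,
        )
        primary.genotypes = [0]
        primary.sizes = np.array([1.0])
        self.sites: list[_Site] = [primary]
        self.primary_trajectory: list = [(0.0, 1.0)]
        self.stop_seeding_time: float | None = None
        self.tracked_division_integral: float = 0.0

    def new_genotype(self, parent: int, kind: str) -> int:
        params, rng = self.params, self.rng
        gid = len(self.genotype_parent)
        mid = len(self.mutation_genotype)
        self.genotype_parent.append(parent)
        self.genotype_mutations.append([mid])
        self.mutation_genotype.append(gid)
        self.mutation_kind.append(kind)
        if kind == "snv":
            c, p, h = _place_snv(params, rng)
            self.mut_chrom.append(c)
            self.mut_pos.append(p)
            self.mut_hap.append(h)
            self.mut_len.append(0)
            self.mut_delta.append(0)
        else:
            # CNV: duplication or deletion of one allele; resample on overlap
            # with a CNV already on this lineage (no overlapping events)
            lineage_cnvs = [
                m
                for m in self._lineage_mut_ids(parent)
                if self.mutation_kind[m] == "cnv"
            ]
            for _ in range(20):
                length = int(np.exp(rng.normal(params.cnv_length_mu, params.cnv_length_sigma)))
                length = max(1000, min(length, params.genome_size // params.n_chromosomes))
                pos = int(rng.integers(0, params.genome_size))
                chrom = pos * params.n_chromosomes // params.genome_size
                if not any(
                    self.mut_chrom[m] == chrom and not (pos + length <= self.mut_pos[m] or self.mut_pos[m] + self.mut_len[m] <= pos)
                    for m in lineage_cnvs
                ):
                    break
            self.mut_chrom.append(chrom)
            self.mut_pos.append(pos)
            self.mut_hap.append(int(rng.integers(0, 2)))
            self.mut_len.append(length)
            self.mut_delta.append(int(rng.choice([-1, 1])))
        return gid

    def _lineage_mut_ids(self, g: int) -> list:
        muts = []
        while g is not None:
            muts.extend(self.genotype_mutations[g])
            g = self.genotype_parent[g]
        return muts

    def new_site(self, parent_site: int, founder_genotype: int, time: float, track_limit: float) -> None:
        site = _Site(
            site_id=len(self.sites),
            parent_site=parent_site,
            founder_genotype=founder_genotype,
            seed_time=time,
            track_limit=track_limit,
        )
        site.genotypes = [founder_genotype]
        site.sizes = np.array([1.0])
        self.sites.append(site)


def _step_site(state: _SimState, site: _Site, t: float, dt: float, seeding_open: bool) -> list:
    """Advance one site by dt; returns the source genotypes of new migrants."""
    params, rng = state.params, state.rng
    b, d, r = params.b, params.d, params.b - params.d
    survival = 1.0 - d / b
    migrations: list[int] = []
    if site.dead:
        return migrations
    start_total = site.total
    if site.deterministic or start_total >= params.switch_size:
        site.deterministic = True
        growth = np.exp(r * dt)
        integral = start_total * (growth - 1.0) / r  # cell-time units
        site.sizes = site.sizes * growth
        if seeding_open:
            n_mig = rng.poisson(params.q_mig * b * integral * survival)
            if n_mig:
                probs = site.sizes / site.sizes.sum()
                for src in rng.choice(len(site.genotypes), size=int(n_mig), p=probs):
                    migrations.append(site.genotypes[int(src)])
        return migrations

    sizes = site.sizes.astype(np.int64)
    track = start_total < site.track_limit
    if track:
        # mutant daughters leave their parent genotype: effective birth rate
        # of a genotype excludes mutating divisions
        b_eff = b * (1.0 - params.u - params.cnv_rate)
    else:
        b_eff = b
    # lineage conditioned on survival: resample any step ending extinct
    for _ in range(10_000):
        new_sizes = _bd_transition(sizes, b_eff, d, dt, rng)
        if new_sizes.sum() > 0:
            break
    else:  # pragma: no cover - p(reaching here) is astronomically small
        new_sizes = sizes.copy()
    mean_sizes = 0.5 * (sizes + new_sizes)
    division_integral = b * mean_sizes.sum() * dt
    if track:
        state.tracked_division_integral += division_integral

    genotypes = list(site.genotypes)
    out_sizes = list(new_sizes.astype(float))
    mean_total = mean_sizes.sum()
    if track and division_integral > 0 and mean_total > 0:
        probs = mean_sizes / mean_total
        n_orig = len(genotypes)
        n_snv = int(rng.poisson(params.u * division_integral))
        n_cnv = int(rng.poisson(params.cnv_rate * division_integral))
        if n_snv + n_cnv:
            parent_idx = rng.choice(n_orig, size=n_snv + n_cnv, p=probs)
            # a spawn born at uniform time within the step grows (or dies)
            # over the residual time by the exact single-cell BD law at the
            # full rates (its would-be mutant children stay inside it until
            # the next step); crediting 1 cell would bias total growth low
            residual = dt * rng.random(n_snv + n_cnv)
            ert = np.exp((b - d) * residual)
            denom = b * ert - d
            alpha = d * (ert - 1.0) / denom
            beta = b * (ert - 1.0) / denom
            alive = rng.random(n_snv + n_cnv) >= alpha
            spawn_sizes = np.zeros(n_snv + n_cnv)
            if alive.any():
                spawn_sizes[alive] = 1.0 + rng.negative_binomial(1, 1.0 - beta[alive])
            for spawn, pi in enumerate(parent_idx):
                # record every mutation event (rate u per division); spawns
                # that die within the step just never enter the population
                kind = "snv" if spawn < n_snv else "cnv"
                gid = state.new_genotype(genotypes[int(pi)], kind)
                if spawn_sizes[spawn] > 0:
                    genotypes.append(gid)
                    out_sizes.append(float(spawn_sizes[spawn]))
    if seeding_open:
        n_mig = rng.poisson(params.q_mig * division_integral * survival)
        if n_mig and mean_total > 0:
            probs = mean_sizes / mean_total
            for src in rng.choice(len(site.genotypes), size=int(n_mig), p=probs):
                migrations.append(site.genotypes[int(src)])

    arr = np.asarray(out_sizes)
    keep = arr > 0
    site.genotypes = [g for g, k in zip(genotypes, keep) if k]
    site.sizes = arr[keep]
    if site.total <= 0:
        site.dead = True
    return migrations


def _run_attempt(params: SimParams, rng: np.random.Generator) -> SimulatedTumor | None:
    # ultimate survival of the founding lineage is decided up front; the
    # surviving run is then simulated conditioned on non-extinction
    if rng.random() >= 1.0 - params.d / params.b:
        return None
    state = _SimState(params, rng)
    t = 0.0
    detected: list[int] = []
    for _ in range(params.max_steps):
        dt = params.time_step
        seeding_open = state.stop_seeding_time is None or t < state.stop_seeding_time
        all_migrations: list[tuple[int, int]] = []
        for site in state.sites:
            if site.dead:
                continue
            for src_genotype in _step_site(state, site, t, dt, seeding_open):
                all_migrations.append((site.site_id, src_genotype))
        t += dt
        n_candidates = len(state.sites) - 1 + len(all_migrations)
        if state.stop_seeding_time is None and n_candidates >= params.m_mets:
            state.stop_seeding_time = t + params.grace_window
        track_limit = params.mutation_track_limit if len(state.sites) - 1 < params.m_mets else params.late_site_track_limit
        for parent_site, genotype in all_migrations:
            state.new_site(parent_site, genotype, t, track_limit)
        primary = state.sites[0]
        if not primary.deterministic and not primary.dead:
            state.primary_trajectory.append((t, primary.total))
        for site in state.sites:
            if site.site_id != 0 and not site.dead and site.detect_time is None and site.total >= params.M:
                site.detect_time = t
                detected.append(site.site_id)
        if len(detected) >= params.m_mets:
            met_sites = detected[: params.m_mets]
            met_sites.sort(key=lambda s: state.sites[s].seed_time)
            return SimulatedTumor(
                params=params,
                genotype_parent=state.genotype_parent,
                genotype_mutations=state.genotype_mutations,
                mutation_genotype=state.mutation_genotype,
                mutation_kind=state.mutation_kind,
                mutation_chrom=np.array(state.mut_chrom, dtype=np.int64),
                mutation_pos=np.array(state.mut_pos, dtype=np.int64),
                mutation_haplotype=np.array(state.mut_hap, dtype=np.int8),
                mutation_cnv_length=np.array(state.mut_len, dtype=np.int64),
                mutation_cnv_delta=np.array(state.mut_delta, dtype=np.int8),
                sites=state.sites,
                met_sites=met_sites,
                primary_trajectory=state.primary_trajectory,
                attempts=1,
            )
        if all(site.dead for site in state.sites):
            return None
    raise RuntimeError("simulation exceeded max_steps without detecting enough metastases")


def simulate_tumor(params: SimParams) -> SimulatedTumor:
    """Run the branching-process simulation, retrying on full extinction.

    With d close to b most attempts go extinct quickly; the attempt counter
    is reported on the returned tumour.
    """
    rng = np.random.default_rng(params.rng_seed)
    for attempt in range(1, params.max_retries + 1):
        result = _run_attempt(params, rng)
        if result is not None:
            result.attempts = attempt
            return result
    raise RuntimeError(f"all {params.max_retries} simulation attempts went extinct")


def _sample_cells(tumor: SimulatedTumor, site_ids: list, weights: list, rng: np.random.Generator) -> dict:
    """Draw the biopsy: genotype -> sampled tumour cell count."""
    params = tumor.params
    cells: dict[int, int] = {}
    total_w = float(sum(weights))
    alloc = rng.multinomial(params.sample_cells, [w / total_w for w in weights])
    for site_id, n_cells in zip(site_ids, alloc):
        site = tumor.sites[site_id]
        if n_cells == 0 or site.total <= 0:
            continue
        probs = site.sizes / site.sizes.sum()
        counts = rng.multinomial(int(n_cells), probs)
        for g, c in zip(site.genotypes, counts):
            if c:
                cells[g] = cells.get(g, 0) + int(c)
    return cells


def _variant_allele_counts(tumor: SimulatedTumor, cells: dict) -> tuple:
    """Per-SNV variant-allele and locus-copy totals over the sampled cells."""
    n_mut = tumor.n_mutations
    var_copies = np.zeros(n_mut)
    snv_ids = [m for m in range(n_mut) if tumor.mutation_kind[m] == "snv"]
    locus_copies = np.full(n_mut, 0.0)
    total_cells = sum(cells.values())
    # CNVs present anywhere in the sampled genotypes
    active_cnvs = set()
    for g in cells:
        for m in tumor.genotype_lineage(g):
            if tumor.mutation_kind[m] == "cnv":
                active_cnvs.add(m)
    overlaps: dict[int, list] = {}
    for cv in active_cnvs:
        c, p0, ln = tumor.mutation_chrom[cv], tumor.mutation_pos[cv], tumor.mutation_cnv_length[cv]
        for mu in snv_ids:
            if tumor.mutation_chrom[mu] == c and p0 <= tumor.mutation_pos[mu] < p0 + ln:
                overlaps.setdefault(mu, []).append(cv)
    plain_locus = 2.0 * total_cells
    locus_copies[:] = plain_locus
    for g, c_g in cells.items():
        lineage = tumor.genotype_lineage(g)
        lineage_set = set(lineage)
        order = {m: i for i, m in enumerate(lineage)}
        for mu in lineage:
            if tumor.mutation_kind[mu] != "snv":
                continue
            vc = 1.0
            for cv in overlaps.get(mu, ()):
                if cv in lineage_set and order[cv] > order[mu] and tumor.mutation_haplotype[cv] == tumor.mutation_haplotype[mu]:
                    vc = max(0.0, vc + tumor.mutation_cnv_delta[cv])
            var_copies[mu] += c_g * vc
        # locus copy-number adjustments for every overlapped SNV locus
        for mu, cvs in overlaps.items():
            delta = sum(int(tumor.mutation_cnv_delta[cv]) for cv in cvs if cv in lineage_set)
            if delta:
                locus_copies[mu] += c_g * max(-1, delta)  # one haplotype never drops below 0
    return var_copies, locus_copies


def sequence_samples(tumor: SimulatedTumor, params: SimParams | None = None, rng: np.random.Generator | None = None) -> tuple:
    """In-silico sequencing of the detected metastases.

    Returns ``(matrix, truth)`` where ``matrix`` is a
    :class:`VariantCallMatrix` over the detected variants and ``truth`` maps
    the retained rows back to ground-truth mutation ids, clonal patterns and
    per-sample true VAFs.
    """
    params = params or tumor.params
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed + 7)
    mets = tumor.met_sites
    n = len(mets)
    if n < params.m_mets:
        raise ValueError("tumour has fewer detected metastases than requested")

    n_poly = min(params.polyphyletic_count, n)
    poly_samples = set(rng.choice(n, size=n_poly, replace=False).tolist()) if n_poly else set()

    n_mut = tumor.n_mutations
    true_vaf = np.zeros((n_mut, n))
    for j, site_id in enumerate(mets):
        site_ids = [site_id]
        weights = [tumor.sites[site_id].total]
        if j in poly_samples:
            others = [s.site_id for s in tumor.sites if not s.dead and s.site_id != site_id and s.total > 0]
            if others:
                other = int(rng.choice(others))
                site_ids.append(other)
                weights.append(tumor.sites[other].total)
        cells = _sample_cells(tumor, site_ids, weights, rng)
        var_copies, locus_copies = _variant_allele_counts(tumor, cells)
        total_cells = sum(cells.values())
        normal_cells = total_cells * (1.0 - params.purity) / params.purity if params.purity < 1.0 else 0.0
        denom = locus_copies + 2.0 * normal_cells
        with np.errstate(invalid="ignore", divide="ignore"):
            true_vaf[:, j] = np.where(denom > 0, var_copies / denom, 0.0)

    snv_rows = np.array([m for m in range(n_mut) if tumor.mutation_kind[m] == "snv"], dtype=np.int64)
    e = params.e_seq
    theta = true_vaf[snv_rows] * (1.0 - e) + (1.0 - true_vaf[snv_rows]) * e / 3.0
    N = rng.negative_binomial(max(1, int(round(params.mean_depth))), 0.5, size=theta.shape)
    K = rng.binomial(N, theta)

    min_reads = params.min_variant_reads_low_cov if params.mean_depth <= params.low_cov_mean else params.min_variant_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf_obs = np.where(N > 0, K / np.maximum(N, 1), 0.0)
    detected = ((vaf_obs >= params.vaf_threshold) & (K >= min_reads)).any(axis=1)
    keep = snv_rows[detected]
    if len(keep) == 0:
        raise RuntimeError("no variant passed the detection filter")

    samples = [f"M{j+1}" for j in range(n)]
    variants = [f"m{int(m)}" for m in keep]
    matrix = VariantCallMatrix(
        patient_id="sim",
        samples=samples,
        variants=variants,
        mut_reads=K[detected],
        coverage=N[detected],
        purity=np.full(n, params.purity),
    )
    clonal = tumor.clonal_masks()
    truth = {
        "mutation_ids": [int(m) for m in keep],
        "clonal_masks": {f"m{int(m)}": int(clonal[m]) for m in keep},
        "true_vaf": {f"m{int(m)}": true_vaf[m].tolist() for m in keep},
        "polyphyletic_samples": sorted(int(j) for j in poly_samples),
        "samples": samples,
    }
    return matrix, truth


def write_simulation(matrix: VariantCallMatrix, tumor: SimulatedTumor, truth: dict, outdir, prefix: str = "sim") -> None:
    """Write the TSV count-table pair and a ground-truth JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.write_count_tables(outdir / f"{prefix}_mut_reads.tsv", outdir / f"{prefix}_coverage.tsv")
    payload = dict(tumor.truth_dict())
    payload.update(truth)
    with open(outdir / f"{prefix}_truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def primary_growth_trajectory(params: SimParams, seed: int) -> list:
    """Trajectory (time, size) of one surviving primary up to the
    deterministic switch; used for growth-rate checks."""
    rng = np.random.default_rng(seed)
    for _ in range(params.max_retries):
        if rng.random() >= 1.0 - params.d / params.b:
            continue
        state = _SimState(params, rng)
        t = 0.0
        while not state.sites[0].deterministic:
            _step_site(state, state.sites[0], t, params.time_step, seeding_open=False)
            t += params.time_step
            if not state.sites[0].deterministic:
                state.primary_trajectory.append((t, state.sites[0].total))
        return state.primary_trajectory
    raise RuntimeError("no surviving lineage within the retry budget")


def single_lineage_survival(b: float, d: float, reps: int, seed: int = 0, cap: int = 300) -> float:
    """Fraction of single-cell lineages that escape extinction.

    Uses the embedded jump chain of the birth-death process (each event is a
    birth with probability b/(b+d)); a lineage reaching ``cap`` cells counts
    as surviving -- the residual extinction probability (d/b)^cap is
    negligible for the default cap.  Exact batching: a walker of size k takes
    k steps at once, which cannot cross zero without ending exactly at zero.
    """
    rng = np.random.default_rng(seed)
    p_birth = b / (b + d)
    sizes = np.ones(reps, dtype=np.int64)
    survived = 0
    while sizes.size:
        ups = rng.binomial(sizes, p_birth)
        sizes = 2 * ups  # k steps: k + ups - (k - ups)
        done_dead = sizes <= 0
        done_surv = sizes >= cap
        survived += int(done_surv.sum())
        sizes = sizes[~(done_dead | done_surv)]
    return survived / reps


def fit_log_growth_rate(trajectory, min_size: float = 100.0) -> float:
    """Least-squares slope of log population size vs time.

    Fit restricted to the window where the population exceeds ``min_size``
    so the early conditioned-on-survival boost does not bias the estimate.
    """
    t = np.array([x for x, nsize in trajectory if nsize >= min_size])
    y = np.array([np.log(nsize) for x, nsize in trajectory if nsize >= min_size])
    if len(t) < 3:
        raise ValueError("trajectory too short above min_size for a slope fit")
    slope = np.polyfit(t, y, 1)[0]
    return float(slope)
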