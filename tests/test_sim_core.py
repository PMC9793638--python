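"""Unit and property tests for the Wright--Fisher engine."""

import numpy as np
import pytest

from inbredsim.sim_core import (
    ConfigurationError,
    EffectModel,
    ExtinctionError,
    GenomeSpec,
    PopulationState,
    burn_in,
    calibrate_k,
    draw_mutation_effects,
    draw_parent_pairs,
    empty_population,
    fitness_from_genotypes,
    load_population,
    make_gamete,
    save_population,
    wf_generation,
)


class TestCalibrateK:
    @pytest.mark.parametrize(
        "mean_s,mean_h,expected",
        [(0.1, 0.2, 15.0), (0.025, 0.2, 60.0), (0.3, 0.5, 0.0), (1.0, 0.5, 0.0)],
    )
    def test_closed_form(self, mean_s, mean_h, expected):
        assert calibrate_k(mean_s, mean_h) == pytest.approx(expected)

    def test_monte_carlo_mean_h(self, rng):
        """The calibrated k reproduces the target mean dominance coefficient."""
        model = EffectModel(0.1, 0.2)
        s = rng.exponential(model.mean_s, 10**6)
        h = rng.uniform(0, np.exp(-model.k * s))
        se = h.std() / 1000.0
        assert abs(h.mean() - 0.2) < 3 * se + 1e-3  # s-capping perturbs < 1e-3

    @pytest.mark.parametrize("mean_h", [0.0, 0.6, -0.1])
    def test_invalid_mean_h(self, mean_h):
        with pytest.raises(ConfigurationError):
            calibrate_k(0.1, mean_h)


class TestDrawMutationEffects:
    def test_zero_fraction_all_neutral(self, rng):
        dele, s, _ = draw_mutation_effects(rng, EffectModel(), 0.0, 1000)
        assert not dele.any()
        assert (s == 0).all()

    def test_deleterious_properties(self, rng):
        model = EffectModel(0.1, 0.2)
        dele, s, h = draw_mutation_effects(rng, model, 1.0, 10**5)
        assert dele.all()
        assert (s > 0).all() and (s <= 1).all()
        assert (h >= 0).all() and (h <= np.exp(-model.k * s)).all()
        se = h.std() / np.sqrt(h.size)
        assert abs(h.mean() - 0.2) < 3 * se + 1e-3

    def test_k_zero_gives_uniform_h(self, rng):
        """mean_h = 0.5 gives k = 0, so h ~ Uniform(0, 1) regardless of s."""
        _, _, h = draw_mutation_effects(rng, EffectModel(0.1, 0.5), 1.0, 10**5)
        assert abs(h.mean() - 0.5) < 0.01


class TestFitness:
    def test_no_deleterious_sites(self):
        w = fitness_from_genotypes(np.array([[0, 2, 1]]), np.zeros(3), np.full(3, 0.5))
        assert w[0] == 1.0

    def test_single_heterozygote(self):
        w = fitness_from_genotypes(np.array([[1]]), np.array([0.5]), np.array([0.2]))
        assert w[0] == pytest.approx(0.9)

    def test_lethal_homozygote(self):
        w = fitness_from_genotypes(np.array([[2]]), np.array([1.0]), np.array([0.1]))
        assert w[0] == 0.0

    def test_multiplicative(self):
        s = np.array([0.5, 0.2])
        h = np.array([0.2, 0.0])
        w = fitness_from_genotypes(np.array([[1, 2]]), s, h)
        assert w[0] == pytest.approx(0.9 * 0.8)

    def test_adding_deleterious_site_never_increases_w(self, rng):
        s = rng.uniform(0.01, 1.0, 30)
        h = rng.uniform(0.0, 0.5, 30)
        x = rng.integers(0, 3, (20, 30))
        w0 = fitness_from_genotypes(x, s, h)
        x2 = x.copy()
        for i in range(20):
            j = rng.integers(30)
            x2[i, j] = min(2, x2[i, j] + 1)
        w1 = fitness_from_genotypes(x2, s, h)
        assert (w1 <= w0 + 1e-12).all()


def _random_state(rng, n=10, n_sites=40, genome=None):
    genome = genome or GenomeSpec(n_chromosomes=2, chrom_length_bp=10**7)
    gpos = np.sort(rng.choice(genome.n_chromosomes * genome.chrom_length_bp,
                              n_sites, replace=False))
    state = empty_population(genome, EffectModel(), n)
    state.chrom = (gpos // genome.chrom_length_bp).astype(np.int32)
    state.pos = gpos % genome.chrom_length_bp
    state.s = np.zeros(n_sites)
    state.h = np.full(n_sites, 0.5)
    state.H = rng.integers(0, 2, (2 * n, n_sites)).astype(np.uint8)
    return state


class TestMakeGamete:
    def test_no_recombination_no_mutation_copies_one_haplotype(self, rng):
        genome = GenomeSpec(n_chromosomes=1, chrom_length_bp=10**7,
                            recomb_rate=0.0, mut_rate=0.0)
        pair = rng.integers(0, 2, (2, 25)).astype(np.uint8)
        chrom = np.zeros(25, np.int32)
        pos = np.sort(rng.choice(10**7, 25, replace=False)).astype(np.int64)
        for _ in range(10):
            gam, new = make_gamete(pair, chrom, pos, genome, rng)
            assert new == []
            assert (gam == pair[0]).all() or (gam == pair[1]).all()

    def test_mean_crossover_count_is_length_times_rate(self, rng):
        """A 125-Mb chromosome at 8e-9 gives one crossover per meiosis."""
        genome = GenomeSpec(n_chromosomes=1)
        lam = genome.chrom_length_bp * genome.recomb_rate
        assert lam == pytest.approx(1.0)
        counts = rng.poisson(lam, 5000)  # the engine draws from this law
        # cross-check through the engine: switches between distinguishable
        # parental haplotypes count crossovers directly
        pair = np.zeros((2, 200), np.uint8)
        pair[1] = 1
        chrom = np.zeros(200, np.int32)
        pos = np.linspace(1, genome.chrom_length_bp - 1, 200).astype(np.int64)
        switches = []
        g0 = GenomeSpec(n_chromosomes=1, mut_rate=0.0)
        for _ in range(2000):
            gam, _ = make_gamete(pair, chrom, pos, g0, rng)
            switches.append(int(np.abs(np.diff(gam.astype(int))).sum()))
        # observed switches undercount crossovers only via double-crossovers
        # between adjacent markers (prob ~ (1/200)^2): negligible here
        mean = np.mean(switches)
        sem = np.std(switches) / np.sqrt(len(switches))
        assert abs(mean - 1.0) < 4 * sem + 0.02

    def test_no_mutation_allele_subset_of_parents(self, rng):
        genome = GenomeSpec(n_chromosomes=2, chrom_length_bp=10**7, mut_rate=0.0)
        state = _random_state(rng, n=6, genome=genome)
        for _ in range(20):
            i = rng.integers(6)
            pair = state.H[2 * i:2 * i + 2]
            gam, _ = make_gamete(pair, state.chrom, state.pos, genome, rng)
            union = pair.max(axis=0)
            assert (gam <= union).all()
            inter = pair.min(axis=0)
            assert (gam >= inter).all()


class TestWfGeneration:
    def test_offspring_alleles_subset_without_mutation(self, rng):
        genome = GenomeSpec(n_chromosomes=2, chrom_length_bp=10**7, mut_rate=0.0)
        state = _random_state(rng, n=10, genome=genome)
        child = wf_generation(state, 10, rng)
        # every derived allele in children existed in parents
        assert child.n_sites <= state.n_sites
        parent_gpos = set(state.gpos.tolist())
        assert set(child.gpos.tolist()) <= parent_gpos

    def test_no_selfing(self, rng):
        state = _random_state(rng, n=8)
        child = wf_generation(state, 50, rng)
        assert (child.sire != child.dam).all()

    def test_extinction_raises(self, rng):
        state = _random_state(rng, n=4, n_sites=1)
        state.s = np.array([1.0])
        state.h = np.array([0.5])
        state.H[:] = 1  # everyone homozygous lethal
        with pytest.raises(ExtinctionError):
            wf_generation(state, 4, rng)

    def test_infinite_sites_unique_positions(self, rng):
        genome = GenomeSpec(n_chromosomes=2, chrom_length_bp=10**6, mut_rate=1e-6)
        pop = burn_in(genome, 20, 50, rng=rng)
        gpos = pop.gpos
        assert len(np.unique(gpos)) == len(gpos)
        assert (np.diff(gpos) > 0).all()  # sorted by (chrom, pos)

    def test_segregating_counts_in_range(self, rng):
        genome = GenomeSpec(n_chromosomes=1, chrom_length_bp=10**7, mut_rate=1e-7)
        pop = burn_in(genome, 30, 60, rng=rng)
        counts = pop.derived_counts()
        assert (counts >= 1).all() and (counts <= 2 * 30 - 1).all()


class TestDrawParentPairs:
    def test_uniform_weights_ordered_pairs_equiprobable(self, rng):
        """With equal fitness all 12 ordered distinct pairs (N=4) are uniform."""
        from scipy import stats

        sires, dams = draw_parent_pairs(rng, 4, 10**5)
        codes = sires * 4 + dams
        observed = np.bincount(codes, minlength=16).reshape(4, 4)
        assert np.trace(observed) == 0  # no selfing
        off_diag = observed[~np.eye(4, dtype=bool)]
        chi2 = stats.chisquare(off_diag)
        assert chi2.pvalue > 1e-4

    def test_zero_fitness_parent_never_drawn(self, rng):
        w = np.array([1.0, 0.0, 1.0, 1.0])
        sires, dams = draw_parent_pairs(rng, 4, 2000, w)
        assert 1 not in set(sires.tolist()) | set(dams.tolist())

    def test_all_zero_raises(self, rng):
        with pytest.raises(ExtinctionError):
            draw_parent_pairs(rng, 4, 10, np.zeros(4))


class TestBurnInNeutralTheory:
    def test_watterson_and_pi(self):
        """Scaled neutral run matches Watterson's E[S] and pairwise diversity.

        N = 50 for 10 N generations on 10 Mb at mu = 1e-8:
        theta = 4 N mu L = 20, E[S] = theta * H_{2N-1} ~ 103.5, pi = 4 N mu /bp.
        """
        genome = GenomeSpec(n_chromosomes=1, chrom_length_bp=10**7,
                            mut_rate=1e-8, deleterious_fraction=0.0)
        n, reps = 50, 20
        theta = 4 * n * genome.mut_rate * genome.total_length_bp
        a = np.sum(1.0 / np.arange(1, 2 * n))
        expected_s = theta * a
        expected_pi = 4 * n * genome.mut_rate
        s_counts, pis = [], []
        for i in range(reps):
            pop = burn_in(genome, n, 10 * n, rng=np.random.default_rng(1000 + i))
            s_counts.append(pop.n_sites)
            p = pop.frequencies()
            pis.append((2 * p * (1 - p) * (2 * n) / (2 * n - 1)).sum()
                       / genome.total_length_bp)
        sem_s = np.std(s_counts, ddof=1) / np.sqrt(reps)
        sem_pi = np.std(pis, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(s_counts) - expected_s) < 3.5 * sem_s + 0.02 * expected_s
        assert abs(np.mean(pis) - expected_pi) < 3.5 * sem_pi + 0.02 * expected_pi

    def test_zero_generations_returns_founders(self, rng):
        pop = burn_in(GenomeSpec(), 10, 0, rng=rng)
        assert pop.n_sites == 0
        assert pop.generation == 0


class TestPurging:
    def test_strong_deleterious_frequency_declines(self, ancestral_pop):
        """Selection removes s > 0.2 alleles in small lines faster than drift.

        Mean frequency of strongly deleterious alleles (conditional on the
        base panel, losses counted as 0) declines over 20 generations with
        natural selection on; drift alone keeps the expectation constant.
        """
        from inbredsim.breeding import SchemeConfig, run_scenario

        deltas = []
        for i in range(60):
            rng = np.random.default_rng(3000 + i)
            res = run_scenario(
                SchemeConfig("RC", 20, 20), ancestral_pop, rng)
            strong = res.line.s > 0.2
            if not strong.any():
                continue
            p0 = res.line.p_base[strong]
            p_now = res.line.genotypes()[:, strong].mean(axis=0) / 2.0
            deltas.append(float((p_now - p0).mean()))
        deltas = np.array(deltas)
        sem = deltas.std(ddof=1) / np.sqrt(deltas.size)
        assert deltas.mean() < -2 * sem  # significantly negative


class TestSerialization:
    def test_round_trip(self, small_ancestral, tmp_path):
        path = tmp_path / "pop.npz"
        save_population(path, small_ancestral)
        back = load_population(path)
        assert back.genome == small_ancestral.genome
        assert (back.H == small_ancestral.H).all()
        assert (back.pos == small_ancestral.pos).all()
        assert back.fixed_log_w == small_ancestral.fixed_log_w
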