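import numpy as np
import pytest

from steppingstone.popstats import pairwise_phi_st, pairwise_wc_theta
from steppingstone.simulate import (
    SimulationParams,
    parameter_set_table,
    proportion_variable_sites,
    replicate_rng,
    simulate_dataset,
    simulate_genealogy,
    simulate_sequences,
)


class TestParameterTable:
    def test_nine_lattice_sets_plus_panmictic_control(self):
        table = parameter_set_table()
        assert len(table) == 10
        assert [p.panmictic for p in table] == [False] * 9 + [True]
        assert table[-1].deme_size == 1e6

    def test_published_combinations(self):
        by_name = {p.name: p for p in parameter_set_table()}
        # set 5: Ne = 1e5, m = 1e-3, Ne*m = 100
        assert by_name["set5"].deme_size == 1e5
        assert by_name["set5"].mig_prop == pytest.approx(1e-3)
        assert by_name["set5"].migrants_per_generation == pytest.approx(100)
        # set 1: Ne = 1e4, m = 1e-3, Ne*m = 10
        assert by_name["set1"].deme_size == 1e4
        assert by_name["set1"].mig_prop == pytest.approx(1e-3)
        assert by_name["set1"].migrants_per_generation == pytest.approx(10)

    def test_migrant_numbers_span_three_decades(self):
        nems = {
            round(p.migrants_per_generation) for p in parameter_set_table()
            if not p.panmictic
        }
        assert nems == {10, 100, 1000}

    def test_shared_constants(self):
        for p in parameter_set_table():
            assert (p.n_demes, p.sample_size, p.locus_length) == (10, 20, 500)
            assert p.mut_rate == 1e-7
            assert p.tstv_ratio == 9.0
            assert p.expansion_time == 10_000.0
            assert p.expansion_factor == 10.0


class TestParamValidation:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            SimulationParams(mig_prop=1.5)
        with pytest.raises(ValueError):
            SimulationParams(expansion_time=0.0)
        with pytest.raises(ValueError):
            SimulationParams(base_freqs=(0.5, 0.5, 0.25, 0.25))
        with pytest.raises(ValueError):
            SimulationParams(n_demes=3, mig_prop=0.0)


class TestGenealogy:
    def test_tree_validity(self, rng):
        params = SimulationParams(
            n_demes=4, deme_size=1e4, mig_prop=1e-2, sample_size=5, name="toy"
        )
        gen = simulate_genealogy(params, rng)
        gen.validate()
        assert gen.n_tips == 20
        # exactly n-1 coalescences, every non-root node has a parent
        assert np.count_nonzero(gen.parent == -1) == 1
        assert gen.time[gen.root] == gen.time.max()

    def test_two_lineage_tmrca_matches_piecewise_expectation(self, rng):
        # single population, instantaneous 10x expansion at T: the pair
        # coalesces at rate 1/N before T (backward) and 10/N after, so the
        # survival integral gives E[T_mrca] = N(1 - e^{-T/N}) + e^{-T/N} N/10
        N, T = 1e4, 1e4
        params = SimulationParams(
            n_demes=1, deme_size=N, mig_prop=0.0, sample_size=2,
            expansion_time=T, panmictic=True,
        )
        expected = N * (1 - np.exp(-T / N)) + np.exp(-T / N) * N / 10
        times = [simulate_genealogy(params, rng).time[-1] for _ in range(4000)]
        se = np.std(times) / np.sqrt(len(times))
        assert abs(np.mean(times) - expected) < 4 * se

    def test_two_deme_tmrca_matches_markov_chain_expectation(self, rng):
        # two demes, one lineage each, constant size: first-step analysis of
        # the competing exponentials (E_apart = 1/(2m) + E_together,
        # E_together = (1 + 2m E_apart)/(1/N + 2m)) solves to
        # E_together = 2N and E_apart = 1/(2m) + 2N.
        N, m = 100.0, 0.02
        e_apart = 1.0 / (2 * m) + 2 * N
        params = SimulationParams(
            n_demes=2, deme_size=N, mig_prop=m, sample_size=1,
            expansion_time=1e12,
        )
        times = [simulate_genealogy(params, rng).time[-1] for _ in range(4000)]
        se = np.std(times) / np.sqrt(len(times))
        assert abs(np.mean(times) - e_apart) < 4 * se


class TestSequences:
    def test_zero_mutation_rate_gives_identical_sequences(self, rng):
        params = SimulationParams(
            n_demes=2, deme_size=1e4, mig_prop=0.01, sample_size=3,
            mut_rate=0.0, locus_length=100,
        )
        gen = simulate_genealogy(params, rng)
        aln = simulate_sequences(gen, params, rng)
        assert len(set(aln.sequences)) == 1

    def test_high_diversity_set_saturates(self, rng):
        params = [p for p in parameter_set_table() if p.name == "set9"][0]
        aln = simulate_dataset(params, rng)
        assert proportion_variable_sites(aln) > 0.60

    def test_labels_and_shapes(self, rng):
        params = SimulationParams(
            n_demes=3, deme_size=1e4, mig_prop=0.01, sample_size=4
        )
        aln = simulate_dataset(params, rng)
        assert aln.codes.shape == (12, 500)
        assert aln.ids[0] == "deme0_ind1"
        assert aln.deme_of["deme2_ind4"] == 2
        assert list(aln.lattice_position) == [0.0, 1.0, 2.0]

    def test_panmictic_pseudo_demes_are_sampling_blocks(self, rng):
        params = SimulationParams(
            deme_size=1e5, mig_prop=0.0, panmictic=True, sample_size=4,
            n_demes=5,
        )
        aln = simulate_dataset(params, rng)
        assert aln.n_demes == 5
        assert np.all(aln.deme_of_sample == np.repeat(np.arange(5), 4))


class TestReproducibility:
    def test_replicate_streams_are_deterministic_and_distinct(self):
        params = SimulationParams(
            n_demes=2, deme_size=1e4, mig_prop=0.01, sample_size=3
        )
        a = simulate_dataset(params, replicate_rng(7, 2, 0))
        b = simulate_dataset(params, replicate_rng(7, 2, 0))
        c = simulate_dataset(params, replicate_rng(7, 2, 1))
        assert np.array_equal(a.codes, b.codes)
        assert not np.array_equal(a.codes, c.codes)


class TestStatisticalControls:
    def test_panmictic_control_has_no_differentiation(self, session_rng):
        """Mean pairwise Phi_ST and theta across pseudo-demes sit at zero
        within Monte-Carlo error over replicate panmictic datasets."""
        params = SimulationParams(
            deme_size=1e5, mig_prop=0.0, panmictic=True, sample_size=5,
            n_demes=6,
        )
        phis, thetas = [], []
        iu = np.triu_indices(6, k=1)
        for _ in range(100):
            aln = simulate_dataset(params, session_rng.spawn(1)[0])
            phis.append(pairwise_phi_st(aln).values[iu].mean())
            thetas.append(pairwise_wc_theta(aln).values[iu].mean())
        for vals in (phis, thetas):
            mean = np.mean(vals)
            se = np.std(vals) / np.sqrt(len(vals))
            assert abs(mean) < 2 * se + 1e-3

    def test_lattice_reflection_symmetry(self, session_rng):
        """Relabeling demes by reflecting the lattice leaves the expected
        pairwise differentiation unchanged (exchangeability)."""
        params = SimulationParams(
            n_demes=4, deme_size=1e4, mig_prop=2.5e-3, sample_size=5
        )
        mats = [
            pairwise_phi_st(simulate_dataset(params, session_rng.spawn(1)[0])).values
            for _ in range(60)
        ]
        mean = np.mean(mats, axis=0)
        reflected = mean[::-1, ::-1]
        spread = np.std(mats, axis=0) / np.sqrt(len(mats))
        off = np.triu_indices(4, k=1)
        assert np.all(
            np.abs(mean[off] - reflected[off]) < 5 * spread[off] + 0.02
        )


class TestCoalescentOracle:
    """Cross-validation of the simulator against msprime configured with the
    same demography (sizes, expansion, neighbor migration)."""

    @pytest.fixture(scope="class")
    def distributions(self, session_rng):
        import msprime

        N, m, T = 1e4, 1e-3, 1e4
        n_demes, n_per, L, mu = 3, 5, 500, 1e-7
        params = SimulationParams(
            n_demes=n_demes, deme_size=N, mig_prop=m, sample_size=n_per,
            locus_length=L, mut_rate=mu, expansion_time=T,
        )
        ours_S, ours_pi = [], []
        for _ in range(150):
            aln = simulate_dataset(params, session_rng.spawn(1)[0])
            ours_S.append(int(np.sum(aln.codes.min(0) != aln.codes.max(0))))
            d = (aln.codes[:, None, :] != aln.codes[None, :, :]).sum(axis=2)
            iu = np.triu_indices(aln.n_samples, k=1)
            ours_pi.append(float(d[iu].mean()))

        demography = msprime.Demography()
        for i in range(n_demes):
            demography.add_population(name=f"d{i}", initial_size=N)
        for i in range(n_demes - 1):
            demography.set_migration_rate(f"d{i}", f"d{i+1}", m)
            demography.set_migration_rate(f"d{i+1}", f"d{i}", m)
        for i in range(n_demes):
            demography.add_population_parameters_change(
                time=T, population=f"d{i}", initial_size=N / 10
            )
        other_S, other_pi = [], []
        ms_seeds = session_rng.integers(1, 2**31 - 1, size=2 * 150)
        for k in range(150):
            ts = msprime.sim_ancestry(
                samples={f"d{i}": n_per for i in range(n_demes)},
                demography=demography, ploidy=1, sequence_length=L,
                random_seed=int(ms_seeds[2 * k]),
            )
            mts = msprime.sim_mutations(
                ts, rate=mu, model=msprime.HKY(kappa=9.0),
                random_seed=int(ms_seeds[2 * k + 1]),
            )
            gm = mts.genotype_matrix()
            var = gm.max(axis=1) != gm.min(axis=1)
            other_S.append(int(var.sum()))
            if gm.shape[0]:
                iu = np.triu_indices(gm.shape[1], k=1)
                diffs = (gm[:, :, None] != gm[:, None, :]).sum(axis=0)
                other_pi.append(float(diffs[iu].mean()))
            else:
                other_pi.append(0.0)
        return (ours_S, other_S), (ours_pi, other_pi)

    def test_segregating_sites_distribution_matches(self, distributions):
        from scipy.stats import ks_2samp

        (ours, other), _ = distributions
        assert ks_2samp(ours, other).pvalue > 0.01

    def test_mean_pairwise_differences_distribution_matches(self, distributions):
        from scipy.stats import ks_2samp

        _, (ours, other) = distributions
        assert ks_2samp(ours, other).pvalue > 0.01
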