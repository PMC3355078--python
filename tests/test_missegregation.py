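import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyocin.karyotype import Karyotype
from karyocin.missegregation import (
    MisSegConfig,
    divide_cell,
    simulate_colony,
    simulate_population,
)

from .oracles import naive_population_sim


class TestDivideCell:
    def test_faithful_division_at_rate_zero(self, rng, diploid):
        d1, d2 = divide_cell(diploid, 0.0, rng)
        assert d1 == diploid and d2 == diploid

    def test_forced_event_splits_every_chromosome(self, rng, diploid):
        d1, d2 = divide_cell(diploid, 1.0, rng)
        for a, b in zip(d1.copies, d2.copies):
            assert sorted((a, b)) == [1, 3]

    def test_monosomic_chromosome_yields_dead_daughter(self, rng, haploid):
        d1, d2 = divide_cell(haploid, 1.0, rng)
        for a, b in zip(d1.copies, d2.copies):
            assert sorted((a, b)) == [0, 2]
        assert not (d1.is_live and d2.is_live)

    def test_all_copies_mode_moves_whole_complement(self, rng, diploid):
        d1, d2 = divide_cell(diploid, 1.0, rng, mode="all_copies")
        for a, b in zip(d1.copies, d2.copies):
            assert sorted((a, b)) == [0, 4]

    @given(
        copies=st.lists(st.integers(1, 3), min_size=16, max_size=16),
        p=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=80, deadline=None)
    def test_copy_number_conservation(self, copies, p, seed):
        parent = Karyotype.from_iterable(copies)
        rng = np.random.default_rng(seed)
        d1, d2 = divide_cell(parent, p, rng)
        for a, b, c in zip(d1.copies, d2.copies, parent.copies):
            assert a + b == 2 * c


class TestSimulatePopulation:
    def test_rate_zero_no_deviants(self, diploid):
        config = MisSegConfig(
            seed_karyotype=diploid,
            missegregation_rate=0.0,
            generations=10,
            population_cap=500,
            replicates=5,
            rng_seed=1,
        )
        result = simulate_population(config)
        assert result.fractions == (0.0,) * 5
        assert result.n_extinct == 0

    def test_reproducible_under_fixed_seed(self, diploid):
        config = MisSegConfig(
            seed_karyotype=diploid,
            missegregation_rate=5e-3,
            generations=8,
            population_cap=200,
            replicates=4,
            rng_seed=99,
        )
        assert simulate_population(config).fractions == simulate_population(config).fractions

    def test_deviant_fraction_monotone_in_rate(self, diploid):
        # common random numbers: same seed, increasing rates
        medians = []
        for rate in (1e-4, 1e-3, 1e-2):
            config = MisSegConfig(
                seed_karyotype=diploid,
                missegregation_rate=rate,
                generations=12,
                population_cap=2000,
                replicates=10,
                rng_seed=7,
            )
            medians.append(simulate_population(config).median)
        assert medians[0] <= medians[1] <= medians[2]

    def test_small_p_analytic_limit(self, diploid):
        # seed all-2: death negligible, mean fraction ~ 1 - (1-p)^(16 g)
        p, g = 5e-4, 6
        config = MisSegConfig(
            seed_karyotype=diploid,
            missegregation_rate=p,
            generations=g,
            population_cap=10_000,
            replicates=40,
            rng_seed=11,
        )
        result = simulate_population(config)
        expected = 1 - (1 - p) ** (16 * g)
        observed = np.mean(result.fractions)
        se = np.std(result.fractions, ddof=1) / np.sqrt(len(result.fractions))
        assert observed == pytest.approx(expected, abs=max(3 * se, 0.01))

    def test_matches_naive_cell_by_cell_simulator(self, diploid):
        # independent oracle: explicit cell list, same division rules
        p, g, reps = 0.01, 3, 400
        rng = np.random.default_rng(5)
        naive = [
            naive_population_sim(tuple(diploid.copies), p, g, rng)
            for _ in range(reps)
        ]
        config = MisSegConfig(
            seed_karyotype=diploid,
            missegregation_rate=p,
            generations=g,
            population_cap=100_000,
            replicates=reps,
            rng_seed=6,
        )
        grouped = simulate_population(config).fractions
        se = np.sqrt(
            np.var(naive, ddof=1) / reps + np.var(grouped, ddof=1) / len(grouped)
        )
        assert np.mean(grouped) == pytest.approx(np.mean(naive), abs=3 * se)

    def test_exact_one_generation_mean(self, diploid):
        # after a single division the deviant fraction is 1 iff any event
        p = 0.02
        config = MisSegConfig(
            seed_karyotype=diploid,
            missegregation_rate=p,
            generations=1,
            population_cap=10,
            replicates=600,
            rng_seed=3,
        )
        result = simulate_population(config)
        expected = 1 - (1 - p) ** 16
        se = np.std(result.fractions, ddof=1) / np.sqrt(len(result.fractions))
        assert np.mean(result.fractions) == pytest.approx(expected, abs=3 * se)


class TestColonyBookkeeping:
    def test_population_cap_enforced(self, diploid, rng):
        colony = simulate_colony(
            diploid, 0.0, 12, population_cap=1000, rng=rng
        )
        assert colony.size == 1000

    def test_lineage_log_consistent_with_groups(self, diploid, rng):
        colony = simulate_colony(
            diploid, 2e-3, 10, population_cap=2000, rng=rng, track_lineages=True
        )
        lineage_ids = {lin for (_, lin) in colony.groups}
        assert lineage_ids <= set(colony.lineages)
        for (karyo, lin), _ in colony.groups.items():
            if lin != 0:
                assert colony.lineages[lin].karyotype == karyo

    def test_sampling_without_replacement_matches_counts(self, diploid, rng):
        colony = simulate_colony(diploid, 0.0, 8, population_cap=300, rng=rng)
        cells = colony.sample_cells(11, rng)
        assert len(cells) == 11
        assert all(k == diploid for k, _ in cells)
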