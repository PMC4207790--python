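import numpy as np
import pytest
from scipy import stats as sps

from adaptmut.experiment import (
    ColonyRecord,
    ExperimentParams,
    GrowthPhaseParams,
    LineageTable,
    fluctuation_summary,
    grow_division_tree,
    simulate_colony_growth,
    simulate_lineage,
)


def make_table(counts_per_lineage):
    """Lineage table with the given number of mutant colonies per lineage."""
    colonies = []
    for lid, k in enumerate(counts_per_lineage):
        for cid in range(k):
            colonies.append(
                ColonyRecord(lid, cid, True, ((f"m{lid}_{cid}", 0),), 1.0)
            )
    return LineageTable(n_lineages=len(counts_per_lineage), colonies=tuple(colonies))


class TestParams:
    def test_rejects_empty_wells(self):
        with pytest.raises(ValueError):
            ExperimentParams(cells_per_well_range=(0, 10))

    def test_rejects_unknown_model(self):
        with pytest.raises(ValueError, match="unknown mutation_model"):
            ExperimentParams(mutation_model="lamarckian")

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            ExperimentParams(p_adapt=1.5)


class TestSimulateLineage:
    def test_zero_induced_probability_gives_no_mutations(self):
        params = ExperimentParams(
            n_lineages=20, mutation_model="induced", p_induced=0.0, seed=3
        )
        table = simulate_lineage(params)
        assert len(table) > 0
        assert all(c.mutations == () for c in table.colonies)

    def test_emergence_generation_two_gives_quarter_fraction(self):
        params = ExperimentParams(
            n_lineages=10, mutation_model="induced", p_induced=1.0, seed=4
        )
        table = simulate_lineage(params)
        gen2 = [c for c in table.colonies if c.mutations[0][1] == 2]
        assert gen2, "expected some generation-2 emergences"
        assert all(c.mutant_fraction == 0.25 for c in gen2)

    def test_mutant_fraction_is_power_of_two(self):
        params = ExperimentParams(
            n_lineages=10, mutation_model="induced", p_induced=1.0, seed=5
        )
        for c in simulate_lineage(params).colonies:
            g = c.mutations[0][1]
            assert g in (0, 1, 2)
            assert c.mutant_fraction == 2.0 ** (-g)

    def test_none_model_has_no_mutations(self):
        params = ExperimentParams(n_lineages=5, mutation_model="none", seed=6)
        assert all(
            c.mutations == () for c in simulate_lineage(params).colonies
        )

    def test_adding_lineages_preserves_earlier_ones(self):
        base = dict(mutation_model="induced", p_induced=0.3, seed=7)
        small = simulate_lineage(ExperimentParams(n_lineages=10, **base))
        large = simulate_lineage(ExperimentParams(n_lineages=25, **base))
        first = [c for c in large.colonies if c.lineage_id < 10]
        assert first == list(small.colonies)

    def test_colony_conservation(self):
        params = ExperimentParams(n_lineages=30, seed=8)
        table = simulate_lineage(params)
        assert len(table) == table.colony_counts_per_lineage().sum()


class TestDivisionTree:
    @pytest.mark.parametrize("n_cells", [1, 2, 3, 5, 8, 13, 16])
    def test_division_event_count_by_enumeration(self, n_cells):
        # with mu = 1 every division event mutates, so the number of mutation
        # events enumerates the division events exactly: n_cells - 1
        rng = np.random.default_rng(0)
        classes = grow_division_tree(n_cells, 1.0, rng)
        assert sum(c for _, c in classes) == n_cells
        n_events = len(classes) - 1
        assert n_events == n_cells - 1

    def test_mean_founder_mutations_matches_enumeration(self):
        # each of the n-1 division events mutates with probability mu, so
        # the exact expectation is mu * (n - 1); check the simulator lands
        # within 3 Monte-Carlo standard errors over 10^4 replicate wells
        mu, n_cells, reps = 1e-3, 1000, 10_000
        rng = np.random.default_rng(42)
        events = np.empty(reps)
        for r in range(reps):
            classes = grow_division_tree(n_cells, mu, rng)
            events[r] = len(classes) - 1
        expected = mu * (n_cells - 1)
        se = events.std(ddof=1) / np.sqrt(reps)
        assert abs(events.mean() - expected) < 3 * se


class TestFluctuationSummary:
    def test_constant_counts_have_zero_ratio(self):
        summary = fluctuation_summary(make_table([1] * 10))
        assert summary.variance_to_mean == 0.0
        assert summary.fraction_lineages_with_mutant == 1.0
        assert summary.histogram == {1: 10}

    def test_single_lineage_rejected(self):
        with pytest.raises(ValueError, match="single lineage"):
            fluctuation_summary(make_table([3]))

    def test_histogram_counts_lineages(self):
        summary = fluctuation_summary(make_table([0, 0, 1, 2, 2]))
        assert summary.histogram == {0: 2, 1: 1, 2: 2}
        assert summary.n_lineages == 5


class TestExchangeability:
    def test_induced_counts_are_exchangeable_across_lineages(self):
        # permutation p-values of a label-dependent statistic must be uniform
        # when mutant counts are exchangeable (KS check over replicates)
        n_sims, n_perm = 200, 199
        rng = np.random.default_rng(123)
        pvals = np.empty(n_sims)
        for s in range(n_sims):
            params = ExperimentParams(
                n_lineages=25,
                cells_per_well_range=(200, 400),
                p_adapt=0.05,
                mutation_model="induced",
                p_induced=0.2,
                seed=10_000 + s,
            )
            counts = simulate_lineage(params).mutant_counts_per_lineage()
            weights = np.arange(len(counts), dtype=float)
            obs = float(weights @ counts)
            perms = np.array(
                [weights @ rng.permutation(counts) for _ in range(n_perm)]
            )
            n_greater = int((perms > obs).sum())
            n_equal = int((perms == obs).sum())
            # randomized tie-breaking makes the p-value exactly uniform
            pvals[s] = (n_greater + rng.uniform() * (n_equal + 1)) / (n_perm + 1)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestSharedMutations:
    @staticmethod
    def _share_probability(mu, reps, seed):
        rng = np.random.default_rng(seed)
        shared = 0
        for _ in range(reps):
            classes = grow_division_tree(128, mu, rng)
            hit = False
            for muts, count in classes:
                if not muts:
                    continue
                n_colonies = rng.binomial(count, 0.25)
                if n_colonies >= 2:
                    hit = True
                    break
            shared += hit
        return shared / reps

    def test_sharing_probability_increases_with_mu(self):
        reps = 10_000
        probs = [
            self._share_probability(mu, reps, seed)
            for seed, mu in enumerate((5e-4, 2e-3, 8e-3))
        ]
        assert probs[0] > 0.0
        assert probs[0] < probs[1] < probs[2]


class TestColonyGrowth:
    def test_zero_noise_plateau_is_exactly_constant(self):
        t = np.arange(0.0, 200.0, 2.0)
        params = GrowthPhaseParams(t1=30.0, t2=90.0, s2=0.0, noise=0.0)
        curve = simulate_colony_growth(t, params, seed=1)
        mask = (curve.series.t >= curve.t1) & (curve.series.t <= curve.t2)
        plateau = curve.series.area[mask]
        assert np.all(plateau == plateau[0])

    def test_defaults_place_arrest_at_two_to_three_days(self):
        params = GrowthPhaseParams()
        arrest_hours = params.t2 - params.t1
        assert 48.0 <= arrest_hours <= 72.0

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate_colony_growth(np.array([0.0, 2.0, 1.0, 3.0] * 5))

    def test_changepoints_snap_to_grid(self):
        t = np.arange(0.0, 200.0, 4.0)
        curve = simulate_colony_growth(
            t, GrowthPhaseParams(t1=31.0, t2=89.0), seed=2
        )
        assert curve.t1 in t and curve.t2 in t
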