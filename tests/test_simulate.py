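"""Simulator validation: renewal-process behaviour, genotype propagation,
analytic oracles, and determinism."""

import math

import numpy as np
import pytest

from tetramap import (
    IntervalClass,
    Locus,
    MarkerMap,
    SegregationClass,
    classify_interval,
    count_breakpoints,
    npd_interference_ratio,
    papazian_expected_fraction,
    segregation_class,
    tabulate_interval,
)
from tetramap.errors import InputError
from tetramap.simulate import (
    NondisjunctionMode,
    SimParams,
    closed_form_tetrad_probs,
    expected_perkins_cm,
    place_crossovers,
    simulate_cohort,
    simulate_tetrad,
)
from tetramap.tetrads import IntervalCounts


class TestPlaceCrossovers:
    def test_poisson_reduction(self, rng):
        """Shape 1 gives Poisson(2L) event counts: mean 1.0 at L = 0.5."""
        n = 10_000
        counts = np.array([len(place_crossovers(0.5, 1.0, rng)) for _ in range(n)])
        se = math.sqrt(1.0 / n)  # Poisson variance = mean
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_poisson_independent_subintervals(self, rng):
        """Shape-1 counts on disjoint subintervals are uncorrelated."""
        n = 10_000
        k1, k2 = np.empty(n), np.empty(n)
        for i in range(n):
            xs = np.asarray(place_crossovers(1.0, 1.0, rng))
            k1[i] = np.count_nonzero(xs < 0.4)
            k2[i] = np.count_nonzero(xs >= 0.6)
        cov = np.cov(k1, k2)[0, 1]
        # Var(cov-hat) ~ Var(k1)Var(k2)/n for independent Poissons
        assert abs(cov) < 3 * math.sqrt(0.8 * 0.8 / n)

    def test_interference_underdisperses_counts(self, rng):
        counts = np.array([len(place_crossovers(0.5, 10.0, rng)) for _ in range(5_000)])
        assert counts.var() < 0.6 * counts.mean()  # well below Poisson

    def test_stationary_rate_for_general_shape(self, rng):
        """The equilibrium first-arrival makes the event rate exactly 2/Morgan
        for any shape."""
        n = 10_000
        counts = np.array([len(place_crossovers(0.5, 5.0, rng)) for _ in range(n)])
        se = math.sqrt(counts.var() / n)
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_positions_sorted_and_in_range(self, rng):
        for shape in (1.0, 3.5):
            xs = place_crossovers(2.0, shape, rng)
            assert xs == sorted(xs)
            assert all(0 <= x < 2.0 for x in xs)

    def test_invalid_inputs(self, rng):
        with pytest.raises(InputError):
            place_crossovers(0.0, 1.0, rng)
        with pytest.raises(InputError):
            place_crossovers(1.0, -1.0, rng)


class TestSimulateTetrad:
    def test_no_crossovers_gives_parental_ditypes(self, chr3_map, rng):
        params = SimParams(marker_map=chr3_map, n_tetrads=1, seed=0)
        for _ in range(50):
            tetrad, truth = simulate_tetrad(params, rng)
            if any(truth.events.values()):
                continue
            for a, b in (("A", "B"), ("B", "C"), ("A", "C")):
                assert classify_interval(tetrad, chr3_map, a, b) is IntervalClass.PD

    def test_single_crossover_in_interval_gives_tetratype(self, chr3_map, rng):
        params = SimParams(marker_map=chr3_map, n_tetrads=1, seed=0)
        seen = 0
        for _ in range(300):
            tetrad, truth = simulate_tetrad(params, rng)
            events = truth.events["III"]
            if len(events) == 1 and 0.0 < events[0][0] < 0.2:
                assert classify_interval(tetrad, chr3_map, "A", "B") is IntervalClass.TT
                seen += 1
        assert seen > 10

    def test_mendelian_segregation_without_conversion(self, chr3_map, rng):
        params = SimParams(marker_map=chr3_map, n_tetrads=1, seed=0)
        for _ in range(100):
            tetrad, _ = simulate_tetrad(params, rng)
            for locus in chr3_map.names:
                assert segregation_class(tetrad, chr3_map, locus) is SegregationClass.TWO_TWO

    def test_forced_conversion_gives_non_mendelian_segregation(self, rng):
        mm = MarkerMap([Locus("A", "I", 0.1)])
        params = SimParams(marker_map=mm, n_tetrads=1, seed=0, conversion_rate=1.0)
        for _ in range(50):
            tetrad, truth = simulate_tetrad(params, rng)
            assert segregation_class(tetrad, mm, "A") in (
                SegregationClass.THREE_ONE,
                SegregationClass.ONE_THREE,
            )
            assert len(truth.conversions) == 1

    def test_breakpoints_track_crossover_events(self, rng):
        """Each crossover recombines exactly two chromatids, so total spore
        breakpoints equal twice the number of events landing in marked
        intervals — exactly so when no two events share an inter-marker gap
        (multi-event gaps can cancel)."""
        mm = MarkerMap([Locus(f"L{i}", "II", 0.25 * i) for i in range(5)])
        params = SimParams(marker_map=mm, n_tetrads=1, seed=0)
        positions = [0.25 * i for i in range(5)]
        checked = 0
        for _ in range(200):
            tetrad, truth = simulate_tetrad(params, rng)
            events = [x for x, _, _ in truth.events["II"] if x < 1.0]
            gaps = [sum(1 for x in events if lo < x < hi)
                    for lo, hi in zip(positions, positions[1:])]
            total_bp = sum(count_breakpoints(s, mm, "II") for s in tetrad.spores)
            assert total_bp % 2 == 0
            assert total_bp <= 2 * len(events)
            if all(g <= 1 for g in gaps):
                assert total_bp == 2 * len(events)
                checked += 1
        assert checked > 50

    def test_obligate_crossover(self, chr3_map, rng):
        params = SimParams(
            marker_map=chr3_map, n_tetrads=1, seed=0, obligate_crossover=True
        )
        for _ in range(50):
            _, truth = simulate_tetrad(params, rng)
            assert len(truth.events["III"]) >= 1


class TestViabilityModel:
    def test_no_death_processes_all_four_viable(self, chr3_map):
        params = SimParams(marker_map=chr3_map, n_tetrads=200, seed=3)
        tetrads, _ = simulate_cohort(params)
        assert all(t.n_viable == 4 for t in tetrads)

    def test_random_death_rate(self, chr3_map):
        params = SimParams(
            marker_map=chr3_map, n_tetrads=4000, seed=3, p_random_spore_death=0.2
        )
        tetrads, _ = simulate_cohort(params)
        dead = sum(4 - t.n_viable for t in tetrads)
        p_hat = dead / (4 * len(tetrads))
        assert abs(p_hat - 0.2) < 3 * math.sqrt(0.2 * 0.8 / (4 * 4000))

    def test_mi_nondisjunction_kills_whole_tetrads(self):
        mm = MarkerMap([Locus("A", "I", 0.01), Locus("B", "I", 0.02)])  # tiny: mostly CO-less
        params = SimParams(
            marker_map=mm, n_tetrads=500, seed=3, p_nondisjunction_if_no_crossover=1.0
        )
        tetrads, truth = simulate_cohort(params)
        for tetrad, t_truth in zip(tetrads, truth.tetrads):
            if not t_truth.events["I"]:
                assert tetrad.n_viable == 0

    def test_nullisomic_mode_kills_spore_pairs(self):
        mm = MarkerMap([Locus("A", "I", 0.01), Locus("B", "I", 0.02)])
        params = SimParams(
            marker_map=mm,
            n_tetrads=500,
            seed=3,
            p_nondisjunction_if_no_crossover=1.0,
            nondisjunction_mode=NondisjunctionMode.NULLISOMIC_ONLY,
        )
        tetrads, truth = simulate_cohort(params)
        for tetrad, t_truth in zip(tetrads, truth.tetrads):
            if not t_truth.events["I"]:
                assert tetrad.n_viable == 2

    def test_dead_spores_written_all_missing(self, chr3_map):
        params = SimParams(
            marker_map=chr3_map, n_tetrads=200, seed=3, p_random_spore_death=0.5
        )
        tetrads, _ = simulate_cohort(params)
        for tetrad in tetrads:
            for spore in tetrad.spores:
                if not spore.viable:
                    assert set(spore.calls) == {"-"}


class TestDeterminism:
    def test_cohort_outputs_byte_identical(self, chr3_map, tmp_path):
        params = SimParams(
            marker_map=chr3_map, n_tetrads=100, seed=42, interference_shape=4.0,
            conversion_rate=0.01, p_random_spore_death=0.05,
        )
        simulate_cohort(params, out_dir=tmp_path / "a")
        simulate_cohort(params, out_dir=tmp_path / "b")
        for name in ("tetrads.tsv", "markers.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_seed_changes_output(self, chr3_map):
        a, _ = simulate_cohort(SimParams(marker_map=chr3_map, n_tetrads=50, seed=1))
        b, _ = simulate_cohort(SimParams(marker_map=chr3_map, n_tetrads=50, seed=2))
        assert any(
            sa.calls != sb.calls for ta, tb in zip(a, b) for sa, sb in zip(ta.spores, tb.spores)
        )


class TestClosedForm:
    def test_zero_length(self):
        assert closed_form_tetrad_probs(0.0) == (1.0, 0.0, 0.0)

    def test_saturation_limit(self):
        pd, tt, npd = closed_form_tetrad_probs(20.0)
        assert pd == pytest.approx(1 / 6, abs=1e-6)
        assert tt == pytest.approx(2 / 3, abs=1e-6)
        assert npd == pytest.approx(1 / 6, abs=1e-6)

    @pytest.mark.parametrize("x", [0.05, 0.1, 0.2, 0.4, 1.0])
    def test_tetratype_closed_form(self, x):
        _, tt, _ = closed_form_tetrad_probs(x)
        assert tt == pytest.approx(2.0 / 3.0 * (1.0 - math.exp(-3.0 * x)), abs=1e-12)

    @pytest.mark.parametrize("x", [0.05, 0.1, 0.2, 0.4, 1.0])
    def test_papazian_self_consistency(self, x):
        """Feeding the no-interference class probabilities into the Papazian
        expectation returns the model's own NPD probability exactly."""
        _, tt, npd = closed_form_tetrad_probs(x)
        frac = papazian_expected_fraction(tt)
        assert abs(npd / frac - 1.0) <= 1e-9

    def test_probabilities_sum_to_one(self):
        for x in (0.01, 0.3, 2.0):
            assert sum(closed_form_tetrad_probs(x)) == pytest.approx(1.0, abs=1e-12)

    def test_negative_length_rejected(self):
        with pytest.raises(InputError):
            closed_form_tetrad_probs(-0.1)


class TestCohortStatistics:
    def test_class_frequencies_match_closed_form(self):
        """Shape-1 cohorts reproduce the analytic (PD, TT, NPD) frequencies."""
        mm = MarkerMap([Locus("A", "III", 0.0), Locus("B", "III", 0.1)])
        n = 20_000
        tetrads, _ = simulate_cohort(SimParams(marker_map=mm, n_tetrads=n, seed=11))
        c = tabulate_interval(tetrads, mm, "A", "B")
        for obs, p in zip((c.pd, c.tt, c.npd), closed_form_tetrad_probs(0.1)):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(obs / n - p) < 3 * se

    def test_npd_ratio_decreases_with_interference(self):
        """Observed/expected NPDs fall monotonically with the shape parameter."""
        mm = MarkerMap([Locus("A", "III", 0.0), Locus("B", "III", 0.2)])
        ratios = []
        for shape in (1.0, 4.0, 10.0):
            tetrads, _ = simulate_cohort(
                SimParams(marker_map=mm, n_tetrads=20_000, seed=5, interference_shape=shape)
            )
            c = tabulate_interval(tetrads, mm, "A", "B")
            res = npd_interference_ratio(c)
            ratios.append(res.npd_obs / res.npd_exp)
        assert ratios[0] > ratios[1] > ratios[2]
        assert abs(ratios[0] - 1.0) < 0.15  # no interference: ratio near 1

    def test_perkins_estimate_consistent_with_oracle(self):
        """Simulated-then-estimated distances converge on the analytic
        expectation of the Perkins estimator as the cohort grows."""
        mm = MarkerMap([Locus("A", "III", 0.0), Locus("B", "III", 0.2)])
        oracle = expected_perkins_cm(0.2)
        from tetramap import perkins_map_distance

        for n, seed in ((500, 21), (5000, 22), (50_000, 23)):
            tetrads, _ = simulate_cohort(SimParams(marker_map=mm, n_tetrads=n, seed=seed))
            est = perkins_map_distance(tabulate_interval(tetrads, mm, "A", "B"))
            # the estimator is a per-tetrad score mean, so its deviation from
            # the analytic expectation shrinks with the standard error
            assert abs(est.cM - oracle) < 3 * est.se
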