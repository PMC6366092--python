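"""ADM construction: density calibration, threshold selection, plot ratios."""

import numpy as np
import pytest

import admap
from admap.adm import ADM, _solve_density_parameter, round_half_away
from admap.errors import InvalidIntervalError, NoStatisticsError, ValidationError
from admap.stats import AA_ORDER, AvgDistanceTable

from conftest import random_sequence


def sparse_table(entries, min_count=10, max_M=9):
    """Table with only the listed (aa, aa, M, mean) cells significant."""
    mean = np.full((20, 20, max_M), np.nan)
    count = np.zeros((20, 20, max_M), dtype=np.int64)
    for a, b, M, d in entries:
        ia, ib = AA_ORDER.index(a), AA_ORDER.index(b)
        mean[ia, ib, M - 1] = mean[ib, ia, M - 1] = d
        count[ia, ib, M - 1] = count[ib, ia, M - 1] = min_count
    return AvgDistanceTable(mean=mean, count=count, min_count=min_count)


class TestTargetPlotCount:
    @pytest.mark.parametrize("N,C,expected", [(2, 36.12, 18), (101, 36.12, 1806), (50, 0.0, 0)])
    def test_density_law(self, N, C, expected):
        assert admap.target_plot_count(N, C) == expected

    def test_round_half_away(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(1.5) == 2
        assert round_half_away(-0.5) == -1


class TestDensityParameter:
    def test_single_range(self):
        assert _solve_density_parameter({1: 100}, 50) == pytest.approx(0.5)

    def test_two_ranges_share_one_scalar(self):
        D = _solve_density_parameter({1: 100, 2: 100}, 90)
        assert D == pytest.approx(0.6)
        assert round_half_away(D * 100) == 60
        assert round_half_away(D / 2 * 100) == 30

    def test_saturation_cancels_the_range_factor(self):
        """At D = M a range plots all of its significant pairs."""
        assert _solve_density_parameter({3: 50}, 50) == pytest.approx(3.0)

    def test_saturation_point_respected_in_mixture(self):
        # range 1 saturates (D >= 1) before the target is met
        D = _solve_density_parameter({1: 10, 2: 100}, 70)
        # f(D) = 10 + (D/2)*100 for D >= 1  ->  D = 1.2
        assert D == pytest.approx(1.2)

    def test_no_statistics(self):
        with pytest.raises(NoStatisticsError):
            _solve_density_parameter({1: 0, 2: 0}, 10)


class TestBuildAdm:
    def test_single_candidate_is_plotted(self):
        table = sparse_table([("A", "G", 1, 5.0)])
        adm = admap.build_adm("ACG", table)
        assert adm.n_plots == 1
        assert tuple(adm.plots[0]) == (1, 3)
        assert adm.density == pytest.approx(1 / 3)

    def test_zero_target_gives_empty_map(self, uniform_table):
        adm = admap.build_adm("ACDEFGHIKL", uniform_table, C=0.0)
        assert adm.n_plots == 0

    def test_all_insignificant_raises(self):
        table = sparse_table([("A", "G", 1, 5.0)])
        with pytest.raises(NoStatisticsError):
            admap.build_adm("CDEF", table)

    def test_density_calibration_over_lengths(self, uniform_table, rng):
        """|density * N - C| <= 5% of C across the 60-219 residue span."""
        C = 36.12
        for N in (60, 101, 150, 219):
            seq = random_sequence(rng, N)
            adm = admap.build_adm(seq, uniform_table, C=C)
            assert abs(adm.density * N - C) <= 0.05 * C

    def test_raising_c_never_removes_plots(self, uniform_table, rng):
        seq = random_sequence(rng, 80)
        low = admap.build_adm(seq, uniform_table, C=20.0)
        high = admap.build_adm(seq, uniform_table, C=36.12)
        low_set = {tuple(p) for p in low.plots}
        high_set = {tuple(p) for p in high.plots}
        assert low_set <= high_set

    def test_deterministic(self, uniform_table, rng):
        seq = random_sequence(rng, 90)
        a = admap.build_adm(seq, uniform_table)
        b = admap.build_adm(seq, uniform_table)
        assert np.array_equal(a.plots, b.plots)
        assert a.thresholds == b.thresholds

    def test_x_residues_are_unplottable(self, uniform_table):
        adm = admap.build_adm("ACDEFGXHIKLM", uniform_table)
        assert not np.any(adm.plots == 7)  # position of the X

    def test_thresholds_reproduce_selection_up_to_ties(self, uniform_table, rng):
        """Significant pairs below the range threshold recover the plotted set;
        the only admissible difference is index-tie-broken pairs exactly at the
        largest plotted distance of their range."""
        seq = random_sequence(rng, 70)
        adm = admap.build_adm(seq, uniform_table)
        plotted = {tuple(map(int, p)) for p in adm.plots}
        boundary = {
            M: adm.plot_dist[adm.plot_M == M].max()
            for M in adm.thresholds
            if np.any(adm.plot_M == M)
        }
        recovered = set()
        for i in range(1, adm.N + 1):
            for j in range(i + 1, adm.N + 1):
                M = admap.range_index(j - i, uniform_table.max_M)
                if M is None or M not in adm.thresholds:
                    continue
                mean, count = uniform_table.lookup(seq[i - 1], seq[j - 1], M)
                if count >= uniform_table.min_count and mean < adm.thresholds[M]:
                    recovered.add((i, j))
        assert plotted <= recovered
        for i, j in recovered - plotted:
            M = admap.range_index(j - i, uniform_table.max_M)
            mean, _ = uniform_table.lookup(seq[i - 1], seq[j - 1], M)
            assert mean == pytest.approx(boundary[M])


def brute_force_plots(seq, table, C):
    """Reference selection: per range, sort significant pairs by (mean, i, j)."""
    fit = admap.fit_D(seq, table, C)
    per_range = {}
    for i in range(1, len(seq) + 1):
        for j in range(i + 1, len(seq) + 1):
            M = admap.range_index(j - i, table.max_M)
            if M is None or seq[i - 1] == "X" or seq[j - 1] == "X":
                continue
            mean, count = table.lookup(seq[i - 1], seq[j - 1], M)
            if count >= table.min_count and np.isfinite(mean):
                per_range.setdefault(M, []).append((mean, i, j))
    chosen = set()
    for M, cands in per_range.items():
        cands.sort()
        for mean, i, j in cands[: fit.plot_counts.get(M, 0)]:
            chosen.add((i, j))
    return chosen


class TestOracleEquivalence:
    def test_matches_brute_force_selection(self, rng):
        """Vectorised construction equals the per-range smallest-distance oracle."""
        for trial in range(30):
            table = admap.make_table("uniform", seed=trial)
            # randomly knock out significance to exercise the P(M) filter
            mask = rng.random(table.count.shape) < 0.3
            mask &= mask.transpose(1, 0, 2)
            count = table.count.copy()
            count[mask] = 0
            table = AvgDistanceTable(mean=table.mean, count=count, min_count=table.min_count)
            seq = random_sequence(rng, int(rng.integers(40, 90)))
            C = float(rng.uniform(10.0, 50.0))
            adm = admap.build_adm(seq, table, C=C)
            assert {tuple(p) for p in adm.plots} == brute_force_plots(seq, table, C)


class TestPlotRatios:
    def test_short_range_only_map(self):
        plots = np.array([(i, i + 3) for i in range(1, 13)])
        adm = ADM.from_plots(60, plots)
        report = admap.plot_ratios(adm)
        assert report.short_range_ratio == pytest.approx(0.2)
        assert report.long_range_ratio == 0.0

    def test_empty_map(self):
        report = admap.plot_ratios(ADM.from_plots(30, np.empty((0, 2))))
        assert report.short_range_ratio == 0.0
        assert report.long_range_ratio == 0.0

    def test_full_interval_is_identity(self, uniform_table, rng):
        seq = random_sequence(rng, 64)
        adm = admap.build_adm(seq, uniform_table)
        whole = admap.plot_ratios(adm)
        restricted = admap.plot_ratios(adm, interval=(1, 64))
        assert whole.short_range_ratio == restricted.short_range_ratio
        assert whole.long_range_ratio == restricted.long_range_ratio

    def test_ratio_split_sums_to_total(self, uniform_table, rng):
        seq = random_sequence(rng, 64)
        adm = admap.build_adm(seq, uniform_table)
        r = admap.plot_ratios(adm)
        assert r.short_range_ratio + r.long_range_ratio == pytest.approx(r.total_ratio)

    @pytest.mark.parametrize("interval", [(10, 5), (0, 20), (5, 100)])
    def test_invalid_intervals_rejected(self, interval):
        adm = ADM.from_plots(30, np.empty((0, 2)))
        with pytest.raises(InvalidIntervalError):
            admap.plot_ratios(adm, interval=interval)
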