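import math

import numpy as np
import pytest
from scipy import stats as sps

from ssrscape.reference_data import (DIMER_COUNTS, DIMER_END_MIDDLE,
                                     HP_END_MIDDLE, TRIMER_COUNTS)
from ssrscape.stats import (MapInterval, density_recombination_correlation,
                            end_middle_expected, end_middle_test,
                            fit_het_curve, round_half_up,
                            scaffold_abundance_flags, select_het_model,
                            starting_preference_test)
from ssrscape.catalog import SsrLocus


class TestStartingPreference:
    def test_ta_at_class_expectation(self):
        res = starting_preference_test(DIMER_COUNTS["AT"])
        assert round_half_up(res.expected["TA"]) == 42186
        assert res.df == 1

    def test_trimer_class_expectation(self):
        res = starting_preference_test(TRIMER_COUNTS["AAT"])
        assert round_half_up(res.expected["AAT"]) == 2937
        assert res.df == 5

    def test_uniform_counts_give_p_one(self):
        res = starting_preference_test(
            {"AC": 100, "CA": 100, "GT": 100, "TG": 100})
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_incomplete_class_rejected(self):
        with pytest.raises(ValueError):
            starting_preference_test({"AC": 5, "CA": 3})

    def test_zero_total_signalled(self):
        with pytest.raises(ValueError):
            starting_preference_test({"AT": 0, "TA": 0})

    def test_matches_scipy_chisquare(self):
        counts = TRIMER_COUNTS["ACT"]
        res = starting_preference_test(counts)
        ref = sps.chisquare(list(dict(sorted(counts.items())).values()))
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestEndMiddle:
    def test_worked_expectations(self):
        assert end_middle_expected(5, 3717) == (pytest.approx(1486.8),
                                                pytest.approx(2230.2))
        assert end_middle_expected(8, 76) == (19, 57)
        assert end_middle_expected(2, 100) == (100, 0)

    def test_sums_to_total(self):
        for n in range(2, 30):
            e, m = end_middle_expected(n, 977)
            assert e + m == pytest.approx(977)

    def test_invalid_repeat_number(self):
        with pytest.raises(ValueError):
            end_middle_expected(1, 10)

    def test_observation_at_expectation_gives_p_one(self):
        stat, p = end_middle_test(200, 300, 5)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_extreme_departure_underflows(self):
        stat, p = end_middle_test(15005, 50, 3)
        assert p == 0.0

    def test_small_tables_match_exact_binomial(self):
        """Direct-summation oracle for sparse cells."""
        end_o, mid_o, n = 5, 1, 10
        _, p = end_middle_test(end_o, mid_o, n)
        total, p0 = end_o + mid_o, 2 / n
        pk = sps.binom.pmf(end_o, total, p0)
        direct = sum(sps.binom.pmf(j, total, p0) for j in range(total + 1)
                     if sps.binom.pmf(j, total, p0) <= pk * (1 + 1e-9))
        assert p == pytest.approx(direct, rel=1e-6)

    def test_p_decreases_along_departure_ray(self):
        ps = [end_middle_test(200 + k, 300 - k, 5)[1] for k in range(0, 250, 50)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_published_tables_reproduce(self):
        """Every printed expectation cell follows from the observed
        columns under the two-terminal-units placement model."""
        from ssrscape.reference_data import (DIMER_END_MIDDLE_EXPECTED,
                                             HP_END_MIDDLE_EXPECTED)
        for table, expected in ((HP_END_MIDDLE, HP_END_MIDDLE_EXPECTED),
                                (DIMER_END_MIDDLE, DIMER_END_MIDDLE_EXPECTED)):
            for rep, (end_o, mid_o) in table.items():
                e, m = end_middle_expected(rep, end_o + mid_o)
                assert (round_half_up(e), round_half_up(m)) == expected[rep]


class TestCurveFits:
    def test_exact_linear(self):
        fit = fit_het_curve([(x, 2 * x + 1) for x in range(3, 10)], "linear")
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_exact_exponential(self):
        pts = [(x, 0.5 * math.exp(0.3 * x)) for x in range(3, 12)]
        fit = fit_het_curve(pts, "exponential")
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.3)
        assert fit.scale == pytest.approx(0.5)

    def test_model_selection(self):
        exp_pts = [(x, 0.5 * math.exp(0.4 * x)) for x in range(3, 12)]
        assert select_het_model(exp_pts).model == "exponential"
        lin_pts = [(x, 2.0 * x) for x in range(3, 12)]
        assert select_het_model(lin_pts).model == "linear"

    def test_noisy_rate_recovered_within_2_se(self):
        rng = np.random.default_rng(4)
        rate, scale = 0.3, 0.5
        x = np.arange(3, 15)
        y = scale * np.exp(rate * x) * np.exp(rng.normal(0, 0.1, len(x)))
        fit = fit_het_curve(list(zip(x, y)), "exponential")
        res = sps.linregress(x, np.log(y))
        assert abs(fit.slope - rate) < 2 * res.stderr

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_het_curve([(1, 1), (2, 2)], "linear")
        with pytest.raises(ValueError):
            fit_het_curve([(3, 1), (3, 2), (3, 3)], "linear")
        with pytest.raises(ValueError):
            fit_het_curve([(1, 0.0), (2, 1.0), (3, 2.0)], "exponential")


def _intervals(densities, base=1.0, slope=1.0):
    """Intervals of 1 Mb whose cM give cm_per_mb = x such that a chosen
    density/x relation holds."""
    out = []
    for i, d in enumerate(densities):
        out.append(MapInterval("s", i * 1_000_000, (i + 1) * 1_000_000, d))
    return out


class TestDensityRecombination:
    def _loci(self, counts):
        loci = []
        for i, k in enumerate(counts):
            for j in range(k):
                s = i * 1_000_000 + j * 50
                loci.append(SsrLocus("s", s, s + 8, "AC", 2, 4))
        return loci

    def test_proportional_density_gives_r2_one(self):
        counts = [10, 20, 30, 40, 50]
        loci = self._loci(counts)
        ivs = [MapInterval("s", i * 1_000_000, (i + 1) * 1_000_000, k / 10)
               for i, k in enumerate(counts)]
        fit, table = density_recombination_correlation(loci, ivs)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(10.0)

    def test_matches_closed_form_least_squares(self):
        rng = np.random.default_rng(8)
        counts = list(rng.integers(5, 60, size=12))
        cms = rng.uniform(0.5, 5.0, size=12)
        loci = self._loci(counts)
        ivs = [MapInterval("s", i * 1_000_000, (i + 1) * 1_000_000, float(c))
               for i, c in enumerate(cms)]
        fit, table = density_recombination_correlation(loci, ivs)
        x, y = np.asarray(cms), np.asarray(counts, dtype=float)
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        sxx = ((x - x.mean()) ** 2).sum()
        assert fit.slope == pytest.approx(sxy / sxx)
        assert fit.intercept == pytest.approx(y.mean() - sxy / sxx * x.mean())
        assert fit.r2 == pytest.approx(sxy ** 2 / (sxx * ((y - y.mean()) ** 2).sum()))

    def test_permuted_densities_are_null(self):
        """Shuffling densities kills the correlation: p roughly uniform,
        small mean r2."""
        rng = np.random.default_rng(9)
        counts = np.arange(10, 130, 10)
        cms = counts / 10.0
        ps, r2s = [], []
        for _ in range(200):
            perm = rng.permutation(counts)
            loci = self._loci(list(perm))
            ivs = [MapInterval("s", i * 1_000_000, (i + 1) * 1_000_000,
                               float(c)) for i, c in enumerate(cms)]
            fit, _ = density_recombination_correlation(loci, ivs)
            ps.append(fit.p_value)
            r2s.append(fit.r2)
        assert np.mean(r2s) < 0.2
        assert 0.25 < np.mean(ps) < 0.75
        assert sps.kstest(ps, "uniform").pvalue > 1e-3

    def test_interval_arithmetic(self):
        iv = MapInterval("s", 0, 2_000_000, 5.0)
        assert iv.cm_per_mb == pytest.approx(2.5)


class TestScaffoldFlags:
    def test_uniform_rate_unflagged(self):
        sizes = {f"sc{i}": 1_000_000 for i in range(5)}
        counts = {f"sc{i}": 1000 for i in range(5)}
        flags = scaffold_abundance_flags(counts, sizes)
        assert all(f.flag == "" for f in flags)

    def test_enriched_scaffold_flagged_positive(self):
        sizes = {f"sc{i}": 1_000_000 for i in range(5)}
        counts = {f"sc{i}": 1000 for i in range(5)}
        counts["sc3"] = 3000
        flags = {f.seq_id: f for f in scaffold_abundance_flags(counts, sizes)}
        assert flags["sc3"].flag == "+"
        assert flags["sc0"].flag == "-" or flags["sc0"].p_value > 0.0

    def test_depleted_scaffold_flagged_negative(self):
        sizes = {"a": 2_000_000, "b": 2_000_000, "c": 2_000_000}
        counts = {"a": 2000, "b": 2000, "c": 200}
        flags = {f.seq_id: f for f in scaffold_abundance_flags(counts, sizes)}
        assert flags["c"].flag == "-"

    def test_p_matches_exact_binomial(self):
        sizes = {"a": 100, "b": 300}
        counts = {"a": 9, "b": 11}
        flags = {f.seq_id: f for f in scaffold_abundance_flags(counts, sizes)}
        direct = sps.binomtest(9, 20, 0.25, alternative="two-sided").pvalue
        assert flags["a"].p_value == pytest.approx(min(1.0, direct * 2))

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            scaffold_abundance_flags({"a": 1}, {"a": 100})
        with pytest.raises(ValueError):
            scaffold_abundance_flags({"a": 1, "b": 1}, {"a": 100, "b": 0})
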