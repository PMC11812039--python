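"""Log-binned maximum likelihood for the scaling exponent and diagnostics."""
import math

import numpy as np
import pytest

import arborscale as arb
from arborscale.fit import (DegenerateSampleError, InsufficientDataError,
                            LogBinnedCounts, binned_log_likelihood, log_bin)


def grid_search_alpha(binned, step=1e-4, hi=10.0):
    """Brute-force argmax of the binned log-likelihood over (0, hi]."""
    grid = np.arange(step, hi + step, step)
    lam = binned.lambda_base
    n, s = binned.n_used, binned.index_weight
    ll = n * np.log1p(-lam ** (-grid)) - grid * math.log(lam) * s
    return float(grid[np.argmax(ll)])


def sample_of(values, **kw):
    return arb.DiameterSample(np.asarray(values, dtype=float), **kw)


class TestLogBin:
    def test_boundary_values_go_up(self):
        binned = log_bin(sample_of([1.0, 2.0, 4.0]), xm=1.0, lambda_base=2.0)
        assert binned.counts == {0: 1, 1: 1, 2: 1}
        assert binned.n_excluded_below_xm == 0

    def test_exclusion_below_cutoff(self):
        binned = log_bin(sample_of([0.5, 1.5]), xm=1.0, lambda_base=2.0)
        assert binned.counts == {0: 1}
        assert binned.n_excluded_below_xm == 1

    def test_floating_boundary_robustness(self):
        # value meant to sit on the bin-3 boundary, built by repeated
        # multiplication so it may land a few ulps to either side
        d = 1.0
        for _ in range(3):
            d *= 2.0
        for xm in (1.0, 0.1, 0.3):
            wobbly = xm * d * (1.0 - 1e-15)
            binned = log_bin(sample_of([wobbly]), xm=xm, lambda_base=2.0)
            assert binned.counts == {3: 1}

    def test_empty_after_exclusion(self):
        with pytest.raises(InsufficientDataError):
            log_bin(sample_of([0.1, 0.2]), xm=1.0)


class TestFitAlpha:
    def test_closed_form_small_table(self):
        binned = LogBinnedCounts(1.0, 2.0, {0: 3, 1: 1}, 0)
        fit = arb.fit_alpha(binned)
        assert fit.alpha_hat == pytest.approx(math.log(5) / math.log(2), rel=1e-12)
        assert fit.alpha_hat == pytest.approx(grid_search_alpha(binned), abs=1e-3)

    @pytest.mark.parametrize("m", [3, 5, 10])
    def test_equal_counts_closed_form(self, m):
        # equal counts in m bins: S = m(m-1)/2, N = m
        binned = LogBinnedCounts(1.0, 2.0, {k: 1 for k in range(m)}, 0)
        expected = math.log1p(2.0 / (m - 1)) / math.log(2.0)
        assert arb.fit_alpha(binned).alpha_hat == pytest.approx(expected, rel=1e-12)

    def test_closed_form_matches_grid_search_on_random_tables(self, rng):
        """The closed form is the argmax of the binned likelihood."""
        for _ in range(25):
            n_bins = rng.integers(2, 8)
            counts = {int(k): int(c) for k, c in
                      enumerate(rng.integers(0, 50, n_bins)) if c > 0}
            if sum(k * c for k, c in counts.items()) == 0:
                continue
            binned = LogBinnedCounts(1.0, 2.0, counts, 0)
            fit = arb.fit_alpha(binned)
            assert fit.alpha_hat == pytest.approx(grid_search_alpha(binned), abs=1e-3)
            # reported likelihood is the model likelihood at the optimum
            assert fit.log_likelihood == pytest.approx(
                binned_log_likelihood(binned, fit.alpha_hat))

    def test_recovery_on_pareto_sample(self, pareto_sample):
        fit = arb.fit_alpha(log_bin(pareto_sample, 1.0, 2.0))
        assert fit.alpha_hat == pytest.approx(2.0, abs=0.05)

    def test_degenerate_single_bin(self):
        with pytest.raises(DegenerateSampleError):
            arb.fit_alpha(LogBinnedCounts(1.0, 2.0, {0: 100}, 0))

    def test_scale_invariance_bit_for_bit(self, pareto_sample):
        for factor in (0.01, 3.7, 1e4):
            scaled = pareto_sample.scaled(factor)
            b1 = log_bin(pareto_sample, 1.0, 2.0)
            b2 = log_bin(scaled, factor, 2.0)
            assert b1.counts == b2.counts
            assert arb.fit_alpha(b1).alpha_hat == arb.fit_alpha(b2).alpha_hat

    @pytest.mark.parametrize("alpha", [1.5, 2.0, 3.0])
    def test_lambda_robustness(self, alpha):
        """Estimates at different bin bases agree on self-similar data."""
        s = arb.sample_diameters(alpha, 1.0, 2000, seed=int(alpha * 13))
        estimates = [arb.fit_alpha(log_bin(s, 1.0, lam)).alpha_hat
                     for lam in (1.5, 2.0, 3.0)]
        assert max(estimates) - min(estimates) < 0.15

    def test_cumulative_convention_matches_tail_slope(self, pareto_sample):
        """alpha is the tail exponent, one less than the density exponent."""
        fit = arb.fit_alpha(log_bin(pareto_sample, 1.0, 2.0))
        slope = arb.tail_slope(arb.tail_curve(pareto_sample), xm=1.0)
        assert -slope == pytest.approx(fit.alpha_hat, abs=0.15)
        assert abs(-slope - (fit.alpha_hat + 1.0)) > 0.5


class TestBootstrap:
    def test_interval_contains_truth_and_is_narrow(self, pareto_sample):
        lo, hi = arb.bootstrap_ci(pareto_sample, 1.0, n_boot=2000, seed=1)
        assert lo <= 2.0 <= hi
        assert hi - lo < 0.2

    def test_monotone_in_level(self, pareto_sample):
        lo95, hi95 = arb.bootstrap_ci(pareto_sample, 1.0, n_boot=2000,
                                      seed=2, level=0.95)
        lo68, hi68 = arb.bootstrap_ci(pareto_sample, 1.0, n_boot=2000,
                                      seed=2, level=0.68)
        assert hi95 - lo95 > hi68 - lo68

    def test_width_shrinks_with_sample_size(self):
        small = arb.sample_diameters(2.0, 1.0, 50, seed=3)
        big = arb.sample_diameters(2.0, 1.0, 5000, seed=3)
        ws = np.diff(arb.bootstrap_ci(small, 1.0, n_boot=2000, seed=4))[0]
        wb = np.diff(arb.bootstrap_ci(big, 1.0, n_boot=2000, seed=4))[0]
        assert ws > wb

    def test_reproducible(self, pareto_sample):
        a = arb.bootstrap_ci(pareto_sample, 1.0, n_boot=1000, seed=5)
        b = arb.bootstrap_ci(pareto_sample, 1.0, n_boot=1000, seed=5)
        assert a == b

    def test_requires_enough_resamples(self, pareto_sample):
        with pytest.raises(ValueError):
            arb.bootstrap_ci(pareto_sample, 1.0, n_boot=10)

    def test_fit_power_law_composes(self, pareto_sample):
        fit = arb.fit_power_law(pareto_sample, 1.0, n_boot=2000, seed=6)
        assert fit.ci_low <= fit.alpha_hat <= fit.ci_high
        assert fit.n_used == len(pareto_sample)


class TestTailCurve:
    def test_small_example(self):
        curve = arb.tail_curve(sample_of([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(curve.diameters, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(curve.percentages,
                                   [100.0, 200.0 / 3.0, 100.0 / 3.0])

    def test_all_equal_sample(self):
        curve = arb.tail_curve(sample_of([2.0, 2.0, 2.0]))
        assert curve.points == [(2.0, 100.0)]

    def test_percentages_non_increasing_and_start_at_100(self, pareto_sample):
        curve = arb.tail_curve(pareto_sample)
        assert curve.percentages[0] == 100.0
        assert np.all(np.diff(curve.percentages) <= 0)

    def test_slope_is_minus_alpha_on_pareto(self, pareto_sample):
        slope = arb.tail_slope(arb.tail_curve(pareto_sample), xm=1.0)
        assert slope == pytest.approx(-2.0, abs=0.1)


class TestThresholdDiagnostic:
    def test_clean_sample_not_flagged(self, pareto_sample):
        fit = arb.fit_alpha(log_bin(pareto_sample, 1.0, 2.0))
        diag = arb.threshold_diagnostic(pareto_sample, fit)
        assert diag.available and not diag.flagged

    def test_censored_small_branches_flagged_at_low_cutoff(self):
        """Curvature from left-censoring should trip the slope check."""
        # censoring RNG seeded independently of the sampler's stream
        rng = np.random.default_rng(987)
        full = arb.sample_diameters(2.0, 0.2, 50_000, seed=10).diameters
        keep = rng.random(full.size) < np.clip(full / 1.0, None, 1.0) ** 2
        censored = sample_of(full[keep])
        fit = arb.fit_alpha(log_bin(censored, 0.25, 2.0))
        diag = arb.threshold_diagnostic(censored, fit)
        assert diag.available and diag.flagged
        # and a cutoff above the censoring region passes
        fit_hi = arb.fit_alpha(log_bin(censored, 1.0, 2.0))
        assert not arb.threshold_diagnostic(censored, fit_hi).flagged

    def test_sparse_first_bin_unavailable(self):
        s = sample_of([1.0, 4.0, 8.0, 16.0])
        fit = arb.fit_alpha(log_bin(s, 1.0, 2.0))
        diag = arb.threshold_diagnostic(s, fit)
        assert not diag.available and not diag.flagged

    def test_choose_xm_lands_above_censoring(self):
        rng = np.random.default_rng(654)
        full = arb.sample_diameters(2.0, 0.2, 20_000, seed=11).diameters
        keep = rng.random(full.size) < np.clip(full / 1.0, None, 1.0) ** 2
        censored = sample_of(full[keep])
        xm = arb.choose_xm(censored)
        d_min = censored.diameters.min()
        assert xm > d_min  # the naive minimum cutoff is rejected
        chosen = arb.fit_alpha(log_bin(censored, xm, 2.0)).alpha_hat
        naive = arb.fit_alpha(log_bin(censored, d_min, 2.0)).alpha_hat
        assert abs(chosen - 2.0) < abs(naive - 2.0)
        assert not arb.threshold_diagnostic(
            censored, arb.fit_alpha(log_bin(censored, xm, 2.0))).flagged
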