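"""Summary estimation, the embedded-category ideal observer, and the
maximum-likelihood criterion fit."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from criterionlab import (
    CriterionPolicy,
    DetectionModel,
    EmbeddedCategoryModel,
    InsufficientDataError,
    NoInteriorBoundaryError,
    NonIdentifiableFitError,
    degeneracy_report,
    embedded_response_probability,
    estimate_summary,
    fit_embedded_observer,
    match_dprime,
    optimal_embedded_criterion,
    simulate_detection,
    simulate_embedded_category,
)
from conftest import embedded_expected_accuracy, weighted_category_density


def detection_table(n_present, hits, n_absent, fas, condition="single"):
    rows = []
    for i in range(n_present):
        rows.append((condition, 1, 1 if i < hits else 0))
    for i in range(n_absent):
        rows.append((condition, 0, 1 if i < fas else 0))
    df = pd.DataFrame(rows, columns=["condition", "truth", "response"])
    df["trial"] = np.arange(len(df))
    df["stimulus"] = 0.0
    return df


class TestEstimateSummary:
    def test_chance_performance(self):
        s = estimate_summary(detection_table(100, 50, 100, 50))["single"]
        assert s.d_prime == pytest.approx(0.0, abs=1e-12)
        assert s.c == pytest.approx(0.0, abs=1e-12)

    def test_boundary_correction_applied(self):
        s = estimate_summary(detection_table(100, 100, 100, 30))["single"]
        assert s.hit_rate == pytest.approx(1 - 1 / 200)

    def test_missing_truth_class(self):
        df = detection_table(100, 50, 100, 50)
        with pytest.raises(InsufficientDataError):
            estimate_summary(df[df["truth"] == 1])

    def test_fixed_criterion_signature_from_simulation(self):
        """A fixed-k observer with sigma 1 -> 2 and matched d' shows the
        inflation signature c_inv < c_val."""
        mu_val, mu_inv = match_dprime(1.0, 2.0, 1.0)
        models = {
            "valid": DetectionModel(mu=mu_val, sigma=1.0),
            "invalid": DetectionModel(mu=mu_inv, sigma=2.0),
        }
        trials = simulate_detection(models, CriterionPolicy.fixed(1.0), 100_000, seed=17)
        summaries = estimate_summary(trials)
        assert summaries["invalid"].c < summaries["valid"].c
        assert summaries["valid"].c == pytest.approx(0.5, abs=0.03)
        assert summaries["invalid"].c == pytest.approx(0.0, abs=0.03)


class TestOptimalEmbeddedCriterion:
    def test_equal_prior_unit_variances(self):
        # v1 = 1, v2 = 4 via sigma_m = 0.5
        model = EmbeddedCategoryModel(
            sigma_narrow=math.sqrt(0.75), sigma_broad=math.sqrt(3.75), sigma_m=0.5
        )
        assert optimal_embedded_criterion(model) == pytest.approx(1.3595, abs=1e-4)

    def test_density_crossing_oracle(self):
        """k* is the root of the weighted-density difference (independent
        root-find) and the weighted densities are equal at +/- k*."""
        model = EmbeddedCategoryModel(sigma_narrow=0.8, sigma_broad=2.0, sigma_m=0.5)
        k_star = optimal_embedded_criterion(model)

        def diff(x):
            d1, d2 = weighted_category_density(x, model)
            return d1 - d2

        k_root = brentq(diff, 1e-6, 10.0, xtol=1e-12)
        assert k_star == pytest.approx(k_root, abs=1e-9)
        for sign in (1.0, -1.0):
            d1, d2 = weighted_category_density(sign * k_star, model)
            assert d1 == pytest.approx(d2, abs=1e-9)

    def test_zero_measurement_noise_grid_oracle(self):
        """With sigma_m = 0 the boundary matches a 1e-6-resolution grid
        scan for the density crossing."""
        model = EmbeddedCategoryModel(sigma_narrow=0.8, sigma_broad=2.0, sigma_m=0.0)
        k_star = optimal_embedded_criterion(model)
        grid = np.arange(0.5, 2.0, 1e-6)
        d1, d2 = weighted_category_density(grid, model)
        k_grid = grid[np.argmin(np.abs(d1 - d2))]
        assert abs(k_star - k_grid) < 1e-5

    def test_matches_accuracy_grid_search(self):
        """Expected-accuracy brute force at 1e-3 resolution agrees with the
        closed form to within the grid resolution."""
        model = EmbeddedCategoryModel(sigma_narrow=0.8, sigma_broad=2.0, sigma_m=0.5)
        k_star = optimal_embedded_criterion(model)
        grid = np.arange(0.0, 6.0, 1e-3)
        acc = embedded_expected_accuracy(grid, model)
        assert abs(grid[np.argmax(acc)] - k_star) <= 1e-3

    def test_strictly_increasing_in_measurement_noise(self):
        ks = [
            optimal_embedded_criterion(
                EmbeddedCategoryModel(sigma_narrow=0.8, sigma_broad=2.0, sigma_m=sm)
            )
            for sm in np.linspace(0.0, 3.0, 13)
        ]
        assert np.all(np.diff(ks) > 0)

    def test_extreme_prior_has_no_interior_boundary(self):
        model = EmbeddedCategoryModel(
            sigma_narrow=0.8, sigma_broad=2.0, sigma_m=0.5, prior_cat1=0.05
        )
        with pytest.raises(NoInteriorBoundaryError):
            optimal_embedded_criterion(model)


class TestResponseProbability:
    @pytest.mark.parametrize(
        "s, k, sigma_m, expected",
        [
            (0.0, 0.0, 0.5, 1.0),
            (2.0, 1.0, 0.5, norm.cdf(2.0) + norm.cdf(-6.0)),
            (1.0, 1.0, 0.7, 0.5 + norm.cdf(-2.0 / 0.7)),  # s = k
        ],
    )
    def test_values(self, s, k, sigma_m, expected):
        assert embedded_response_probability(s, k, sigma_m) == pytest.approx(
            expected, abs=1e-9
        )

    def test_symmetric_and_increasing_in_magnitude(self):
        s = np.linspace(0.0, 5.0, 50)
        p = embedded_response_probability(s, 1.0, 0.5)
        assert np.all(np.diff(p) > 0)
        np.testing.assert_allclose(
            embedded_response_probability(-s, 1.0, 0.5), p, atol=1e-12
        )

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            embedded_response_probability(0.0, 1.0, 0.0)


class TestFitEmbeddedObserver:
    def test_parameter_recovery(self):
        model = EmbeddedCategoryModel(sigma_narrow=0.8, sigma_broad=2.0, sigma_m=0.5)
        trials = simulate_embedded_category(model, 1.0, 20_000, seed=7)
        fit = fit_embedded_observer(trials)
        assert fit.converged
        assert fit.k_hat == pytest.approx(1.0, rel=0.05)
        assert fit.sigma_m_hat == pytest.approx(0.5, rel=0.05)
        assert fit.se_k > 0 and fit.se_sigma_m > 0

    def test_small_criterion_recovered_near_bound(self):
        model = EmbeddedCategoryModel(sigma_narrow=0.8, sigma_broad=2.0, sigma_m=0.5)
        trials = simulate_embedded_category(model, 0.05, 20_000, seed=8)
        fit = fit_embedded_observer(trials)
        assert fit.k_hat == pytest.approx(0.05, abs=0.05)

    def test_all_identical_responses_rejected(self):
        df = pd.DataFrame(
            {"trial": range(100), "condition": "single", "truth": 1,
             "stimulus": np.linspace(-2, 2, 100), "response": 1}
        )
        with pytest.raises(NonIdentifiableFitError):
            fit_embedded_observer(df)

    def test_zero_criterion_observer_is_non_identifiable(self):
        """k = 0 makes every response 'category 2', so the fit signals the
        non-identifiable condition rather than returning a bound estimate."""
        trials = simulate_embedded_category(EmbeddedCategoryModel(), 0.0, 1_000, seed=9)
        with pytest.raises(NonIdentifiableFitError):
            fit_embedded_observer(trials)

    def test_fixed_vs_flexible_discrimination(self):
        """A fixed-k observer fitted at two sigma_m levels yields matching
        k_hat; a linearly scaling observer yields clearly different k_hat."""
        def fit_at(sigma_m, k, seed):
            model = EmbeddedCategoryModel(sigma_narrow=0.8, sigma_broad=2.0, sigma_m=sigma_m)
            return fit_embedded_observer(
                simulate_embedded_category(model, k, 10_000, seed=seed)
            )

        fixed_lo, fixed_hi = fit_at(0.5, 1.0, 31), fit_at(1.0, 1.0, 32)
        se = math.hypot(fixed_lo.se_k, fixed_hi.se_k)
        assert abs(fixed_lo.k_hat - fixed_hi.k_hat) < 3 * se

        flex_lo, flex_hi = fit_at(0.5, 1.0, 33), fit_at(1.0, 2.0, 34)
        se = math.hypot(flex_lo.se_k, flex_hi.se_k)
        assert abs(flex_lo.k_hat - flex_hi.k_hat) > 3 * se


class TestDegeneracyReport:
    def test_family_rows_and_identical_rates(self):
        rep = degeneracy_report(1.0, 0.5, [1.0, 2.0])
        fam = rep.family.set_index("sigma")
        assert fam.loc[1.0, "mu"] == pytest.approx(1.0)
        assert fam.loc[1.0, "k"] == pytest.approx(1.0)
        assert fam.loc[2.0, "mu"] == pytest.approx(2.0)
        assert fam.loc[2.0, "k"] == pytest.approx(2.0)
        assert fam["H"].std() == pytest.approx(0.0, abs=1e-12)
        assert fam["F"].std() == pytest.approx(0.0, abs=1e-12)

    def test_pair_annotations(self):
        rep = degeneracy_report(1.0, 0.5, [1.0, 2.0])
        pair = rep.iarf_pair.set_index("policy")
        assert pair.loc["fixed", "k_ratio"] == 1.0
        assert pair.loc["sqrt", "k_ratio"] == pytest.approx(math.sqrt(2))
        assert pair.loc["fixed", "iarf_status"] == "strictly_inside"
        assert pair.loc["sqrt", "iarf_status"] == "strictly_inside"
        assert pair.loc["optimal", "iarf_status"] == "boundary"

    def test_zero_summary_family(self):
        rep = degeneracy_report(0.0, 0.0, [0.5, 1.0, 2.0])
        assert (rep.family["mu"] == 0).all()
        assert (rep.family["k"] == 0).all()
        assert rep.iarf_pair is None  # k_val = 0 leaves the IARF undefined

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            degeneracy_report(1.0, 0.5, [])
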