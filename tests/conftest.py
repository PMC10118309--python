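"""Shared helpers for the test suite."""

import numpy as np
from scipy.stats import norm


def z_rate_variance(p: float, n: int) -> float:
    """Delta-method variance of z(p_hat) for a binomial rate estimate."""
    return p * (1.0 - p) / (n * norm.pdf(norm.ppf(p)) ** 2)


def criterion_se(h: float, f: float, n_present: int, n_absent: int) -> float:
    """Delta-method standard error of the empirical relative criterion
    c_hat = -(z(H_hat) + z(F_hat)) / 2."""
    return 0.5 * np.sqrt(
        z_rate_variance(h, n_present) + z_rate_variance(f, n_absent)
    )


def weighted_category_density(x, model):
    """Prior-weighted marginal measurement densities of the two embedded
    categories, evaluated at x.  Returns (w1*p1(x), w2*p2(x))."""
    v1 = model.sigma_narrow**2 + model.sigma_m**2
    v2 = model.sigma_broad**2 + model.sigma_m**2
    d1 = model.prior_cat1 * norm.pdf(x, 0.0, np.sqrt(v1))
    d2 = (1.0 - model.prior_cat1) * norm.pdf(x, 0.0, np.sqrt(v2))
    return d1, d2


def embedded_expected_accuracy(k, model):
    """Expected accuracy of the |x| > k rule; marginal x|C ~ N(0, v_C)."""
    v1 = model.sigma_narrow**2 + model.sigma_m**2
    v2 = model.sigma_broad**2 + model.sigma_m**2
    p_correct_1 = 2.0 * norm.cdf(k / np.sqrt(v1)) - 1.0  # |x| <= k given C1
    p_correct_2 = 2.0 * norm.cdf(-k / np.sqrt(v2))  # |x| > k given C2
    return model.prior_cat1 * p_correct_1 + (1.0 - model.prior_cat1) * p_correct_2
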