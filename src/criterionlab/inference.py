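"""Inference: SDT summaries from trials, the embedded-category ideal
observer, and maximum-likelihood recovery of the absolute criterion.

The payoff of the embedded-category design is identifiability.  In a
detection task the measurable pair (d', c) is consistent with a whole
family of (mu, sigma, k) triples (:func:`degeneracy_report`), so fixed and
flexible criteria cannot be told apart.  In the embedded task the stimulus
axis is physical (orientation in degrees), so the criterion ``k`` and the
measurement noise ``sigma_m`` enter the response probability of each trial
directly and can both be recovered by maximum likelihood
(:func:`fit_embedded_observer`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from . import sdt_core
from .criterion_models import ConditionPair, iarf_satisfied
from .exceptions import (
    DegenerateModelError,
    InsufficientDataError,
    NoInteriorBoundaryError,
    NonIdentifiableFitError,
)
from .sdt_core import SDTSummary, correct_boundary_rate, summary_from_rates
from .synthetic_observer import EmbeddedCategoryModel

__all__ = [
    "EmbeddedFit",
    "DegeneracyReport",
    "estimate_summary",
    "optimal_embedded_criterion",
    "embedded_response_probability",
    "fit_embedded_observer",
    "degeneracy_report",
]


# ---------------------------------------------------------------------------
# detection-task summaries

def estimate_summary(trials: pd.DataFrame) -> dict[str, SDTSummary]:
    """Per-condition (H, F, d', c) from a detection trial table.

    Hit rate is the "present" response fraction among present trials,
    false-alarm rate among absent trials; rates of exactly 0 or 1 receive
    the 1/(2N) boundary correction before the z-transform.
    """
    out: dict[str, SDTSummary] = {}
    for label, grp in trials.groupby("condition", sort=False):
        present = grp[grp["truth"] == 1]
        absent = grp[grp["truth"] == 0]
        if len(present) == 0 or len(absent) == 0:
            raise InsufficientDataError(
                f"condition {label!r} lacks a truth class "
                f"(present={len(present)}, absent={len(absent)})"
            )
        h = correct_boundary_rate(present["response"].mean(), len(present))
        f = correct_boundary_rate(absent["response"].mean(), len(absent))
        out[label] = summary_from_rates(h, f)
    return out


# ---------------------------------------------------------------------------
# embedded-category ideal observer

def optimal_embedded_criterion(model: EmbeddedCategoryModel) -> float:
    """Accuracy-maximizing boundary k* of the embedded-category task.

    The measurement is marginally ``Normal(0, v_C)`` per category with
    ``v_1 = sigma_narrow**2 + sigma_m**2`` and
    ``v_2 = sigma_broad**2 + sigma_m**2``.  With prior odds
    ``pi = prior_cat1 / (1 - prior_cat1)`` the prior-weighted category
    densities cross at

        ``k***2 = (log(v2/v1) + 2 log pi) / (1/v1 - 1/v2)``

    provided the numerator is positive; otherwise one response is always
    optimal and :class:`NoInteriorBoundaryError` is raised.  Because both
    variances grow with ``sigma_m`` but their *ratio* shrinks toward 1,
    k* increases strictly with measurement noise — the incentive to shift
    the criterion that the detection task lacks.
    """
    if model.sigma_narrow == model.sigma_broad:
        raise DegenerateModelError("equal category SDs leave no boundary")
    v1 = model.sigma_narrow**2 + model.sigma_m**2
    v2 = model.sigma_broad**2 + model.sigma_m**2
    log_odds = math.log(model.prior_cat1 / (1.0 - model.prior_cat1))
    bracket = math.log(v2 / v1) + 2.0 * log_odds
    if bracket <= 0:
        raise NoInteriorBoundaryError(
            "prior is extreme enough that responding 'category 2' everywhere "
            "(or nowhere) is optimal; no interior boundary exists"
        )
    return math.sqrt(bracket / (1.0 / v1 - 1.0 / v2))


def embedded_response_probability(s, k: float, sigma_m: float):
    """P(respond "category 2" | stimulus s) for the |x| > k rule.

    ``Phi((s - k)/sigma_m) + Phi((-k - s)/sigma_m)`` — symmetric in s and
    increasing in |s|.  This is the Bernoulli kernel of the ML fit.
    """
    if not sigma_m > 0:
        raise ValueError(f"sigma_m must be > 0, got {sigma_m}")
    s = np.asarray(s, dtype=float)
    p = norm.cdf((s - k) / sigma_m) + norm.cdf((-k - s) / sigma_m)
    return float(p) if p.ndim == 0 else p


# ---------------------------------------------------------------------------
# maximum-likelihood fit

@dataclass(frozen=True)
class EmbeddedFit:
    """Result of the embedded-category criterion fit.

    ``se_k``/``se_sigma_m`` are observed-information standard errors
    (delta method for sigma_m, which is fitted on the log scale); they are
    NaN when the Hessian is not positive definite, e.g. with k at the 0
    bound.
    """

    k_hat: float
    sigma_m_hat: float
    log_likelihood: float
    converged: bool
    n_trials: int
    se_k: float = float("nan")
    se_sigma_m: float = float("nan")

    def __post_init__(self) -> None:
        if self.k_hat < 0 or not self.sigma_m_hat > 0:
            raise ValueError("need k_hat >= 0 and sigma_m_hat > 0")


def _nll(params: np.ndarray, s: np.ndarray, r: np.ndarray) -> float:
    k, log_sigma = params
    p = embedded_response_probability(s, k, math.exp(log_sigma))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(np.where(r == 1, np.log(p), np.log1p(-p))))


def _observed_info_se(
    s: np.ndarray, r: np.ndarray, k: float, log_sigma: float
) -> tuple[float, float]:
    """Standard errors from a central-difference Hessian of the NLL."""
    theta = np.array([k, log_sigma])
    h = np.array([1e-4 * (1.0 + abs(k)), 1e-4])
    if k - h[0] < 0:  # keep evaluations inside the k >= 0 domain
        h[0] = k / 2.0 if k > 0 else 0.0
    if h[0] == 0.0:
        return float("nan"), float("nan")
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            if i == j:
                e = np.zeros(2)
                e[i] = h[i]
                hess[i, i] = (
                    _nll(theta + e, s, r)
                    - 2 * _nll(theta, s, r)
                    + _nll(theta - e, s, r)
                ) / h[i] ** 2
            else:
                ei, ej = np.zeros(2), np.zeros(2)
                ei[i], ej[j] = h[i], h[j]
                hess[i, j] = (
                    _nll(theta + ei + ej, s, r)
                    - _nll(theta + ei - ej, s, r)
                    - _nll(theta - ei + ej, s, r)
                    + _nll(theta - ei - ej, s, r)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")
    if cov[0, 0] <= 0 or cov[1, 1] <= 0:
        return float("nan"), float("nan")
    se_k = math.sqrt(cov[0, 0])
    se_sigma = math.exp(log_sigma) * math.sqrt(cov[1, 1])  # delta method
    return se_k, se_sigma


def fit_embedded_observer(
    trials: pd.DataFrame, sigma_m0: float | None = None
) -> EmbeddedFit:
    """Fit (k, sigma_m) to embedded-category trials by maximum likelihood.

    Maximizes the Bernoulli log-likelihood with kernel
    :func:`embedded_response_probability` over the per-trial (stimulus,
    response) pairs, using bounded quasi-Newton (L-BFGS-B) on
    ``(k, log sigma_m)``.  Five deterministic starts around data-driven
    initial values guard against the k <-> sigma_m trade-off ridge; the
    log parameterization keeps sigma_m strictly positive.

    Parameters
    ----------
    trials:
        Trial table with ``stimulus`` and binary ``response`` columns.
    sigma_m0:
        Optional starting value for the measurement-noise SD; defaults to
        0.3 x the stimulus SD.
    """
    s = trials["stimulus"].to_numpy(dtype=float)
    r = trials["response"].to_numpy(dtype=int)
    if len(s) < 2:
        raise InsufficientDataError("need at least 2 trials to fit")
    if r.min() == r.max():
        raise NonIdentifiableFitError(
            "all responses identical; (k, sigma_m) are not identifiable"
        )
    scale = float(np.std(s)) or 1.0
    cat1_s = np.abs(s[r == 0])
    k0 = float(np.median(cat1_s)) if cat1_s.size else 0.5 * scale
    k0 = max(k0, 1e-3 * scale)
    s0 = float(sigma_m0) if sigma_m0 is not None else 0.3 * scale
    s0 = max(s0, 1e-6)
    starts = [
        (k0, s0),
        (0.5 * k0, 0.5 * s0),
        (1.5 * k0, 2.0 * s0),
        (k0, 0.2 * s0),
        (0.5 * float(np.max(np.abs(s))), s0),
    ]
    bounds = [(0.0, None), (math.log(1e-6 * scale), math.log(50.0 * scale))]
    best = None
    for k_init, sig_init in starts:
        res = minimize(
            _nll,
            x0=np.array([k_init, math.log(sig_init)]),
            args=(s, r),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    k_hat = float(best.x[0])
    log_sigma_hat = float(best.x[1])
    se_k, se_sigma = _observed_info_se(s, r, k_hat, log_sigma_hat)
    return EmbeddedFit(
        k_hat=k_hat,
        sigma_m_hat=math.exp(log_sigma_hat),
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
        n_trials=len(s),
        se_k=se_k,
        se_sigma_m=se_sigma,
    )


# ---------------------------------------------------------------------------
# detection-task degeneracy

@dataclass(frozen=True)
class DegeneracyReport:
    """The (mu, sigma, k) family consistent with one (d', c) pair.

    ``family`` has one row per sigma choice with the implied (H, F) — all
    identical, which is the unidentifiability.  ``iarf_pair`` classifies
    fixed (k ratio 1), square-root and linear criterion ratios for the
    condition pair (min, max) of the sigma grid against the IARF, showing
    that both fixed and flexible solutions sit inside the region.
    """

    d_prime: float
    c: float
    family: pd.DataFrame
    iarf_pair: pd.DataFrame | None


def degeneracy_report(
    d_prime: float, c: float, sigma_grid
) -> DegeneracyReport:
    """Enumerate detection-task parameter triples consistent with (d', c)."""
    sigmas = np.atleast_1d(np.asarray(sigma_grid, dtype=float))
    if sigmas.size == 0 or np.any(sigmas <= 0):
        raise ValueError("sigma_grid must be non-empty and strictly positive")
    rows = []
    for sigma in sigmas:
        mu, k = sdt_core.params_family_from_summary(d_prime, c, sigma)
        model = sdt_core.DetectionModel(mu=mu, sigma=sigma)
        h, f = sdt_core.rates_from_params(model, k)
        rows.append({"sigma": sigma, "mu": mu, "k": k, "H": h, "F": f})
    family = pd.DataFrame(rows)

    pair = None
    k_val = family["k"].iloc[int(np.argmin(sigmas))]
    if sigmas.size >= 2 and sigmas.max() > sigmas.min() and k_val > 0:
        s_lo, s_hi = float(sigmas.min()), float(sigmas.max())
        ratio = s_hi / s_lo
        prows = []
        for label, k_ratio in [
            ("fixed", 1.0),
            ("sqrt", math.sqrt(ratio)),
            ("optimal", ratio),
        ]:
            cp = ConditionPair(
                sigma_val=s_lo,
                sigma_inv=s_hi,
                k_val=float(k_val),
                k_inv=float(k_val) * k_ratio,
            )
            prows.append(
                {
                    "policy": label,
                    "k_ratio": k_ratio,
                    "k_inv": cp.k_inv,
                    "iarf_status": iarf_satisfied(cp),
                }
            )
        pair = pd.DataFrame(prows)
    return DegeneracyReport(d_prime=d_prime, c=c, family=family, iarf_pair=pair)
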