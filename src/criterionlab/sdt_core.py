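"""Closed-form signal detection theory for the yes/no detection task.

The generative model: on each trial a stimulus is absent (``s = 0``) with
probability ``1 - prior_present`` or present (``s = mu``) with probability
``prior_present``; the observer draws a noisy measurement
``x ~ Normal(s, sigma**2)`` and answers "present" whenever ``x`` exceeds an
*absolute* criterion ``k`` expressed in measurement units.

Two unit-free summaries are observable in an experiment:

* discriminability  ``d' = z(H) - z(F) = mu / sigma``
* relative criterion ``c = -(z(H) + z(F)) / 2 = (k - mu/2) / sigma``

where ``z`` is the standard-normal quantile function, ``H`` the hit rate and
``F`` the false-alarm rate.  The central identifiability fact this module
exposes is that the two measurable quantities ``(d', c)`` are functions of
*three* absolute quantities ``(mu, sigma, k)``: any choice of ``sigma``
yields a parameter triple reproducing the same ``(H, F)``, so the absolute
criterion is unidentifiable from a detection experiment alone
(:func:`params_family_from_summary`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy.stats import norm

from .exceptions import BoundaryRateError, DegenerateModelError

__all__ = [
    "DetectionModel",
    "SDTSummary",
    "AbsoluteCriterion",
    "log_posterior_ratio",
    "relative_from_absolute",
    "absolute_from_relative",
    "rates_from_params",
    "summary_from_rates",
    "bayes_criterion",
    "params_family_from_summary",
    "correct_boundary_rate",
    "load_detection_config",
    "write_summaries",
]


@dataclass(frozen=True)
class DetectionModel:
    """Generative model of one attention condition of the detection task.

    Parameters
    ----------
    mu:
        Mean of the measurement distribution when the stimulus is present,
        in measurement units.  Absent trials have mean 0.  Must be >= 0 by
        the convention that "present" lies above "absent".
    sigma:
        Measurement-noise standard deviation, same units.  Inattention is
        modeled purely as a larger ``sigma``.
    prior_present:
        Probability that the stimulus is present on a trial (default 0.5,
        equal base rates).
    """

    mu: float
    sigma: float
    prior_present: float = 0.5

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if not 0 < self.prior_present < 1:
            raise ValueError(
                f"prior_present must be in (0, 1), got {self.prior_present}"
            )

    @property
    def d_prime(self) -> float:
        """Discriminability mu / sigma."""
        return self.mu / self.sigma

    @property
    def log_prior_odds(self) -> float:
        """log(prior_present / (1 - prior_present))."""
        return math.log(self.prior_present / (1.0 - self.prior_present))


@dataclass(frozen=True)
class SDTSummary:
    """Hit/false-alarm rates with their z-transformed summaries."""

    hit_rate: float
    fa_rate: float
    d_prime: float
    c: float

    def __post_init__(self) -> None:
        if not 0 < self.hit_rate < 1 or not 0 < self.fa_rate < 1:
            raise BoundaryRateError(
                "hit_rate and fa_rate must lie strictly inside (0, 1); "
                "apply correct_boundary_rate first"
            )


@dataclass(frozen=True)
class AbsoluteCriterion:
    """Criterion in measurement units."""

    k: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.k):
            raise ValueError(f"k must be finite, got {self.k}")


def log_posterior_ratio(x, model: DetectionModel):
    """Log posterior ratio of "present" over "absent" at measurement ``x``.

    ``LPR(x) = log(prior odds) + (mu / sigma**2) * (x - mu/2)`` — an affine,
    strictly increasing function of the measurement, which is why
    thresholding the measurement itself is an equivalent decision rule.

    Raises
    ------
    DegenerateModelError
        If ``mu = 0`` (the two stimulus classes coincide and the ratio no
        longer depends on ``x``).
    """
    if model.mu == 0:
        raise DegenerateModelError(
            "log posterior ratio is constant in x when mu = 0"
        )
    x = np.asarray(x, dtype=float)
    lpr = model.log_prior_odds + (model.mu / model.sigma**2) * (x - model.mu / 2.0)
    return lpr if lpr.ndim else float(lpr)


def relative_from_absolute(k, mu, sigma):
    """Relative criterion ``c = (k - mu/2) / sigma`` (dimensionless)."""
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return (np.asarray(k, dtype=float) - mu / 2.0) / sigma


def absolute_from_relative(c, d_prime, sigma):
    """Absolute criterion ``k = sigma * (c + d'/2)`` in measurement units.

    Inverse of :func:`relative_from_absolute` when ``mu = d' * sigma``.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return sigma * (np.asarray(c, dtype=float) + d_prime / 2.0)


def rates_from_params(model: DetectionModel, k) -> tuple[float, float]:
    """Analytic hit and false-alarm rates of a threshold observer.

    ``H = Phi((mu - k) / sigma)``, ``F = Phi(-k / sigma)`` where ``Phi`` is
    the standard-normal CDF.
    """
    h = norm.cdf((model.mu - np.asarray(k, dtype=float)) / model.sigma)
    f = norm.cdf(-np.asarray(k, dtype=float) / model.sigma)
    if np.ndim(k) == 0:
        return float(h), float(f)
    return h, f


def summary_from_rates(hit_rate: float, fa_rate: float) -> SDTSummary:
    """Standard SDT summaries from rates: ``d' = z(H) - z(F)``,
    ``c = -(z(H) + z(F)) / 2``.

    Rates of exactly 0 or 1 raise :class:`BoundaryRateError`; correct them
    first with :func:`correct_boundary_rate`.
    """
    if not 0 < hit_rate < 1 or not 0 < fa_rate < 1:
        raise BoundaryRateError(
            f"rates must be strictly inside (0, 1), got H={hit_rate}, F={fa_rate}"
        )
    z_h = norm.ppf(hit_rate)
    z_f = norm.ppf(fa_rate)
    return SDTSummary(
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        d_prime=z_h - z_f,
        c=-(z_h + z_f) / 2.0,
    )


def correct_boundary_rate(rate: float, n: int) -> float:
    """1/(2N) correction for empirical rates of exactly 0 or 1.

    With ``n`` trials of the relevant truth class, 0 becomes ``1/(2n)`` and
    1 becomes ``1 - 1/(2n)``; interior rates pass through unchanged.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rate <= 0:
        return 1.0 / (2 * n)
    if rate >= 1:
        return 1.0 - 1.0 / (2 * n)
    return rate


def bayes_criterion(model: DetectionModel) -> tuple[float, float]:
    """Accuracy-maximizing criterion of the Bayesian observer.

    Returns the pair ``(k_bayes, c_bayes)`` with

    ``k_bayes = mu/2 - (sigma**2 / mu) * log(prior odds)``
    ``c_bayes = -(sigma / mu) * log(prior odds)``

    Under equal priors the log prior odds vanish, so ``k_bayes = mu/2`` and
    the relative criterion is exactly 0 regardless of ``mu`` and ``sigma``.
    Thresholding the measurement at ``k_bayes`` is the same decision rule as
    thresholding the log posterior ratio at 0.
    """
    if model.mu == 0:
        raise DegenerateModelError("Bayes criterion undefined when mu = 0")
    lo = model.log_prior_odds
    k_bayes = model.mu / 2.0 - (model.sigma**2 / model.mu) * lo
    c_bayes = -(model.sigma / model.mu) * lo
    return k_bayes, c_bayes


def params_family_from_summary(
    d_prime: float, c: float, sigma_choice: float
) -> tuple[float, float]:
    """One member of the (mu, sigma, k) family consistent with (d', c).

    For any ``sigma_choice > 0`` the triple
    ``(mu, sigma, k) = (d' * sigma, sigma, sigma * (c + d'/2))`` reproduces
    the identical hit and false-alarm rates — the solution degeneracy that
    makes the absolute criterion unidentifiable in a detection task.
    """
    if not sigma_choice > 0:
        raise ValueError(f"sigma_choice must be > 0, got {sigma_choice}")
    mu = d_prime * sigma_choice
    k = absolute_from_relative(c, d_prime, sigma_choice)
    return mu, float(k)


# ---------------------------------------------------------------------------
# plain-text I/O

def load_detection_config(path) -> dict:
    """Read a detection parameter set from a YAML config.

    Recognized keys: ``mu``, ``sigma``, ``prior_present`` (optional,
    default 0.5), ``k`` (optional).  Returns a dict with a ``"model"``
    :class:`DetectionModel` and a ``"k"`` float (or None).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model = DetectionModel(
        mu=float(raw["mu"]),
        sigma=float(raw["sigma"]),
        prior_present=float(raw.get("prior_present", 0.5)),
    )
    k = raw.get("k")
    return {"model": model, "k": None if k is None else float(k)}


def write_summaries(rows: Iterable[Mapping], path) -> None:
    """Write per-condition SDT summaries as CSV.

    Each row mapping supplies ``condition, H, F, d_prime, c, k, sigma``.
    """
    import pandas as pd

    cols = ["condition", "H", "F", "d_prime", "c", "k", "sigma"]
    df = pd.DataFrame(list(rows))
    df[cols].to_csv(path, index=False)
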