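"""Criterion-setting policies and the solution-space (IARF) analysis.

A *criterion policy* is a rule mapping the measurement-noise level ``sigma``
to an absolute criterion ``k``.  The empirical signature of subjective
inflation — matched d' with a more liberal relative criterion under
inattention — constrains the pair of absolute criteria only through the
inequality

    ``k_inv < (sigma_inv / sigma_val) * k_val``,  with ``k_val > 0``,

the IARF (the inequality accounting for the inflation findings).  Every
power-law policy ``k = k_ref * (sigma / sigma_ref)**gamma`` with
``gamma in [0, 1)`` lies strictly inside the region, the d'-matched
Bayes-optimal policy (``gamma = 1``) traces its boundary, and the fixed
policy is merely the ``gamma = 0`` special case — so the signature cannot
identify a fixed criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "CriterionPolicy",
    "ConditionPair",
    "policy_criterion",
    "iarf_satisfied",
    "iarf_region",
    "signature_under_policy",
    "default_region_grid",
    "IARF_TOL",
]

PolicyKind = Literal["fixed", "power", "bayes_optimal", "misbelief_bayes"]

#: boundary tolerance of the IARF classification, in criterion-ratio units
IARF_TOL = 1e-9


@dataclass(frozen=True)
class CriterionPolicy:
    """A rule mapping noise level sigma to an absolute criterion k.

    kinds
    -----
    ``fixed``
        k = k_ref at every noise level (equivalently power with gamma = 0).
    ``power``
        k = k_ref * (sigma / sigma_ref)**gamma; gamma = 0.5 is the
        square-root observer, gamma = 1 the linear one.
    ``bayes_optimal``
        linear scaling k = k_ref * (sigma / sigma_ref) — the accuracy-
        maximizing policy for a d'-matched detection task with equal priors.
    ``misbelief_bayes``
        a Bayesian observer holding a *wrong belief* about how much the
        noise changed: away from sigma_ref it sets the d'-matched Bayes
        criterion under a believed noise of
        ``believed_sigma_ratio * sigma_ref`` instead of the true sigma,
        giving k = k_ref * believed_sigma_ratio.  A believed ratio of 1
        reduces to ``fixed``; a believed ratio equal to the true ratio
        reduces to ``bayes_optimal``.
    """

    kind: PolicyKind
    k_ref: float
    sigma_ref: float = 1.0
    gamma: float | None = None
    believed_sigma_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "power", "bayes_optimal", "misbelief_bayes"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not self.sigma_ref > 0:
            raise ValueError(f"sigma_ref must be > 0, got {self.sigma_ref}")
        if self.kind == "power" and self.gamma is None:
            raise ValueError("power policy requires gamma")
        if self.kind == "misbelief_bayes":
            if self.believed_sigma_ratio is None or not self.believed_sigma_ratio > 0:
                raise ValueError(
                    "misbelief_bayes policy requires believed_sigma_ratio > 0"
                )

    @classmethod
    def fixed(cls, k_ref: float, sigma_ref: float = 1.0) -> "CriterionPolicy":
        return cls(kind="fixed", k_ref=k_ref, sigma_ref=sigma_ref)

    @classmethod
    def power(
        cls, k_ref: float, gamma: float, sigma_ref: float = 1.0
    ) -> "CriterionPolicy":
        return cls(kind="power", k_ref=k_ref, sigma_ref=sigma_ref, gamma=gamma)

    @classmethod
    def bayes_optimal(cls, k_ref: float, sigma_ref: float = 1.0) -> "CriterionPolicy":
        return cls(kind="bayes_optimal", k_ref=k_ref, sigma_ref=sigma_ref)

    @classmethod
    def misbelief(
        cls, k_ref: float, believed_sigma_ratio: float, sigma_ref: float = 1.0
    ) -> "CriterionPolicy":
        return cls(
            kind="misbelief_bayes",
            k_ref=k_ref,
            sigma_ref=sigma_ref,
            believed_sigma_ratio=believed_sigma_ratio,
        )

    @property
    def effective_gamma(self) -> float | None:
        """Scaling exponent for the power-law kinds, None for misbelief."""
        if self.kind == "fixed":
            return 0.0
        if self.kind == "bayes_optimal":
            return 1.0
        if self.kind == "power":
            return self.gamma
        return None


@dataclass(frozen=True)
class ConditionPair:
    """Absolute criteria and noise levels of a valid/invalid condition pair.

    The standing assumption of the analysis is ``sigma_inv > sigma_val``
    (inattention only adds noise) and ``k_val > 0`` (the empirically
    observed conservative valid-condition criterion).
    """

    sigma_val: float
    sigma_inv: float
    k_val: float
    k_inv: float

    def __post_init__(self) -> None:
        if not 0 < self.sigma_val < self.sigma_inv:
            raise ValueError(
                "need sigma_inv > sigma_val > 0, got "
                f"sigma_val={self.sigma_val}, sigma_inv={self.sigma_inv}"
            )
        if not self.k_val > 0:
            raise ValueError(f"k_val must be > 0, got {self.k_val}")

    @property
    def sigma_ratio(self) -> float:
        return self.sigma_inv / self.sigma_val

    @property
    def k_ratio(self) -> float:
        return self.k_inv / self.k_val


def policy_criterion(policy: CriterionPolicy, sigma):
    """Absolute criterion the policy sets at noise level ``sigma``."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    if policy.kind == "fixed":
        k = np.broadcast_to(float(policy.k_ref), sigma.shape).copy()
    elif policy.kind == "power":
        k = policy.k_ref * (sigma / policy.sigma_ref) ** policy.gamma
    elif policy.kind == "bayes_optimal":
        k = policy.k_ref * (sigma / policy.sigma_ref)
    else:  # misbelief_bayes: believed noise replaces the true one off-reference
        believed = np.where(
            np.isclose(sigma, policy.sigma_ref),
            policy.sigma_ref,
            policy.sigma_ref * policy.believed_sigma_ratio,
        )
        k = policy.k_ref * believed / policy.sigma_ref
    return float(k) if k.ndim == 0 else k


def iarf_satisfied(pair: ConditionPair, tol: float = IARF_TOL) -> str:
    """Classify a condition pair against the IARF.

    Returns ``"strictly_inside"`` when ``k_inv < (sigma_inv/sigma_val)*k_val``
    by more than ``tol`` (in k_val units), ``"boundary"`` within ``tol``,
    ``"outside"`` otherwise.
    """
    bound = pair.sigma_ratio * pair.k_val
    margin = (bound - pair.k_inv) / pair.k_val  # ratio units
    if margin > tol:
        return "strictly_inside"
    if margin >= -tol:
        return "boundary"
    return "outside"


def default_region_grid() -> tuple[np.ndarray, np.ndarray]:
    """Default (sigma_ratio, k_ratio) grids for the IARF region map."""
    return np.linspace(1.0, 3.0, 251), np.linspace(0.0, 2.5, 251)


def iarf_region(
    sigma_ratio_grid, k_ratio_grid, tol: float = IARF_TOL
) -> pd.DataFrame:
    """Map IARF status over a grid of (sigma_inv/sigma_val, k_inv/k_val).

    In ratio units the IARF reads ``k_ratio < sigma_ratio``: the linear
    (gamma = 1) policy traces the boundary diagonal, the fixed policy the
    horizontal line at k_ratio = 1, and everything below the diagonal is
    inside.  Points with sigma_ratio < 1 are flagged ``"invalid"`` — they
    would mean inattention *reduced* the noise.

    Returns a long-format DataFrame with columns
    ``sigma_ratio, k_ratio, status``.
    """
    s = np.asarray(sigma_ratio_grid, dtype=float)
    k = np.asarray(k_ratio_grid, dtype=float)
    if s.size == 0 or k.size == 0:
        raise ValueError("region grids must be non-empty")
    if np.any(s <= 0) or np.any(k < 0):
        raise ValueError("sigma ratios must be > 0 and k ratios >= 0")
    ss, kk = np.meshgrid(s, k, indexing="ij")
    margin = ss - kk
    status = np.where(
        margin > tol,
        "strictly_inside",
        np.where(margin >= -tol, "boundary", "outside"),
    )
    status = np.where(ss < 1.0 - tol, "invalid", status)
    return pd.DataFrame(
        {
            "sigma_ratio": ss.ravel(),
            "k_ratio": kk.ravel(),
            "status": status.ravel(),
        }
    )


def signature_under_policy(
    policy: CriterionPolicy,
    sigma_val: float,
    sigma_inv: float,
    d_prime_matched: float,
) -> tuple[float, float]:
    """Relative criteria (c_val, c_inv) the policy produces under d' matching.

    Per condition the stimulus magnitude is titrated to ``mu = d' * sigma``
    and the relative criterion follows as ``c = k/sigma - d'/2``.  Policies
    with effective gamma < 1 and k_val > 0 yield the inflation signature
    ``c_inv < c_val``; gamma = 1 leaves the relative criterion unchanged.
    """
    if not d_prime_matched > 0:
        raise ValueError("d_prime_matched must be > 0")
    if not sigma_inv > sigma_val:
        raise ValueError("need sigma_inv > sigma_val")
    out = []
    for sigma in (sigma_val, sigma_inv):
        k = policy_criterion(policy, sigma)
        out.append(float(k / sigma - d_prime_matched / 2.0))
    return out[0], out[1]
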