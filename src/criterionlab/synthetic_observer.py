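"""Seeded trial-level simulators for the detection and embedded-category tasks.

Both simulators emit a *trial table*: a pandas DataFrame with columns

    trial      0-based index over all rows
    condition  condition label ("valid"/"invalid" for detection, "single"
               for one-condition runs)
    truth      generating class (0 = absent / 1 = present; or 1 / 2 for
               the embedded categories)
    stimulus   the physical stimulus value s on that trial (measurement
               units; degrees for orientation)
    response   the observer's binary answer (1 = "present" / "category 2")

Responses are deterministic given the drawn measurement and the criterion;
all randomness flows from a single integer seed through per-condition
child streams (numpy ``SeedSequence``), so identical seeds reproduce the
table bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .criterion_models import CriterionPolicy, policy_criterion
from .sdt_core import DetectionModel

__all__ = [
    "EmbeddedCategoryModel",
    "TRIAL_COLUMNS",
    "simulate_detection",
    "simulate_embedded_category",
    "match_dprime",
    "read_trials",
    "write_trials",
]

TRIAL_COLUMNS = ("trial", "condition", "truth", "stimulus", "response")

#: orientation SDs beyond this (degrees) make the no-wraparound assumption dubious
_WRAP_WARN_DEG = 30.0


@dataclass(frozen=True)
class EmbeddedCategoryModel:
    """Generative model of the embedded-category orientation task.

    A stimulus orientation is drawn from one of two zero-mean Gaussian
    distributions: a narrow one (category 1) or a broad one (category 2),
    both centered on horizontal (0 degrees).  The observer sees the
    orientation through Gaussian measurement noise of SD ``sigma_m``.
    Because the categories differ in *spread*, the optimal boundary moves
    outward as measurement noise grows — which is what makes the absolute
    criterion identifiable in this task.

    Defaults (0.8 / 2.0 / 0.5 degrees, equal priors) are package choices
    for a plausible desk-scale instance of the task; see docs/methods.md.
    """

    sigma_narrow: float = 0.8
    sigma_broad: float = 2.0
    sigma_m: float = 0.5
    prior_cat1: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.sigma_narrow < self.sigma_broad:
            raise ValueError(
                "need 0 < sigma_narrow < sigma_broad, got "
                f"{self.sigma_narrow}, {self.sigma_broad}"
            )
        if self.sigma_m < 0:
            raise ValueError(f"sigma_m must be >= 0, got {self.sigma_m}")
        if not 0 < self.prior_cat1 < 1:
            raise ValueError(f"prior_cat1 must be in (0, 1), got {self.prior_cat1}")
        if self.sigma_broad > _WRAP_WARN_DEG or self.sigma_m > _WRAP_WARN_DEG:
            warnings.warn(
                "category or measurement SD exceeds 30 degrees; the "
                "no-wraparound Gaussian approximation may be poor",
                stacklevel=3,
            )


def match_dprime(
    sigma_val: float, sigma_inv: float, d_prime_target: float
) -> tuple[float, float]:
    """Stimulus magnitudes (mu_val, mu_inv) that equate d' across conditions.

    Analytic titration: since d' = mu/sigma, matching requires
    ``mu_c = d' * sigma_c`` in each condition.
    """
    if sigma_val <= 0 or sigma_inv <= 0 or d_prime_target < 0:
        raise ValueError("sigmas must be > 0 and d_prime_target >= 0")
    return d_prime_target * sigma_val, d_prime_target * sigma_inv


def simulate_detection(
    models: Mapping[str, DetectionModel],
    policy: CriterionPolicy,
    n_per_condition: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate a threshold observer on the detection task.

    For each condition (mapping key -> :class:`DetectionModel`): the
    stimulus is present with the model's prior, the measurement is
    ``x ~ Normal(s, sigma**2)``, and the response is
    ``x > policy_criterion(policy, sigma)`` (a tie counts as "absent").
    """
    if n_per_condition < 1:
        raise ValueError(f"n_per_condition must be >= 1, got {n_per_condition}")
    if not models:
        raise ValueError("need at least one condition model")
    children = np.random.SeedSequence(seed).spawn(len(models))
    frames = []
    offset = 0
    for (label, model), child in zip(models.items(), children):
        rng = np.random.default_rng(child)
        present = rng.random(n_per_condition) < model.prior_present
        s = np.where(present, model.mu, 0.0)
        x = s + rng.normal(0.0, model.sigma, n_per_condition)
        k = policy_criterion(policy, model.sigma)
        frames.append(
            pd.DataFrame(
                {
                    "trial": np.arange(offset, offset + n_per_condition),
                    "condition": label,
                    "truth": present.astype(int),
                    "stimulus": s,
                    "response": (x > k).astype(int),
                }
            )
        )
        offset += n_per_condition
    out = pd.concat(frames, ignore_index=True)
    out.attrs["seed"] = seed
    return out


def simulate_embedded_category(
    model: EmbeddedCategoryModel,
    k: float,
    n_trials: int,
    seed: int,
    condition: str = "single",
) -> pd.DataFrame:
    """Simulate a symmetric-threshold observer on the embedded-category task.

    Per trial: category drawn with ``prior_cat1``; orientation
    ``s ~ Normal(0, sigma_C**2)``; measurement ``x ~ Normal(s, sigma_m**2)``;
    response "category 2" iff ``|x| > k`` (tie -> category 1).
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cat1 = rng.random(n_trials) < model.prior_cat1
    sd = np.where(cat1, model.sigma_narrow, model.sigma_broad)
    s = rng.normal(0.0, 1.0, n_trials) * sd
    x = s + rng.normal(0.0, 1.0, n_trials) * model.sigma_m
    out = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "condition": condition,
            "truth": np.where(cat1, 1, 2),
            "stimulus": s,
            "response": (np.abs(x) > k).astype(int),
        }
    )
    out.attrs["seed"] = seed
    return out


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as plain CSV with the canonical column order."""
    trials.loc[:, list(TRIAL_COLUMNS)].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df
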