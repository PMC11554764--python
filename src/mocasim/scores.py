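"""Normative score models and raw-score generation.

Four published normative equations give the mean MoCA score of a cognitively
healthy Italian as a function of age and education years; each is a linear
model in one transformed age term and one transformed education term,
written in centered form so the intercept is the mean score at the centering
constants. Raw scores for an individual are the normative mean for their age
and education, minus a fixed offset for MCI or dementia, plus i.i.d.
Gaussian noise representing unobserved influences. Scores may optionally be
rounded to the nearest integer and clipped to the valid range [0, 30].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "NormativeEquation",
    "ScoreGenParams",
    "EQUATIONS",
    "get_equation",
    "expected_score",
    "status_offset",
    "generate_raw_scores",
]

ArrayLike = float | np.ndarray


@dataclass(frozen=True)
class NormativeEquation:
    """One normative mean-score model in centered linear form.

    ``mean = intercept + age_coefficient * (age_basis(age) - age_center)
    + edu_coefficient * (edu_basis(edu) - edu_center)``.
    """

    id: str
    age_basis: Callable[[ArrayLike], ArrayLike]
    edu_basis: Callable[[ArrayLike], ArrayLike]
    age_basis_name: str
    edu_basis_name: str
    intercept: float
    age_coefficient: float
    edu_coefficient: float
    age_center: float
    edu_center: float

    def design_columns(
        self, age: ArrayLike, edu: ArrayLike
    ) -> tuple[np.ndarray, np.ndarray]:
        """Centered (age, education) regressor columns for these covariates."""
        t_age = np.asarray(self.age_basis(np.asarray(age, dtype=float)))
        t_edu = np.asarray(self.edu_basis(np.asarray(edu, dtype=float)))
        return t_age - self.age_center, t_edu - self.edu_center


def _log10_100_minus_age(age: ArrayLike) -> ArrayLike:
    age = np.asarray(age, dtype=float)
    if np.any(age >= 100):
        raise ValueError("log10(100 - age) basis requires age < 100")
    return np.log10(100.0 - age)


def _ln_edu(edu: ArrayLike) -> ArrayLike:
    edu = np.asarray(edu, dtype=float)
    if np.any(edu <= 0):
        raise ValueError("log education basis requires edu > 0")
    return np.log(edu)


def _reciprocal_edu(edu: ArrayLike) -> ArrayLike:
    edu = np.asarray(edu, dtype=float)
    if np.any(edu <= 0):
        raise ValueError("reciprocal education basis requires edu > 0")
    return 1.0 / edu


def _sqrt_edu(edu: ArrayLike) -> ArrayLike:
    edu = np.asarray(edu, dtype=float)
    if np.any(edu < 0):
        raise ValueError("square-root education basis requires edu >= 0")
    return np.sqrt(edu)


EQUATIONS: dict[str, NormativeEquation] = {
    eq.id: eq
    for eq in [
        NormativeEquation(
            id="aiello",
            age_basis=lambda a: np.asarray(a, dtype=float) ** 3,
            edu_basis=_ln_edu,
            age_basis_name="age^3",
            edu_basis_name="ln(edu)",
            intercept=24.17,
            age_coefficient=-0.000008,
            edu_coefficient=3.331407,
            age_center=297697.18,
            edu_center=2.325648,
        ),
        NormativeEquation(
            id="conti",
            age_basis=lambda a: np.asarray(a, dtype=float),
            edu_basis=_reciprocal_edu,
            age_basis_name="age",
            edu_basis_name="1/edu",
            intercept=23.28,
            age_coefficient=-0.175,
            edu_coefficient=-24.3,
            age_center=70.08,
            edu_center=0.126,
        ),
        NormativeEquation(
            id="santangelo",
            age_basis=_log10_100_minus_age,
            edu_basis=_sqrt_edu,
            age_basis_name="log10(100-age)",
            edu_basis_name="sqrt(edu)",
            intercept=21.98,
            age_coefficient=4.228,
            edu_coefficient=3.201,
            age_center=1.58,
            edu_center=3.25,
        ),
        NormativeEquation(
            id="montemurro",
            age_basis=lambda a: np.asarray(a, dtype=float),
            edu_basis=lambda e: np.asarray(e, dtype=float),
            age_basis_name="age",
            edu_basis_name="edu",
            intercept=25.468,
            age_coefficient=-0.089,
            edu_coefficient=0.187,
            age_center=67.086,
            edu_center=11.245,
        ),
    ]
}


def get_equation(name: str) -> NormativeEquation:
    """Look up a normative equation by its registry name."""
    try:
        return EQUATIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown equation {name!r}; choose from {sorted(EQUATIONS)}"
        ) from None


@dataclass(frozen=True)
class ScoreGenParams:
    """Parameters of the raw-score generating process.

    ``residual_sd`` is the standard deviation (points) of the i.i.d. Gaussian
    noise around the normative mean; 2.9 in the main configuration, 3.4 in a
    robustness variant. ``offset_mci`` and ``offset_dementia`` are the mean
    score deficits (points) of MCI and dementia patients relative to healthy
    peers of the same age and education. When ``round_scores`` is set, scores
    are rounded half-away-from-zero to the nearest integer and then clipped
    to ``clip_range``.
    """

    residual_sd: float = 2.9
    offset_mci: float = 5.1
    offset_dementia: float = 10.7
    round_scores: bool = False
    clip_range: tuple[float, float] = (0.0, 30.0)

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.offset_mci < 0 or self.offset_dementia < 0:
            raise ValueError("status offsets must be non-negative")
        if self.clip_range[0] > self.clip_range[1]:
            raise ValueError("clip_range bounds must be ordered")


def expected_score(eq: NormativeEquation, age: ArrayLike, edu: ArrayLike) -> ArrayLike:
    """Healthy-population mean score under ``eq``; no rounding, no clipping."""
    c_age, c_edu = eq.design_columns(age, edu)
    out = eq.intercept + eq.age_coefficient * c_age + eq.edu_coefficient * c_edu
    return float(out) if out.ndim == 0 else out


def status_offset(params: ScoreGenParams, status: str | np.ndarray) -> ArrayLike:
    """Points subtracted from the healthy mean for a cognitive status."""
    if isinstance(status, str):
        status = np.asarray([status])
        scalar = True
    else:
        status = np.asarray(status)
        scalar = False
    known = np.isin(status, ["healthy", "MCI", "dementia"])
    if not known.all():
        raise ValueError(f"unknown cognitive status {status[~known][0]!r}")
    out = np.zeros(status.shape)
    out[status == "MCI"] = params.offset_mci
    out[status == "dementia"] = params.offset_dementia
    return float(out[0]) if scalar else out


def generate_raw_scores(
    cohort: pd.DataFrame,
    eq: NormativeEquation,
    params: ScoreGenParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign raw scores to a sampled cohort, returning a new DataFrame.

    ``raw_score = expected_score(age, edu) - status_offset + N(0, residual_sd)``
    per individual, with i.i.d. errors; rounding and clipping are applied
    afterwards when enabled (rounding first, then clipping -- immaterial for
    integer bounds but fixed for determinism).
    """
    mean = expected_score(eq, cohort["age"].to_numpy(), cohort["edu_years"].to_numpy())
    offs = status_offset(params, cohort["status"].to_numpy())
    raw = mean - offs + rng.normal(0.0, params.residual_sd, size=len(cohort))
    if params.round_scores:
        # round half away from zero (scores are positive, so half up)
        raw = np.floor(raw + 0.5)
        raw = np.clip(raw, *params.clip_range)
    out = cohort.copy()
    out["raw_score"] = raw
    return out
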