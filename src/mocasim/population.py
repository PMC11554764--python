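"""Super-population model: the joint distribution of sex, age group,
education, and cognitive status, and cohort sampling from it.

The population of interest is Italian residents aged 55-89. It is described
by a fully tabulated joint distribution over 2 sexes x 7 five-year age
groups x 5 education categories (5, 8, 11, 13, or 17 completed years of
schooling) x 3 cognitive statuses (healthy, MCI, dementia) -- 210 cells in
total. Cohorts are drawn i.i.d. from this distribution; within a sampled
age group, age is assigned uniformly on the half-open real interval
[low, high + 1), so an individual in the "85-89" group may be 89.999 years
old.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "EDUCATION_YEARS",
    "STATUSES",
    "JointDistributionTable",
    "load_joint_table",
    "sample_cohort",
]

AGE_GROUPS: list[tuple[int, int]] = [
    (55, 59), (60, 64), (65, 69), (70, 74), (75, 79), (80, 84), (85, 89),
]
EDUCATION_YEARS: list[int] = [5, 8, 11, 13, 17]
#: Completed education levels corresponding to EDUCATION_YEARS (the 11- and
#: 13-year categories both count as three completed levels).
EDUCATION_LEVELS: list[int] = [1, 2, 3, 3, 4]
STATUSES: list[str] = ["healthy", "MCI", "dementia"]
SEXES: list[str] = ["female", "male"]

_EXPECTED_CELLS = len(SEXES) * len(AGE_GROUPS) * len(EDUCATION_YEARS) * len(STATUSES)
#: Printed percentages are rounded to 3 decimals; 210 cells of +-5e-4
#: rounding error keep the total within this slack of 100.
_SUM_SLACK_PERCENT = 0.15


class TableValidationError(ValueError):
    """Raised when a joint-distribution fixture fails validation."""


@dataclass(frozen=True)
class JointDistributionTable:
    """Validated, normalized joint distribution over the 210 population cells.

    Attributes
    ----------
    cells
        One row per cell with columns ``sex``, ``age_low``, ``age_high``,
        ``edu_years``, ``edu_levels``, ``status``, ``percent`` (as printed)
        and ``probability`` (normalized so the column sums to exactly 1).
    """

    cells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.cells
        if len(df) != _EXPECTED_CELLS:
            raise TableValidationError(
                f"expected {_EXPECTED_CELLS} cells, got {len(df)}"
            )
        bad = df[df["percent"] < 0]
        if not bad.empty:
            row = bad.iloc[0]
            raise TableValidationError(
                f"negative probability in cell ({row.sex}, {row.age_low}-"
                f"{row.age_high}, {row.edu_years}y, {row.status})"
            )
        total = df["percent"].sum()
        if abs(total - 100.0) > _SUM_SLACK_PERCENT:
            raise TableValidationError(
                f"cell percentages sum to {total:.4f}, expected 100 "
                f"within {_SUM_SLACK_PERCENT}"
            )
        keys = df[["sex", "age_low", "edu_years", "status"]]
        if keys.duplicated().any():
            raise TableValidationError("duplicate (sex, age, edu, status) cell")

    @property
    def probabilities(self) -> np.ndarray:
        """Normalized cell probabilities, summing to exactly 1."""
        return self.cells["probability"].to_numpy()

    def cell_probability(
        self, sex: str, age_low: int, edu_years: int, status: str
    ) -> float:
        """Normalized probability of a single cell, addressed by its key."""
        df = self.cells
        m = (
            (df["sex"] == sex)
            & (df["age_low"] == age_low)
            & (df["edu_years"] == edu_years)
            & (df["status"] == status)
        )
        sel = df.loc[m, "probability"]
        if len(sel) != 1:
            raise KeyError((sex, age_low, edu_years, status))
        return float(sel.iloc[0])

    def marginal_prevalence(self) -> pd.Series:
        """Marginal probability of each cognitive status."""
        return self.cells.groupby("status", sort=False)["probability"].sum()


def load_joint_table(source: str | None = None) -> JointDistributionTable:
    """Load and validate a joint-distribution table.

    Parameters
    ----------
    source
        Path to a CSV with columns ``sex, age_low, age_high, edu_years,
        edu_levels, status, percent``. By default the packaged table of the
        2023 Italian resident population aged 55-89 is used.

    Returns
    -------
    JointDistributionTable
        With probabilities rescaled to sum to exactly 1.
    """
    if source is None:
        ref = resources.files("mocasim.data") / "table1_joint_distribution.csv"
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)
    expected_cols = {
        "sex", "age_low", "age_high", "edu_years", "edu_levels", "status", "percent",
    }
    missing = expected_cols - set(df.columns)
    if missing:
        raise TableValidationError(f"fixture missing columns: {sorted(missing)}")
    df = df.copy()
    df["probability"] = df["percent"] / df["percent"].sum()
    return JointDistributionTable(cells=df.reset_index(drop=True))


def sample_cohort(
    table: JointDistributionTable, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample a cohort of ``n`` individuals i.i.d. from the joint distribution.

    The cell is chosen by a single flattened 210-way categorical draw; age is
    then drawn uniformly on ``[age_low, age_high + 1)`` of the sampled cell's
    age group. Scores are not set.

    Returns
    -------
    pandas.DataFrame
        Columns ``sex``, ``age`` (continuous years), ``age_low``,
        ``age_high``, ``edu_years``, ``status``; one row per individual.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    cells = table.cells
    idx = rng.choice(len(cells), size=n, p=table.probabilities)
    picked = cells.iloc[idx].reset_index(drop=True)
    low = picked["age_low"].to_numpy(dtype=float)
    high = picked["age_high"].to_numpy(dtype=float)
    age = low + rng.random(n) * (high + 1.0 - low)
    return pd.DataFrame(
        {
            "sex": picked["sex"].to_numpy(),
            "age": age,
            "age_low": picked["age_low"].to_numpy(),
            "age_high": picked["age_high"].to_numpy(),
            "edu_years": picked["edu_years"].to_numpy(),
            "status": picked["status"].to_numpy(),
        }
    )
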