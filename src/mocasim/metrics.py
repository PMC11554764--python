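"""Discrimination and cutoff-based screening metrics.

Orientation conventions used throughout: lower scores indicate impairment,
so an individual screens positive when their score is strictly below the
cutoff (scores equal to the cutoff are negative). The AUC is the
Mann-Whitney probability that a randomly chosen impaired individual scores
below a randomly chosen healthy one, ties counted half. Cutoffs that hit a
preselected marginal specificity or sensitivity are linearly interpolated
empirical quantiles (the "type 7" rule) of the relevant development-sample
score distribution, so for continuous scores the operating point is
achieved exactly in the development sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .population import AGE_GROUPS, EDUCATION_YEARS

__all__ = [
    "auc",
    "find_cutoff_specificity",
    "find_cutoff_sensitivity",
    "CutoffSet",
    "sens_spec",
]


def auc(positive_scores: np.ndarray, negative_scores: np.ndarray) -> float:
    """Mann-Whitney AUC with the low-score-positive orientation.

    Equals P(positive < negative) + 0.5 * P(positive == negative) over all
    cross-class pairs, which is the trapezoidal area under the empirical ROC
    curve.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC undefined: one class is empty")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    scores = np.concatenate([pos, neg])
    # negate so that the decision score increases with impairment
    return float(roc_auc_score(labels, -scores))


def find_cutoff_specificity(
    healthy_scores: np.ndarray, target_specificity: float
) -> float:
    """Threshold at which the healthy sample attains the target specificity.

    Specificity is the fraction of healthy scores classified negative
    (score >= cutoff); the cutoff is the interpolated empirical quantile of
    the healthy scores at probability ``1 - target_specificity``.
    """
    if not 0.0 < target_specificity < 1.0:
        raise ValueError("target specificity must be in (0, 1)")
    healthy_scores = np.asarray(healthy_scores, dtype=float)
    if healthy_scores.size == 0:
        raise ValueError("no healthy scores to determine a cutoff from")
    return float(np.quantile(healthy_scores, 1.0 - target_specificity))


def find_cutoff_sensitivity(
    mci_scores: np.ndarray, target_sensitivity: float
) -> float:
    """Threshold at which the MCI sample attains the target sensitivity.

    Sensitivity is the fraction of MCI scores classified positive
    (score < cutoff); the cutoff is the interpolated empirical quantile of
    the MCI scores at probability ``target_sensitivity``.
    """
    if not 0.0 < target_sensitivity < 1.0:
        raise ValueError("target sensitivity must be in (0, 1)")
    mci_scores = np.asarray(mci_scores, dtype=float)
    if mci_scores.size == 0:
        raise ValueError("no MCI scores to determine a cutoff from")
    return float(np.quantile(mci_scores, target_sensitivity))


@dataclass(frozen=True)
class CutoffSet:
    """The three marginal thresholds for one score type.

    ``spec977``/``spec841``: development-sample healthy-score quantiles
    achieving 97.7% / 84.1% marginal specificity. ``sens841``:
    development-sample MCI-score quantile achieving 84.1% marginal
    sensitivity. Positive (impaired) means score strictly below the
    threshold, so the higher-specificity cutoff is the lower threshold.
    """

    spec977: float
    spec841: float
    sens841: float

    @classmethod
    def from_development(
        cls, healthy_scores: np.ndarray, mci_scores: np.ndarray
    ) -> "CutoffSet":
        return cls(
            spec977=find_cutoff_specificity(healthy_scores, 0.977),
            spec841=find_cutoff_specificity(healthy_scores, 0.841),
            sens841=find_cutoff_sensitivity(mci_scores, 0.841),
        )


def sens_spec(
    cohort: pd.DataFrame,
    score_type: str,
    cutoff: float,
    stratified: bool = False,
) -> tuple[float, float] | tuple[float, float, pd.DataFrame]:
    """Sensitivity and specificity at a cutoff, marginally and per stratum.

    Evaluation is restricted to MCI and healthy individuals (dementia cases
    are excluded, matching the screening contrast of distinguishing MCI
    from no cognitive impairment). Sensitivity is the fraction of MCI
    individuals with score < cutoff; specificity the fraction of healthy
    individuals with score >= cutoff.

    Parameters
    ----------
    cohort
        Must carry ``status`` plus the score column named by ``score_type``
        (``"raw"`` -> ``raw_score``, ``"corrected"`` -> ``corrected_score``);
        stratified output additionally needs ``age_low`` and ``edu_years``.
    stratified
        When true, also return a DataFrame indexed by (age_low, edu_years)
        with per-stratum ``sensitivity``, ``specificity``, ``n_mci``,
        ``n_healthy``; strata with no members of a class carry NaN for the
        undefined metric.
    """
    col = {"raw": "raw_score", "corrected": "corrected_score"}[score_type]
    eva = cohort[cohort["status"] != "dementia"]
    is_mci = (eva["status"] == "MCI").to_numpy()
    if not is_mci.any() or is_mci.all():
        raise ValueError("need both MCI and healthy individuals to evaluate")
    positive = eva[col].to_numpy() < cutoff
    se = float(positive[is_mci].mean())
    sp = float((~positive[~is_mci]).mean())
    if not stratified:
        return se, sp
    return se, sp, _stratum_table(eva, positive, is_mci)


def _stratum_table(
    eva: pd.DataFrame, positive: np.ndarray, is_mci: np.ndarray
) -> pd.DataFrame:
    """Per-(age group, education) sensitivity/specificity via bincount."""
    age_lows = np.array(AGE_GROUPS)[:, 0]
    edu_years = np.array(EDUCATION_YEARS)
    a_idx = np.searchsorted(age_lows, eva["age_low"].to_numpy())
    e_idx = np.searchsorted(edu_years, eva["edu_years"].to_numpy())
    sidx = a_idx * len(edu_years) + e_idx
    n = len(age_lows) * len(edu_years)
    n_mci = np.bincount(sidx[is_mci], minlength=n).astype(float)
    n_healthy = np.bincount(sidx[~is_mci], minlength=n).astype(float)
    tp = np.bincount(sidx[is_mci & positive], minlength=n).astype(float)
    tn = np.bincount(sidx[~is_mci & ~positive], minlength=n).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(n_mci > 0, tp / n_mci, np.nan)
        spec = np.where(n_healthy > 0, tn / n_healthy, np.nan)
    index = pd.MultiIndex.from_product(
        [age_lows, edu_years], names=["age_low", "edu_years"]
    )
    return pd.DataFrame(
        {"sensitivity": sens, "specificity": spec, "n_mci": n_mci, "n_healthy": n_healthy},
        index=index,
    )
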