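"""Nonparametric ROC analysis of ordinal global ratings.

Each examiner ends every assessment with a 1-5 Likert rating of how likely
pulmonary hypertension is (5 = most likely). Sweeping a threshold over the
ordinal levels yields the empirical ROC curve; its trapezoidal area equals
the Mann-Whitney two-sample statistic with ties given half credit, and the
Hanley-McNeil closed form supplies the standard error and 95% CI for the
area. An area below 0.5 (an examiner whose confidence runs *against* the
disease) is reported as-is, never reflected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import ExamDataset
from .errors import EstimationError

__all__ = ["ROCResult", "mann_whitney_auc", "roc_points", "hanley_ci", "roc_curve_result",
           "roc_report"]

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve and its area for one rater.

    ``points`` is an (k, 2) array of (FPR, TPR) operating points running
    monotonically from (0, 0) to (1, 1), one point per rating threshold.
    """

    points: np.ndarray
    auc: float
    se: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int
    examiner_id: str | None = None
    examiner_group: str | None = None


def _as_arrays(ratings, status) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(ratings, dtype=float)
    s = np.asarray(status, dtype=bool)
    if r.shape != s.shape or r.ndim != 1:
        raise EstimationError("ratings and status must be 1-d arrays of equal length")
    if s.all() or not s.any():
        raise EstimationError("ROC needs both diseased and non-diseased subjects")
    return r, s


def mann_whitney_auc(ratings, status) -> float:
    """Probability that a diseased subject outranks a non-diseased one.

    Computed from midranks: ``AUC = (R+ − n+(n+ + 1)/2) / (n+ · n−)`` where
    ``R+`` is the rank sum of the diseased group — identical to the
    pairwise count with ties worth 1/2.
    """
    r, s = _as_arrays(ratings, status)
    n_pos = int(s.sum())
    n_neg = int(len(s) - n_pos)
    ranks = rankdata(r)
    u = ranks[s].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_points(ratings, status) -> np.ndarray:
    """Operating points (FPR, TPR) for thresholds 'rating >= c', swept from
    above the maximum level (0, 0) down to the minimum level (1, 1)."""
    r, s = _as_arrays(ratings, status)
    n_pos, n_neg = s.sum(), (~s).sum()
    levels = np.unique(r)[::-1]
    pts = [(0.0, 0.0)]
    for c in levels:
        call_pos = r >= c
        pts.append(((call_pos & ~s).sum() / n_neg, (call_pos & s).sum() / n_pos))
    return np.asarray(pts)


def hanley_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, float, float]:
    """Hanley-McNeil standard error and 95% CI for a nonparametric AUC.

    ``SE² = [A(1−A) + (n+−1)(Q₁−A²) + (n−−1)(Q₂−A²)] / (n+ n−)`` with
    ``Q₁ = A/(2−A)`` and ``Q₂ = 2A²/(1+A)``; the normal-approximation CI is
    clipped to [0, 1]. Returns ``(se, lo, hi)``.
    """
    if not 0.0 <= auc <= 1.0:
        raise EstimationError(f"AUC must lie in [0, 1], got {auc}")
    if n_pos < 1 or n_neg < 1:
        raise EstimationError("both classes need at least one subject")
    a = float(auc)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    se = float(np.sqrt(max(var, 0.0)))
    return se, max(0.0, a - _Z95 * se), min(1.0, a + _Z95 * se)


def roc_curve_result(
    ratings,
    status,
    examiner_id: str | None = None,
    examiner_group: str | None = None,
) -> ROCResult:
    """Full nonparametric ROC result for one set of ordinal ratings."""
    r, s = _as_arrays(ratings, status)
    auc = mann_whitney_auc(r, s)
    pts = roc_points(r, s)
    n_pos, n_neg = int(s.sum()), int((~s).sum())
    se, lo, hi = hanley_ci(auc, n_pos, n_neg)
    return ROCResult(
        points=pts,
        auc=auc,
        se=se,
        ci=(lo, hi),
        n_pos=n_pos,
        n_neg=n_neg,
        examiner_id=examiner_id,
        examiner_group=examiner_group,
    )


def roc_report(dataset: ExamDataset) -> tuple[pd.DataFrame, list[ROCResult]]:
    """Per-examiner ROC table: one row per examiner with group label, AUC,
    Hanley SE and 95% CI. An examiner whose rated subjects fall in a single
    disease class is skipped with a logged warning."""
    merged = dataset.merged_ratings()
    if merged.empty:
        raise EstimationError("dataset contains no global ratings")
    roster = dataset.examiners.set_index("examiner_id")["examiner_group"]
    rows, results = [], []
    for examiner_id, sub in merged.groupby("examiner_id", sort=True):
        status = sub["ph_status"].to_numpy(dtype=bool)
        if status.all() or not status.any():
            logger.warning(
                "examiner %s rated subjects from a single disease class; skipped", examiner_id
            )
            continue
        group = roster.get(examiner_id)
        res = roc_curve_result(
            sub["rating"].to_numpy(), status, examiner_id=str(examiner_id),
            examiner_group=group,
        )
        results.append(res)
        rows.append(
            {
                "examiner_id": examiner_id,
                "examiner_group": group,
                "auc": res.auc,
                "se": res.se,
                "ci_lo": res.ci[0],
                "ci_hi": res.ci[1],
                "n_pos": res.n_pos,
                "n_neg": res.n_neg,
            }
        )
    if not rows:
        raise EstimationError("no examiner had subjects from both disease classes")
    return pd.DataFrame(rows), results
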