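"""Sensitivity, specificity and likelihood ratios from a 2x2 table.

Conventions for a finding-vs-disease cross-classification::

                 disease (PH)   no disease
    finding +ve       TP            FP
    finding -ve       FN            TN

Point estimates and 95% intervals follow the standard diagnostic-accuracy
toolkit:

* proportions (Sn, Sp) get Wilson score intervals;
* likelihood ratios get log-method intervals, ``exp(ln LR ± 1.96·SE)`` with
  ``SE(ln LR+) = sqrt(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN))`` and the FN/TN
  analogue for LR−;
* any zero cell triggers the Haldane–Anscombe continuity correction (0.5
  added to all four cells), applied to point estimates and intervals alike
  so that e.g. a table with FP = 0 still yields a finite LR+ and a
  specificity below 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from statsmodels.stats.proportion import proportion_confint

from .errors import DataError, EstimationError

__all__ = [
    "ContingencyTable",
    "IntervalEstimate",
    "AccuracyEstimate",
    "apply_continuity_correction",
    "proportion_ci",
    "likelihood_ratios",
    "accuracy_summary",
    "pool_tables",
]

_Z95 = 1.959963984540054  # normal 97.5% quantile


class IntervalEstimate(NamedTuple):
    """A point estimate with a 95% interval (confidence or credible)."""

    point: float
    lo: float
    hi: float


@dataclass(frozen=True)
class ContingencyTable:
    """The four cells of a finding-vs-disease 2x2 table.

    Cells are stored as floats because the continuity correction adds 0.5
    to every cell; raw study data always have integer cells.
    """

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                raise DataError(f"cell {name} must be a finite non-negative number, got {v!r}")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.tp, self.fp, self.fn, self.tn)

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_diseased(self) -> float:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> float:
        return self.fp + self.tn

    @property
    def has_zero_cell(self) -> bool:
        return any(c == 0 for c in self.cells)

    @property
    def is_integer(self) -> bool:
        return all(float(c).is_integer() for c in self.cells)

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class AccuracyEstimate:
    """Test characteristics of a binary finding against a gold standard.

    ``sensitivity``/``specificity`` are proportions in [0, 1];
    ``lr_pos``/``lr_neg`` are the positive and negative likelihood ratios.
    Each carries a 95% interval. ``corrected`` records whether the
    continuity correction fired; ``method`` labels how intervals were built.
    """

    sensitivity: IntervalEstimate
    specificity: IntervalEstimate
    lr_pos: IntervalEstimate
    lr_neg: IntervalEstimate
    corrected: bool = False
    method: str = "Wilson (proportions); log-method (LRs)"

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "lr_pos", "lr_neg"):
            est = getattr(self, name)
            if not (est.lo <= est.point <= est.hi):
                raise EstimationError(f"{name}: interval {est} does not bracket the point")

    def to_row(self) -> dict:
        """Flat dict for report assembly (percentages for Sn/Sp)."""
        return {
            "sn_pct": 100 * self.sensitivity.point,
            "sn_lo_pct": 100 * self.sensitivity.lo,
            "sn_hi_pct": 100 * self.sensitivity.hi,
            "sp_pct": 100 * self.specificity.point,
            "sp_lo_pct": 100 * self.specificity.lo,
            "sp_hi_pct": 100 * self.specificity.hi,
            "lr_pos": self.lr_pos.point,
            "lr_pos_lo": self.lr_pos.lo,
            "lr_pos_hi": self.lr_pos.hi,
            "lr_neg": self.lr_neg.point,
            "lr_neg_lo": self.lr_neg.lo,
            "lr_neg_hi": self.lr_neg.hi,
            "corrected": self.corrected,
        }

    def format_row(self) -> str:
        """One display line matching the usual table style: percentages to
        one decimal, likelihood ratios to two."""
        sn, sp, lp, ln = self.sensitivity, self.specificity, self.lr_pos, self.lr_neg
        return (
            f"Sn {100 * sn.point:.1f}%  Sp {100 * sp.point:.1f}%  "
            f"LR+ {lp.point:.2f} [{lp.lo:.2f}-{lp.hi:.2f}]  "
            f"LR- {ln.point:.2f} [{ln.lo:.2f}-{ln.hi:.2f}]"
            + ("  (continuity-corrected)" if self.corrected else "")
        )


def apply_continuity_correction(table: ContingencyTable) -> ContingencyTable:
    """Haldane–Anscombe correction: if any cell is zero, add 0.5 to all four
    cells; otherwise return the table unchanged."""
    if table.has_zero_cell:
        return ContingencyTable(table.tp + 0.5, table.fp + 0.5, table.fn + 0.5, table.tn + 0.5)
    return table


def proportion_ci(successes: float, n: float) -> IntervalEstimate:
    """Binomial proportion with its 95% Wilson score interval.

    Raises :class:`EstimationError` for ``n == 0`` and
    :class:`DataError` for counts outside ``0 <= successes <= n``.
    """
    if n <= 0:
        raise EstimationError("cannot estimate a proportion from n = 0 trials")
    if not 0 <= successes <= n:
        raise DataError(f"successes must lie in [0, n]; got {successes} of {n}")
    lo, hi = proportion_confint(successes, n, alpha=0.05, method="wilson")
    point = successes / n
    # guard against float residue at the k=0 / k=n boundaries
    return IntervalEstimate(
        point, max(0.0, min(float(lo), point)), min(1.0, max(float(hi), point))
    )


def _check_margins(table: ContingencyTable) -> None:
    if table.n_diseased == 0 or table.n_healthy == 0:
        raise EstimationError(
            "table has an empty margin (no diseased or no non-diseased subjects); "
            f"cells = {table.cells}"
        )


def likelihood_ratios(table: ContingencyTable) -> AccuracyEstimate:
    """Positive and negative likelihood ratios with log-method 95% CIs.

    The continuity correction is applied first whenever the table contains
    a zero cell, so both point estimates and intervals are finite; the
    ``corrected`` flag records that this happened. The returned record also
    carries Sn/Sp (Wilson intervals) computed from the same, possibly
    corrected, cells so the LR identities ``LR+ = Sn/(1−Sp)`` and
    ``LR− = (1−Sn)/Sp`` hold exactly.
    """
    _check_margins(table)
    corrected = table.has_zero_cell
    t = apply_continuity_correction(table)
    tp, fp, fn, tn = t.cells
    sn = tp / (tp + fn)
    sp = tn / (fp + tn)
    if sp == 1.0:
        # unreachable after correction for integer input; guards float tables
        raise EstimationError("specificity is exactly 1; apply the continuity correction first")
    if sn == 1.0:
        raise EstimationError("sensitivity is exactly 1; apply the continuity correction first")
    lr_pos = sn / (1 - sp)
    lr_neg = (1 - sn) / sp
    se_pos = math.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
    se_neg = math.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
    return AccuracyEstimate(
        sensitivity=proportion_ci(tp, tp + fn),
        specificity=proportion_ci(tn, fp + tn),
        lr_pos=IntervalEstimate(
            lr_pos, lr_pos * math.exp(-_Z95 * se_pos), lr_pos * math.exp(_Z95 * se_pos)
        ),
        lr_neg=IntervalEstimate(
            lr_neg, lr_neg * math.exp(-_Z95 * se_neg), lr_neg * math.exp(_Z95 * se_neg)
        ),
        corrected=corrected,
    )


def accuracy_summary(table: ContingencyTable) -> AccuracyEstimate:
    """Full test-characteristics record for one 2x2 table: continuity
    correction, Sn/Sp with Wilson CIs, LRs with log-method CIs."""
    return likelihood_ratios(table)


def pool_tables(tables: list[ContingencyTable]) -> ContingencyTable:
    """Cell-wise sum of raw (integer-cell) tables from multiple studies."""
    if not tables:
        raise DataError("cannot pool an empty list of tables")
    for i, t in enumerate(tables):
        if not t.is_integer:
            raise DataError(f"table {i} has non-integer cells {t.cells}; pool raw counts only")
    out = tables[0]
    for t in tables[1:]:
        out = out + t
    return out
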