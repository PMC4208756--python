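"""Domain model and tabular I/O for multi-rater physical-examination studies.

The study design represented here: every subject undergoes right heart
catheterization (RHC) giving a mean pulmonary artery pressure (mPAP, mmHg),
which dichotomizes disease status; several examiners, each labelled
specialist or generalist, independently assess a fixed set of physical signs
at rest and during a slow inspiratory maneuver (binary present/absent), and
give a 1-5 Likert global rating of how likely pulmonary hypertension is.

Data are exchanged as three UTF-8 CSV files with header rows:

``findings.csv``   subject_id, examiner_id, examiner_group, sign, phase, present
``rhc.csv``        subject_id, mpap
``ratings.csv``    subject_id, examiner_id, rating
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, EmptySelectionError

__all__ = [
    "SIGNS",
    "PHASES",
    "GROUPS",
    "PH_MPAP_THRESHOLD",
    "classify_ph",
    "ExamDataset",
    "read_exam_dataset",
    "write_exam_dataset",
    "build_contingency",
]

#: The five pre-specified physical signs of pulmonary hypertension.
SIGNS = ("rv_lift", "loud_p2", "s4", "tr_murmur", "jvd_elevated")

#: Each sign is assessed during quiet breathing and during slow inspiration.
PHASES = ("rest", "inspiration")

#: Examiner experience strata.
GROUPS = ("specialist", "generalist")

#: mPAP cut-off (mmHg): disease is mPAP strictly above this value.
PH_MPAP_THRESHOLD = 25.0

_FINDINGS_COLS = ["subject_id", "examiner_id", "examiner_group", "sign", "phase", "present"]
_RHC_COLS = ["subject_id", "mpap"]
_RATINGS_COLS = ["subject_id", "examiner_id", "rating"]
_KEY_COLS = ["subject_id", "examiner_id", "sign", "phase"]


def classify_ph(mpap: float) -> bool:
    """Dichotomize a right-heart-catheterization mPAP into disease status.

    Pulmonary hypertension is defined as mPAP > 25 mmHg; a subject at
    exactly 25 mmHg belongs to the normal-pressure group.

    Parameters
    ----------
    mpap : float
        Mean pulmonary artery pressure in mmHg; must be positive.

    Raises
    ------
    DataError
        If ``mpap`` is missing, non-numeric or not positive.
    """
    try:
        value = float(mpap)
    except (TypeError, ValueError):
        raise DataError(f"mpap must be a positive number, got {mpap!r}") from None
    if not np.isfinite(value) or value <= 0:
        raise DataError(f"mpap must be a positive number, got {mpap!r}")
    return value > PH_MPAP_THRESHOLD


@dataclass
class ExamDataset:
    """Validated long-format container for one examination study.

    Attributes
    ----------
    findings : DataFrame
        One row per subject x examiner x sign x phase with a 0/1 ``present``
        column; ``examiner_group`` is constant per examiner.
    rhc : DataFrame
        One row per subject: ``mpap`` and the derived boolean ``ph_status``.
    ratings : DataFrame
        One 1-5 global rating per (subject, examiner) pair (may be empty).
    """

    findings: pd.DataFrame
    rhc: pd.DataFrame
    ratings: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_RATINGS_COLS))

    def __post_init__(self) -> None:
        self.findings = _validate_findings(self.findings)
        self.rhc = _validate_rhc(self.rhc)
        self.ratings = _validate_ratings(self.ratings)
        self._cross_validate()

    def _cross_validate(self) -> None:
        known = set(self.rhc["subject_id"])
        for name, frame in (("findings", self.findings), ("ratings", self.ratings)):
            orphans = set(frame["subject_id"]) - known
            if orphans:
                raise DataError(
                    f"{name} reference subjects with no RHC record: {sorted(orphans)[:5]}"
                )
        roster = self.examiners
        extra = set(self.ratings["examiner_id"]) - set(roster["examiner_id"])
        if extra:
            raise DataError(f"ratings reference unknown examiners: {sorted(extra)[:5]}")

    @property
    def examiners(self) -> pd.DataFrame:
        """Roster of examiners with their group labels, sorted by id."""
        roster = (
            self.findings[["examiner_id", "examiner_group"]]
            .drop_duplicates()
            .sort_values("examiner_id", ignore_index=True)
        )
        return roster

    @property
    def n_subjects(self) -> int:
        return len(self.rhc)

    def merged_findings(self) -> pd.DataFrame:
        """Findings joined with per-subject disease status."""
        return self.findings.merge(
            self.rhc[["subject_id", "ph_status"]], on="subject_id", validate="m:1"
        )

    def merged_ratings(self) -> pd.DataFrame:
        """Ratings joined with per-subject disease status."""
        return self.ratings.merge(
            self.rhc[["subject_id", "ph_status"]], on="subject_id", validate="m:1"
        )


def _require_columns(frame: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise DataError(f"{name} is missing required column(s): {missing}")


def _check_enum(frame: pd.DataFrame, col: str, allowed: tuple[str, ...], name: str) -> None:
    bad = frame.loc[~frame[col].isin(allowed)]
    if not bad.empty:
        row = int(bad.index[0])
        raise DataError(
            f"{name} row {row}: invalid {col} {bad[col].iloc[0]!r} (allowed: {allowed})"
        )


def _validate_findings(frame: pd.DataFrame) -> pd.DataFrame:
    frame = pd.DataFrame(frame).reset_index(drop=True)
    _require_columns(frame, _FINDINGS_COLS, "findings")
    _check_enum(frame, "examiner_group", GROUPS, "findings")
    _check_enum(frame, "sign", SIGNS, "findings")
    _check_enum(frame, "phase", PHASES, "findings")
    present = pd.to_numeric(frame["present"], errors="coerce")
    bad = frame.loc[~present.isin([0, 1])]
    if not bad.empty:
        raise DataError(
            f"findings row {int(bad.index[0])}: present must be 0 or 1, "
            f"got {bad['present'].iloc[0]!r}"
        )
    frame["present"] = present.astype(np.int8)
    dup = frame.duplicated(subset=_KEY_COLS)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = frame.loc[row, _KEY_COLS].tolist()
        raise DataError(f"findings row {row}: duplicate assessment key {key}")
    groups = frame.groupby("examiner_id")["examiner_group"].nunique()
    unstable = groups[groups > 1]
    if not unstable.empty:
        raise DataError(
            f"examiner_group must be constant per examiner; inconsistent for "
            f"{unstable.index.tolist()}"
        )
    return frame[_FINDINGS_COLS]


def _validate_rhc(frame: pd.DataFrame) -> pd.DataFrame:
    frame = pd.DataFrame(frame).reset_index(drop=True)
    _require_columns(frame, _RHC_COLS, "rhc")
    dup = frame.duplicated(subset=["subject_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataError(f"rhc row {row}: duplicate subject_id {frame.loc[row, 'subject_id']!r}")
    mpap = pd.to_numeric(frame["mpap"], errors="coerce")
    bad = frame.loc[mpap.isna() | (mpap <= 0)]
    if not bad.empty:
        raise DataError(
            f"rhc row {int(bad.index[0])}: mpap must be a positive number, "
            f"got {bad['mpap'].iloc[0]!r}"
        )
    frame["mpap"] = mpap.astype(float)
    frame["ph_status"] = frame["mpap"] > PH_MPAP_THRESHOLD
    return frame[["subject_id", "mpap", "ph_status"]]


def _validate_ratings(frame: pd.DataFrame) -> pd.DataFrame:
    frame = pd.DataFrame(frame).reset_index(drop=True)
    if frame.empty and not set(_RATINGS_COLS) <= set(frame.columns):
        return pd.DataFrame(columns=_RATINGS_COLS)
    _require_columns(frame, _RATINGS_COLS, "ratings")
    rating = pd.to_numeric(frame["rating"], errors="coerce")
    bad = frame.loc[~rating.isin([1, 2, 3, 4, 5])]
    if not bad.empty:
        raise DataError(
            f"ratings row {int(bad.index[0])}: rating must be an integer in 1..5, "
            f"got {bad['rating'].iloc[0]!r}"
        )
    frame["rating"] = rating.astype(np.int8)
    dup = frame.duplicated(subset=["subject_id", "examiner_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = frame.loc[row, ["subject_id", "examiner_id"]].tolist()
        raise DataError(f"ratings row {row}: duplicate rating key {key}")
    return frame[_RATINGS_COLS]


def read_exam_dataset(directory: str | Path) -> ExamDataset:
    """Read ``findings.csv``, ``rhc.csv`` and (optionally) ``ratings.csv``
    from *directory* into a validated :class:`ExamDataset`.

    Raises
    ------
    DataError
        On missing files/columns, unknown enum values, out-of-range ratings
        or duplicate keys; messages name the offending row.
    """
    directory = Path(directory)
    paths = {name: directory / f"{name}.csv" for name in ("findings", "rhc", "ratings")}
    for name in ("findings", "rhc"):
        if not paths[name].exists():
            raise DataError(f"required file not found: {paths[name]}")
    findings = pd.read_csv(paths["findings"])
    rhc = pd.read_csv(paths["rhc"])
    if paths["ratings"].exists():
        ratings = pd.read_csv(paths["ratings"])
    else:
        ratings = pd.DataFrame(columns=_RATINGS_COLS)
    return ExamDataset(findings=findings, rhc=rhc, ratings=ratings)


def write_exam_dataset(dataset: ExamDataset, directory: str | Path) -> dict[str, Path]:
    """Write the three CSV files; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, frame, cols in (
        ("findings", dataset.findings, _FINDINGS_COLS),
        ("rhc", dataset.rhc, _RHC_COLS),
        ("ratings", dataset.ratings, _RATINGS_COLS),
    ):
        path = directory / f"{name}.csv"
        frame[cols].to_csv(path, index=False)
        out[name] = path
    return out


def build_contingency(
    dataset: ExamDataset,
    sign: str,
    phase: str,
    examiner_group: str | None = None,
):
    """Pool assessments of one sign/phase into a 2x2 table against disease.

    Every matching assessment contributes one count: TP if the finding was
    recorded present in a diseased subject, and so on. ``examiner_group``
    restricts to one experience stratum (``None`` pools all examiners).
    This is a descriptive cross-tabulation; inferential summaries that
    respect the clustering by examiner live in :mod:`phexam.rater_model`.
    """
    from .contingency import ContingencyTable

    if sign not in SIGNS:
        raise DataError(f"unknown sign {sign!r} (allowed: {SIGNS})")
    if phase not in PHASES:
        raise DataError(f"unknown phase {phase!r} (allowed: {PHASES})")
    if examiner_group is not None and examiner_group not in GROUPS:
        raise DataError(f"unknown examiner_group {examiner_group!r} (allowed: {GROUPS})")
    merged = dataset.merged_findings()
    mask = (merged["sign"] == sign) & (merged["phase"] == phase)
    if examiner_group is not None:
        mask &= merged["examiner_group"] == examiner_group
    sel = merged.loc[mask]
    if sel.empty:
        raise EmptySelectionError(
            f"no assessments match sign={sign!r}, phase={phase!r}, "
            f"examiner_group={examiner_group!r}"
        )
    pos = sel["present"].to_numpy().astype(bool)
    dis = sel["ph_status"].to_numpy().astype(bool)
    return ContingencyTable(
        tp=int((pos & dis).sum()),
        fp=int((pos & ~dis).sum()),
        fn=int((~pos & dis).sum()),
        tn=int((~pos & ~dis).sum()),
    )
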