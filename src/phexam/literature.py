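"""Published 2x2 tables on physical signs of pulmonary hypertension.

Cell counts from the handful of historical studies that reported enough
data (cases *and* controls) to reconstruct a finding-vs-disease
cross-classification: the 1968 phonocardiographic series of Sutton, Harris
& Leatham (loud P2, with the companion normal-subject series of Harris &
Sutton as controls), the liver-transplant cohort of Pilatis et al. (2000)
and the systemic-sclerosis cohort of Ungerer et al. (1983). These counts
are study inputs, shipped so the likelihood-ratio computations can be
reproduced without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .contingency import ContingencyTable, accuracy_summary

__all__ = ["LiteratureStudy", "LITERATURE_TABLES", "literature_report"]


@dataclass(frozen=True)
class LiteratureStudy:
    key: str
    study: str
    finding: str
    table: ContingencyTable


LITERATURE_TABLES: tuple[LiteratureStudy, ...] = (
    LiteratureStudy(
        key="sutton_harris_combined",
        study="Sutton, Harris & Leatham (1968) + Harris & Sutton (1968)",
        finding="P2>A2",
        table=ContingencyTable(tp=45, fp=1, fn=54, tn=123),
    ),
    LiteratureStudy(
        key="sutton_alone",
        study="Sutton, Harris & Leatham (1968)",
        finding="P2>A2",
        table=ContingencyTable(tp=45, fp=0, fn=54, tn=34),
    ),
    LiteratureStudy(
        key="sutton_p2_ge_a2",
        study="Sutton, Harris & Leatham (1968)",
        finding="P2>=A2",
        table=ContingencyTable(tp=72, fp=10, fn=27, tn=24),
    ),
    LiteratureStudy(
        key="pilatis_loud_p2",
        study="Pilatis et al. (2000)",
        finding="loud P2",
        table=ContingencyTable(tp=3, fp=1, fn=5, tn=46),
    ),
    LiteratureStudy(
        key="pilatis_rv_heave",
        study="Pilatis et al. (2000)",
        finding="RV heave",
        table=ContingencyTable(tp=3, fp=2, fn=5, tn=45),
    ),
    LiteratureStudy(
        key="ungerer_exam",
        study="Ungerer et al. (1983)",
        finding="composite physical exam",
        table=ContingencyTable(tp=8, fp=4, fn=8, tn=29),
    ),
)

#: The Sutton-alone case series and the Harris & Sutton control series;
#: summing their cells reproduces the combined loud-P2 row.
HARRIS_CONTROLS = ContingencyTable(tp=0, fp=1, fn=0, tn=89)


def literature_report() -> pd.DataFrame:
    """Accuracy summary for every shipped literature table, one row each."""
    rows = []
    for entry in LITERATURE_TABLES:
        est = accuracy_summary(entry.table)
        rows.append(
            {
                "key": entry.key,
                "study": entry.study,
                "finding": entry.finding,
                "tp": entry.table.tp,
                "fp": entry.table.fp,
                "fn": entry.table.fn,
                "tn": entry.table.tn,
                **est.to_row(),
            }
        )
    return pd.DataFrame(rows)
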