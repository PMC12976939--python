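"""Built-in example data.

``example_cohort`` transcribes the per-case summary of a published 19-case
revision-arthroplasty cohort (cases worked up for possible periprosthetic
joint infection): number of HPF patches per whole-slide image, the median
and interquartile range of the per-HPF neutrophil count, and the three
reference verdicts (histology report, microbiological culture, and the
multidisciplinary-team conclusion). It lets the diagnosis engine and the
paired-classifier statistics be exercised end to end without access to
slides.

Note the published IQRs are reproduced verbatim; in a few rows the printed
median lies outside the printed IQR, so treat the IQR columns as
descriptive only.
"""

from __future__ import annotations

import pandas as pd

from .diagnose import CaseRecord, classify_case

_COHORT_ROWS = [
    # case_id, patches, median, q1, q3, histology, microbiology, mdt
    ("case01", 339, 167, 45, 263, "infected", "growth", "infected"),
    ("case02", 165, 27, 1, 18, "infected", "growth", "infected"),
    ("case03", 1579, 20, 3, 14, "infected", "growth", "infected"),
    ("case04", 3625, 11, 2, 9, "infected", "growth", "infected"),
    ("case05", 3376, 9, 2, 8, "infected", "growth", "infected"),
    ("case06", 96, 7, 1, 8, "infected", "no_growth", "infected"),
    ("case07", 832, 7, 2, 8, "uncertain", "growth", "infected"),
    ("case08", 34, 6, 3, 8, "not_infected", "growth", "infected"),
    ("case09", 431, 5, 1, 6, "not_infected", "no_growth", "not_infected"),
    ("case10", 504, 5, 2, 6, "infected", "growth", "infected"),
    ("case11", 385, 3, 1, 3, "not_infected", "no_growth", "not_infected"),
    ("case12", 505, 3, 1, 3, "not_infected", "no_growth", "not_infected"),
    ("case13", 397, 3, 1, 3, "infected", "no_growth", "infected"),
    ("case14", 239, 3, 1, 4, "not_infected", "no_growth", "not_infected"),
    ("case15", 321, 3, 1, 3, "uncertain", "no_growth", "not_infected"),
    ("case16", 673, 2, 1, 2, "infected", "growth", "infected"),
    ("case17", 46, 2, 1, 2, "not_infected", "no_growth", "not_infected"),
    ("case18", 218, 2, 1, 2, "not_infected", "no_growth", "not_infected"),
    ("case19", 21, 1, 1, 1, "not_infected", "no_growth", "not_infected"),
]


def example_cohort() -> pd.DataFrame:
    """The 19-case example cohort as a tidy DataFrame."""
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=[
            "case_id",
            "patches",
            "median",
            "q1",
            "q3",
            "histology",
            "microbiology",
            "mdt",
        ],
    )


def example_cohort_records(threshold: float = 5.0, rule: str = "ge") -> list[CaseRecord]:
    """The example cohort as classified :class:`CaseRecord` objects.

    Raw per-HPF counts are not published, so records carry only the summary
    statistics; the prediction is recomputed from the median via
    :func:`neutrocount.diagnose.classify_case`.
    """
    records = []
    for cid, patches, med, q1, q3, hist, micro, mdt in _COHORT_ROWS:
        records.append(
            CaseRecord(
                case_id=cid,
                n_patches=patches,
                median=float(med),
                iqr=(float(q1), float(q3)),
                predicted=classify_case(float(med), threshold, rule),
                references={"histology": hist, "microbiology": micro, "mdt": mdt},
            )
        )
    return records
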