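"""Cohort-table handling: subject records, group assignment, CSV I/O.

Subjects are split into ``low`` and ``high`` depressive-symptom groups by
the MADRS-SIGMA total score with the conventional cut-off of >8: a score
of 9 or more places a subject in the high group, a score of exactly 8
stays in the low group.  The group column is always derived from the
score, never trusted from an input file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

log = logging.getLogger(__name__)

MADRS_MIN = 0
MADRS_MAX = 60
#: total score above which a subject is assigned to the high-symptom group
MADRS_CUTOFF = 8

REQUIRED_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "nihss",
    "madrs_total",
    "history_depression",
    "antidepressant",
)
#: optional item-level symptom flags; feed only the demographic report
OPTIONAL_COLUMNS = (
    "reported_sadness",
    "reported_discouragement",
    "reported_loss_of_interest",
)

SEX_VALUES = ("female", "male")


class CohortValidationError(ValueError):
    """Raised when a cohort table or subject record fails validation."""


def assign_group(madrs_total: int) -> str:
    """Assign the depressive-symptom group from a MADRS-SIGMA total score.

    Parameters
    ----------
    madrs_total:
        Total score on the 10-item MADRS-SIGMA interview, range 0-60.

    Returns
    -------
    ``"high"`` if the score is strictly greater than 8, else ``"low"``.
    """
    score = int(madrs_total)
    if score != madrs_total:
        raise CohortValidationError(f"madrs_total must be an integer, got {madrs_total!r}")
    if not MADRS_MIN <= score <= MADRS_MAX:
        raise CohortValidationError(
            f"madrs_total {score} outside the valid range [{MADRS_MIN}, {MADRS_MAX}]"
        )
    return "high" if score > MADRS_CUTOFF else "low"


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the cohort table.

    ``group`` is always derived from ``madrs_total`` at construction.
    """

    subject_id: str
    age: float
    sex: str
    nihss: int
    madrs_total: int
    history_depression: bool
    antidepressant: bool
    reported_sadness: Optional[bool] = None
    reported_discouragement: Optional[bool] = None
    reported_loss_of_interest: Optional[bool] = None
    group: str = field(init=False)

    def __post_init__(self) -> None:
        try:
            group = assign_group(self.madrs_total)
        except CohortValidationError as exc:
            raise CohortValidationError(f"subject {self.subject_id!r}: {exc}") from exc
        if self.sex not in SEX_VALUES:
            raise CohortValidationError(
                f"subject {self.subject_id!r}: sex must be one of {SEX_VALUES}, got {self.sex!r}"
            )
        if not self.age > 0:
            raise CohortValidationError(f"subject {self.subject_id!r}: age must be positive")
        if self.nihss < 0:
            raise CohortValidationError(f"subject {self.subject_id!r}: nihss must be non-negative")
        object.__setattr__(self, "group", group)


@dataclass
class CohortTable:
    """Ordered collection of subject records with per-group counts."""

    records: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterable[SubjectRecord]:
        return iter(self.records)

    @property
    def n_low(self) -> int:
        return sum(1 for r in self.records if r.group == "low")

    @property
    def n_high(self) -> int:
        return sum(1 for r in self.records if r.group == "high")

    def subset(self, group: str) -> "CohortTable":
        return CohortTable([r for r in self.records if r.group == group])

    def to_frame(self) -> pd.DataFrame:
        """Return the cohort as a DataFrame (group column included)."""
        rows = []
        for r in self.records:
            row = {
                "subject_id": r.subject_id,
                "age": r.age,
                "sex": r.sex,
                "nihss": r.nihss,
                "madrs_total": r.madrs_total,
                "history_depression": r.history_depression,
                "antidepressant": r.antidepressant,
                "group": r.group,
            }
            for col in OPTIONAL_COLUMNS:
                val = getattr(r, col)
                if val is not None:
                    row[col] = val
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _parse_bool(value, subject_id: str, column: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str):
        lowered = value.strip().lower()
        if lowered in ("true", "yes", "1"):
            return True
        if lowered in ("false", "no", "0"):
            return False
    raise CohortValidationError(
        f"subject {subject_id!r}: cannot interpret {column}={value!r} as a yes/no flag"
    )


def load_cohort(path: str | Path) -> CohortTable:
    """Load a cohort table from CSV and derive the group column.

    The file must carry a header with the columns
    ``subject_id, age, sex, nihss, madrs_total, history_depression,
    antidepressant``; item-level symptom flags
    (``reported_sadness``, ``reported_discouragement``,
    ``reported_loss_of_interest``) are optional and, when absent, treated
    as missing rather than imputed.  Any ``group`` column in the file is
    ignored: the grouping is recomputed from ``madrs_total``.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortValidationError(f"{path}: empty cohort file") from exc
    if frame.empty:
        raise CohortValidationError(f"{path}: cohort file has no rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required columns {missing}")

    records = []
    for _, row in frame.iterrows():
        sid = str(row["subject_id"])
        try:
            madrs = int(row["madrs_total"])
            nihss = int(row["nihss"])
            age = float(row["age"])
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(f"subject {sid!r}: non-numeric field ({exc})") from exc
        optional = {}
        for col in OPTIONAL_COLUMNS:
            if col in frame.columns and not pd.isna(row[col]):
                optional[col] = _parse_bool(row[col], sid, col)
        records.append(
            SubjectRecord(
                subject_id=sid,
                age=age,
                sex=str(row["sex"]).strip().lower(),
                nihss=nihss,
                madrs_total=madrs,
                history_depression=_parse_bool(row["history_depression"], sid, "history_depression"),
                antidepressant=_parse_bool(row["antidepressant"], sid, "antidepressant"),
                **optional,
            )
        )
    cohort = CohortTable(records)
    frame_all = cohort.to_frame()
    for name, sub in frame_all.groupby("group"):
        log.info(
            "cohort %s group %s: n=%d age %.1f(%.1f) madrs %.1f(%.1f) nihss %.1f(%.1f)",
            path.name,
            name,
            len(sub),
            sub["age"].mean(),
            sub["age"].std(),
            sub["madrs_total"].mean(),
            sub["madrs_total"].std(),
            sub["nihss"].mean(),
            sub["nihss"].std(),
        )
    return cohort
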