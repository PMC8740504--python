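"""Patient-level data model and counting-process views.

A cohort is a set of subjects followed from diagnosis (time 0) to death or
censoring.  In counting-process notation, subject i carries N_i(t) (0 until
death, then 1) and the at-risk indicator Y_i(t) = I(T_i >= t); the estimators
consume the aggregated risk sets and death counts at the unique death times.

Only classical right censoring from t = 0 is supported: delayed entry
(left truncation / period analysis) is rejected at load time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ratetable import to_decimal_year

logger = logging.getLogger(__name__)

__all__ = ["Subject", "CohortAtRisk", "CohortValidationError", "load_cohort", "risk_sets"]

#: column names a cohort file must not contain (delayed entry unsupported)
_ENTRY_ALIASES = {"entry", "entry_time", "start", "start_time", "tstart", "left_trunc"}


class CohortValidationError(ValueError):
    """Raised when cohort rows fail validation; message lists offending rows."""


@dataclass
class Subject:
    """One patient: follow-up, vital status, and the keys driving table lookups.

    ``time`` is years since diagnosis at death (``event`` = 1) or censoring
    (``event`` = 0).  ``rate_keys`` match the subject to the expected rate
    table's strata; ``standard_stratum`` is the joint covariate cell used for
    external standardisation weights.
    """

    id: object
    time: float
    event: int
    age_at_diagnosis: float | None = None
    diagnosis_date: float | None = None  # decimal year
    rate_keys: dict = field(default_factory=dict)
    standard_stratum: str | None = None

    def validate(self) -> list[str]:
        problems = []
        if not (self.time > 0):
            problems.append(f"time must be > 0 (got {self.time})")
        if self.event not in (0, 1):
            problems.append(f"event must be 0 or 1 (got {self.event})")
        if self.age_at_diagnosis is not None and self.age_at_diagnosis < 0:
            problems.append(f"age at diagnosis must be >= 0 (got {self.age_at_diagnosis})")
        return problems


def load_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
) -> list[Subject]:
    """Load a delimited cohort file into validated :class:`Subject` records.

    Canonical columns are ``id, time, event, age_dx, date_dx, std_stratum``;
    ``schema`` maps canonical names to the file's column names.  Any other
    column is taken as a rate-table matching key.  Validation problems are
    collected per row and raised together.
    """
    df = pd.read_csv(path, sep=sep)
    schema = dict(schema or {})
    cols = {
        name: schema.get(name, name)
        for name in ("id", "time", "event", "age_dx", "date_dx", "std_stratum")
    }
    lowered = {c.lower() for c in df.columns}
    entry_like = sorted(lowered & _ENTRY_ALIASES)
    if entry_like:
        raise CohortValidationError(
            f"column(s) {entry_like} look like delayed-entry times; late entry "
            "(left truncation / period analysis) is not supported — follow-up "
            "must start at diagnosis"
        )
    for req in ("id", "time", "event"):
        if cols[req] not in df.columns:
            raise CohortValidationError(f"cohort file is missing required column {cols[req]!r}")

    known = {v for v in cols.values() if v in df.columns}
    key_cols = [c for c in df.columns if c not in known]

    subjects: list[Subject] = []
    errors: list[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rec = dict(zip(df.columns, row))
        try:
            date = rec.get(cols["date_dx"])
            date = to_decimal_year(date) if date is not None and not pd.isna(date) else None
        except Exception as exc:
            errors.append(f"row {row_no}: {exc}")
            continue
        age = rec.get(cols["age_dx"])
        age = float(age) if age is not None and not pd.isna(age) else None
        std = rec.get(cols["std_stratum"])
        std = str(std) if std is not None and not pd.isna(std) else None
        try:
            subj = Subject(
                id=rec[cols["id"]],
                time=float(rec[cols["time"]]),
                event=int(rec[cols["event"]]),
                age_at_diagnosis=age,
                diagnosis_date=date,
                rate_keys={k: str(rec[k]) for k in key_cols},
                standard_stratum=std,
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"row {row_no}: {exc}")
            continue
        for problem in subj.validate():
            errors.append(f"row {row_no} (id={subj.id!r}): {problem}")
        subjects.append(subj)

    if errors:
        shown = "\n  ".join(errors[:20])
        more = f"\n  ... and {len(errors) - 20} more" if len(errors) > 20 else ""
        raise CohortValidationError(f"cohort validation failed:\n  {shown}{more}")

    times = np.array([s.time for s in subjects])
    events = np.array([s.event for s in subjects])
    logger.info(
        "loaded cohort: n=%d, events=%d, censored=%d, follow-up %.3f-%.3f y",
        len(subjects), int(events.sum()), int((1 - events).sum()),
        times.min() if len(times) else float("nan"),
        times.max() if len(times) else float("nan"),
    )
    return subjects


@dataclass
class CohortAtRisk:
    """Aggregated counting-process view: risk sets and deaths at event times.

    Deaths at a time are processed before censorings at the same time, so a
    subject censored exactly at a death time is still in that risk set
    (the >= convention in Y_i(t) = I(T_i >= t)).
    """

    subjects: list
    times: np.ndarray
    events: np.ndarray
    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_deaths: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.times)

    def at_risk_indices(self, s: float) -> np.ndarray:
        """Indices of subjects with Y_i(s) = 1, i.e. T_i >= s."""
        return np.nonzero(self.times >= s)[0]

    def death_indices(self, s: float) -> np.ndarray:
        """Indices with dN_i(s) = 1."""
        return np.nonzero((self.times == s) & (self.events == 1))[0]


def risk_sets(subjects: Sequence[Subject] | CohortAtRisk) -> CohortAtRisk:
    """Build the risk-set view from a subject collection."""
    if isinstance(subjects, CohortAtRisk):
        return subjects
    subjects = list(subjects)
    if not subjects:
        raise CohortValidationError("cohort is empty")
    times = np.array([s.time for s in subjects], dtype=float)
    events = np.array([s.event for s in subjects], dtype=int)
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        warnings.warn("cohort has no events; all estimates will be flat", stacklevel=2)
    sorted_times = np.sort(times)
    n = len(times)
    n_at_risk = n - np.searchsorted(sorted_times, event_times, side="left")
    death_times = np.sort(times[events == 1])
    n_deaths = (
        np.searchsorted(death_times, event_times, side="right")
        - np.searchsorted(death_times, event_times, side="left")
    )
    return CohortAtRisk(subjects, times, events, event_times, n_at_risk, n_deaths)
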