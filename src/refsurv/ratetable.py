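"""Population mortality rate tables and per-subject expected hazard paths.

Relative-survival estimation needs, for every patient, the mortality rate a
demographically matched member of the general population would experience at
each moment of follow-up.  National life tables provide these rates on a grid
of attained age (completed years) by calendar year, optionally stratified by
further demographic keys (sex, deprivation, region, ...).  This module loads
and validates such tables, answers point lookups, and integrates the matched
rate along a subject's follow-up into the cumulative expected hazard

    H*_i(t) = integral_0^t h*_i(s) ds,      S*_i(t) = exp(-H*_i(t)),

where the matched rate h*_i changes only when the subject crosses an age
birthday or a calendar new year.  The same machinery, pointed at a second
("reference") table, yields H**_i and S**_i for reference adjustment.

Conventions (documented because national life tables do not standardise
them): attained age floors to completed years, calendar year is the civil
year, both cells are half-open [a, a+1); rates are constant within each
one-year x one-year cell; one year equals 365.25 days; ages above the oldest
row carry the oldest row forward; calendar years outside the covered range
clamp to the nearest covered year.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

__all__ = [
    "RateTable",
    "RateTableError",
    "ExpectedHazardPath",
    "load_ratetable",
    "lookup_rate",
    "expected_hazard_path",
    "to_decimal_year",
]


class RateTableError(ValueError):
    """Raised for malformed, incomplete, or mis-queried rate tables."""


def to_decimal_year(value) -> float:
    """Convert an ISO date, ``datetime.date`` or decimal year to a decimal year.

    Uses years = days / 365.25 from January 1 of the civil year, which keeps
    the arithmetic timezone-free and reproducible.
    """
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    if isinstance(value, _dt.datetime):
        value = value.date()
    if isinstance(value, _dt.date):
        jan1 = _dt.date(value.year, 1, 1)
        return value.year + (value - jan1).days / DAYS_PER_YEAR
    if isinstance(value, str):
        text = value.strip()
        try:
            return float(text)
        except ValueError:
            pass
        try:
            return to_decimal_year(_dt.date.fromisoformat(text))
        except ValueError as exc:
            raise RateTableError(
                f"cannot parse {value!r} as a date: use ISO dates (YYYY-MM-DD) "
                "or decimal years"
            ) from exc
    raise RateTableError(f"unsupported date value {value!r}")


@dataclass
class RateTable:
    """Population mortality rates per person-year on an age x year x strata grid.

    The grid is dense and complete: every (age, year, stratum) cell within the
    declared ranges holds a finite non-negative rate, so lookups never miss.
    """

    age_min: int
    age_max: int
    year_min: int
    year_max: int
    strata_keys: tuple
    cell_index: dict
    rates: np.ndarray  # shape (n_ages, n_years, n_cells)
    max_age_policy: str = "carry_forward"

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        age_col: str = "age",
        year_col: str = "year",
        rate_col: str = "rate",
        strata_keys: Sequence[str] | None = None,
    ) -> "RateTable":
        for col in (age_col, year_col, rate_col):
            if col not in df.columns:
                raise RateTableError(f"rate table is missing required column {col!r}")
        if strata_keys is None:
            strata_keys = [c for c in df.columns if c not in (age_col, year_col, rate_col)]
        strata_keys = tuple(strata_keys)

        ages = df[age_col].to_numpy()
        years = df[year_col].to_numpy()
        if not np.all(np.equal(np.mod(ages, 1), 0)) or not np.all(np.equal(np.mod(years, 1), 0)):
            raise RateTableError("age and year columns must be integers")
        ages = ages.astype(int)
        years = years.astype(int)
        rates = pd.to_numeric(df[rate_col], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(rates)):
            bad = df.index[~np.isfinite(rates)][:5].tolist()
            raise RateTableError(f"non-numeric or non-finite rates at rows {bad}")
        if np.any(rates < 0):
            bad = df.index[rates < 0][:5].tolist()
            raise RateTableError(f"negative rates at rows {bad}")

        if strata_keys:
            combos = list(map(tuple, df[list(strata_keys)].astype(str).to_numpy()))
        else:
            combos = [()] * len(df)
        cell_index: dict = {}
        for combo in combos:
            if combo not in cell_index:
                cell_index[combo] = len(cell_index)

        a0, a1 = int(ages.min()), int(ages.max())
        y0, y1 = int(years.min()), int(years.max())
        grid = np.full((a1 - a0 + 1, y1 - y0 + 1, len(cell_index)), np.nan)
        ai = ages - a0
        yi = years - y0
        ci = np.array([cell_index[c] for c in combos])
        if len({(a, y, c) for a, y, c in zip(ai, yi, ci)}) != len(df):
            seen: set = set()
            for a, y, c in zip(ages, years, combos):
                key = (a, y, c)
                if key in seen:
                    raise RateTableError(f"duplicate rate-table cell (age={a}, year={y}, stratum={c})")
                seen.add(key)
        grid[ai, yi, ci] = rates

        if np.any(np.isnan(grid)):
            missing = np.argwhere(np.isnan(grid))
            inv = {v: k for k, v in cell_index.items()}
            cells = [
                f"(age={a0 + a}, year={y0 + y}, stratum={inv[c]})"
                for a, y, c in missing[:10]
            ]
            raise RateTableError(
                f"rate table is incomplete: {len(missing)} missing cell(s), "
                f"first: {', '.join(cells)}"
            )
        return cls(a0, a1, y0, y1, strata_keys, cell_index, grid)

    @classmethod
    def constant(
        cls,
        rate: float,
        ages: tuple = (0, 109),
        years: tuple = (1990, 2039),
    ) -> "RateTable":
        """A table holding one rate in every cell (no strata); simulation shorthand."""
        if rate < 0 or not math.isfinite(rate):
            raise RateTableError(f"constant rate must be finite and >= 0, got {rate}")
        grid = np.full((ages[1] - ages[0] + 1, years[1] - years[0] + 1, 1), float(rate))
        return cls(ages[0], ages[1], years[0], years[1], (), {(): 0}, grid)

    @classmethod
    def zero(cls, ages: tuple = (0, 109), years: tuple = (1990, 2039)) -> "RateTable":
        return cls.constant(0.0, ages, years)

    def scaled(self, factor: float) -> "RateTable":
        """A copy with every rate multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise RateTableError("scale factor must be >= 0")
        return RateTable(
            self.age_min, self.age_max, self.year_min, self.year_max,
            self.strata_keys, dict(self.cell_index), self.rates * factor,
            self.max_age_policy,
        )

    # -- queries -----------------------------------------------------------

    @property
    def is_constant(self) -> bool:
        return bool(np.all(self.rates == self.rates.flat[0]))

    def _cell(self, stratum) -> int:
        if stratum is None:
            key: tuple = ()
        elif isinstance(stratum, Mapping):
            try:
                key = tuple(str(stratum[k]) for k in self.strata_keys)
            except KeyError as exc:
                raise RateTableError(
                    f"subject is missing rate key {exc.args[0]!r} required by the table "
                    f"(strata: {list(self.strata_keys)})"
                ) from None
        else:
            key = tuple(str(v) for v in stratum)
        try:
            return self.cell_index[key]
        except KeyError:
            raise RateTableError(
                f"unknown stratum {key!r}; table strata {list(self.strata_keys)} "
                f"cover {sorted(self.cell_index)[:10]}"
            ) from None

    def rate_grid(self, stratum=None) -> np.ndarray:
        """The (age x year) rate matrix for one stratum."""
        return self.rates[:, :, self._cell(stratum)]

    def lookup(self, attained_age: float, calendar_year: float, stratum=None) -> float:
        """Rate per person-year for (attained_age, calendar_year, stratum).

        Age floors to completed years and carries the oldest row forward above
        ``age_max``; calendar year clamps to the covered range.
        """
        a = int(math.floor(attained_age))
        if a < self.age_min:
            raise RateTableError(
                f"attained age {attained_age} below table minimum {self.age_min}"
            )
        a = min(a, self.age_max)
        y = int(math.floor(calendar_year))
        y = min(max(y, self.year_min), self.year_max)
        return float(self.rates[a - self.age_min, y - self.year_min, self._cell(stratum)])

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns age, year, <strata...>, rate."""
        rows = []
        inv = {v: k for k, v in self.cell_index.items()}
        for c in range(self.rates.shape[2]):
            combo = inv[c]
            for a in range(self.age_min, self.age_max + 1):
                for y in range(self.year_min, self.year_max + 1):
                    rows.append((a, y, *combo, self.rates[a - self.age_min, y - self.year_min, c]))
        cols = ["age", "year", *self.strata_keys, "rate"]
        return pd.DataFrame(rows, columns=cols)


def load_ratetable(
    path,
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
    strata_keys: Sequence[str] | None = None,
) -> RateTable:
    """Load a long-format delimited rate table.

    ``schema`` maps the canonical names ``age``, ``year``, ``rate`` to the
    file's column names; all remaining columns are treated as strata keys
    unless ``strata_keys`` narrows them.
    """
    df = pd.read_csv(path, sep=sep)
    schema = dict(schema or {})
    age_col = schema.get("age", "age")
    year_col = schema.get("year", "year")
    rate_col = schema.get("rate", "rate")
    return RateTable.from_frame(df, age_col, year_col, rate_col, strata_keys)


def lookup_rate(table: RateTable, attained_age: float, calendar_year: float, stratum=None) -> float:
    """Functional alias for :meth:`RateTable.lookup`."""
    return table.lookup(attained_age, calendar_year, stratum)


@dataclass
class ExpectedHazardPath:
    """One subject's piecewise-constant expected hazard on the follow-up scale.

    ``breakpoints`` start at 0 and end at the construction horizon; the matched
    rate is constant on each segment; ``cumulative`` holds H* at every
    breakpoint so evaluation anywhere is piecewise-linear interpolation.
    """

    subject_id: object
    breakpoints: np.ndarray
    segment_rates: np.ndarray
    cumulative: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.segment_rates = np.asarray(self.segment_rates, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)

    @classmethod
    def from_segments(cls, subject_id, breakpoints, segment_rates) -> "ExpectedHazardPath":
        bp = np.asarray(breakpoints, dtype=float)
        sr = np.asarray(segment_rates, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(sr * np.diff(bp))])
        return cls(subject_id, bp, sr, cum)

    @classmethod
    def zero(cls, subject_id, horizon: float) -> "ExpectedHazardPath":
        return cls.from_segments(subject_id, [0.0, float(horizon)], [0.0])

    @property
    def horizon(self) -> float:
        return float(self.breakpoints[-1])

    def cumhaz(self, t):
        """H*(t); accepts scalars or arrays in [0, horizon]."""
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-12) or np.any(t > self.horizon + 1e-9):
            raise ValueError(
                f"time outside [0, {self.horizon}] for hazard path of subject "
                f"{self.subject_id!r}"
            )
        return np.interp(t, self.breakpoints, self.cumulative)

    def survival(self, t):
        """S*(t) = exp(-H*(t))."""
        return np.exp(-self.cumhaz(t))


def expected_hazard_path(
    subject,
    table: RateTable,
    horizon: float,
    frozen_year: int | None = None,
) -> ExpectedHazardPath:
    """Integrate the matched population rate along a subject's follow-up.

    Breakpoints are placed exactly where the attained age or the attained
    calendar year increments; within each segment the matched cell rate is
    constant.  ``frozen_year`` holds the calendar-year lookup constant, which
    is how a single-year reference rate set (e.g. national rates for one
    calendar year) is applied while the attained-age progression is kept.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    age0 = subject.age_at_diagnosis
    if age0 is None:
        raise ValueError(f"subject {subject.id!r} has no age at diagnosis")
    year0 = subject.diagnosis_date
    if year0 is None and frozen_year is None:
        raise ValueError(f"subject {subject.id!r} has no diagnosis date")

    cuts = [np.array([0.0, horizon])]
    frac_a = age0 - math.floor(age0)
    first_a = (1.0 - frac_a) if frac_a > 1e-9 else 1.0
    if first_a < horizon:
        cuts.append(np.arange(first_a, horizon, 1.0))
    if frozen_year is None:
        frac_y = year0 - math.floor(year0)
        first_y = (1.0 - frac_y) if frac_y > 1e-9 else 1.0
        if first_y < horizon:
            cuts.append(np.arange(first_y, horizon, 1.0))
    bp = np.unique(np.concatenate(cuts))

    mids = 0.5 * (bp[:-1] + bp[1:])
    ages = np.floor(age0 + mids).astype(int)
    if ages.min() < table.age_min:
        raise RateTableError(
            f"subject {subject.id!r}: attained age {ages.min()} below table "
            f"minimum {table.age_min}"
        )
    ages = np.minimum(ages, table.age_max)
    if frozen_year is not None:
        years = np.full(mids.shape, int(frozen_year))
    else:
        years = np.floor(year0 + mids).astype(int)
    years = np.clip(years, table.year_min, table.year_max)

    grid = table.rate_grid(getattr(subject, "rate_keys", None) or None)
    seg_rates = grid[ages - table.age_min, years - table.year_min]
    return ExpectedHazardPath.from_segments(subject.id, bp, seg_rates)
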