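"""Weighted counting-process estimators of marginal survival quantities.

The estimators operate on the unique death times of a cohort.  With
time-dependent weights w_i(s) = w_i^B S**_i(s)/S*_i(s) recomputed at each
unique event time, and per-subject expected-hazard increments dH*_i, dH**_i
accrued over the interval since the previous event time while at risk, the
increments are

    dLambda_R(s) = sum_i w_i(s) Y_i(s) {dN_i(s) - dH*_i(s)} / sum_i w_i(s) Y_i(s)
    dH_R**(s)   = sum_i w_i(s) Y_i(s)  dH**_i(s)            / sum_i w_i(s) Y_i(s)
    dH_R(s)     = dLambda_R(s) + dH_R**(s)

giving the reference-adjusted marginal all-cause cumulative hazard H_R, the
net cumulative hazard Lambda_R (Sasieni–Brentnall form), the reference
population part H_R**, all-cause survival S_R = exp(-H_R) and crude
probabilities of death due to cancer / other causes obtained by integrating
S_R(u-) against the respective increments.

Special cases (each recovered exactly, and asserted in the test suite):
identical expected and reference tables with unit pre-weights collapse to the
Nelson–Aalen all-cause estimator; zero reference hazard (S** = 1) makes
Lambda_R the Pohar Perme net cumulative hazard; unit weights make Lambda_R
the Ederer II net estimator; dropping dH** while keeping the ratio weights
gives the Sasieni–Brentnall net index.

Variance uses Poisson-type increments for the weighted cumulative hazards
(expected-hazard increments treated as deterministic) with delta-method /
influence-function propagation to S_R and the crude probabilities;
confidence intervals are on the log scale for cumulative hazards and the
log(-log) scale for probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortAtRisk, risk_sets
from .ratetable import ExpectedHazardPath, RateTable, expected_hazard_path
from .weights import standard_weights

__all__ = [
    "EstimateSeries",
    "EstimationError",
    "all_cause_cumhaz",
    "reference_adjusted_cumhaz",
    "crude_probabilities",
    "variance_ci",
    "estimate",
    "MODES",
]

MODES = (
    "observed",
    "reference_adjusted",
    "pohar_perme",
    "ederer2",
    "sasieni_brentnall",
)

#: probability-like columns get log(-log) CIs; hazards get log-scale CIs
_PROB_COLS = ("F", "F_R_C", "F_R_O")
_HAZ_COLS = ("H", "Lambda_R", "H_R")


class EstimationError(RuntimeError):
    """Raised when an estimator cannot be evaluated on the given inputs."""


@dataclass
class EstimateSeries:
    """Step-function estimates over the event-time (or interval) grid.

    ``table`` is indexed by time and holds whichever of the columns
    H, F, Lambda_R, H_R_pop, H_R, S_R, F_R_C, F_R_O have been computed,
    plus se_/lo_/hi_ columns after :func:`variance_ci`.  Values between grid
    points follow by last-value-carried-forward; before the first grid point
    every cumulative hazard is 0 and S_R is 1.
    """

    times: np.ndarray
    table: pd.DataFrame
    mode: str
    metadata: dict = field(default_factory=dict)
    level: float | None = None
    # per-increment internals reused by crude_probabilities / variance_ci
    _den: np.ndarray | None = field(default=None, repr=False)
    _vnum: np.ndarray | None = field(default=None, repr=False)
    _dLam: np.ndarray | None = field(default=None, repr=False)
    _dHpop: np.ndarray | None = field(default=None, repr=False)

    def _baseline(self, col: str) -> float:
        if col.startswith("se_"):
            return 0.0
        if col in ("S_R", "lo_S_R", "hi_S_R"):
            return 1.0
        return 0.0

    def at(self, report_times) -> pd.DataFrame:
        """Step-function values at arbitrary times (LVCF)."""
        rt = np.atleast_1d(np.asarray(report_times, dtype=float))
        idx = np.searchsorted(self.times, rt, side="right") - 1
        out = {}
        for col in self.table.columns:
            vals = self.table[col].to_numpy()
            base = self._baseline(col)
            if vals.size == 0:
                out[col] = np.full(rt.shape, base)
            else:
                out[col] = np.where(idx >= 0, vals[np.clip(idx, 0, None)], base)
        return pd.DataFrame(out, index=pd.Index(rt, name="time"))

    def value_at(self, t: float, col: str) -> float:
        return float(self.at([t])[col].iloc[0])

    def to_tidy(self) -> pd.DataFrame:
        """Long format: one row per (time, quantity) with se and CI if present."""
        rows = []
        for col in self.table.columns:
            if col.startswith(("se_", "lo_", "hi_")):
                continue
            block = pd.DataFrame(
                {
                    "time": self.times,
                    "quantity": col,
                    "estimate": self.table[col].to_numpy(),
                }
            )
            for pre, name in (("se_", "se"), ("lo_", "ci_low"), ("hi_", "ci_high")):
                full = pre + col
                block[name] = self.table[full].to_numpy() if full in self.table else np.nan
            block["mode"] = self.mode
            rows.append(block)
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

def _build_paths(subjects, table, horizon, frozen_year=None):
    if table is None:
        return None
    return [expected_hazard_path(s, table, horizon, frozen_year=frozen_year) for s in subjects]


def _weighted_increments(
    times: np.ndarray,
    events: np.ndarray,
    wB: np.ndarray,
    paths_exp: list | None,
    paths_ref: list | None,
    ratio_weights: bool,
):
    """Accumulate the weighted sums over subjects at every unique event time.

    Returns (event_times, dLam, dHpop, den, vnum) where den is the weighted
    number at risk and vnum the sum of squared weights over deaths (the
    Poisson variance numerator).
    """
    ev = np.unique(times[events == 1])
    m = ev.size
    den = np.zeros(m)
    numL = np.zeros(m)
    numO = np.zeros(m)
    vnum = np.zeros(m)
    if m == 0:
        return ev, numL, numO, den, vnum

    for i in range(len(times)):
        mi = int(np.searchsorted(ev, times[i], side="right"))
        if mi == 0:
            continue
        s = ev[:mi]
        if paths_exp is not None:
            pe = paths_exp[i]
            He = np.interp(s, pe.breakpoints, pe.cumulative)
        else:
            He = None
        if paths_ref is not None:
            pr = paths_ref[i]
            Hr = np.interp(s, pr.breakpoints, pr.cumulative)
        else:
            Hr = None
        if ratio_weights:
            a = He if He is not None else 0.0
            b = Hr if Hr is not None else 0.0
            w = wB[i] * np.exp(a - b)
            if np.isscalar(w) or w.ndim == 0:
                w = np.full(mi, float(w))
        else:
            w = np.full(mi, wB[i])
        den[:mi] += w
        if He is not None:
            numL[:mi] -= w * np.diff(He, prepend=0.0)
        if Hr is not None:
            numO[:mi] += w * np.diff(Hr, prepend=0.0)
        if events[i]:
            wi = w[mi - 1]
            numL[mi - 1] += wi
            vnum[mi - 1] += wi * wi

    if np.any(den <= 0):
        bad = ev[den <= 0][:5]
        raise EstimationError(f"zero weighted risk at event time(s) {bad}")
    return ev, numL / den, numO / den, den, vnum


def _subject_arrays(subjects):
    subjects = list(subjects)
    times = np.array([s.time for s in subjects], dtype=float)
    events = np.array([s.event for s in subjects], dtype=int)
    return subjects, times, events


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def all_cause_cumhaz(cohort) -> EstimateSeries:
    """Nelson–Aalen marginal all-cause cumulative hazard H and F = 1 - exp(-H)."""
    car = risk_sets(cohort)
    ev, dLam, dHpop, den, vnum = _weighted_increments(
        car.times, car.events, np.ones(car.n_subjects), None, None, ratio_weights=False
    )
    H = np.cumsum(dLam)
    table = pd.DataFrame({"H": H, "F": 1.0 - np.exp(-H)}, index=pd.Index(ev, name="time"))
    return EstimateSeries(
        ev, table, mode="observed",
        _den=den, _vnum=vnum, _dLam=dLam, _dHpop=dHpop,
    )


def reference_adjusted_cumhaz(
    subjects,
    expected: RateTable | None,
    reference: RateTable | None = None,
    *,
    weights: np.ndarray | None = None,
    standard: Mapping[str, float] | None = None,
    mode: str = "reference_adjusted",
    frozen_reference_year: int | None = None,
) -> EstimateSeries:
    """Weighted net / reference-adjusted cumulative hazards on the event grid.

    ``mode`` selects the estimator family:

    * ``reference_adjusted`` — ratio weights S**/S*, population part dH** kept
      (requires both tables): the full reference-adjusted all-cause measure;
    * ``sasieni_brentnall`` — ratio weights, dH** dropped: net index;
    * ``pohar_perme`` — zero reference hazard (S** = 1): net estimator with
      inverse-expected-survival weights;
    * ``ederer2`` — unit weights, dH** dropped: classical net estimator.

    ``weights`` are the per-subject time-fixed w^B (defaults to 1); pass a
    ``standard`` distribution instead to have them computed from the cohort.
    """
    if mode not in MODES or mode == "observed":
        raise ValueError(f"mode must be one of {MODES[1:]}, got {mode!r}")
    subjects, times, events = _subject_arrays(subjects)
    if not subjects:
        raise EstimationError("empty cohort")
    if expected is None:
        raise EstimationError(f"mode {mode!r} requires an expected rate table")
    needs_ref = mode in ("reference_adjusted", "sasieni_brentnall")
    if needs_ref and reference is None:
        raise EstimationError(f"mode {mode!r} requires a reference rate table")

    standardised = weights is not None or standard is not None
    if weights is None:
        weights = standard_weights(subjects, standard) if standard is not None else np.ones(len(subjects))
    wB = np.asarray(weights, dtype=float)
    if np.any(wB <= 0):
        raise EstimationError("time-fixed weights must be strictly positive")

    horizon = float(times.max()) + 1e-9
    paths_exp = _build_paths(subjects, expected, horizon)
    ratio = mode != "ederer2"
    if mode in ("pohar_perme", "ederer2"):
        paths_ref = None
    else:
        paths_ref = _build_paths(subjects, reference, horizon, frozen_year=frozen_reference_year)

    ev, dLam, dHpop, den, vnum = _weighted_increments(
        times, events, wB, paths_exp, paths_ref, ratio_weights=ratio
    )
    include_pop = mode == "reference_adjusted"
    if not include_pop:
        dHpop = np.zeros_like(dHpop)

    Lam = np.cumsum(dLam)
    Hpop = np.cumsum(dHpop)
    H_R = Lam + Hpop
    table = pd.DataFrame(
        {
            "Lambda_R": Lam,
            "H_R_pop": Hpop,
            "H_R": H_R,
            "S_R": np.exp(-H_R),
        },
        index=pd.Index(ev, name="time"),
    )
    meta = {
        "mode": mode,
        "frozen_reference_year": frozen_reference_year,
        "standardised": standardised,
    }
    return EstimateSeries(
        ev, table, mode=mode, metadata=meta,
        _den=den, _vnum=vnum, _dLam=dLam, _dHpop=dHpop,
    )


def crude_probabilities(series: EstimateSeries, *, allocation: str = "proportional") -> EstimateSeries:
    """Append crude probabilities of death due to cancer and other causes.

    ``proportional`` (default) splits each total increment
    S_R(u-) - S_R(u) between causes in proportion to dLambda_R(u) and
    dH_R**(u), so F_R_C + F_R_O = 1 - S_R holds exactly at every grid point.
    ``literal`` accumulates the plain integrals S_R(u-) dLambda_R(u) and
    S_R(u-) dH_R**(u); the two agree up to second order in the increments.
    """
    if allocation not in ("proportional", "literal"):
        raise ValueError(f"unknown allocation {allocation!r}")
    if series._dLam is None or "S_R" not in series.table:
        raise EstimationError("crude probabilities need a cumulative-hazard series")
    S = series.table["S_R"].to_numpy()
    Sprev = np.concatenate([[1.0], S[:-1]])
    dLam, dHpop = series._dLam, series._dHpop
    if allocation == "proportional":
        dH = dLam + dHpop
        # exact split of Sprev - S = Sprev*(1 - e^{-dH}) in proportion to the
        # cause increments; the factor tends to 1 as dH -> 0, so zero-total
        # intervals still pass their (signed) cause contributions through
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(np.abs(dH) > 1e-12, -np.expm1(-dH) / dH, 1.0)
        F_C = np.cumsum(Sprev * dLam * factor)
        F_O = (1.0 - S) - F_C
    else:
        F_C = np.cumsum(Sprev * dLam)
        F_O = np.cumsum(Sprev * dHpop)
    table = series.table.copy()
    table["F_R_C"] = F_C
    table["F_R_O"] = F_O
    meta = dict(series.metadata, allocation=allocation)
    return replace(series, table=table, metadata=meta)


def variance_ci(series: EstimateSeries, level: float = 0.95) -> EstimateSeries:
    """Append se_/lo_/hi_ columns for every estimated quantity.

    Cumulative-hazard variances accumulate sum_i w_i(s)^2 dN_i(s) / D(s)^2
    with D the weighted number at risk; survival and crude probabilities use
    influence-function (delta-method) propagation.  CIs are log-scale for
    hazards and log(-log)-scale for probabilities, clipped to [0, 1].
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if series._den is None:
        raise EstimationError("variance requires increment internals")
    from scipy.stats import norm  # local import: scipy only needed here

    z = float(norm.ppf(0.5 + level / 2.0))
    table = series.table.copy()
    m = series.times.size
    if m == 0:
        warnings.warn("variance requested on an empty event grid; returning zeros")
        return replace(series, table=table, level=level)

    den = series._den
    c = np.where(den > 0, series._vnum / np.where(den > 0, den, 1.0) ** 2, 0.0)
    cumU = np.cumsum(c)

    def _log_ci(x, se):
        lo = np.zeros_like(x)
        hi = np.zeros_like(x)
        pos = x > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.exp(np.minimum(z * se[pos] / x[pos], 300.0))
        lo[pos] = x[pos] / ratio
        hi[pos] = x[pos] * ratio
        return lo, hi

    def _cloglog_ci(F, se):
        lo = np.zeros_like(F)
        hi = np.zeros_like(F)
        inner = (F > 1e-12) & (F < 1 - 1e-12)
        g = -np.log1p(-F[inner])  # -log(1-F)
        # cap the transformed se: beyond this the interval is [0, 1] anyway
        se_theta = np.minimum(se[inner] / ((1.0 - F[inner]) * g), 30.0)
        lo[inner] = 1.0 - np.exp(-g * np.exp(-z * se_theta))
        hi[inner] = 1.0 - np.exp(-g * np.exp(z * se_theta))
        hi[F >= 1 - 1e-12] = 1.0
        lo[F >= 1 - 1e-12] = F[F >= 1 - 1e-12]
        return np.clip(lo, 0.0, 1.0), np.clip(hi, 0.0, 1.0)

    for col in ("H", "Lambda_R", "H_R"):
        if col in table:
            x = table[col].to_numpy()
            se = np.sqrt(cumU)
            lo, hi = _log_ci(x, se)
            table[f"se_{col}"] = se
            table[f"lo_{col}"], table[f"hi_{col}"] = lo, hi
    if "H_R_pop" in table:
        # expected-rate increments are treated as deterministic
        table["se_H_R_pop"] = 0.0
        table["lo_H_R_pop"] = table["H_R_pop"]
        table["hi_H_R_pop"] = table["H_R_pop"]
    if "S_R" in table:
        S = table["S_R"].to_numpy()
        se = S * np.sqrt(cumU)
        table["se_S_R"] = se
        if "hi_H_R" in table:
            table["lo_S_R"] = np.exp(-table["hi_H_R"].to_numpy())
            table["hi_S_R"] = np.exp(-table["lo_H_R"].to_numpy())
    if "F" in table and "H" in table:
        F = table["F"].to_numpy()
        se = (1.0 - F) * np.sqrt(cumU)
        table["se_F"] = se
        table["lo_F"] = 1.0 - np.exp(-table["lo_H"].to_numpy())
        table["hi_F"] = 1.0 - np.exp(-table["hi_H"].to_numpy())

    if "F_R_C" in table:
        S = table["S_R"].to_numpy()
        Sprev = np.concatenate([[1.0], S[:-1]])
        for col, anchor in (("F_R_C", Sprev), ("F_R_O", np.zeros(m))):
            Fx = table[col].to_numpy()
            # influence of the martingale mass at s on F(t):
            #   [anchor(s) - (F(t) - F(s))] / D(s)
            g = anchor + Fx
            var = (
                np.cumsum(c * g * g)
                - 2.0 * Fx * np.cumsum(c * g)
                + Fx * Fx * cumU
            )
            se = np.sqrt(np.clip(var, 0.0, None))
            lo, hi = _cloglog_ci(Fx, se)
            table[f"se_{col}"] = se
            table[f"lo_{col}"], table[f"hi_{col}"] = lo, hi

    return replace(series, table=table, level=level)


# ---------------------------------------------------------------------------
# high-level driver
# ---------------------------------------------------------------------------

def estimate(
    subjects,
    expected: RateTable | None = None,
    reference: RateTable | None = None,
    *,
    standard: Mapping[str, float] | None = None,
    mode: str = "observed",
    level: float | None = 0.95,
    frozen_reference_year: int | None = None,
    allocation: str = "proportional",
    grid=None,
) -> EstimateSeries:
    """One-call driver: hazards, crude probabilities, variances, merged table.

    With ``grid`` (an :class:`refsurv.grouped_time.IntervalGrid`) the same
    estimands are computed with the grouped-time (lifetable) approximation;
    otherwise in continuous time at the unique event times.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    subjects = list(subjects)
    if grid is not None:
        from .grouped_time import grouped_estimates

        series = grouped_estimates(
            subjects, grid, expected=expected, reference=reference,
            standard=standard, mode=mode,
            frozen_reference_year=frozen_reference_year,
        )
        observed = None if mode == "observed" else grouped_estimates(subjects, grid, mode="observed")
    else:
        if mode == "observed":
            series = all_cause_cumhaz(subjects)
            observed = None
        else:
            series = reference_adjusted_cumhaz(
                subjects, expected, reference, standard=standard, mode=mode,
                frozen_reference_year=frozen_reference_year,
            )
            observed = all_cause_cumhaz(subjects)

    if mode != "observed":
        series = crude_probabilities(series, allocation=allocation)
    if level is not None:
        series = variance_ci(series, level)
        if observed is not None:
            observed = variance_ci(observed, level)
    if observed is not None:
        merged = series.table.join(observed.table, how="left")
        series = replace(series, table=merged)
    return series
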