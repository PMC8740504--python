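"""Synthetic cohorts with known excess hazards and closed-form truths.

The generator draws patients whose all-cause hazard is the sum of a matched
population (expected) rate and a stratum-specific excess rate,
h_i(t) = h*_i(t) + lambda_i(t), exactly the decomposition the estimators
assume.  Event times are drawn by inversion on the merged piecewise-constant
grid (age birthdays, calendar new years, excess-hazard pieces), so sampling
is exact with no rejection step.  Cause-of-death labels are never attached
to the cohort the estimators see — the whole point of the relative-survival
framework is that they are unavailable — but can be requested separately for
debugging.

For specs whose hazards are constant in time (constant excess rates per
stratum and constant expected/reference rates) the estimands have closed
forms, e.g. the crude probability of death due to cancer under other-cause
rate mu:

    F_C(t) = lambda / (lambda + mu) * (1 - exp(-(lambda + mu) t)),

extended piecewise, and marginal truths are mixtures over strata (the
weighting schemes of the estimators are constructed so that their population
limits are exactly these mixtures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Subject
from .ratetable import RateTable, expected_hazard_path

__all__ = [
    "PiecewiseHazard",
    "StratumSpec",
    "SimulationSpec",
    "TruthTable",
    "simulate_cohort",
    "truth",
    "write_cohort_csv",
    "write_ratetable_csv",
    "write_standard_csv",
]


@dataclass(frozen=True)
class PiecewiseHazard:
    """A piecewise-constant hazard: rate ``rates[k]`` on [breaks[k], breaks[k+1]).

    The last rate extends to infinity.
    """

    breaks: tuple
    rates: tuple

    def __post_init__(self):
        b = tuple(float(x) for x in self.breaks)
        r = tuple(float(x) for x in self.rates)
        if len(b) != len(r):
            raise ValueError("breaks and rates must have equal length")
        if b[0] != 0.0:
            raise ValueError("hazard pieces must start at 0")
        if any(x2 <= x1 for x1, x2 in zip(b, b[1:])):
            raise ValueError("breaks must be strictly increasing")
        if any(x < 0 for x in r):
            raise ValueError("rates must be >= 0")
        object.__setattr__(self, "breaks", b)
        object.__setattr__(self, "rates", r)

    @classmethod
    def constant(cls, rate: float) -> "PiecewiseHazard":
        return cls((0.0,), (float(rate),))

    @classmethod
    def from_spec(cls, spec) -> "PiecewiseHazard":
        if isinstance(spec, PiecewiseHazard):
            return spec
        if isinstance(spec, (int, float)):
            return cls.constant(float(spec))
        if isinstance(spec, Mapping):
            return cls(tuple(spec["breaks"]), tuple(spec["rates"]))
        raise ValueError(f"cannot interpret excess-hazard spec {spec!r}")

    def cumhaz(self, t):
        t = np.asarray(t, dtype=float)
        knots = np.array(self.breaks + (max(1e6, float(np.max(t, initial=0.0)) + 1.0),))
        cum = np.concatenate([[0.0], np.cumsum(np.array(self.rates) * np.diff(knots))])
        return np.interp(t, knots, cum)

    def rate_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.breaks, t, side="right")) - 1
        return self.rates[idx]


def _as_table(spec) -> RateTable:
    if isinstance(spec, RateTable):
        return spec
    if isinstance(spec, (int, float)):
        return RateTable.constant(float(spec))
    raise ValueError(f"cannot interpret rate-table spec {spec!r}")


@dataclass
class StratumSpec:
    """One simulated population cell: mixture weight, ages, keys, excess hazard."""

    label: str
    proportion: float
    excess: PiecewiseHazard
    age: tuple = ("fixed", 65.0)  # ("fixed", a) or ("uniform", lo, hi)
    rate_keys: dict = field(default_factory=dict)

    def draw_ages(self, rng: np.random.Generator, size: int) -> np.ndarray:
        kind = self.age[0]
        if kind == "fixed":
            return np.full(size, float(self.age[1]))
        if kind == "uniform":
            return rng.uniform(float(self.age[1]), float(self.age[2]), size)
        raise ValueError(f"unknown age distribution {self.age!r}")


@dataclass
class SimulationSpec:
    """Full description of a synthetic cohort study.

    ``expected`` / ``reference`` may be :class:`RateTable` objects or plain
    floats (constant rate per person-year shorthand).  ``standard`` is the
    external standardisation distribution; when omitted the sample mixture
    doubles as the standard.
    """

    n: int
    strata: list
    expected: object = 0.05
    reference: object = None
    admin_censoring: float = 6.0
    dropout_rate: float = 0.0
    diagnosis_window: tuple = (2008.0, 2013.0)
    standard: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        total = sum(s.proportion for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum proportions sum to {total}, not 1")
        if self.admin_censoring <= 0:
            raise ValueError("administrative censoring horizon must be > 0")

    @property
    def expected_table(self) -> RateTable:
        return _as_table(self.expected)

    @property
    def reference_table(self) -> RateTable | None:
        return None if self.reference is None else _as_table(self.reference)

    @property
    def standard_proportions(self) -> dict:
        if self.standard is not None:
            return dict(self.standard)
        return {s.label: s.proportion for s in self.strata}

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "SimulationSpec":
        strata = []
        for s in cfg["strata"]:
            age = s.get("age", {"fixed": 65.0})
            if isinstance(age, Mapping):
                if "fixed" in age:
                    age_t = ("fixed", float(age["fixed"]))
                elif "uniform" in age:
                    lo, hi = age["uniform"]
                    age_t = ("uniform", float(lo), float(hi))
                else:
                    raise ValueError(f"unknown age spec {age!r}")
            else:
                age_t = ("fixed", float(age))
            strata.append(
                StratumSpec(
                    label=str(s["label"]),
                    proportion=float(s["proportion"]),
                    excess=PiecewiseHazard.from_spec(s.get("excess", 0.0)),
                    age=age_t,
                    rate_keys={k: str(v) for k, v in (s.get("rate_keys") or {}).items()},
                )
            )

        def table_spec(value):
            if value is None:
                return None
            if isinstance(value, Mapping):
                if "constant" in value:
                    return float(value["constant"])
                if "path" in value:
                    from .ratetable import load_ratetable

                    return load_ratetable(value["path"], value.get("schema"))
                raise ValueError(f"unknown rate-table spec {value!r}")
            return float(value)

        return cls(
            n=int(cfg["n"]),
            strata=strata,
            expected=table_spec(cfg.get("expected", 0.05)),
            reference=table_spec(cfg.get("reference")),
            admin_censoring=float(cfg.get("admin_censoring", 6.0)),
            dropout_rate=float(cfg.get("dropout_rate", 0.0)),
            diagnosis_window=tuple(cfg.get("diagnosis_window", (2008.0, 2013.0))),
            standard={str(k): float(v) for k, v in cfg["standard"].items()}
            if cfg.get("standard")
            else None,
            seed=cfg.get("seed"),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def simulate_cohort(
    spec: SimulationSpec,
    seed: int | None = None,
    return_causes: bool = False,
):
    """Draw a cohort from ``spec``; reproducible given the seed.

    Returns the subject list, or ``(subjects, causes)`` with per-subject
    cause labels ("cancer" / "other" / "") when ``return_causes`` is set —
    the labels exist for debugging only and must never feed the estimators.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n
    props = np.array([s.proportion for s in spec.strata])
    stratum_idx = rng.choice(len(spec.strata), size=n, p=props)
    ages = np.empty(n)
    for k, s in enumerate(spec.strata):
        mask = stratum_idx == k
        ages[mask] = s.draw_ages(rng, int(mask.sum()))
    lo, hi = spec.diagnosis_window
    dx_dates = rng.uniform(lo, hi, n)
    E = rng.exponential(size=n)
    if spec.dropout_rate > 0:
        dropout = rng.exponential(1.0 / spec.dropout_rate, n)
    else:
        dropout = np.full(n, np.inf)

    table = spec.expected_table
    horizon = spec.admin_censoring + 1e-6
    subjects: list[Subject] = []
    causes: list[str] = []
    for i in range(n):
        st = spec.strata[stratum_idx[i]]
        proto = Subject(
            id=i, time=1.0, event=0,
            age_at_diagnosis=float(ages[i]), diagnosis_date=float(dx_dates[i]),
            rate_keys=dict(st.rate_keys), standard_stratum=st.label,
        )
        pe = expected_hazard_path(proto, table, horizon)
        lam = st.excess
        knots = np.unique(
            np.concatenate(
                [pe.breakpoints, [b for b in lam.breaks if 0 < b < horizon], [horizon]]
            )
        )
        cum = np.interp(knots, pe.breakpoints, pe.cumulative) + lam.cumhaz(knots)
        if E[i] >= cum[-1]:
            T = np.inf
        else:
            idx = int(np.searchsorted(cum, E[i], side="right"))
            rate = (cum[idx] - cum[idx - 1]) / (knots[idx] - knots[idx - 1])
            T = knots[idx - 1] + (E[i] - cum[idx - 1]) / rate
        cens = min(dropout[i], spec.admin_censoring)
        if T < cens:
            proto.time = float(T)
            proto.event = 1
            if return_causes:
                lam_t = lam.rate_at(T)
                mu_rate = _expected_rate_at(pe, T)  # hazard split at the event time
                p_cancer = lam_t / (lam_t + mu_rate) if (lam_t + mu_rate) > 0 else 0.0
                causes.append("cancer" if rng.uniform() < p_cancer else "other")
        else:
            proto.time = float(cens)
            proto.event = 0
            if return_causes:
                causes.append("")
        subjects.append(proto)
    if return_causes:
        return subjects, causes
    return subjects


def _expected_rate_at(path, t: float) -> float:
    idx = int(np.searchsorted(path.breakpoints, t, side="right")) - 1
    idx = min(idx, len(path.segment_rates) - 1)
    return float(path.segment_rates[idx])


# ---------------------------------------------------------------------------
# closed-form truths
# ---------------------------------------------------------------------------

def _constant_rate(spec_table) -> float:
    if spec_table is None:
        return 0.0
    if isinstance(spec_table, (int, float)):
        return float(spec_table)
    if isinstance(spec_table, RateTable) and spec_table.is_constant:
        return float(spec_table.rates.flat[0])
    raise ValueError(
        "closed-form truths require constant expected/reference rates "
        "(a float or a constant RateTable)"
    )


def _crude_piecewise(lam: PiecewiseHazard, mu: float, t: float, cause: str) -> float:
    """Integral of S(u) x cause-specific rate over [0, t] for piecewise lam, const mu."""
    total = 0.0
    cum = 0.0  # cumulative all-cause hazard at piece start
    breaks = list(lam.breaks) + [math.inf]
    for k, rate in enumerate(lam.rates):
        u0, u1 = breaks[k], min(breaks[k + 1], t)
        if u1 <= u0:
            break
        a = rate + mu
        num = rate if cause == "cancer" else mu
        S0 = math.exp(-cum)
        if a > 0:
            total += S0 * (num / a) * (1.0 - math.exp(-a * (u1 - u0)))
        cum += a * (u1 - u0)
        if breaks[k + 1] >= t:
            break
    return total


@dataclass
class TruthTable:
    """Exact estimand values per stratum and marginal, at requested times."""

    frame: pd.DataFrame  # columns: time, group, quantity, value

    def value(self, group: str, quantity: str, time: float) -> float:
        f = self.frame
        row = f[
            (f["group"] == group)
            & (f["quantity"] == quantity)
            & (np.isclose(f["time"], time))
        ]
        if row.empty:
            raise KeyError(f"no truth value for ({group}, {quantity}, {time})")
        return float(row["value"].iloc[0])


def truth(spec: SimulationSpec, times: Sequence[float]) -> TruthTable:
    """Closed-form estimand truths for piecewise-constant hazards.

    Per stratum: net survival, all-cause survival, and crude probabilities
    under the expected and under the reference other-cause rates.  Marginal
    rows ``sample`` and ``standard`` are mixtures over strata with the sample
    and the standard proportions respectively; the latter are the population
    limits of the standardised, reference-adjusted estimators.
    """
    mu_star = _constant_rate(spec.expected)
    mu_ref = _constant_rate(spec.reference) if spec.reference is not None else mu_star
    times = [float(t) for t in times]
    rows = []

    per_stratum: dict = {}
    for s in spec.strata:
        lam = s.excess
        vals = {}
        for t in times:
            Lam = float(lam.cumhaz(t))
            entry = {
                "net_survival": math.exp(-Lam),
                "all_cause_survival": math.exp(-Lam - mu_star * t),
                "all_cause_survival_reference": math.exp(-Lam - mu_ref * t),
                "crude_cancer": _crude_piecewise(lam, mu_star, t, "cancer"),
                "crude_other": _crude_piecewise(lam, mu_star, t, "other"),
                "crude_cancer_reference": _crude_piecewise(lam, mu_ref, t, "cancer"),
                "crude_other_reference": _crude_piecewise(lam, mu_ref, t, "other"),
            }
            vals[t] = entry
            for q, v in entry.items():
                rows.append((t, s.label, q, v))
        per_stratum[s.label] = vals

    sample_props = {s.label: s.proportion for s in spec.strata}
    mixtures = {"sample": sample_props, "standard": spec.standard_proportions}
    for group, props in mixtures.items():
        total_p = sum(props.values())
        for t in times:
            quantities = next(iter(per_stratum.values()))[t].keys()
            for q in quantities:
                v = sum(p * per_stratum[lab][t][q] for lab, p in props.items()) / total_p
                rows.append((t, group, q, v))

    frame = pd.DataFrame(rows, columns=["time", "group", "quantity", "value"])
    return TruthTable(frame)


# ---------------------------------------------------------------------------
# round-trip writers (the CLI file dialects)
# ---------------------------------------------------------------------------

def write_cohort_csv(subjects: Sequence[Subject], path) -> None:
    key_names = sorted({k for s in subjects for k in s.rate_keys})
    rows = []
    for s in subjects:
        rows.append(
            {
                "id": s.id,
                "time": s.time,
                "event": s.event,
                "age_dx": s.age_at_diagnosis,
                "date_dx": s.diagnosis_date,
                **{k: s.rate_keys.get(k, "") for k in key_names},
                "std_stratum": s.standard_stratum,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ratetable_csv(table: RateTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_standard_csv(standard: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"std_stratum": list(standard), "proportion": list(standard.values())}
    ).to_csv(path, index=False)
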