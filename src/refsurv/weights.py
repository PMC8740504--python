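"""Standardisation and reference weights.

Two weight layers make group comparisons fair:

* time-fixed pre-weights ``w_i^B`` reweight the analysed group's joint
  covariate cells (e.g. age-group x deprivation) to an external standard
  distribution, exactly as in traditional external age standardisation:
  w^B(g) = standard proportion of cell g / sample proportion of cell g;

* a time-dependent factor ``S**_i(t) / S*_i(t)`` — the ratio of the
  subject's expected survival under the reference rates to that under the
  matched rates — keeps the hypothetical population at risk aligned with the
  reference standard as follow-up accrues.

The combined weight is w_i(t) = w_i^B * S**_i(t)/S*_i(t)
= w_i^B * exp(H*_i(t) - H**_i(t)).  Setting S** to 1 (zero reference hazard)
gives the inverse-expected-survival weighting of the Pohar Perme net
estimator; identical tables and no standardisation give w_i(t) = 1.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ratetable import RateTable, expected_hazard_path

__all__ = ["WeightSpec", "WeightError", "standard_weights", "time_weight"]

_SUM_TOL = 1e-9


class WeightError(ValueError):
    """Raised when a standard distribution cannot be applied to a sample."""


@dataclass
class WeightSpec:
    """Time-fixed standardisation weights for one analysed group.

    ``mode`` is ``"none"`` (all w^B = 1) or ``"external"`` (ratio of the
    external standard to the group's own joint covariate-cell shares).
    """

    standard_proportions: dict
    sample_proportions: dict
    mode: str = "external"

    def __post_init__(self):
        if self.mode not in ("none", "external"):
            raise WeightError(f"unknown weight mode {self.mode!r}")
        if self.mode == "external":
            for name, props in (
                ("standard", self.standard_proportions),
                ("sample", self.sample_proportions),
            ):
                total = sum(props.values())
                if abs(total - 1.0) > _SUM_TOL:
                    raise WeightError(f"{name} proportions sum to {total}, not 1")

    def w_B(self, stratum) -> float:
        if self.mode == "none":
            return 1.0
        key = str(stratum)
        if key not in self.sample_proportions:
            raise WeightError(f"stratum {key!r} not present in the analysed sample")
        if key not in self.standard_proportions:
            raise WeightError(
                f"sample stratum {key!r} is absent from the standard distribution; "
                "cannot standardise"
            )
        std = self.standard_proportions[key]
        if std <= 0:
            raise WeightError(
                f"sample stratum {key!r} has zero standard proportion; cannot standardise"
            )
        return std / self.sample_proportions[key]

    @classmethod
    def from_cohort(
        cls,
        subjects: Sequence,
        standard_proportions: Mapping[str, float] | None,
    ) -> "WeightSpec":
        """Build weights from a cohort's own cell shares against a standard.

        Standard cells that are empty in the sample are dropped with a warning
        and the standard is renormalised over the remaining cells.
        """
        labels = [str(s.standard_stratum) for s in subjects]
        if standard_proportions is None:
            counts = Counter(labels)
            sample = {k: v / len(labels) for k, v in counts.items()}
            return cls(dict(sample), sample, mode="none")
        if any(s.standard_stratum is None for s in subjects):
            raise WeightError("some subjects lack a standardisation stratum label")
        counts = Counter(labels)
        sample = {k: v / len(labels) for k, v in counts.items()}

        standard = {str(k): float(v) for k, v in standard_proportions.items()}
        total = sum(standard.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise WeightError(f"standard proportions sum to {total}, not 1")

        missing = sorted(set(sample) - set(standard))
        if missing:
            raise WeightError(
                f"sample strata {missing} are absent from the standard distribution"
            )
        zero_std = sorted(k for k in sample if standard.get(k, 0.0) <= 0)
        if zero_std:
            raise WeightError(
                f"sample strata {zero_std} have zero standard proportion; cannot standardise"
            )
        empty = sorted(set(standard) - set(sample))
        if empty:
            warnings.warn(
                f"standard strata {empty} are empty in the sample; dropping them "
                "and renormalising the standard",
                stacklevel=2,
            )
            standard = {k: v for k, v in standard.items() if k in sample}
            total = sum(standard.values())
            standard = {k: v / total for k, v in standard.items()}
        return cls(standard, sample, mode="external")


def standard_weights(
    subjects: Sequence,
    standard_proportions: Mapping[str, float] | None,
) -> np.ndarray:
    """Per-subject time-fixed weights w_i^B.

    All subjects in a joint covariate cell share one weight, and the weighted
    cell shares reproduce the standard distribution exactly.
    """
    spec = WeightSpec.from_cohort(subjects, standard_proportions)
    return np.array([spec.w_B(s.standard_stratum) for s in subjects], dtype=float)


def time_weight(
    subject,
    t: float,
    expected: RateTable,
    reference: RateTable | None,
    w_B: float = 1.0,
    frozen_reference_year: int | None = None,
) -> float:
    """w_i(t) = w^B * S**_i(t)/S*_i(t) = w^B * exp(H*_i(t) - H**_i(t)).

    ``reference=None`` means zero reference hazard (S** = 1), yielding the
    Pohar Perme inverse-expected-survival weight w^B / S*_i(t).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return float(w_B)
    pe = expected_hazard_path(subject, expected, horizon=t)
    h_star = float(pe.cumhaz(t))
    if reference is None:
        h_ref = 0.0
    else:
        pr = expected_hazard_path(subject, reference, horizon=t, frozen_year=frozen_reference_year)
        h_ref = float(pr.cumhaz(t))
    return float(w_B) * float(np.exp(h_star - h_ref))
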