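"""Closed-form diagnostic accuracy of one and two symptoms.

For a binary rule "symptom present" in a 2x2 population table with
prevalence ``d``, baseline incidence ``ir`` and risk ratio ``rr``:

* sensitivity = min(ir * rr, 1)  (the at-risk incidence)
* specificity = 1 - ir
* AUC of the single binary rule = (sensitivity + specificity) / 2,
  the trapezoid area over the three ROC points.

When the at-risk incidence reaches 1 (ir * rr >= 1, the *capped*
regime) every diseased subject presents the symptom, so sensitivity
and the negative predictive value are both exactly 1.

The two-symptom rules ("both present", "at least one present") follow
the same algebra with the joint rates substituted for (ir, rr).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .measures import EpidemiologicalMeasures, TwoSymptomRates

__all__ = [
    "AccuracyProfile",
    "single_symptom_accuracy",
    "single_symptom_auc",
    "two_symptom_accuracy",
    "expected_overall_incidence",
]


@dataclass(frozen=True)
class AccuracyProfile:
    """Accuracy of one binary symptom rule for detecting the disease.

    ``observed_symptom_odds`` is the population ratio of subjects with
    the symptom pattern to subjects without it. ``ppv`` is NaN when the
    pattern never occurs (zero incidence rule).
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    observed_symptom_odds: float
    auc: float


def _binary_rule_profile(d: float, ir: float, rr: float) -> AccuracyProfile:
    """Accuracy profile of a rule with incidence ``ir`` and risk ratio ``rr``."""
    p1 = min(ir * rr, 1.0)           # incidence among diseased (capped)
    p0 = ir                          # incidence among non-diseased
    present = d * p1 + (1.0 - d) * p0
    absent = d * (1.0 - p1) + (1.0 - d) * (1.0 - p0)
    ppv = d * p1 / present if present > 0.0 else math.nan
    npv = (1.0 - d) * (1.0 - p0) / absent if absent > 0.0 else math.nan
    odds = present / absent if absent > 0.0 else math.inf
    return AccuracyProfile(
        sensitivity=p1,
        specificity=1.0 - p0,
        ppv=ppv,
        npv=npv,
        observed_symptom_odds=odds,
        auc=0.5 * (p1 + 1.0 - p0),
    )


def single_symptom_accuracy(m: EpidemiologicalMeasures) -> AccuracyProfile:
    """Closed-form accuracy of a single symptom for disease diagnosis."""
    return _binary_rule_profile(m.d, m.ir, m.rr)


def single_symptom_auc(m: EpidemiologicalMeasures) -> float:
    """AUC of a single symptom: 0.5 + (min(ir*rr, 1) - ir) / 2.

    Equals (sensitivity + specificity) / 2; 0.5 exactly when rr = 1,
    1 - ir/2 in the capped regime, and below 0.5 when rr < 1 (no
    orientation flip is applied anywhere in this package).
    """
    return 0.5 + 0.5 * (m.at_risk_incidence - m.ir)


def two_symptom_accuracy(
    d: float, rates: TwoSymptomRates
) -> tuple[AccuracyProfile, AccuracyProfile]:
    """Accuracy of the "both symptoms" and "at least one symptom" rules.

    Returns ``(both, at_least_one)`` profiles for prevalence ``d`` and
    the joint rates in ``rates``.
    """
    if not 0.0 < d < 1.0:
        raise ValueError(f"d must be in (0,1), got {d}")
    both = _binary_rule_profile(d, rates.ir_both, rates.rr_both)
    one = _binary_rule_profile(d, rates.ir_one, rates.rr_one)
    return both, one


def expected_overall_incidence(m: EpidemiologicalMeasures) -> float:
    """Population symptom incidence: d*min(ir*rr,1) + (1-d)*ir."""
    return m.d * m.at_risk_incidence + (1.0 - m.d) * m.ir
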