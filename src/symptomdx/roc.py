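"""ROC analysis of symptom counts with a fixed orientation.

Subjects are scored by their symptom count and classified as diseased
when the count meets a half-integer cutpoint k - 0.5 (so "threshold 5.5"
reads as "6 or more symptoms"). The orientation is fixed — cases are
assumed to have the higher counts — and is never flipped: with risk
ratios below 1 the AUC legitimately falls below 0.5 and must be reported
that way.

AUC is the Mann–Whitney probability P(count_case > count_control) +
0.5 * P(tie), which equals the trapezoid area under the empirical ROC.
Confidence intervals use DeLong's structural-components variance with a
normal approximation (the pROC default). The operating point maximizes
the absolute Youden index |sensitivity + specificity - 1|, ties broken
toward the smallest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .simulate import Cohort

__all__ = [
    "CountROC",
    "OperatingPoint",
    "AUCCurve",
    "roc_from_counts",
    "delong_ci",
    "best_operating_point",
    "auc_curve",
]


@dataclass(frozen=True)
class CountROC:
    """ROC over integer-count thresholds k - 0.5, k = 0..K+1."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    n_symptoms_used: int


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    youden_abs: float


@dataclass(frozen=True)
class AUCCurve:
    """AUC, CI and best operating point per number of symptoms used.

    ``extremal_k`` marks the maximal AUC when rr > 1 (or rr = 1) and the
    minimal AUC when rr < 1; ``overlap_flags[i]`` is True when the i-th
    95% CI overlaps the extremal AUC's CI.
    """

    ks: np.ndarray
    aucs: np.ndarray
    ci_lows: np.ndarray
    ci_highs: np.ndarray
    best_points: tuple[OperatingPoint, ...]
    extremal_k: int
    extremal_auc: float
    overlap_flags: np.ndarray
    target: str

    def to_frame(self):
        """Long-format table (k, auc, ci, best point, overlap flag)."""
        import pandas as pd

        return pd.DataFrame({
            "k": self.ks,
            "auc": self.aucs,
            "ci_low": self.ci_lows,
            "ci_high": self.ci_highs,
            "threshold": [bp.threshold for bp in self.best_points],
            "sensitivity": [bp.sensitivity for bp in self.best_points],
            "specificity": [bp.specificity for bp in self.best_points],
            "youden_abs": [bp.youden_abs for bp in self.best_points],
            "overlap": self.overlap_flags,
            "target": self.target,
        })


def _split_counts(counts, labels) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(counts)
    labels = np.asarray(labels)
    if counts.shape != labels.shape or counts.ndim != 1:
        raise ValueError("counts and labels must be 1-D and equally long")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    mask = labels.astype(bool)
    cases, controls = counts[mask], counts[~mask]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be non-empty")
    return cases, controls


def roc_from_counts(counts, labels, n_symptoms: int | None = None) -> CountROC:
    """Empirical count-threshold ROC with Mann–Whitney AUC and DeLong CI.

    ``n_symptoms`` fixes the count range 0..K (defaults to max(counts));
    thresholds are the half-integers k - 0.5 for k = 0..K+1, so the ROC
    endpoints (sens, spec) = (1, 0) and (0, 1) are always present.
    """
    cases, controls = _split_counts(counts, labels)
    k_max = int(max(cases.max(), controls.max()))
    big_k = k_max if n_symptoms is None else int(n_symptoms)
    if k_max > big_k:
        raise ValueError(f"counts exceed n_symptoms={big_k}")
    b1 = np.bincount(cases, minlength=big_k + 1).astype(np.float64)
    b0 = np.bincount(controls, minlength=big_k + 1).astype(np.float64)
    m, n = b1.sum(), b0.sum()
    cdf1 = np.cumsum(b1) / m
    cdf0 = np.cumsum(b0) / n
    thresholds = np.arange(big_k + 2) - 0.5
    # at t = k - 0.5: sens = P(count >= k | case), spec = P(count < k | control)
    sens = np.concatenate(([1.0], 1.0 - cdf1))
    spec = np.concatenate(([0.0], cdf0))
    below = np.concatenate(([0.0], np.cumsum(b0)[:-1]))  # controls strictly below
    auc = float(b1 @ (below + 0.5 * b0) / (m * n))
    ci = delong_ci(counts, labels)
    return CountROC(thresholds=thresholds, sensitivities=sens,
                    specificities=spec, auc=auc, auc_ci=ci,
                    n_symptoms_used=big_k)


def _delong_auc_variance(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """Mann–Whitney AUC and DeLong variance via midranks.

    V10[i] = mean over controls of the tie-credited indicator against
    case i; V01[j] likewise for control j. var(AUC) = S10/m + S01/n.
    """
    m, n = len(cases), len(controls)
    tz = rankdata(np.concatenate([cases, controls]))
    tx = rankdata(cases)
    ty = rankdata(controls)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def delong_ci(counts, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-approximation CI for the AUC, truncated to [0, 1].

    Degenerate (zero-variance) inputs give a zero-width interval at the
    point estimate.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    cases, controls = _split_counts(counts, labels)
    auc, var = _delong_auc_variance(cases, controls)
    if var <= 0.0:
        return auc, auc
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def best_operating_point(roc: CountROC) -> OperatingPoint:
    """Threshold maximizing |sens + spec - 1|; ties -> smallest threshold."""
    j = np.abs(roc.sensitivities + roc.specificities - 1.0)
    i = int(np.argmax(j))  # first maximum = smallest threshold
    return OperatingPoint(threshold=float(roc.thresholds[i]),
                          sensitivity=float(roc.sensitivities[i]),
                          specificity=float(roc.specificities[i]),
                          youden_abs=float(j[i]))


def count_rule_operating_point(
    m, replicates: int = 10, base_seed: int | None = None
) -> OperatingPoint:
    """Best symptom-count operating point estimated over replicate cohorts.

    Simulates ``replicates`` cohorts under the measures ``m`` (all
    ``n_symptoms`` symptoms counted), finds each cohort's best operating
    point, takes the modal best threshold across replicates (ties toward
    the smallest threshold), and returns that threshold with the mean
    sensitivity and specificity evaluated at it. Averaging over
    replicates follows the study design (several simulations per
    parameter combination) and stabilizes the threshold choice when
    adjacent cutpoints have nearly equal Youden index.
    """
    from collections import Counter
    from dataclasses import replace as _replace

    from .simulate import simulate_cohort

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    root = base_seed if base_seed is not None else m.seed
    seeds = np.random.SeedSequence(root).generate_state(replicates) % (2**31)
    rocs = []
    for rep in range(replicates):
        cohort = simulate_cohort(_replace(m, seed=int(seeds[rep])))
        counts = cohort.symptoms.astype(np.int64).sum(axis=1)
        rocs.append(roc_from_counts(counts, cohort.disease,
                                    n_symptoms=m.n_symptoms))
    thresholds = [best_operating_point(r).threshold for r in rocs]
    counter = Counter(thresholds)
    top = max(counter.values())
    t_star = min(t for t, c in counter.items() if c == top)
    idx = int(np.flatnonzero(rocs[0].thresholds == t_star)[0])
    sens = float(np.mean([r.sensitivities[idx] for r in rocs]))
    spec = float(np.mean([r.specificities[idx] for r in rocs]))
    return OperatingPoint(threshold=t_star, sensitivity=sens,
                          specificity=spec, youden_abs=abs(sens + spec - 1.0))


def auc_curve(cohort: Cohort, target: str = "primary") -> AUCCurve:
    """AUC versus number of symptoms used, for either disease label.

    For k = 1..K the score is the row sum over the first k symptom
    columns (under exchangeability any nested subset is distributionally
    equivalent; the first-k choice is deterministic). ``target`` selects
    the label: ``"primary"`` (the symptom-causing disease) or
    ``"associated"`` (the correlated disease that causes no symptoms).
    """
    if target == "primary":
        labels = cohort.disease
    elif target == "associated":
        labels = cohort.associated_disease
    else:
        raise ValueError(f"target must be 'primary' or 'associated', got {target!r}")

    scores = cohort.symptoms.astype(np.int64).cumsum(axis=1)
    big_k = cohort.measures.n_symptoms
    ks = np.arange(1, big_k + 1)
    aucs = np.empty(big_k)
    lows = np.empty(big_k)
    highs = np.empty(big_k)
    bps = []
    for k in ks:
        roc = roc_from_counts(scores[:, k - 1], labels, n_symptoms=int(k))
        aucs[k - 1] = roc.auc
        lows[k - 1], highs[k - 1] = roc.auc_ci
        bps.append(best_operating_point(roc))

    # maximal AUC for rr >= 1, minimal for rr < 1; never reoriented
    ext = int(np.argmin(aucs) if cohort.measures.rr < 1.0 else np.argmax(aucs))
    overlap = (lows <= highs[ext]) & (highs >= lows[ext])
    return AUCCurve(ks=ks, aucs=aucs, ci_lows=lows, ci_highs=highs,
                    best_points=tuple(bps), extremal_k=int(ks[ext]),
                    extremal_auc=float(aucs[ext]), overlap_flags=overlap,
                    target=target)
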