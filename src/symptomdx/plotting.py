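"""Optional matplotlib helpers. CSV tables are the canonical output;
these figures are a convenience, not an analysis surface."""

from __future__ import annotations

import numpy as np

from .roc import AUCCurve, best_operating_point, roc_from_counts
from .simulate import Cohort


def plot_roc_curves(cohort: Cohort, ks=None, ax=None):
    """Overlaid count-threshold ROC curves for 1..K symptoms.

    Best operating points are marked in red, one per curve.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    scores = cohort.symptoms.astype(np.int64).cumsum(axis=1)
    ks = range(1, cohort.measures.n_symptoms + 1) if ks is None else ks
    for k in ks:
        roc = roc_from_counts(scores[:, k - 1], cohort.disease, n_symptoms=k)
        ax.plot(1 - roc.specificities, roc.sensitivities,
                color="0.6", lw=0.8, zorder=1)
        bp = best_operating_point(roc)
        ax.plot(1 - bp.specificity, bp.sensitivity, "o", color="red",
                ms=3, zorder=2)
    ax.plot([0, 1], [0, 1], ls=":", color="0.3", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    return ax


def plot_auc_by_k(curve: AUCCurve, ax=None):
    """AUC against the number of symptoms used, grey where the 95% CI
    overlaps the extremal AUC's CI."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    colors = np.where(curve.overlap_flags, "0.6", "C0")
    ax.scatter(curve.ks, curve.aucs, c=colors, s=12)
    ax.vlines(curve.ks, curve.ci_lows, curve.ci_highs, colors=colors, lw=0.7)
    ax.axhline(0.5, ls=":", color="0.3", lw=0.8)
    ax.set_xlabel("number of symptoms used")
    ax.set_ylabel("AUC")
    return ax
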