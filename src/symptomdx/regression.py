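"""OLS meta-models approximating simulated accuracy outcomes.

Each simulated record's outcome (overall symptom correlation,
single-symptom sensitivity/specificity/AUC, extremal AUC and its best
operating point, associated-disease AUC) is regressed on the assumed
epidemiological measures, stratified by whether the at-risk incidence
reached 1. In the capped stratum the at-risk incidence is constant at 1
and is therefore omitted as a covariate. The observable-measures model
instead regresses per-(record, k) AUCs on the *observed* overall symptom
correlation, overall symptom incidence and the number of symptoms used.

Raw two-sided t p-values and t-based 95% CIs are reported without
multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionSummary", "fit_ols", "reproduce_table", "TABLE_IDS"]

TABLE_IDS = tuple(range(4, 13))

# assumed-measure covariates, in presentation order
_MEASURE_COLS = {
    "disease_correlation": "rho_dd",
    "proportion_diseased": "d",
    "baseline_incidence": "ir",
    "risk_ratio": "rr",
    "at_risk_incidence": "at_risk_incidence",
    "baseline_symptom_correlation": "rho_ss",
}

_TABLE_OUTCOMES = {
    4: ("overall_correlation", "overall symptom correlation"),
    5: ("sens_single", "single-symptom sensitivity"),
    6: ("spec_single", "single-symptom specificity"),
    7: ("auc_single", "single-symptom AUC"),
    8: ("extremal_auc_primary", "extremal AUC, primary disease"),
    9: ("best_sensitivity_primary", "best-set sensitivity, primary disease"),
    10: ("best_specificity_primary", "best-set specificity, primary disease"),
    11: ("extremal_auc_associated", "extremal AUC, associated disease"),
}

_INTERACTION_PAIRS = [
    ("disease_correlation", "proportion_diseased"),
    ("disease_correlation", "baseline_incidence"),
    ("disease_correlation", "risk_ratio"),
    ("disease_correlation", "baseline_symptom_correlation"),
]


@dataclass(frozen=True)
class RegressionSummary:
    """One fitted OLS meta-model with publication-style table contents."""

    outcome: str
    stratum: str
    params: pd.DataFrame  # index: term; columns: coef, ci_low, ci_high, p
    r_squared: float
    adj_r_squared: float
    nobs: int
    dependent_mean: float
    dependent_sd: float
    dependent_median: float
    dependent_min: float
    dependent_max: float
    dropped: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        """Flat CSV-ready block: coefficient rows plus a footer."""
        body = self.params.reset_index(names="term")
        body.insert(0, "stratum", self.stratum)
        body.insert(0, "outcome", self.outcome)
        footer = pd.DataFrame({
            "outcome": self.outcome, "stratum": self.stratum,
            "term": ["adjusted_r_squared", "dependent_mean", "dependent_sd",
                     "dependent_median", "dependent_min", "dependent_max",
                     "n_observations"],
            "coef": [self.adj_r_squared, self.dependent_mean,
                     self.dependent_sd, self.dependent_median,
                     self.dependent_min, self.dependent_max, self.nobs],
        })
        return pd.concat([body, footer], ignore_index=True)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        return path


def _drop_rank_deficient(exog: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop columns that do not increase the design rank."""
    if np.linalg.matrix_rank(exog.to_numpy()) == exog.shape[1]:
        return exog, []
    keep: list[str] = []
    dropped: list[str] = []
    rank = 0
    for col in exog.columns:
        cand = exog[keep + [col]].to_numpy()
        new_rank = np.linalg.matrix_rank(cand)
        if new_rank > rank:
            keep.append(col)
            rank = new_rank
        else:
            dropped.append(col)
    return exog[keep], dropped


def fit_ols(
    y,
    X: pd.DataFrame,
    interactions: list[tuple[str, str]] | None = None,
    outcome: str = "y",
    stratum: str = "all",
) -> RegressionSummary:
    """Ordinary least squares of ``y`` on the named covariates in ``X``.

    ``interactions`` adds product columns named ``"a:b"``. Constant and
    rank-deficient covariates are dropped with a warning naming them,
    never silently. Rows with any NaN are excluded.
    """
    X = X.copy()
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y and X must have the same length")
    for a, b in interactions or []:
        X[f"{a}:{b}"] = X[a] * X[b]

    keep = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    y, X = y[keep], X.loc[keep]

    dropped: list[str] = []
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant covariates: {const}", stacklevel=2)
        dropped += const
        X = X.drop(columns=const)
    X, rank_dropped = _drop_rank_deficient(X)
    if rank_dropped:
        warnings.warn(f"dropping rank-deficient covariates: {rank_dropped}",
                      stacklevel=2)
        dropped += rank_dropped
    if len(y) <= X.shape[1] + 1:
        raise ValueError(
            f"need n > p + 1 observations, got n={len(y)}, p={X.shape[1]}")

    exog = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, exog).fit()
    ci = res.conf_int(alpha=0.05)
    params = pd.DataFrame({
        "coef": res.params, "ci_low": ci[0], "ci_high": ci[1],
        "p": res.pvalues,
    })
    params.index = ["intercept" if t == "const" else t for t in exog.columns]
    return RegressionSummary(
        outcome=outcome, stratum=stratum, params=params,
        r_squared=float(res.rsquared), adj_r_squared=float(res.rsquared_adj),
        nobs=int(res.nobs),
        dependent_mean=float(np.mean(y)), dependent_sd=float(np.std(y, ddof=1)),
        dependent_median=float(np.median(y)),
        dependent_min=float(np.min(y)), dependent_max=float(np.max(y)),
        dropped=tuple(dropped),
    )


def _assumed_covariates(records: pd.DataFrame, with_at_risk: bool) -> pd.DataFrame:
    cols = dict(_MEASURE_COLS)
    if not with_at_risk:
        cols.pop("at_risk_incidence")
    return pd.DataFrame({name: records[src].to_numpy(dtype=float)
                         for name, src in cols.items()},
                        index=records.index)


def reproduce_table(
    table_id: int,
    records: pd.DataFrame,
    auc_by_k: pd.DataFrame | None = None,
) -> dict[str, RegressionSummary]:
    """Fit the meta-model(s) of one results table from the grid records.

    Tables 4-10 regress a per-record outcome on the assumed measures in
    the two at-risk-incidence strata (``uncapped`` / ``capped``); table
    11 adds the disease-correlation interaction terms; table 12 fits the
    observable-measures model on per-(record, k) AUCs in the ``all`` and
    ``rr_gt_1`` strata and requires ``auc_by_k``.
    """
    if table_id not in TABLE_IDS:
        raise ValueError(f"unknown table id {table_id}; expected 4..12")
    ok = records[records["status"] == "ok"]

    if table_id == 12:
        if auc_by_k is None:
            raise ValueError("table 12 requires the per-k AUC table")
        merged = auc_by_k[auc_by_k["target"] == "primary"].merge(
            ok[["record_id", "rr", "overall_correlation", "overall_incidence"]],
            on="record_id", how="inner")
        out: dict[str, RegressionSummary] = {}
        for stratum, sel in (("all", merged),
                             ("rr_gt_1", merged[merged["rr"] > 1.0])):
            X = pd.DataFrame({
                "overall_symptom_correlation": sel["overall_correlation"],
                "overall_symptom_incidence": sel["overall_incidence"],
                "number_of_symptoms": sel["k"].astype(float),
            })
            out[stratum] = fit_ols(sel["auc"], X, outcome="auc_per_k",
                                   stratum=stratum)
        return out

    col, label = _TABLE_OUTCOMES[table_id]
    interactions = _INTERACTION_PAIRS if table_id == 11 else None
    out = {}
    for stratum, capped in (("uncapped", False), ("capped", True)):
        sel = ok[ok["capped"] == capped]
        if sel.empty:
            raise ValueError(f"no records in the {stratum} stratum")
        X = _assumed_covariates(sel, with_at_risk=not capped)
        out[stratum] = fit_ols(sel[col], X, interactions=interactions,
                               outcome=label, stratum=stratum)
    return out
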