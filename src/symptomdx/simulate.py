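"""Cohort simulator: correlated binary diseases and symptoms.

Cohorts mirror the study design: ``n_subjects`` individuals receive a
primary disease status (prevalence ``d``), an associated disease with the
same marginal prevalence correlated with the first at ``rho_dd``, and
``n_symptoms`` exchangeable binary symptoms. Symptom probability is
``min(ir*rr, 1)`` among the diseased and ``ir`` among the non-diseased;
within each disease-status group symptoms share an exchangeable pairwise
correlation ``rho_ss`` and the two groups are generated independently.

Correlated binaries come from latent-Gaussian thresholding with an
equicorrelated one-factor latent structure. The latent correlation is
solved numerically so that the *binary* (phi) correlation of any column
pair equals the requested target: with equal marginals ``p`` the phi
correlation is ``(P11 - p^2) / (p(1-p))`` where ``P11`` is the
equal-threshold bivariate-normal orthant probability, available in
closed form through Owen's T function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri, owens_t

from .measures import EpidemiologicalMeasures

__all__ = [
    "Cohort",
    "CohortSummary",
    "orthant_probability",
    "latent_correlation",
    "correlated_bernoulli",
    "simulate_diseases",
    "simulate_cohort",
    "summarize_cohort",
    "write_cohort",
    "read_cohort",
]


# ---------------------------------------------------------------------------
# latent-correlation machinery


def orthant_probability(z: float, r: float) -> float:
    """P(X < z, Y < z) for standard bivariate normal with correlation r.

    Uses the equal-threshold identity Phi2(z, z; r) = Phi(z) - 2*T(z, a)
    with a = sqrt((1-r)/(1+r)), exact for r in (-1, 1).
    """
    if not -1.0 < r < 1.0:
        raise ValueError(f"correlation must be in (-1,1), got {r}")
    a = np.sqrt((1.0 - r) / (1.0 + r))
    return float(ndtr(z) - 2.0 * owens_t(z, a))


@lru_cache(maxsize=4096)
def latent_correlation(p: float, rho: float) -> float:
    """Latent normal correlation giving phi correlation ``rho`` at marginal ``p``.

    Solves Phi2(z, z; r) = p^2 + rho*p*(1-p) for r, with z the p-quantile
    of the standard normal. With equal marginals the phi correlation
    increases continuously from 0 (r=0) to 1 (r->1), so any target in
    [0, 1) is attainable; the bracket check below guards the numerics.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0,1), got {p}")
    if not 0.0 <= rho < 1.0:
        raise ValueError(
            f"target phi correlation must be in [0,1), got {rho}; "
            "phi = 1 is degenerate (identical columns)")
    if rho == 0.0:
        return 0.0
    z = float(ndtri(p))
    target = p * p + rho * p * (1.0 - p)
    hi = 1.0 - 1e-12
    f = lambda r: orthant_probability(z, r) - target
    if not (f(0.0) < 0.0 < f(hi)):
        max_phi = (orthant_probability(z, hi) - p * p) / (p * (1.0 - p))
        raise ValueError(
            f"phi correlation {rho} unattainable at p={p}; "
            f"feasible range is [0, {max_phi:.6f})")
    return float(brentq(f, 0.0, hi, xtol=1e-13, rtol=8.9e-16))


def correlated_bernoulli(
    n: int, p: float, rho: float, k: int, rng: np.random.Generator
) -> np.ndarray:
    """n x k matrix of Bernoulli(p) columns with pairwise phi correlation rho.

    All column pairs share the same target correlation (exchangeable
    one-factor latent structure); columns are marginally Bernoulli(p).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    r = latent_correlation(p, rho)  # also validates p and rho
    z = ndtri(p)
    if r == 0.0:
        latent = rng.standard_normal((n, k))
    else:
        shared = rng.standard_normal((n, 1))
        latent = np.sqrt(r) * shared + np.sqrt(1.0 - r) * rng.standard_normal((n, k))
    return (latent < z).astype(np.int8)


def simulate_diseases(
    n: int, d: float, rho_dd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Primary and associated disease vectors, both Bernoulli(d), phi = rho_dd."""
    pair = correlated_bernoulli(n, d, rho_dd, 2, rng)
    return pair[:, 0].copy(), pair[:, 1].copy()


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class Cohort:
    """A simulated cohort: disease statuses plus a 0/1 symptom matrix."""

    disease: np.ndarray
    associated_disease: np.ndarray
    symptoms: np.ndarray
    measures: EpidemiologicalMeasures
    seed: int | None

    def __post_init__(self) -> None:
        n, k = self.symptoms.shape
        if n != self.measures.n_subjects or k != self.measures.n_symptoms:
            raise ValueError("symptom matrix shape does not match measures")
        if len(self.disease) != n or len(self.associated_disease) != n:
            raise ValueError("disease vector length does not match measures")


def simulate_cohort(
    m: EpidemiologicalMeasures, rng: np.random.Generator | None = None
) -> Cohort:
    """Simulate one cohort under the measures ``m``.

    Reproducibility: given identical ``m`` (including ``m.seed``) and no
    explicit ``rng``, the cohort is bit-identical. Three deterministic
    sub-streams are spawned from the root seed: diseases, symptoms of the
    diseased, symptoms of the non-diseased.
    """
    if rng is None:
        root = np.random.SeedSequence(m.seed)
        children = [np.random.default_rng(s) for s in root.spawn(3)]
        seed_used = m.seed
    else:
        children = rng.spawn(3)
        seed_used = None
    rng_dis, rng_case, rng_ctrl = children

    disease, associated = simulate_diseases(m.n_subjects, m.d, m.rho_dd, rng_dis)
    is_case = disease.astype(bool)
    n1 = int(is_case.sum())
    n0 = m.n_subjects - n1

    symptoms = np.empty((m.n_subjects, m.n_symptoms), dtype=np.int8)
    p1 = m.at_risk_incidence
    if p1 >= 1.0:
        # cap binds: every diseased subject presents every symptom
        symptoms[is_case] = 1
    else:
        symptoms[is_case] = correlated_bernoulli(n1, p1, m.rho_ss, m.n_symptoms, rng_case)
    symptoms[~is_case] = correlated_bernoulli(n0, m.ir, m.rho_ss, m.n_symptoms, rng_ctrl)

    return Cohort(disease=disease, associated_disease=associated,
                  symptoms=symptoms, measures=m, seed=seed_used)


@dataclass(frozen=True)
class CohortSummary:
    """Empirical counterparts of the assumed epidemiological measures."""

    empirical_prevalence: float
    empirical_baseline_incidence: np.ndarray   # per symptom, non-diseased rows
    mean_baseline_incidence: float
    empirical_at_risk_incidence: np.ndarray    # per symptom, diseased rows
    mean_at_risk_incidence: float
    empirical_risk_ratio: np.ndarray           # per symptom
    mean_risk_ratio: float
    overall_symptom_incidence: float           # grand mean of the matrix
    overall_symptom_correlation: float         # mean off-diagonal phi, everyone
    baseline_symptom_correlation: float        # same, non-diseased only
    disease_phi: float


def _mean_offdiag_corr(x: np.ndarray) -> float:
    """Mean off-diagonal Pearson (phi) correlation of the columns of x."""
    if x.shape[0] < 2 or x.shape[1] < 2:
        return float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x.astype(np.float64), rowvar=False)
    iu = np.triu_indices_from(c, k=1)
    return float(np.nanmean(c[iu]))


def summarize_cohort(c: Cohort) -> CohortSummary:
    """Observable summaries of a cohort; errors if a disease class is empty."""
    is_case = c.disease.astype(bool)
    n1 = int(is_case.sum())
    if n1 == 0 or n1 == len(c.disease):
        raise ValueError(
            "risk ratio undefined: cohort has "
            f"{n1} diseased of {len(c.disease)} subjects")
    base = c.symptoms[~is_case].mean(axis=0)
    risk = c.symptoms[is_case].mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rr_hat = np.where(base > 0, risk / np.where(base > 0, base, np.nan), np.nan)
    with np.errstate(invalid="ignore"):
        dphi = np.corrcoef(c.disease.astype(float),
                           c.associated_disease.astype(float))[0, 1]
    return CohortSummary(
        empirical_prevalence=float(is_case.mean()),
        empirical_baseline_incidence=base,
        mean_baseline_incidence=float(base.mean()),
        empirical_at_risk_incidence=risk,
        mean_at_risk_incidence=float(risk.mean()),
        empirical_risk_ratio=rr_hat,
        mean_risk_ratio=float(np.nanmean(rr_hat)),
        overall_symptom_incidence=float(c.symptoms.mean()),
        overall_symptom_correlation=_mean_offdiag_corr(c.symptoms),
        baseline_symptom_correlation=_mean_offdiag_corr(c.symptoms[~is_case]),
        disease_phi=float(dphi),
    )


# ---------------------------------------------------------------------------
# I/O: flat TSV + JSON sidecar


def _sidecar_path(tsv_path: Path) -> Path:
    return tsv_path.with_suffix(".json")


def write_cohort(c: Cohort, tsv_path: str | Path) -> Path:
    """Write a cohort as TSV (subject_id, disease, associated_disease, s1..sK)
    with a JSON sidecar holding the measures and seed. Returns the TSV path."""
    tsv_path = Path(tsv_path)
    tsv_path.parent.mkdir(parents=True, exist_ok=True)
    k = c.symptoms.shape[1]
    df = pd.DataFrame({"subject_id": np.arange(1, len(c.disease) + 1),
                       "disease": c.disease,
                       "associated_disease": c.associated_disease})
    for j in range(k):
        df[f"s{j + 1}"] = c.symptoms[:, j]
    df.to_csv(tsv_path, sep="\t", index=False)
    meta = {"measures": c.measures.to_dict(), "seed": c.seed}
    _sidecar_path(tsv_path).write_text(json.dumps(meta, indent=2))
    return tsv_path


def read_cohort(tsv_path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    tsv_path = Path(tsv_path)
    meta = json.loads(_sidecar_path(tsv_path).read_text())
    m = EpidemiologicalMeasures.from_dict(meta["measures"])
    df = pd.read_csv(tsv_path, sep="\t")
    sym_cols = [f"s{j + 1}" for j in range(m.n_symptoms)]
    return Cohort(
        disease=df["disease"].to_numpy(np.int8),
        associated_disease=df["associated_disease"].to_numpy(np.int8),
        symptoms=df[sym_cols].to_numpy(np.int8),
        measures=m,
        seed=meta.get("seed"),
    )
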