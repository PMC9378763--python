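"""Epidemiological parameter sets for symptom/disease simulations.

A single configuration couples a primary disease (prevalence ``d``) that
causes symptoms with an associated disease that does not, plus the symptom
generation parameters: baseline incidence ``ir`` among the non-diseased,
risk ratio ``rr`` among the diseased, and exchangeable pairwise
correlations between the two diseases (``rho_dd``) and between symptoms
within a disease-status group (``rho_ss``).

The symptom probability among the diseased, ``ir * rr``, is capped at 1
("at-risk incidence"); configurations where the cap binds form their own
analysis stratum throughout the package.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class EpidemiologicalMeasures:
    """One parameter combination of the simulation study.

    Parameters
    ----------
    d : float
        Proportion of the population with the symptom-causing disease,
        in (0, 1).
    ir : float
        Baseline symptom incidence among the non-diseased, in (0, 1).
    rr : float
        Risk ratio of symptom occurrence among the diseased, > 0. The
        at-risk incidence ``min(ir * rr, 1)`` is capped at 1.
    rho_dd : float
        Phi correlation between the primary and the associated disease,
        in [0, 1).
    rho_ss : float
        Baseline pairwise (phi) correlation between symptoms within a
        disease-status group, in [0, 1).
    n_subjects, n_symptoms : int
        Cohort dimensions.
    seed : int or None
        Root RNG seed for a simulated cohort.
    """

    d: float
    ir: float
    rr: float
    rho_dd: float = 0.0
    rho_ss: float = 0.0
    n_subjects: int = 10_000
    n_symptoms: int = 40
    seed: int | None = None

    def __post_init__(self) -> None:
        _require(0.0 < self.d < 1.0, f"d must be in (0,1), got {self.d}")
        _require(0.0 < self.ir < 1.0, f"ir must be in (0,1), got {self.ir}")
        _require(self.rr > 0.0, f"rr must be > 0, got {self.rr}")
        _require(0.0 <= self.rho_dd < 1.0,
                 f"rho_dd must be in [0,1), got {self.rho_dd}")
        _require(0.0 <= self.rho_ss < 1.0,
                 f"rho_ss must be in [0,1), got {self.rho_ss}")
        _require(int(self.n_subjects) >= 2, "n_subjects must be >= 2")
        _require(int(self.n_symptoms) >= 1, "n_symptoms must be >= 1")

    @property
    def at_risk_incidence(self) -> float:
        """Symptom probability among the diseased, min(ir * rr, 1)."""
        return min(self.ir * self.rr, 1.0)

    @property
    def capped(self) -> bool:
        """True when the at-risk incidence reaches 1 (ir * rr >= 1)."""
        return self.ir * self.rr >= 1.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "EpidemiologicalMeasures":
        return cls(**{k: data[k] for k in
                      ("d", "ir", "rr", "rho_dd", "rho_ss",
                       "n_subjects", "n_symptoms", "seed") if k in data})


@dataclass(frozen=True)
class TwoSymptomRates:
    """Joint occurrence rates for a pair of symptoms.

    ``ir_both``/``rr_both`` describe both symptoms presenting together,
    ``ir_one``/``rr_one`` at least one presenting. These are free inputs
    (or empirical estimates from a cohort): no analytic bridge from the
    pairwise symptom correlation to the joint rates is offered.
    """

    ir_both: float
    rr_both: float
    ir_one: float
    rr_one: float

    def __post_init__(self) -> None:
        _require(0.0 <= self.ir_both <= self.ir_one <= 1.0,
                 "need 0 <= ir_both <= ir_one <= 1, got "
                 f"ir_both={self.ir_both}, ir_one={self.ir_one}")
        _require(self.rr_both > 0.0, f"rr_both must be > 0, got {self.rr_both}")
        _require(self.rr_one > 0.0, f"rr_one must be > 0, got {self.rr_one}")
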