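"""Simulated survival cohorts with a known adipose-score effect.

Patients draw an ADI score from a Beta distribution; overall survival is
exponential with a hazard that steps up by exp(true_log_hr) for patients
above a true ADI cutpoint (the dichotomized-effect world the downstream
stratification assumes). Independent exponential censoring is applied on
top. A continuous effect of ADI on the log hazard is available as an
option but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters for one cohort.

    ``baseline_hazard`` is in events per unit time for the low-ADI group;
    ``censoring_rate`` is the rate of the independent censoring process
    (0 disables censoring). With ``continuous_effect=True`` the hazard is
    baseline * exp(true_log_hr * ADI) instead of a step at
    ``true_cutpoint``.
    """

    n_patients: int
    true_log_hr: float = 0.0
    true_cutpoint: float = 0.25
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.02
    adi_alpha: float = 2.0
    adi_beta: float = 5.0
    continuous_effect: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if not 0 <= self.true_cutpoint <= 1:
            raise ValueError("true_cutpoint must lie in [0, 1]")
        if self.adi_alpha <= 0 or self.adi_beta <= 0:
            raise ValueError("Beta distribution parameters must be > 0")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort as a patient table.

    Returns a DataFrame with columns ``patient_id``, ``adi``, ``time``,
    ``event``, ``true_group`` (high/low by the true cutpoint), plus
    nuisance covariates ``sex`` and ``bmi`` for plumbing tests. Event
    times are Exponential with the per-patient hazard; observed time is
    min(event, censoring) and ``event`` flags whether death was observed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0xC0C0, spec.seed & 0x7FFFFFFF]))
    n = spec.n_patients
    adi = rng.beta(spec.adi_alpha, spec.adi_beta, size=n)

    if spec.continuous_effect:
        log_rel = spec.true_log_hr * adi
    else:
        log_rel = spec.true_log_hr * (adi > spec.true_cutpoint)
    hazard = spec.baseline_hazard * np.exp(log_rel)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)

    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "adi": adi,
            "time": time,
            "event": event,
            "true_group": np.where(adi > spec.true_cutpoint, "high", "low"),
            "sex": rng.choice(["F", "M"], size=n),
            "bmi": np.round(rng.normal(25.0, 4.0, size=n), 1),
        }
    )
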