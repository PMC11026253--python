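"""Cohort-level feature-table generator.

Generates a long-format table — one row per patient × location × pacing
frequency, with all clinical covariates and all seven AP shape properties —
from a linear mixed-effects generating model with a per-patient random
intercept:

    y = intercept + Σ coefficient × covariate + b_patient + ε,
    b_patient ~ N(0, patient_sd²),  ε ~ N(0, residual_sd²)

The default coefficients and covariate prevalences emulate a published
congenital-heart-disease cohort (25 patients, 22 tetralogy of Fallot / 3
atrial septal defect) so that parameter-recovery simulations have realistic
truth values.  Categorical covariates use treatment coding with reference
levels ASD, unrepaired, acyanotic, mild RV–PA gradient, no beta blocker,
none/mild proBNP, and no clinical arrhythmia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortGeneratingModel",
    "generate_cohort",
    "COVARIATES",
    "DEPENDENTS",
    "DEFAULT_FIXED_EFFECTS",
    "DEFAULT_PREVALENCES",
]

DEPENDENTS = ("RMP", "APA", "dVdt_max", "APD20", "APD50", "APD90", "AUC90")

#: covariates of the AP mixed models, in reporting order
COVARIATES = (
    "stim_frequency",
    "disease_type",            # 1 = TOF, 0 = ASD
    "repair_status",           # 1 = repaired (with prolonged QRS)
    "age",                     # years
    "cyanosis",
    "rvpa_moderate",           # RV–PA gradient dummies vs reference "mild"
    "rvpa_severe",
    "probnp_severe",
    "beta_blocker",
    "clinical_arrhythmia",
    "tissue_arrhythmia",
    "impaired_apd_shortening",
    "apd_alternans",
)

#: default generating coefficients per dependent variable (units of that
#: dependent: mV, V/s, ms, or mV*s); "Intercept" is the reference-level mean
DEFAULT_FIXED_EFFECTS: dict[str, dict[str, float]] = {
    "RMP": {
        "Intercept": -73.40, "stim_frequency": 0.38, "disease_type": -3.98,
        "repair_status": 0.11, "age": 0.10, "cyanosis": 1.81,
        "rvpa_moderate": 1.35, "rvpa_severe": 0.48, "probnp_severe": -0.72,
        "beta_blocker": -1.63, "clinical_arrhythmia": 0.30,
        "tissue_arrhythmia": 0.78, "impaired_apd_shortening": -0.59,
        "apd_alternans": 1.05,
    },
    "APA": {
        "Intercept": 82.87, "stim_frequency": -1.38, "disease_type": 5.06,
        "repair_status": -0.57, "age": 0.01, "cyanosis": -4.17,
        "rvpa_moderate": 13.38, "rvpa_severe": 5.36, "probnp_severe": 3.78,
        "beta_blocker": 6.05, "clinical_arrhythmia": -1.81,
        "tissue_arrhythmia": 5.11, "impaired_apd_shortening": 2.42,
        "apd_alternans": 2.35,
    },
    "dVdt_max": {
        "Intercept": 124.16, "stim_frequency": -15.85, "disease_type": 17.89,
        "repair_status": 76.90, "age": -1.59, "cyanosis": -31.32,
        "rvpa_moderate": 36.16, "rvpa_severe": 2.27, "probnp_severe": 11.88,
        "beta_blocker": 29.94, "clinical_arrhythmia": 27.32,
        "tissue_arrhythmia": 15.28, "impaired_apd_shortening": -34.58,
        "apd_alternans": 10.71,
    },
    "APD20": {
        "Intercept": 112.16, "stim_frequency": -22.78, "disease_type": -5.02,
        "repair_status": -59.93, "age": 1.50, "cyanosis": 2.00,
        "rvpa_moderate": -21.60, "rvpa_severe": -10.88, "probnp_severe": 23.42,
        "beta_blocker": 8.87, "clinical_arrhythmia": -12.22,
        "tissue_arrhythmia": 27.92, "impaired_apd_shortening": 52.68,
        "apd_alternans": 28.82,
    },
    "APD50": {
        "Intercept": 157.43, "stim_frequency": -37.32, "disease_type": 29.16,
        "repair_status": -31.86, "age": 1.56, "cyanosis": 21.05,
        "rvpa_moderate": 12.26, "rvpa_severe": 20.47, "probnp_severe": 26.36,
        "beta_blocker": 25.18, "clinical_arrhythmia": -29.27,
        "tissue_arrhythmia": 43.80, "impaired_apd_shortening": 93.51,
        "apd_alternans": 6.67,
    },
    "APD90": {
        "Intercept": 217.62, "stim_frequency": -41.46, "disease_type": 37.08,
        "repair_status": 12.30, "age": 0.98, "cyanosis": 41.21,
        "rvpa_moderate": 41.16, "rvpa_severe": 45.84, "probnp_severe": 16.37,
        "beta_blocker": 31.39, "clinical_arrhythmia": -56.37,
        "tissue_arrhythmia": 41.41, "impaired_apd_shortening": 127.82,
        "apd_alternans": -24.15,
    },
    "AUC90": {
        "Intercept": 11.86, "stim_frequency": -3.22, "disease_type": 3.49,
        "repair_status": -2.74, "age": 0.16, "cyanosis": 1.15,
        "rvpa_moderate": 3.51, "rvpa_severe": 2.73, "probnp_severe": 2.80,
        "beta_blocker": 3.13, "clinical_arrhythmia": -2.80,
        "tissue_arrhythmia": 4.52, "impaired_apd_shortening": 8.17,
        "apd_alternans": 0.42,
    },
}

#: marginal prevalences of the binary / categorical covariates (cohort of 25)
DEFAULT_PREVALENCES: dict[str, float] = {
    "disease_type": 22 / 25,
    "repair_status": 6 / 25,
    "cyanosis": 9 / 25,
    "rvpa_moderate": 2 / 25,
    "rvpa_severe": 11 / 25,
    "probnp_severe": 12 / 25,
    "beta_blocker": 9 / 25,
    "clinical_arrhythmia": 6 / 25,
    "tissue_arrhythmia": 13 / 25,
    "impaired_apd_shortening": 6 / 25,
    "apd_alternans": 12 / 25,
}

#: between-patient (random intercept) and within-patient residual SDs per
#: dependent — chosen as realistic inter-individual spreads on each scale
DEFAULT_PATIENT_SD: dict[str, float] = {
    "RMP": 3.0, "APA": 6.0, "dVdt_max": 30.0,
    "APD20": 20.0, "APD50": 25.0, "APD90": 30.0, "AUC90": 2.0,
}
DEFAULT_RESIDUAL_SD: dict[str, float] = {
    "RMP": 2.0, "APA": 4.0, "dVdt_max": 20.0,
    "APD20": 12.0, "APD50": 15.0, "APD90": 18.0, "AUC90": 1.2,
}


@dataclass
class CohortGeneratingModel:
    """Generating truth of the cohort feature table.

    ``fixed_effects`` maps each dependent variable to a coefficient map
    (including ``"Intercept"``); ``patient_sd`` / ``residual_sd`` give the
    random-intercept and residual standard deviations per dependent;
    ``covariate_frequencies`` the marginal prevalences of the categorical
    covariates.  Age (years) is drawn log-normally to mimic a cohort mixing
    infants undergoing primary repair with adults re-operated decades later.
    """

    fixed_effects: dict = field(default_factory=lambda: {
        d: dict(c) for d, c in DEFAULT_FIXED_EFFECTS.items()
    })
    patient_sd: dict = field(default_factory=lambda: dict(DEFAULT_PATIENT_SD))
    residual_sd: dict = field(default_factory=lambda: dict(DEFAULT_RESIDUAL_SD))
    covariate_frequencies: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    age_log_median_years: float = 2.5
    age_log_sigma: float = 1.4
    age_range_years: tuple = (0.33, 56.0)

    def __post_init__(self) -> None:
        for dep, coeffs in self.fixed_effects.items():
            if dep not in DEPENDENTS:
                raise ValueError(f"unknown dependent variable {dep!r}")
            for name in coeffs:
                if name != "Intercept" and name not in COVARIATES:
                    raise ValueError(f"unknown covariate in fixed_effects: {name!r}")
        for dep in self.fixed_effects:
            if self.patient_sd.get(dep, 0.0) < 0:
                raise ValueError("patient_sd must be >= 0")
            if self.residual_sd.get(dep, 1.0) < 0:
                raise ValueError("residual_sd must be >= 0")
        for name in self.covariate_frequencies:
            if name not in COVARIATES:
                raise ValueError(f"unknown covariate in covariate_frequencies: {name!r}")

    @classmethod
    def null(cls, keep_intercepts: bool = True) -> "CohortGeneratingModel":
        """All-null model: every coefficient zero (intercepts optionally kept)."""
        fx = {
            d: {
                k: (v if (k == "Intercept" and keep_intercepts) else 0.0)
                for k, v in c.items()
            }
            for d, c in DEFAULT_FIXED_EFFECTS.items()
        }
        return cls(fixed_effects=fx)


def _sample_covariates(
    model: CohortGeneratingModel, n_patients: int, rng: np.random.Generator
) -> pd.DataFrame:
    p = model.covariate_frequencies
    cov = pd.DataFrame(index=range(n_patients))
    # RV–PA gradient is a 3-level categorical sampled jointly
    p_mod = p.get("rvpa_moderate", 0.0)
    p_sev = p.get("rvpa_severe", 0.0)
    grad = rng.choice(3, size=n_patients, p=[1 - p_mod - p_sev, p_mod, p_sev])
    cov["rvpa_moderate"] = (grad == 1).astype(float)
    cov["rvpa_severe"] = (grad == 2).astype(float)
    for name in COVARIATES:
        if name in ("stim_frequency", "age", "rvpa_moderate", "rvpa_severe"):
            continue
        cov[name] = rng.binomial(1, p.get(name, 0.0), size=n_patients).astype(float)
    age = model.age_log_median_years * np.exp(
        rng.normal(0.0, model.age_log_sigma, size=n_patients)
    )
    cov["age"] = np.clip(age, *model.age_range_years)
    return cov


def generate_cohort(
    model: CohortGeneratingModel | None = None,
    n_patients: int = 25,
    locations_per_patient: int = 3,
    freqs=(0.5, 1.0, 2.0, 3.0, 4.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the long-format feature table and the true random intercepts.

    Returns ``(table, intercepts)``: one table row per patient × location ×
    frequency with all covariates and all dependents, and one intercepts row
    per patient per dependent (columns = dependents).
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    model = model or CohortGeneratingModel()
    rng = np.random.default_rng(seed)

    cov = _sample_covariates(model, n_patients, rng)
    intercepts = pd.DataFrame(
        {
            dep: rng.normal(0.0, model.patient_sd.get(dep, 0.0), size=n_patients)
            for dep in model.fixed_effects
        },
        index=[f"P{i:03d}" for i in range(n_patients)],
    )
    intercepts.index.name = "patient_id"

    rows = []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        for loc in range(locations_per_patient):
            for f in freqs:
                row = {
                    "patient_id": pid,
                    "location_id": f"L{loc}",
                    "stim_frequency": float(f),
                }
                row.update({c: float(cov.loc[i, c]) for c in cov.columns})
                rows.append(row)
    table = pd.DataFrame(rows)

    for dep, coeffs in model.fixed_effects.items():
        lin = np.full(len(table), coeffs.get("Intercept", 0.0))
        for name, beta in coeffs.items():
            if name == "Intercept":
                continue
            lin = lin + beta * table[name].to_numpy()
        b = intercepts[dep].reindex(table["patient_id"]).to_numpy()
        eps = rng.normal(0.0, model.residual_sd.get(dep, 0.0), size=len(table))
        table[dep] = lin + b + eps
    return table, intercepts
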