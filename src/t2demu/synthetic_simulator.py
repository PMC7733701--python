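"""Synthetic stand-in for the expensive whole-body T2D simulator.

The real multi-scale simulator maps a subject's initial condition x to the
6-month outcome vector y = (BMI, fasting glucose baseline GBL, adipose
TNF-alpha) but takes hours per trajectory.  This module provides an explicit,
configurable response surface y = psi*(x) + eps with the statistical features
the downstream analyses rely on:

* nonlinearity in baseline BMI (hinge terms with knees at 25 and 22 kg/m^2);
* dominant BMI0 / carbohydrate / age effects, smaller sex / protein / fat
  effects and deliberately weak physical-activity effects;
* switch-like "risk escalation" interactions (high BMI0 x high-carbohydrate
  diet x older age raises fasting glucose; high BMI0 x older age raises
  TNF-alpha), emulating the threshold behaviour of metabolic/inflammatory
  dynamics that no low-order polynomial in the predictors can represent;
* trivariate Gaussian residual noise with a configurable covariance.

Energy balance enters through E = intake/TDEE - 1, the fractional caloric
surplus of the subject's diet over their expenditure; the exercise pattern is
summarised by the weekly activity dose N * D * (I/100) / 60 (hours per week
weighted by relative intensity).  Everything is deterministic given the
parameters and a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_design import (
    AnthropometricProfile,
    SubjectSpec,
    assign_anthropometrics,
    design_table,
)
from .energy_model import (
    LEVEL_MULTIPLIERS,
    apply_intake_levels,
    compute_energy_budget,
    plan_reference_meals,
    total_intake_kcal,
)

__all__ = [
    "OUTCOME_NAMES",
    "OutcomeVector",
    "ResponseSurfaceParams",
    "activity_dose",
    "energy_imbalance",
    "evaluate_response_surface",
    "simulate_outcomes",
    "generate_dataset",
]

OUTCOME_NAMES = ("bmi6", "gbl6", "tnf6")


@dataclass(frozen=True)
class OutcomeVector:
    """Outcome triple at the fixed 6-month horizon."""

    bmi6: float   # kg/m^2
    gbl6: float   # mg/dL, fasting glucose baseline
    tnf6: float   # arbitrary concentration units, adipose TNF-alpha

    def as_array(self) -> np.ndarray:
        return np.array([self.bmi6, self.gbl6, self.tnf6])


def _default_sigma() -> list[list[float]]:
    sds = np.array([0.3, 4.0, 0.3])
    corr = np.full((3, 3), 0.3)
    np.fill_diagonal(corr, 1.0)
    return (corr * np.outer(sds, sds)).tolist()


@dataclass(frozen=True)
class ResponseSurfaceParams:
    """Coefficients of the synthetic response surface and residual covariance.

    Sex contrasts are centred (male = +1/2, female = -1/2).  Setting every
    effect coefficient to zero leaves the baselines (bmi0, 85 mg/dL, 2 units).
    """

    # --- BMI at 6 months ---
    bmi_energy: float = 0.25        # fractional BMI response per unit E
    bmi_activity: float = -0.02     # kg/m^2 per unit weekly activity dose
    bmi_age: float = 0.015          # kg/m^2 per year from age 48
    bmi_sex: float = 0.3            # male - female contrast, kg/m^2
    # --- fasting glucose baseline ---
    gbl_baseline: float = 85.0      # mg/dL
    gbl_bmi0: float = 3.5           # mg/dL per (bmi0 - knee)^1.5
    gbl_bmi0_knee: float = 25.0     # kg/m^2
    gbl_carb: float = 12.0          # mg/dL per unit carb multiplier above 1
    gbl_age: float = 0.08           # mg/dL per year from age 28
    gbl_protein: float = 2.0        # mg/dL per unit protein multiplier above 1
    gbl_fat: float = 2.0            # mg/dL per unit fat multiplier above 1
    gbl_sex: float = -1.0           # male - female contrast, mg/dL
    gbl_activity: float = -0.5      # mg/dL per unit weekly activity dose
    gbl_escalation: float = 25.0    # mg/dL jump: bmi0>25 & high carb & age>=48
    # --- adipose TNF-alpha ---
    tnf_baseline: float = 2.0
    tnf_age: float = 0.05           # units per year of age
    tnf_carb: float = 1.5           # units per unit carb multiplier above 1
    tnf_bmi0: float = 0.12          # units per kg/m^2 above the knee
    tnf_bmi0_knee: float = 22.0     # kg/m^2
    tnf_protein: float = 0.3
    tnf_fat: float = 0.3
    tnf_sex: float = 0.1            # male - female contrast
    tnf_activity: float = -0.05     # units per unit weekly activity dose
    tnf_escalation: float = 0.9     # units jump: bmi0>25 & age>=48
    # --- residual covariance (3x3, symmetric PSD) ---
    sigma: list[list[float]] = field(default_factory=_default_sigma)

    def sigma_array(self) -> np.ndarray:
        s = np.asarray(self.sigma, dtype=float)
        if s.shape != (3, 3):
            raise ValueError("sigma must be 3x3")
        return s

    def validate_sigma(self) -> np.ndarray:
        s = self.sigma_array()
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        w = np.linalg.eigvalsh(s)
        if w.min() < -1e-10:
            raise ValueError("sigma must be positive semidefinite")
        return s

    def zero_effects(self) -> "ResponseSurfaceParams":
        """Copy with every effect coefficient zeroed (baseline-only surface)."""
        zeroed = {
            name: 0.0
            for name in (
                "bmi_energy", "bmi_activity", "bmi_age", "bmi_sex",
                "gbl_bmi0", "gbl_carb", "gbl_age", "gbl_protein", "gbl_fat",
                "gbl_sex", "gbl_activity", "gbl_escalation",
                "tnf_age", "tnf_carb", "tnf_bmi0", "tnf_protein", "tnf_fat",
                "tnf_sex", "tnf_activity", "tnf_escalation",
            )
        }
        return replace(self, **zeroed)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ResponseSurfaceParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def activity_dose(spec: SubjectSpec) -> float:
    """Weekly exercise dose: sessions x duration x relative intensity, in
    intensity-weighted hours per week.  Zero for sedentary subjects."""
    if spec.sessions_per_week == 0:
        return 0.0
    return (
        spec.sessions_per_week
        * spec.session_duration
        * (spec.session_intensity / 100.0)
        / 60.0
    )


def energy_imbalance(spec: SubjectSpec, profile: AnthropometricProfile) -> float:
    """Fractional caloric surplus E = intake/TDEE - 1 of the subject's diet.

    Computed through the actual meal plan, so E reduces to
    ``0.5 (cm-1) + 0.2 (pm-1) + 0.3 (fm-1)`` in the level multipliers.
    """
    budget = compute_energy_budget(spec, profile)
    plan = apply_intake_levels(
        plan_reference_meals(budget),
        spec.carb_level,
        spec.protein_level,
        spec.fat_level,
    )
    return total_intake_kcal(plan) / budget.tdee - 1.0


def evaluate_response_surface(
    spec: SubjectSpec,
    profile: AnthropometricProfile,
    params: ResponseSurfaceParams | None = None,
) -> OutcomeVector:
    """Noise-free surface value psi*(x) for one subject.  Deterministic."""
    p = params if params is not None else ResponseSurfaceParams()
    bmi0 = profile.bmi0
    e = energy_imbalance(spec, profile)
    act = activity_dose(spec)
    sex_c = (1.0 if spec.sex == "male" else 0.0) - 0.5
    cm = LEVEL_MULTIPLIERS[spec.carb_level]
    pm = LEVEL_MULTIPLIERS[spec.protein_level]
    fm = LEVEL_MULTIPLIERS[spec.fat_level]
    high_bmi0 = 1.0 if bmi0 > 25.0 else 0.0
    high_carb = 1.0 if cm > 1.2 else 0.0
    older = 1.0 if spec.age >= 48 else 0.0

    bmi6 = (
        bmi0 * (1.0 + p.bmi_energy * e)
        + p.bmi_activity * act
        + p.bmi_age * (spec.age - 48.0)
        + p.bmi_sex * sex_c
    )
    gbl6 = (
        p.gbl_baseline
        + p.gbl_bmi0 * max(0.0, bmi0 - p.gbl_bmi0_knee) ** 1.5
        + p.gbl_carb * (cm - 1.0)
        + p.gbl_age * (spec.age - 28.0)
        + p.gbl_protein * (pm - 1.0)
        + p.gbl_fat * (fm - 1.0)
        + p.gbl_sex * sex_c
        + p.gbl_activity * act
        + p.gbl_escalation * high_bmi0 * high_carb * older
    )
    tnf6 = (
        p.tnf_baseline
        + p.tnf_age * spec.age
        + p.tnf_carb * (cm - 1.0)
        + p.tnf_bmi0 * max(0.0, bmi0 - p.tnf_bmi0_knee)
        + p.tnf_protein * (pm - 1.0)
        + p.tnf_fat * (fm - 1.0)
        + p.tnf_sex * sex_c
        + p.tnf_activity * act
        + p.tnf_escalation * high_bmi0 * older
    )
    return OutcomeVector(bmi6=bmi6, gbl6=gbl6, tnf6=tnf6)


def _noise_transform(sigma: np.ndarray) -> np.ndarray:
    """Matrix A with A @ A.T == sigma; exact zero for sigma == 0."""
    w, v = np.linalg.eigh(sigma)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_outcomes(
    spec: SubjectSpec,
    profile: AnthropometricProfile,
    params: ResponseSurfaceParams | None = None,
    rng: np.random.Generator | None = None,
) -> OutcomeVector:
    """Surface value plus one trivariate Gaussian residual draw."""
    p = params if params is not None else ResponseSurfaceParams()
    sigma = p.validate_sigma()
    rng = np.random.default_rng() if rng is None else rng
    mean = evaluate_response_surface(spec, profile, p).as_array()
    noise = _noise_transform(sigma) @ rng.standard_normal(3)
    y = mean + noise
    return OutcomeVector(bmi6=float(y[0]), gbl6=float(y[1]), tnf6=float(y[2]))


def generate_dataset(
    specs,
    params: ResponseSurfaceParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one outcome row per subject specification.

    Returns the design table (categorical factors plus decoded
    anthropometrics) augmented with the three outcome columns.  A single RNG
    stream seeded with ``seed`` draws the residuals in design order, so the
    table is reproducible row for row.
    """
    specs = list(specs)
    p = params if params is not None else ResponseSurfaceParams()
    sigma = p.validate_sigma()
    rng = np.random.default_rng(seed)

    df = design_table(specs)
    surface = np.empty((len(specs), 3))
    for k, spec in enumerate(specs):
        profile = assign_anthropometrics(spec)
        surface[k] = evaluate_response_surface(spec, profile, p).as_array()
    noise = rng.standard_normal((len(specs), 3)) @ _noise_transform(sigma).T
    y = surface + noise
    for j, name in enumerate(OUTCOME_NAMES):
        df[name] = y[:, j]
    return df
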