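"""Energy budget and meal planning for the dietary design factors.

Total daily energy expenditure (TDEE) is decomposed into resting energy
expenditure (REE, Mifflin-St Jeor), activity energy expenditure (AEE, a
VO2-based fixture) and the thermic effect of food (TEF, 10% of balanced
intake).  The TDEE defines the reference ("med") diet: calories are split
25/45/30% over breakfast/lunch/dinner, each meal 50/20/30% over
carbohydrate/protein/fat calories, and converted to grams with the Atwater
general factors (4/4/9 kcal/g).  The low/high diet levels scale the
reference grams by 0.8 and 1.5.

TEF is defined as 10% of *intake*, which at caloric balance equals TDEE;
the circular definition TDEE = REE + AEE + 0.10 * TDEE is resolved in closed
form as TDEE = (REE + AEE) / 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort_design import AnthropometricProfile, SubjectSpec

__all__ = [
    "MEAL_FRACTIONS",
    "MACRO_FRACTIONS",
    "ATWATER_KCAL_PER_G",
    "LEVEL_MULTIPLIERS",
    "TEF_FRACTION",
    "KCAL_PER_LITRE_O2",
    "EnergyBudget",
    "Meal",
    "MealPlan",
    "vo2max_relative",
    "compute_ree",
    "compute_aee",
    "compute_energy_budget",
    "plan_reference_meals",
    "apply_intake_levels",
    "total_intake_kcal",
]

#: Share of TDEE eaten at each meal.
MEAL_FRACTIONS = {"breakfast": 0.25, "lunch": 0.45, "dinner": 0.30}
#: Share of each meal's calories per macronutrient.
MACRO_FRACTIONS = {"carb": 0.50, "protein": 0.20, "fat": 0.30}
#: Atwater general factor system, kcal per gram.
ATWATER_KCAL_PER_G = {"carb": 4.0, "protein": 4.0, "fat": 9.0}
#: Gram multipliers for the three diet levels.
LEVEL_MULTIPLIERS = {"low": 0.8, "med": 1.0, "high": 1.5}
#: Thermic effect of food as a fraction of intake.
TEF_FRACTION = 0.10
#: Energy equivalent of oxygen, kcal per litre O2 consumed.
KCAL_PER_LITRE_O2 = 5.0

# VO2max fixture: relative VO2max (mL O2 / kg / min) declines 0.30 per year
# from a sex-specific value at age 20, floored at 20.
_VO2MAX_AT_20 = {"male": 50.0, "female": 42.0}
_VO2MAX_DECLINE_PER_YEAR = 0.30
_VO2MAX_FLOOR = 20.0


@dataclass(frozen=True)
class EnergyBudget:
    """Daily energy expenditure decomposition, kcal/day."""

    ree: float
    aee: float
    tef: float
    tdee: float


@dataclass(frozen=True)
class Meal:
    """One meal at some diet level: total calories and macronutrient grams."""

    calories: float
    carb_g: float
    protein_g: float
    fat_g: float


@dataclass(frozen=True)
class MealPlan:
    breakfast: Meal
    lunch: Meal
    dinner: Meal

    @property
    def meals(self) -> dict[str, Meal]:
        return {"breakfast": self.breakfast, "lunch": self.lunch, "dinner": self.dinner}


def vo2max_relative(sex: str, age: float) -> float:
    """Relative VO2max (mL/kg/min) for the fixture decline model."""
    return max(
        _VO2MAX_FLOOR, _VO2MAX_AT_20[sex] - _VO2MAX_DECLINE_PER_YEAR * (age - 20.0)
    )


def compute_ree(sex: str, age: float, weight: float, height: float) -> float:
    """Resting energy expenditure (kcal/day), Mifflin-St Jeor.

    ``10 w[kg] + 6.25 h[cm] - 5 age[y] + (+5 male | -161 female)``.
    """
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    sex_term = 5.0 if sex == "male" else -161.0
    return 10.0 * weight + 6.25 * (height * 100.0) - 5.0 * age + sex_term


def compute_aee(spec: SubjectSpec, profile: AnthropometricProfile) -> float:
    """Daily activity energy expenditure (kcal/day) of the exercise pattern.

    Oxygen uptake at the prescribed intensity is
    ``VO2max_rel(sex, age) * (intensity/100) * weight / 1000`` L/min; each
    litre of O2 costs 5 kcal; sessions are averaged over the week.  Zero for
    sedentary subjects.
    """
    if spec.sessions_per_week == 0:
        return 0.0
    vo2_l_per_min = (
        vo2max_relative(spec.sex, spec.age)
        * (spec.session_intensity / 100.0)
        * profile.weight
        / 1000.0
    )
    kcal_per_session = KCAL_PER_LITRE_O2 * vo2_l_per_min * spec.session_duration
    return spec.sessions_per_week / 7.0 * kcal_per_session


def compute_energy_budget(
    spec: SubjectSpec, profile: AnthropometricProfile
) -> EnergyBudget:
    """TDEE = (REE + AEE) / (1 - TEF fraction), with TEF = 10% of intake."""
    ree = compute_ree(spec.sex, spec.age, profile.weight, profile.height)
    aee = compute_aee(spec, profile)
    tdee = (ree + aee) / (1.0 - TEF_FRACTION)
    tef = tdee - ree - aee  # == TEF_FRACTION * tdee, identity exact
    return EnergyBudget(ree=ree, aee=aee, tef=tef, tdee=tdee)


def _reference_meal(calories: float) -> Meal:
    return Meal(
        calories=calories,
        carb_g=MACRO_FRACTIONS["carb"] * calories / ATWATER_KCAL_PER_G["carb"],
        protein_g=MACRO_FRACTIONS["protein"] * calories / ATWATER_KCAL_PER_G["protein"],
        fat_g=MACRO_FRACTIONS["fat"] * calories / ATWATER_KCAL_PER_G["fat"],
    )


def plan_reference_meals(budget: EnergyBudget) -> MealPlan:
    """Reference ("med") meal plan whose total intake equals TDEE."""
    if budget.tdee <= 0:
        raise ValueError("TDEE must be positive")
    return MealPlan(
        breakfast=_reference_meal(MEAL_FRACTIONS["breakfast"] * budget.tdee),
        lunch=_reference_meal(MEAL_FRACTIONS["lunch"] * budget.tdee),
        dinner=_reference_meal(MEAL_FRACTIONS["dinner"] * budget.tdee),
    )


def _scale_meal(meal: Meal, cm: float, pm: float, fm: float) -> Meal:
    carb_g = meal.carb_g * cm
    protein_g = meal.protein_g * pm
    fat_g = meal.fat_g * fm
    calories = (
        carb_g * ATWATER_KCAL_PER_G["carb"]
        + protein_g * ATWATER_KCAL_PER_G["protein"]
        + fat_g * ATWATER_KCAL_PER_G["fat"]
    )
    return Meal(calories=calories, carb_g=carb_g, protein_g=protein_g, fat_g=fat_g)


def apply_intake_levels(
    plan: MealPlan, carb_level: str, protein_level: str, fat_level: str
) -> MealPlan:
    """Scale each macronutrient's grams by its level multiplier (0.8/1.0/1.5)."""
    cm = LEVEL_MULTIPLIERS[carb_level]
    pm = LEVEL_MULTIPLIERS[protein_level]
    fm = LEVEL_MULTIPLIERS[fat_level]
    return MealPlan(
        breakfast=_scale_meal(plan.breakfast, cm, pm, fm),
        lunch=_scale_meal(plan.lunch, cm, pm, fm),
        dinner=_scale_meal(plan.dinner, cm, pm, fm),
    )


def total_intake_kcal(plan: MealPlan) -> float:
    """Total daily calories of a meal plan."""
    return plan.breakfast.calories + plan.lunch.calories + plan.dinner.calories
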