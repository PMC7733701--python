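"""Full factorial virtual-subject cohort design.

A virtual subject is defined by nine categorical initial-condition factors:
sex, age, weight class, height class, a physical-activity pattern (sessions
per week, minutes per session, intensity as %VO2max) and the low/med/high
level of each dietary macronutrient (carbohydrate, protein, fat).  Sedentary
subjects (zero sessions per week) carry no duration or intensity, so the
activity factor contributes ``1 + 3 * 3 * 2 = 19`` cells and the complete
design enumerates

    2 (sex) * 5 (age) * 3 (weight) * 3 (height) * 19 (activity) * 27 (diet)
    = 46,170

distinct subjects.  This module enumerates that design, parses/serialises
the compact string notation used to label subjects (e.g.
``"female 28 obese tall 2 60/40 low/high/low"``) and decodes the categorical
anthropometric classes into concrete height, weight and baseline BMI.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "SEXES",
    "AGES",
    "WEIGHT_CLASSES",
    "HEIGHT_CLASSES",
    "SESSIONS",
    "DURATIONS",
    "INTENSITIES",
    "LEVELS",
    "DEFAULT_HEIGHTS",
    "DEFAULT_TARGET_BMI",
    "SubjectSpec",
    "AnthropometricProfile",
    "SpecParseError",
    "enumerate_design",
    "iter_design",
    "encode_spec",
    "decode_spec",
    "assign_anthropometrics",
    "design_table",
    "load_anthropometric_table",
]

SEXES = ("female", "male")
AGES = (28, 38, 48, 58, 68)
WEIGHT_CLASSES = ("underweight", "normal", "overweight")
HEIGHT_CLASSES = ("short", "average", "tall")
SESSIONS = (0, 1, 2, 3)
DURATIONS = (30, 60, 90)       # minutes per session
INTENSITIES = (40, 60)         # % of VO2max
LEVELS = ("low", "med", "high")

# "obese" appears in one worked subject string as a synonym of the heaviest
# weight class; accept it on input, always emit "overweight".
_WEIGHT_ALIASES = {"obese": "overweight"}

#: Height (m) for each sex and height class.  Male values are evenly spaced
#: at 0.13 m and anchored so that a tall male is 1.91 m; female values sit
#: 0.12-0.17 m below, evenly spaced at 0.105 m.  Editable via
#: :func:`assign_anthropometrics`'s ``heights`` argument or a JSON table.
DEFAULT_HEIGHTS: Mapping[tuple[str, str], float] = {
    ("male", "short"): 1.65,
    ("male", "average"): 1.78,
    ("male", "tall"): 1.91,
    ("female", "short"): 1.53,
    ("female", "average"): 1.635,
    ("female", "tall"): 1.74,
}

#: Target baseline BMI (kg/m^2) per weight class.  Weight is derived as
#: target BMI x height^2 truncated to 2 decimals, which makes a tall
#: underweight male weigh 18.0 * 1.91^2 = 65.6658 -> 65.66 kg.
DEFAULT_TARGET_BMI: Mapping[str, float] = {
    "underweight": 18.0,
    "normal": 23.0,
    "overweight": 28.0,
}


class SpecParseError(ValueError):
    """Raised when a subject string cannot be parsed into a SubjectSpec."""


@dataclass(frozen=True)
class SubjectSpec:
    """One cell of the factorial design: the categorical initial condition.

    ``session_duration`` and ``session_intensity`` are ``None`` exactly when
    ``sessions_per_week`` is 0.
    """

    sex: str
    age: int
    weight_class: str
    height_class: str
    sessions_per_week: int
    session_duration: int | None
    session_intensity: int | None
    carb_level: str
    protein_level: str
    fat_level: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age not in AGES:
            raise ValueError(f"age {self.age!r} not in {AGES}")
        if self.weight_class not in WEIGHT_CLASSES:
            raise ValueError(f"unknown weight class {self.weight_class!r}")
        if self.height_class not in HEIGHT_CLASSES:
            raise ValueError(f"unknown height class {self.height_class!r}")
        if self.sessions_per_week not in SESSIONS:
            raise ValueError(
                f"sessions_per_week {self.sessions_per_week!r} not in {SESSIONS}"
            )
        if self.sessions_per_week == 0:
            if self.session_duration is not None or self.session_intensity is not None:
                raise ValueError(
                    "sedentary subjects (0 sessions/week) must not specify "
                    "session duration or intensity"
                )
        else:
            if self.session_duration not in DURATIONS:
                raise ValueError(
                    f"session_duration {self.session_duration!r} not in {DURATIONS}"
                )
            if self.session_intensity not in INTENSITIES:
                raise ValueError(
                    f"session_intensity {self.session_intensity!r} not in {INTENSITIES}"
                )
        for name in ("carb_level", "protein_level", "fat_level"):
            if getattr(self, name) not in LEVELS:
                raise ValueError(f"{name} {getattr(self, name)!r} not in {LEVELS}")

    @property
    def is_sedentary(self) -> bool:
        return self.sessions_per_week == 0


@dataclass(frozen=True)
class AnthropometricProfile:
    """Concrete anthropometrics decoded from the categorical classes."""

    height: float   # meters
    weight: float   # kilograms
    bmi0: float     # kg/m^2, equals weight / height**2

    def __post_init__(self) -> None:
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be positive")
        if abs(self.bmi0 - self.weight / self.height**2) > 1e-9:
            raise ValueError("bmi0 inconsistent with weight / height^2")


def iter_design() -> Iterator[SubjectSpec]:
    """Yield every admissible subject specification exactly once.

    Sedentary subjects are emitted once per remaining factor combination;
    active subjects expand over all duration x intensity combinations, so the
    activity factor contributes ``1 + 3 * |D| * |I| = 19`` cells.
    """
    activity: list[tuple[int, int | None, int | None]] = [(0, None, None)]
    activity += [
        (n, d, i)
        for n in SESSIONS
        if n > 0
        for d in DURATIONS
        for i in INTENSITIES
    ]
    for sex, age, wc, hc in itertools.product(SEXES, AGES, WEIGHT_CLASSES, HEIGHT_CLASSES):
        for n, d, i in activity:
            for carb, prot, fat in itertools.product(LEVELS, LEVELS, LEVELS):
                yield SubjectSpec(sex, age, wc, hc, n, d, i, carb, prot, fat)


def enumerate_design() -> list[SubjectSpec]:
    """Return the full factorial design (46,170 subject specifications)."""
    return list(iter_design())


def encode_spec(spec: SubjectSpec) -> str:
    """Serialise a spec to its canonical string form.

    Canonical layout: ``sex age weight_class height_class N [D/I] C/P/F``;
    the duration/intensity token is omitted for sedentary subjects.
    """
    parts = [
        spec.sex,
        str(spec.age),
        spec.weight_class,
        spec.height_class,
        str(spec.sessions_per_week),
    ]
    if spec.sessions_per_week > 0:
        parts.append(f"{spec.session_duration}/{spec.session_intensity}")
    parts.append(f"{spec.carb_level}/{spec.protein_level}/{spec.fat_level}")
    return " ".join(parts)


def _classify_body_token(token: str) -> tuple[str, str]:
    """Return ('weight'|'height', canonical class) for one body-class token."""
    t = _WEIGHT_ALIASES.get(token, token)
    if t in WEIGHT_CLASSES:
        return "weight", t
    if t in HEIGHT_CLASSES:
        return "height", t
    raise SpecParseError(f"unknown body-class token {token!r}")


def decode_spec(text: str) -> SubjectSpec:
    """Parse a subject string into a :class:`SubjectSpec`.

    Accepts the weight and height class tokens in either order and "obese" as
    an alias of "overweight".  Raises :class:`SpecParseError` on any unknown
    token and :class:`ValueError` when a duration/intensity token accompanies
    a sedentary (0 sessions) subject.

    Examples
    --------
    >>> decode_spec("female 28 obese tall 2 60/40 low/high/low").weight_class
    'overweight'
    """
    tokens = text.split()
    if len(tokens) not in (6, 7):
        raise SpecParseError(
            f"expected 6 or 7 whitespace-separated tokens, got {len(tokens)}: {text!r}"
        )
    sex = tokens[0]
    if sex not in SEXES:
        raise SpecParseError(f"unknown sex token {tokens[0]!r}")
    try:
        age = int(tokens[1])
    except ValueError:
        raise SpecParseError(f"unreadable age token {tokens[1]!r}") from None

    kind_a, cls_a = _classify_body_token(tokens[2])
    kind_b, cls_b = _classify_body_token(tokens[3])
    if {kind_a, kind_b} != {"weight", "height"}:
        raise SpecParseError(
            f"tokens {tokens[2]!r} and {tokens[3]!r} must name one weight and "
            "one height class"
        )
    weight_class = cls_a if kind_a == "weight" else cls_b
    height_class = cls_a if kind_a == "height" else cls_b

    try:
        sessions = int(tokens[4])
    except ValueError:
        raise SpecParseError(f"unreadable session-count token {tokens[4]!r}") from None

    if len(tokens) == 7:
        pa_token, diet_token = tokens[5], tokens[6]
        pa_parts = pa_token.split("/")
        if len(pa_parts) != 2:
            raise SpecParseError(f"unreadable duration/intensity token {pa_token!r}")
        try:
            duration: int | None = int(pa_parts[0])
            intensity: int | None = int(pa_parts[1])
        except ValueError:
            raise SpecParseError(
                f"unreadable duration/intensity token {pa_token!r}"
            ) from None
        if sessions == 0:
            raise ValueError(
                "duration/intensity given for a sedentary subject (0 sessions)"
            )
    else:
        duration = intensity = None
        diet_token = tokens[5]

    diet_parts = diet_token.split("/")
    if len(diet_parts) != 3:
        raise SpecParseError(f"unreadable diet token {diet_token!r}")
    for part in diet_parts:
        if part not in LEVELS:
            raise SpecParseError(f"unknown diet level token {part!r}")
    carb, prot, fat = diet_parts

    try:
        return SubjectSpec(
            sex, age, weight_class, height_class, sessions, duration, intensity,
            carb, prot, fat,
        )
    except ValueError as exc:  # enum violations from __post_init__
        raise SpecParseError(str(exc)) from None


def _truncate2(x: float) -> float:
    """Truncate (not round) to 2 decimals; tolerates float representation dust."""
    return math.floor(x * 100 + 1e-9) / 100


def assign_anthropometrics(
    spec: SubjectSpec,
    heights: Mapping[tuple[str, str], float] | None = None,
    target_bmi: Mapping[str, float] | None = None,
) -> AnthropometricProfile:
    """Decode the categorical classes into height, weight and baseline BMI.

    Height comes from a fixed sex x height-class lookup; weight is the class
    target BMI times height squared, truncated to two decimals (reproducing
    the 1.91 m / 65.66 kg tall-underweight-male anchor).  Deterministic.
    """
    heights = DEFAULT_HEIGHTS if heights is None else heights
    target_bmi = DEFAULT_TARGET_BMI if target_bmi is None else target_bmi
    height = heights[(spec.sex, spec.height_class)]
    weight = _truncate2(target_bmi[spec.weight_class] * height**2)
    return AnthropometricProfile(height=height, weight=weight, bmi0=weight / height**2)


def load_anthropometric_table(
    path,
) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """Load a JSON anthropometric fixture: ``{"heights": {"male": {"tall": ...}},
    "target_bmi": {"underweight": ...}}``."""
    with open(path) as fh:
        raw = json.load(fh)
    heights = {
        (sex, hc): float(v)
        for sex, by_class in raw["heights"].items()
        for hc, v in by_class.items()
    }
    target_bmi = {wc: float(v) for wc, v in raw["target_bmi"].items()}
    return heights, target_bmi


def design_table(
    specs: Sequence[SubjectSpec] | None = None,
    heights: Mapping[tuple[str, str], float] | None = None,
    target_bmi: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Tabulate the design, one row per subject, with decoded anthropometrics.

    Absent physical-activity fields of sedentary subjects export as empty
    cells (pandas NA) in the ``d_pa`` / ``i_pa`` columns.
    """
    if specs is None:
        specs = enumerate_design()
    rows = []
    for spec in specs:
        prof = assign_anthropometrics(spec, heights=heights, target_bmi=target_bmi)
        rows.append(
            {
                "sex": spec.sex,
                "age": spec.age,
                "weight_class": spec.weight_class,
                "height_class": spec.height_class,
                "n_pa": spec.sessions_per_week,
                "d_pa": spec.session_duration,
                "i_pa": spec.session_intensity,
                "carb": spec.carb_level,
                "protein": spec.protein_level,
                "fat": spec.fat_level,
                "height_m": prof.height,
                "weight_kg": prof.weight,
                "bmi0": prof.bmi0,
            }
        )
    df = pd.DataFrame(rows)
    df["d_pa"] = df["d_pa"].astype("Int64")
    df["i_pa"] = df["i_pa"].astype("Int64")
    return df
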