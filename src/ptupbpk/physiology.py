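"""Virtual individuals and populations for whole-body PBPK simulation.

A virtual :class:`Individual` carries the anatomy and physiology the model
needs: organ volumes, organ blood flows, hematocrit and plasma albumin.
Organ sizes and flows are interpolated from a bundled age- and sex-resolved
reference table (ICRP-89-style reference persons) and rescaled to the
requested body size: volumes linearly with body weight, blood flows through
cardiac output with the standard allometric exponent 0.75.

Plasma albumin follows the logarithmic ontogeny function

    albumin(age) = 1.1287 * ln(age_years) + 33.746   [g/L]

which rises steeply through infancy and slowly in adulthood; it is the basis
for scaling the fraction unbound between age groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Organ",
    "Individual",
    "PopulationSpec",
    "AGE_GROUPS",
    "albumin_at_age",
    "reference_individual",
    "age_group_defaults",
    "generate_population",
    "population_to_frame",
    "load_reference_table",
]

# Albumin ontogeny coefficients (g/L per ln-year, intercept g/L)
ALBUMIN_SLOPE = 1.1287
ALBUMIN_INTERCEPT = 33.746

# Unprinted whole-body defaults, overridable per individual.
DEFAULT_HCT = 0.45      # hematocrit, both sexes
DEFAULT_F_CELL = 0.60   # intracellular volume fraction of liver tissue

# Supported age range of the bundled reference table (years).
AGE_RANGE = (0.0, 85.0)

# Organs perfused in parallel from the arterial pool; liver additionally
# receives the portal venous outflow of spleen, stomach and gut.
SYSTEMIC_ORGANS = (
    "liver", "kidney", "brain", "heart", "muscle",
    "spleen", "stomach", "gut", "rest",
)
PORTAL_ORGANS = ("spleen", "stomach", "gut")
ALL_ORGANS = SYSTEMIC_ORGANS + ("lung",)
BLOOD_POOLS = ("arterial_blood", "venous_blood")


@dataclass(frozen=True)
class Organ:
    """One organ: tissue volume (L) and blood perfusion (L/min)."""

    volume: float
    flow: float


@dataclass(frozen=True)
class Individual:
    """A virtual subject: demographics plus whole-body physiology."""

    age: float              # years (fractional allowed)
    weight: float           # kg
    height: float           # cm
    sex: str                # "male" | "female"
    hct: float              # hematocrit, fraction of blood volume
    albumin: float          # plasma albumin, g/L
    f_cell: float           # liver intracellular fraction
    cardiac_output: float   # L/min
    organs: dict[str, Organ] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 0.0 < self.hct < 1.0:
            raise ValueError(f"hematocrit must lie in (0, 1), got {self.hct}")
        if not 0.0 < self.f_cell < 1.0:
            raise ValueError(f"f_cell must lie in (0, 1), got {self.f_cell}")
        for name, organ in self.organs.items():
            if organ.volume <= 0.0:
                raise ValueError(f"non-positive volume for {name}")
            if name not in BLOOD_POOLS and name != "lung" and organ.flow <= 0.0:
                raise ValueError(f"non-positive flow for {name}")
        if self.organs:
            q_sum = sum(self.organs[o].flow for o in SYSTEMIC_ORGANS)
            if abs(q_sum - self.cardiac_output) > 0.01 * self.cardiac_output:
                raise ValueError(
                    "systemic organ flows do not balance cardiac output: "
                    f"{q_sum:.4f} vs {self.cardiac_output:.4f} L/min"
                )

    @property
    def bmi(self) -> float:
        """Body mass index, weight / height^2 in kg/m^2."""
        return self.weight / (self.height / 100.0) ** 2

    @property
    def q_portal(self) -> float:
        """Portal venous inflow to the liver (L/min): spleen + stomach + gut."""
        return sum(self.organs[o].flow for o in PORTAL_ORGANS)


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a virtual cohort."""

    n: int
    age_range: tuple[float, float]      # years, closed interval
    proportion_female: float
    group_label: str = "adult"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if not 0.0 <= self.proportion_female <= 1.0:
            raise ValueError("proportion_female must lie in [0, 1]")
        lo, hi = self.age_range
        if not 0.0 <= lo <= hi:
            raise ValueError("invalid age range")
        if self.group_label not in AGE_GROUPS:
            raise ValueError(f"unknown group label {self.group_label!r}")


def albumin_at_age(age: float) -> float:
    """Plasma albumin concentration (g/L) at a given age in years.

    Raises ``ValueError`` for non-positive ages (the logarithmic ontogeny
    function is undefined at and below zero).
    """
    if age <= 0.0:
        raise ValueError(f"age must be positive (years), got {age}")
    return ALBUMIN_SLOPE * math.log(age) + ALBUMIN_INTERCEPT


_REFERENCE_TABLE: pd.DataFrame | None = None


def load_reference_table() -> pd.DataFrame:
    """Load the bundled age-sex reference physiology table."""
    global _REFERENCE_TABLE
    if _REFERENCE_TABLE is None:
        with resources.files("ptupbpk.data").joinpath(
            "physiology_reference.tsv"
        ).open() as fh:
            _REFERENCE_TABLE = pd.read_csv(fh, sep="\t", comment="#")
    return _REFERENCE_TABLE


def _interp_reference(age: float, sex: str) -> tuple[dict[str, dict], float, float]:
    """Interpolate the reference table at (age, sex).

    Returns (organ rows, reference weight, reference cardiac output) where
    organ rows map organ -> {volume_L, flow_frac_co}, linearly interpolated
    in age between tabulated reference persons of the requested sex.
    """
    table = load_reference_table()
    sub = table[table["sex"] == sex]
    ages = np.sort(sub["age_y"].unique())
    organs: dict[str, dict] = {}
    for organ, grp in sub.groupby("organ"):
        grp = grp.sort_values("age_y")
        organs[organ] = {
            "volume_L": float(np.interp(age, grp["age_y"], grp["volume_L"])),
            "flow_frac_co": float(np.interp(age, grp["age_y"], grp["flow_frac_co"])),
        }
    pts = sub.drop_duplicates("age_y").sort_values("age_y")
    w_ref = float(np.interp(age, pts["age_y"], pts["weight_kg"]))
    co_ref = float(np.interp(age, pts["age_y"], pts["co_L_min"]))
    return organs, w_ref, co_ref


def reference_individual(
    age: float,
    weight: float,
    height: float,
    sex: str = "male",
    *,
    hct: float = DEFAULT_HCT,
    f_cell: float = DEFAULT_F_CELL,
) -> Individual:
    """Build a virtual individual of the given demographics.

    Organ volumes are interpolated from the bundled reference table at the
    requested age and sex, then rescaled linearly with body weight relative
    to the reference person of that age; blood flows scale through cardiac
    output with weight^0.75. Albumin is set by the ontogeny function.
    """
    if not AGE_RANGE[0] < age <= AGE_RANGE[1]:
        raise ValueError(
            f"age {age} y outside the supported range "
            f"({AGE_RANGE[0]}, {AGE_RANGE[1]}] years of the reference table"
        )
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")

    rows, w_ref, co_ref = _interp_reference(age, sex)
    w_scale = weight / w_ref
    co = co_ref * w_scale ** 0.75

    # Interpolated fractions may drift off unity between table rows; renormalise
    # over the systemic organs so flows balance cardiac output by construction.
    frac_sum = sum(rows[o]["flow_frac_co"] for o in SYSTEMIC_ORGANS)

    organs: dict[str, Organ] = {}
    for name in SYSTEMIC_ORGANS:
        frac = rows[name]["flow_frac_co"] / frac_sum
        organs[name] = Organ(volume=rows[name]["volume_L"] * w_scale, flow=frac * co)
    organs["lung"] = Organ(volume=rows["lung"]["volume_L"] * w_scale, flow=co)
    for name in BLOOD_POOLS:
        organs[name] = Organ(volume=rows[name]["volume_L"] * w_scale, flow=0.0)

    return Individual(
        age=age,
        weight=weight,
        height=height,
        sex=sex,
        hct=hct,
        albumin=albumin_at_age(age),
        f_cell=f_cell,
        cardiac_output=co,
        organs=organs,
    )


# Age-group templates: mean demographics of the six modelled groups and the
# default population age spans. Ages in years (days converted as d/365).
AGE_GROUPS: dict[str, dict] = {
    "adult": {
        "age": 25.7, "weight": 60.98, "height": 167.60,
        "age_range": (18.0, 60.0),
    },
    "elderly": {
        "age": 70.5, "weight": 58.04, "height": 165.40,
        "age_range": (60.0, 81.0),
    },
    "term_infant": {
        "age": 13.5 / 365.0, "weight": 4.28, "height": 54.11,
        "age_range": (0.0, 27.0 / 365.0),
    },
    "infant": {
        "age": 1.0, "weight": 10.66, "height": 81.49,
        "age_range": (28.0 / 365.0, 23.0 / 12.0),
    },
    "children": {
        "age": 6.5, "weight": 21.46, "height": 118.94,
        "age_range": (1.0, 11.0),
    },
    "adolescent": {
        "age": 14.5, "weight": 51.37, "height": 162.81,
        "age_range": (12.0, 17.0),
    },
}

# Sampling a population age of exactly zero is disallowed (albumin ontogeny);
# newborn ages are floored at 6 hours of life.
MIN_POPULATION_AGE = 0.25 / 365.0

# Between-subject variability of the generated cohorts (geometric CV),
# truncated at +/- 3 SD on the log scale.
WEIGHT_CV = 0.15
HEIGHT_CV = 0.04


def age_group_defaults(group_label: str, sex: str = "male") -> Individual:
    """The template (mean) individual of one of the six age groups."""
    if group_label not in AGE_GROUPS:
        raise ValueError(
            f"unknown group {group_label!r}; expected one of {sorted(AGE_GROUPS)}"
        )
    g = AGE_GROUPS[group_label]
    return reference_individual(g["age"], g["weight"], g["height"], sex)


def _truncated_lognormal(
    rng: np.random.Generator, median: float, cv: float, size: int
) -> np.ndarray:
    """Log-normal samples around ``median`` with geometric CV, +/-3 SD truncation."""
    if cv == 0.0:
        return np.full(size, median)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    z = rng.standard_normal(size)
    z = np.clip(z, -3.0, 3.0)
    return median * np.exp(sigma * z)


def generate_population(
    spec: PopulationSpec,
    *,
    age_range: tuple[float, float] | None = None,
    weight_cv: float = WEIGHT_CV,
    height_cv: float = HEIGHT_CV,
) -> list[Individual]:
    """Generate a virtual cohort for one age group.

    Exactly ``round(n * proportion_female)`` females; ages uniform on the
    requested closed interval (floored at 6 h of life for newborn groups);
    weight and height log-normal around the group template with the stated
    geometric CVs, truncated at three log-SD. Fully reproducible by seed.
    """
    rng = np.random.default_rng(spec.seed)
    template = AGE_GROUPS[spec.group_label]
    lo, hi = age_range if age_range is not None else spec.age_range
    lo = max(lo, MIN_POPULATION_AGE)

    n = spec.n
    n_female = round(n * spec.proportion_female)
    sexes = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sexes)

    ages = rng.uniform(lo, hi, size=n)
    weights = _truncated_lognormal(rng, template["weight"], weight_cv, n)
    heights = _truncated_lognormal(rng, template["height"], height_cv, n)

    return [
        reference_individual(float(a), float(w), float(h), str(s))
        for a, w, h, s in zip(ages, weights, heights, sexes)
    ]


def population_to_frame(individuals: Iterable[Individual]) -> pd.DataFrame:
    """Tabulate a cohort, one row per individual (export format)."""
    rows = [
        {
            "id": i,
            "sex": ind.sex,
            "age_y": ind.age,
            "weight_kg": ind.weight,
            "height_cm": ind.height,
            "bmi": ind.bmi,
            "albumin_g_per_L": ind.albumin,
        }
        for i, ind in enumerate(individuals)
    ]
    return pd.DataFrame(rows)


def with_overrides(ind: Individual, **kwargs) -> Individual:
    """Return a copy of an individual with selected fields replaced."""
    return replace(ind, **kwargs)
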