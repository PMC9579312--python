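"""Extrapolation of the adult model to elderly and pediatric groups.

Two drug-specific quantities are rescaled between age groups:

* total plasma clearance, by allometry with the standard 3/4 exponent,

      CL_target = CL_adult * (W_target / W_adult) ** 0.75

  split into hepatic and renal components in the adult proportion;

* fraction unbound, through the albumin ontogeny function, assuming binding
  to a single protein class whose concentration tracks albumin:

      fu_target = 1 / (1 + (1 - fu_adult) * P_target / (P_adult * fu_adult))

The group's specific clearances (1/min) are then recomputed for the group
template physiology so the scaled bundle can be simulated directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .compound import CompoundParams, bind_specific_clearances, ptu
from .physiology import AGE_GROUPS, Individual, age_group_defaults, albumin_at_age

__all__ = [
    "ScaledGroupParams",
    "ADULT_REFERENCE",
    "allometric_clearance",
    "scale_fraction_unbound",
    "scale_group",
]

ALLOMETRIC_EXPONENT = 0.75

# Adult anchors of the scaling: demographics of the trial population and the
# optimised adult whole-body clearance.
ADULT_REFERENCE = {
    "age": 25.7,          # years
    "weight": 60.98,      # kg
    "CL_total": 9.0,      # L/h
    "fu": 0.18,
    # adult hepatic:renal split of plasma clearance, L/h/kg
    "CL_hepatic_per_kg": 0.09,
    "CL_renal_per_kg": 0.05,
}


@dataclass(frozen=True)
class ScaledGroupParams:
    """Clearance/fu bundle of one age group plus its template individual."""

    group_label: str
    CL_total: float            # L/h
    CL_total_per_kg: float     # L/h/kg
    CL_hepatic_per_kg: float   # L/h/kg
    CL_renal_per_kg: float     # L/h/kg
    fu: float
    CL_spec_hepatic: float     # 1/min, for the template physiology
    CL_spec_renal: float       # 1/min
    template: Individual

    def __post_init__(self) -> None:
        if not 0.0 < self.fu <= 1.0:
            raise ValueError("fu must lie in (0, 1]")
        split = self.CL_hepatic_per_kg + self.CL_renal_per_kg
        if abs(split - self.CL_total_per_kg) > 0.10 * self.CL_total_per_kg:
            raise ValueError("hepatic+renal split inconsistent with total beyond 10%")


def allometric_clearance(CL_ad: float, W_ad: float, W_tar: float) -> float:
    """Scale a whole-body clearance (L/h) to a target body weight (kg)."""
    if CL_ad <= 0 or W_ad <= 0 or W_tar <= 0:
        raise ValueError("clearance and weights must be positive")
    return CL_ad * (W_tar / W_ad) ** ALLOMETRIC_EXPONENT


def scale_fraction_unbound(fu_ad: float, age_ad: float, age_tar: float) -> float:
    """Scale fraction unbound between ages via plasma albumin concentrations."""
    if not 0.0 < fu_ad <= 1.0:
        raise ValueError("fu_ad must lie in (0, 1]")
    p_ad = albumin_at_age(age_ad)
    p_tar = albumin_at_age(age_tar)
    return 1.0 / (1.0 + (1.0 - fu_ad) * p_tar / (p_ad * fu_ad))


def scale_group(
    group_label: str,
    compound: CompoundParams | None = None,
    *,
    adult: dict | None = None,
) -> ScaledGroupParams:
    """Build the scaled parameter bundle of one age group.

    Total clearance is scaled allometrically to the group template weight and
    split hepatic:renal in the adult proportion; fu follows the albumin
    ontogeny; the specific clearances are recomputed for the group template
    physiology through the well-stirred conversions.
    """
    ref = dict(ADULT_REFERENCE)
    if adult is not None:
        ref.update(adult)
    if group_label not in AGE_GROUPS:
        raise ValueError(f"unknown group {group_label!r}")
    template = age_group_defaults(group_label)
    compound = compound if compound is not None else ptu()

    cl_total = allometric_clearance(ref["CL_total"], ref["weight"], template.weight)
    cl_per_kg = cl_total / template.weight
    split_h = ref["CL_hepatic_per_kg"] / (
        ref["CL_hepatic_per_kg"] + ref["CL_renal_per_kg"]
    )
    cl_h = cl_per_kg * split_h
    cl_r = cl_per_kg * (1.0 - split_h)
    fu = scale_fraction_unbound(ref["fu"], ref["age"], template.age)

    scaled_compound = compound.with_(
        fu=fu,
        clearance=replace(
            compound.clearance,
            CL_pls_total=cl_per_kg,
            CL_pls_hepatic=cl_h,
            CL_pls_renal=cl_r,
        ),
    )
    bound = bind_specific_clearances(scaled_compound, template)

    return ScaledGroupParams(
        group_label=group_label,
        CL_total=cl_total,
        CL_total_per_kg=cl_per_kg,
        CL_hepatic_per_kg=cl_h,
        CL_renal_per_kg=cl_r,
        fu=fu,
        CL_spec_hepatic=bound.clearance.CL_spec_hepatic,
        CL_spec_renal=bound.clearance.CL_spec_renal,
        template=template,
    )


def scaled_compound(group: ScaledGroupParams, compound: CompoundParams | None = None) -> CompoundParams:
    """Compound parameters carrying a group's scaled fu and clearances."""
    compound = compound if compound is not None else ptu()
    return compound.with_(
        fu=group.fu,
        clearance=replace(
            compound.clearance,
            CL_pls_total=group.CL_total_per_kg,
            CL_pls_hepatic=group.CL_hepatic_per_kg,
            CL_pls_renal=group.CL_renal_per_kg,
            CL_spec_hepatic=group.CL_spec_hepatic,
            CL_spec_renal=group.CL_spec_renal,
        ),
    )
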