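"""Whole-body PBPK ODE system: assembly, integration, reporting.

The model is a flow-limited whole-body circuit: an oral dose sits in the gut
lumen and is absorbed with first-order rate ka into the gut tissue, whose
venous (portal) outflow drains into the liver together with spleen and
stomach — hepatic first-pass extraction therefore arises from the structure
rather than from a bioavailability factor. Arterial blood perfuses all organs
in parallel; organ outflows collect in the venous pool which passes through
the lung back to the arterial side.

Every organ except the brain is perfusion-limited (one well-stirred tissue
space, vascular space merged into it) with thermodynamic tissue:plasma
partition coefficient Kp; the brain is split into a vascular and a tissue
space exchanging across the blood-brain barrier with a permeability-surface
area product, which delays the brain peak well past the plasma peak.
Elimination is first-order from liver (hepatic specific clearance, referenced
to intracellular liver volume) and kidney (renal specific clearance), the
same well-stirred rates that interconvert with whole-body plasma clearance
in :mod:`ptupbpk.compound`.

Amounts are carried in micrograms and volumes in litres, so concentrations
fall out directly in ng/mL; the integrated system is linear, hence dose
linearity of AUC and Cmax is exact up to solver tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .compound import CompoundParams, absorption_rate_constant, bind_specific_clearances, partition_coefficients
from .physiology import Individual, PORTAL_ORGANS

__all__ = [
    "SimulationConfig",
    "ConcentrationTimeProfile",
    "SimulationResult",
    "PopulationResult",
    "ModelSpec",
    "CLINICAL_SCHEDULE",
    "default_output_grid",
    "build_model",
    "simulate",
    "simulate_population",
    "tissue_report",
]

# Sampling schedule of the crossover trial that anchors the adult model (h).
CLINICAL_SCHEDULE = (
    0.0, 0.25, 0.5, 0.67, 0.83, 1.0, 1.25, 1.5, 1.75,
    2.0, 2.33, 2.67, 3.0, 4.0, 5.0, 6.0, 8.0, 12.0,
)

# Effective blood-brain-barrier exchange area (cm^2). Together with the
# specific organ permeability this sets the brain equilibration time constant;
# the value is calibrated so the brain peaks hours after plasma.
BRAIN_SURFACE_AREA_CM2 = 1600.0
# Vascular fraction of total brain volume in the two-space brain model.
BRAIN_VASCULAR_FRACTION = 0.04

# Organs solved as perfusion-limited well-stirred spaces (brain handled apart).
PERFUSION_ORGANS = (
    "heart", "kidney", "liver", "muscle", "spleen", "stomach", "gut", "rest",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Dose, route, duration and numerical settings of one simulation."""

    dose: float | None = None          # mg (exclusive with dose_per_kg)
    dose_per_kg: float | None = None   # mg/kg, resolved per subject
    route: str = "oral"                # "oral" | "iv_bolus"
    duration: float = 12.0             # h
    output_grid: tuple[float, ...] | None = None  # h; default: dense + schedule
    rtol: float = 1e-8
    atol: float = 1e-10                # micrograms
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.dose is None) == (self.dose_per_kg is None):
            raise ValueError("exactly one of dose / dose_per_kg must be set")
        amount = self.dose if self.dose is not None else self.dose_per_kg
        if amount is not None and amount < 0:
            raise ValueError("dose must be non-negative")
        if self.route not in ("oral", "iv_bolus"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.output_grid is not None:
            grid = np.asarray(self.output_grid)
            if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
                raise ValueError("output grid must be strictly increasing")
            if self.duration < grid[-1]:
                raise ValueError("duration shorter than the output grid")

    def resolve_dose_ug(self, individual: Individual) -> float:
        if self.dose is not None:
            return self.dose * 1000.0
        return self.dose_per_kg * individual.weight * 1000.0


def default_output_grid(duration: float = 12.0) -> np.ndarray:
    """Dense 1-minute grid merged with the clinical sampling schedule."""
    dense = np.arange(0.0, duration + 1e-9, 1.0 / 60.0)
    sched = [t for t in CLINICAL_SCHEDULE if t <= duration + 1e-9]
    return np.unique(np.round(np.concatenate([dense, sched, [duration]]), 9))


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One compartment's concentration-time course (ng/mL vs h)."""

    compartment: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.concentrations):
            raise ValueError("times and concentrations differ in length")
        if np.any(np.asarray(self.concentrations) < 0):
            raise ValueError("negative concentration in profile")

    def scaled(self, k: float) -> "ConcentrationTimeProfile":
        return ConcentrationTimeProfile(
            self.compartment, self.times, self.concentrations * k
        )


@dataclass
class SimulationResult:
    """Profiles for plasma and tissues plus the amounts ledger."""

    times: np.ndarray                       # h
    profiles: dict[str, np.ndarray]         # label -> ng/mL on `times`
    ledger: pd.DataFrame                    # amounts in micrograms vs time
    metadata: dict = field(default_factory=dict)

    def profile(self, label: str = "venous_plasma") -> ConcentrationTimeProfile:
        return ConcentrationTimeProfile(label, self.times, self.profiles[label])

    def to_long_frame(self, subject_id: int | str = 0) -> pd.DataFrame:
        rows = []
        for label, conc in self.profiles.items():
            rows.append(pd.DataFrame({
                "subject_id": subject_id,
                "compartment": label,
                "time_h": self.times,
                "conc_ng_per_mL": conc,
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class PopulationResult:
    """Per-subject results and pointwise summary bands of venous plasma."""

    results: list[SimulationResult]
    bands: pd.DataFrame   # time_h, mean, p2.5, p97.5, p5, p95


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of the assembled ODE system."""

    individual: Individual
    compound: CompoundParams    # with specific clearances bound
    kps: dict[str, float]
    ka: float                   # 1/h
    brain_permeability_limited: bool = True
    ps_brain: float = 0.0       # L/h, blood-brain-barrier PS product
    elimination: bool = True
    lumped: bool = False        # one-compartment collapse (diagnostics)

    @property
    def state_labels(self) -> list[str]:
        if self.lumped:
            return ["gut_lumen", "central", "eliminated"]
        labels = ["gut_lumen", "arterial_blood", "venous_blood", "lung"]
        if self.brain_permeability_limited:
            labels += ["brain_vascular", "brain_tissue"]
        else:
            labels += ["brain"]
        labels += list(PERFUSION_ORGANS)
        labels += ["eliminated_hepatic", "eliminated_renal"]
        return labels


def build_model(
    individual: Individual,
    compound: CompoundParams,
    *,
    kp_override: dict[str, float] | float | None = None,
    brain_permeability_limited: bool = True,
    elimination: bool = True,
    lumped: bool = False,
    scale_absorption_with_age: bool = True,
) -> ModelSpec:
    """Assemble the whole-body model for one individual and one compound.

    ``kp_override`` replaces computed partition coefficients (a scalar applies
    to every organ); ``lumped`` collapses the body into a single well-mixed
    compartment of the total volume for verification against the closed-form
    one-compartment solution.
    """
    bound = bind_specific_clearances(compound, individual) if elimination else compound
    kps = partition_coefficients(compound, individual)
    kps["brain"] = kps.get("brain", 1.0)
    if kp_override is not None:
        if isinstance(kp_override, dict):
            kps.update(kp_override)
        else:
            kps = {k: float(kp_override) for k in kps}
    missing = [o for o in PERFUSION_ORGANS + ("lung", "brain") if o not in kps]
    if missing:
        raise KeyError(f"partition coefficient missing for organ(s): {missing}")
    ka = absorption_rate_constant(
        compound, individual, scale_with_age=scale_absorption_with_age
    )
    ps_brain = compound.P_org * BRAIN_SURFACE_AREA_CM2 * 60.0 / 1000.0  # L/h
    return ModelSpec(
        individual=individual,
        compound=bound,
        kps=kps,
        ka=ka,
        brain_permeability_limited=brain_permeability_limited,
        ps_brain=ps_brain,
        elimination=elimination,
        lumped=lumped,
    )


def _system_matrix(model: ModelSpec) -> tuple[np.ndarray, dict[str, int], dict[str, float]]:
    """Constant coefficient matrix M of dA/dt = M A, plus state index and volumes."""
    ind = model.individual
    comp = model.compound
    bp = comp.blood_plasma_ratio
    labels = model.state_labels
    idx = {name: i for i, name in enumerate(labels)}
    n = len(labels)
    m = np.zeros((n, n))

    volumes: dict[str, float] = {}

    if model.lumped:
        v_central = sum(o.volume for o in ind.organs.values())
        volumes["central"] = v_central
        m[idx["gut_lumen"], idx["gut_lumen"]] = -model.ka
        m[idx["central"], idx["gut_lumen"]] = model.ka
        if model.elimination:
            cl_total = comp.clearance.CL_pls_total * ind.weight  # L/h
            m[idx["central"], idx["central"]] = -cl_total / v_central
            m[idx["eliminated"], idx["central"]] = cl_total / v_central
        return m, idx, volumes

    flows = {name: ind.organs[name].flow * 60.0 for name in ind.organs}  # L/h
    co = ind.cardiac_output * 60.0
    v = {name: ind.organs[name].volume for name in ind.organs}
    v_art = v["arterial_blood"]
    v_ven = v["venous_blood"]

    volumes.update({k: v[k] for k in v})
    if model.brain_permeability_limited:
        volumes["brain_vascular"] = v["brain"] * BRAIN_VASCULAR_FRACTION
        volumes["brain_tissue"] = v["brain"] * (1.0 - BRAIN_VASCULAR_FRACTION)

    def out_coeff(organ: str) -> float:
        # venous blood concentration leaving a perfusion-limited organ per
        # unit amount: C_vb = (A/V) * BP / Kp
        return bp / (model.kps[organ] * v[organ])

    i_lum, i_art, i_ven = idx["gut_lumen"], idx["arterial_blood"], idx["venous_blood"]

    # absorption: lumen -> gut tissue
    m[i_lum, i_lum] -= model.ka
    m[idx["gut"], i_lum] += model.ka

    # lung in series with the full cardiac output: venous -> lung -> arterial
    m[idx["lung"], i_ven] += co / v_ven
    m[i_ven, i_ven] -= co / v_ven
    m[idx["lung"], idx["lung"]] -= co * out_coeff("lung")
    m[i_art, idx["lung"]] += co * out_coeff("lung")
    m[i_art, i_art] -= co / v_art

    # parallel systemic organs
    for organ in PERFUSION_ORGANS:
        i_o = idx[organ]
        q = flows[organ]
        m[i_o, i_art] += q / v_art
        if organ == "liver":
            continue  # liver outflow handled below at arterial + portal flow
        m[i_o, i_o] -= q * out_coeff(organ)
        if organ in PORTAL_ORGANS:
            m[idx["liver"], i_o] += q * out_coeff(organ)   # portal drainage
        else:
            m[i_ven, i_o] += q * out_coeff(organ)
    # liver outflow carries hepatic arterial plus portal flow
    q_liver_out = flows["liver"] + sum(flows[o] for o in PORTAL_ORGANS)
    m[idx["liver"], idx["liver"]] -= q_liver_out * out_coeff("liver")
    m[i_ven, idx["liver"]] += q_liver_out * out_coeff("liver")

    # brain
    if model.brain_permeability_limited:
        i_bv, i_bt = idx["brain_vascular"], idx["brain_tissue"]
        v_bv = volumes["brain_vascular"]
        v_bt = volumes["brain_tissue"]
        q_br = flows["brain"]
        ps = model.ps_brain
        kp_br = model.kps["brain"]
        m[i_bv, i_art] += q_br / v_art
        m[i_bv, i_bv] -= q_br / v_bv
        m[i_ven, i_bv] += q_br / v_bv
        # barrier flux PS * (C_plasma_vascular - C_tissue / Kp)
        m[i_bv, i_bv] -= ps / (bp * v_bv)
        m[i_bv, i_bt] += ps / (kp_br * v_bt)
        m[i_bt, i_bv] += ps / (bp * v_bv)
        m[i_bt, i_bt] -= ps / (kp_br * v_bt)
    else:
        i_b = idx["brain"]
        q_br = flows["brain"]
        m[i_b, i_art] += q_br / v_art
        m[i_b, i_b] -= q_br * out_coeff("brain")
        m[i_ven, i_b] += q_br * out_coeff("brain")

    if model.elimination:
        cl = model.compound.clearance
        fu = comp.fu
        # hepatic: k_spec * fu * f_cell * V_liv * C_liver_plasma, per hour
        k_h = cl.CL_spec_hepatic * 60.0 * fu * ind.f_cell * v["liver"]
        coeff_h = k_h / (model.kps["liver"] * v["liver"])
        m[idx["liver"], idx["liver"]] -= coeff_h
        m[idx["eliminated_hepatic"], idx["liver"]] += coeff_h
        # renal: k_spec * fu * V_kid * C_kidney_plasma, per hour
        k_r = cl.CL_spec_renal * 60.0 * fu * v["kidney"]
        coeff_r = k_r / (model.kps["kidney"] * v["kidney"])
        m[idx["kidney"], idx["kidney"]] -= coeff_r
        m[idx["eliminated_renal"], idx["kidney"]] += coeff_r

    return m, idx, volumes


def simulate(model: ModelSpec, config: SimulationConfig) -> SimulationResult:
    """Integrate the model and report profiles, ledger and metadata."""
    ind = model.individual
    dose_ug = config.resolve_dose_ug(ind)
    grid = (
        np.asarray(config.output_grid, dtype=float)
        if config.output_grid is not None
        else default_output_grid(config.duration)
    )

    matrix, idx, volumes = _system_matrix(model)
    n = matrix.shape[0]
    y0 = np.zeros(n)
    if config.route == "oral":
        y0[idx["gut_lumen"]] = dose_ug
    else:
        target = "central" if model.lumped else "venous_blood"
        y0[idx[target]] = dose_ug

    sol = solve_ivp(
        lambda t, y: matrix @ y,
        (0.0, float(grid[-1])),
        y0,
        method="LSODA",
        t_eval=grid,
        rtol=config.rtol,
        atol=config.atol,
        jac=lambda t, y: matrix,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)  # solver noise below atol may dip negative

    bp = model.compound.blood_plasma_ratio
    profiles: dict[str, np.ndarray] = {}
    if model.lumped:
        profiles["central"] = y[idx["central"]] / volumes["central"]
        profiles["venous_plasma"] = profiles["central"]
        body = y[idx["central"]]
        eliminated_h = y[idx["eliminated"]]
        eliminated_r = np.zeros_like(eliminated_h)
    else:
        profiles["venous_plasma"] = y[idx["venous_blood"]] / volumes["venous_blood"] / bp
        profiles["arterial_plasma"] = y[idx["arterial_blood"]] / volumes["arterial_blood"] / bp
        for organ in PERFUSION_ORGANS + ("lung",):
            profiles[organ] = y[idx[organ]] / volumes[organ]
        if model.brain_permeability_limited:
            profiles["brain"] = y[idx["brain_tissue"]] / volumes["brain_tissue"]
        else:
            profiles["brain"] = y[idx["brain"]] / volumes["brain"]
        body_states = [
            k for k in idx
            if k not in ("gut_lumen", "eliminated_hepatic", "eliminated_renal")
        ]
        body = sum(y[idx[k]] for k in body_states)
        eliminated_h = y[idx["eliminated_hepatic"]]
        eliminated_r = y[idx["eliminated_renal"]]

    ledger = pd.DataFrame({
        "time_h": grid,
        "gut_ug": y[idx["gut_lumen"]],
        "body_ug": body,
        "elim_hepatic_ug": eliminated_h,
        "elim_renal_ug": eliminated_r,
    })
    totals = ledger[["gut_ug", "body_ug", "elim_hepatic_ug", "elim_renal_ug"]].sum(axis=1)
    if dose_ug > 0:
        drift = np.max(np.abs(totals - dose_ug)) / dose_ug
        if drift > 1e-3:
            raise RuntimeError(f"mass-balance drift {drift:.2e} exceeds 0.1%")

    meta = {
        "dose_ug": dose_ug,
        "route": config.route,
        "rtol": config.rtol,
        "atol": config.atol,
        "ka_per_h": model.ka,
        "kp_method": "poulin-theil",
        "brain_permeability_limited": model.brain_permeability_limited,
        "weight_kg": ind.weight,
        "seed": config.seed,
    }
    return SimulationResult(times=grid, profiles=profiles, ledger=ledger, metadata=meta)


def simulate_population(
    individuals: Sequence[Individual],
    compound: CompoundParams,
    config: SimulationConfig,
    **build_kwargs,
) -> PopulationResult:
    """Simulate every individual and summarise venous plasma across subjects.

    Emits pointwise mean together with the 2.5/97.5 and 5/95 percentile
    curves of the per-subject venous plasma concentrations.
    """
    results = [
        simulate(build_model(ind, compound, **build_kwargs), config)
        for ind in individuals
    ]
    stack = np.vstack([r.profiles["venous_plasma"] for r in results])
    bands = pd.DataFrame({
        "time_h": results[0].times,
        "mean": stack.mean(axis=0),
        "p2.5": np.percentile(stack, 2.5, axis=0),
        "p97.5": np.percentile(stack, 97.5, axis=0),
        "p5": np.percentile(stack, 5.0, axis=0),
        "p95": np.percentile(stack, 95.0, axis=0),
    })
    return PopulationResult(results=results, bands=bands)


TISSUE_REPORT_ORDER = (
    "venous_plasma", "brain", "heart", "kidney", "liver",
    "lung", "muscle", "spleen", "stomach",
)


def tissue_report(result: SimulationResult) -> pd.DataFrame:
    """Non-compartmental PK parameters for plasma and each reported tissue."""
    from .evaluation import nca  # local import: evaluation depends on this module

    rows = []
    for label in TISSUE_REPORT_ORDER:
        pk = nca(result.profile(label))
        rows.append({
            "compartment": label,
            "AUC_0-t": pk.auc_t,
            "Tmax": pk.tmax,
            "Cmax": pk.cmax,
        })
    return pd.DataFrame(rows).set_index("compartment")
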