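"""Model evaluation: NCA, mean fold error, exposure folds and TOST.

* Non-compartmental analysis computes AUC by the trapezoidal rule on the
  sampled grid (linear by default, linear-up/log-down optionally for sparse
  clinical grids), Cmax/Tmax from the grid maximum, and extrapolates
  AUC to infinity from a log-linear terminal fit when the tail declines
  cleanly.
* Mean fold error (MFE = predicted/observed) qualifies a model prediction;
  a parameter passes when 0.5 < MFE < 2 (open interval).
* The two-one-sided-tests (TOST) procedure assesses average bioequivalence
  of a 2x2 crossover on the log scale with sequence, period, formulation and
  subject(sequence) fixed effects; the 90% confidence interval of the
  geometric mean ratio must fall inside 80.00-125.00%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pbpk_core import ConcentrationTimeProfile

__all__ = [
    "PKParameters",
    "MFEReport",
    "BEResult",
    "nca",
    "mean_fold_error",
    "exposure_fold",
    "tost_bioequivalence",
]

BE_LIMITS = (80.0, 125.0)      # % acceptance interval of the GMR
MFE_WINDOW = (0.5, 2.0)        # open qualification window
LAMBDA_Z_MIN_R2 = 0.9


@dataclass(frozen=True)
class PKParameters:
    """Non-compartmental summary of one concentration-time profile."""

    auc_t: float                 # ng*h/mL, to the last sampled point
    cmax: float                  # ng/mL
    tmax: float | None           # h; None for an all-zero profile
    auc_inf: float | None = None  # ng*h/mL; None when the tail is unreliable
    lambda_z: float | None = None  # 1/h

    def __post_init__(self) -> None:
        if self.auc_inf is not None and self.auc_inf < self.auc_t - 1e-9:
            raise ValueError("AUC_0-inf cannot be below AUC_0-t")


@dataclass(frozen=True)
class MFEReport:
    parameter: str
    predicted: float
    observed: float
    mfe: float
    passed: bool


@dataclass(frozen=True)
class BEResult:
    parameter: str
    geomean_test: float
    geomean_reference: float
    gmr_percent: float
    ci90_percent: tuple[float, float]
    passed: bool
    n_subjects: int


def _auc_trapezoid(t: np.ndarray, c: np.ndarray, method: str) -> float:
    if method == "linear":
        return float(np.trapezoid(c, t))
    if method != "linuplogdown":
        raise ValueError(f"unknown AUC method {method!r}")
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c1 < c0 and c1 > 0 and c0 > 0:
            auc += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            auc += dt * (c0 + c1) / 2.0
    return auc


def nca(
    profile: ConcentrationTimeProfile,
    *,
    auc_method: str = "linear",
    n_terminal: int = 3,
) -> PKParameters:
    """Non-compartmental PK parameters of one profile.

    Requires at least three samples including t = 0. AUC to infinity adds
    Clast/lambda_z from a log-linear regression over the last ``n_terminal``
    points, reported only when they decline monotonically with fit r^2 of at
    least 0.9.
    """
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.concentrations, dtype=float)
    if len(t) < 3:
        raise ValueError("NCA requires at least 3 time points")
    if abs(t[0]) > 1e-12:
        raise ValueError("NCA requires the profile to start at t = 0")

    auc_t = _auc_trapezoid(t, c, auc_method)
    if np.all(c == 0.0):
        return PKParameters(auc_t=0.0, cmax=0.0, tmax=None)

    i_max = int(np.argmax(c))   # first occurrence on ties
    cmax = float(c[i_max])
    tmax = float(t[i_max])

    auc_inf = None
    lambda_z = None
    tail_t = t[-n_terminal:]
    tail_c = c[-n_terminal:]
    if np.all(tail_c > 0) and np.all(np.diff(tail_c) < 0):
        fit = stats.linregress(tail_t, np.log(tail_c))
        if fit.slope < 0 and fit.rvalue ** 2 >= LAMBDA_Z_MIN_R2:
            lambda_z = -float(fit.slope)
            auc_inf = auc_t + float(tail_c[-1]) / lambda_z
    return PKParameters(
        auc_t=float(auc_t), cmax=cmax, tmax=tmax,
        auc_inf=auc_inf, lambda_z=lambda_z,
    )


def mean_fold_error(predicted: float, observed: float, parameter: str = "") -> MFEReport:
    """Predicted/observed ratio with the open (0.5, 2) qualification window."""
    if observed <= 0:
        raise ValueError("observed value must be positive")
    mfe = predicted / observed
    return MFEReport(
        parameter=parameter,
        predicted=predicted,
        observed=observed,
        mfe=mfe,
        passed=MFE_WINDOW[0] < mfe < MFE_WINDOW[1],
    )


def exposure_fold(target: dict | PKParameters, reference: dict | PKParameters) -> dict[str, float]:
    """Elementwise target/reference ratio of PK parameters."""
    def as_dict(x):
        if isinstance(x, PKParameters):
            return {"AUC_0-t": x.auc_t, "Cmax": x.cmax, "Tmax": x.tmax}
        return dict(x)

    tar, ref = as_dict(target), as_dict(reference)
    folds = {}
    for key in tar:
        if key in ref and tar[key] is not None and ref[key] is not None:
            if ref[key] <= 0:
                raise ValueError(f"reference {key} must be positive")
            folds[key] = tar[key] / ref[key]
    return folds


def _subject_parameters(data: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Per subject x period NCA parameter values from a crossover dataset."""
    key = {"AUC_0-t": "auc_t", "AUC_0-inf": "auc_inf", "Cmax": "cmax"}.get(parameter)
    if key is None:
        raise ValueError(
            f"unsupported BE parameter {parameter!r}; "
            "expected 'AUC_0-t', 'AUC_0-inf' or 'Cmax'"
        )
    rows = []
    for (subj, period), grp in data.groupby(["subject_id", "period"]):
        grp = grp.sort_values("time_h")
        pk = nca(ConcentrationTimeProfile(
            compartment="plasma",
            times=grp["time_h"].to_numpy(),
            concentrations=grp["conc_ng_per_mL"].to_numpy(),
        ))
        value = getattr(pk, key)
        if value is None or value <= 0:
            raise ValueError(
                f"subject {subj} period {period}: {parameter} unavailable or non-positive"
            )
        rows.append({
            "subject_id": subj,
            "period": period,
            "sequence": grp["sequence"].iloc[0],
            "formulation": grp["formulation"].iloc[0],
            "value": value,
        })
    return pd.DataFrame(rows)


def tost_bioequivalence(data: pd.DataFrame, parameter: str = "AUC_0-t") -> BEResult:
    """Average bioequivalence of a 2x2 crossover by the TOST procedure.

    ``data`` is a long-format crossover dataset with columns subject_id,
    sequence, period, formulation, time_h, conc_ng_per_mL. The chosen NCA
    parameter is computed per subject and period, log-transformed and
    analysed by least squares with sequence, period, formulation and
    subject-within-sequence effects; the 90% CI of the formulation contrast
    (T vs R) is back-transformed to the GMR scale and compared with the
    80.00-125.00% interval.
    """
    import statsmodels.api as sm

    params = _subject_parameters(data, parameter)
    n_subj = params["subject_id"].nunique()
    seq_sizes = params.drop_duplicates("subject_id").groupby("sequence").size()
    if len(seq_sizes) < 2 or (seq_sizes < 2).any():
        raise ValueError("TOST requires at least 2 subjects in each sequence")

    y = np.log(params["value"].to_numpy())
    x = pd.concat(
        [
            pd.get_dummies(params["subject_id"], prefix="s", drop_first=True),
            pd.get_dummies(params["period"], prefix="p", drop_first=True),
            pd.get_dummies(params["formulation"], prefix="f", drop_first=True),
        ],
        axis=1,
    ).astype(float)
    x = sm.add_constant(x)
    # formulation contrast column: T vs R (dummies are alphabetical, R dropped)
    contrast = "f_T"
    if contrast not in x.columns:
        raise ValueError("dataset must contain both T and R formulations")

    fit = sm.OLS(y, x).fit()
    est = fit.params[contrast]
    se = fit.bse[contrast]
    df = int(fit.df_resid)
    tcrit = stats.t.ppf(0.95, df)
    lo, hi = est - tcrit * se, est + tcrit * se

    in_t = params["formulation"] == "T"
    gmean_t = float(np.exp(np.mean(np.log(params.loc[in_t, "value"]))))
    gmean_r = float(np.exp(np.mean(np.log(params.loc[~in_t, "value"]))))

    ci = (100.0 * math.exp(lo), 100.0 * math.exp(hi))
    return BEResult(
        parameter=parameter,
        geomean_test=gmean_t,
        geomean_reference=gmean_r,
        gmr_percent=100.0 * math.exp(est),
        ci90_percent=ci,
        passed=BE_LIMITS[0] <= ci[0] and ci[1] <= BE_LIMITS[1],
        n_subjects=int(n_subj),
    )
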