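"""Noncompartmental analysis and prediction-accuracy metrics.

pk_summary computes the standard IV summary set: Cmax/tmax by direct
maximum, AUC by the linear trapezoid on the given sampling grid, the
terminal rate lambda_z by log-linear least squares on the last
``n_terminal`` samples, AUCinf = AUClast + Clast/lambda_z, and
CL = dose / AUCinf (per kg when the dose is per kg).

Accuracy metrics follow the fold-error convention: per-parameter
predicted/observed ratios flagged against the 2-fold acceptance band
[0.5, 2.0] (inclusive), the geometric mean fold error
GMFE = 10^(mean log10(Cpred/Cobs)) computed with *signed* logs -- so
systematic under-prediction gives GMFE < 1 and under-/over-predictions can
cancel -- and RMSE = sqrt(mean (Cpred - Cobs)^2) in concentration units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PkSummary",
    "AccuracyReport",
    "pk_summary",
    "fold_errors",
    "gmfe",
    "rmse",
    "validate_predictions",
    "FOLD_BOUNDS",
]

#: Inclusive acceptance band for predicted/observed fold errors.
FOLD_BOUNDS = (0.5, 2.0)

#: Parameters compared between predicted and observed summaries.
_COMPARED = ("cmax", "auc_inf", "cl", "t_half")


@dataclass(frozen=True)
class PkSummary:
    """IV noncompartmental summary.

    cmax ng/mL, tmax min, auc_last and auc_inf ug*min/mL, cl mL/min/kg,
    t_half min, lambda_z 1/min.
    """

    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float
    cl: float
    t_half: float
    lambda_z: float


def pk_summary(profile: pd.DataFrame, dose_per_kg: float,
               n_terminal: int = 3) -> PkSummary:
    """Summarise a concentration-time profile.

    ``profile`` needs columns ``time_min`` and ``conc_ng_ml``;
    ``dose_per_kg`` is in ug/kg so that CL comes out in mL/min/kg.
    """
    t = np.asarray(profile["time_min"], dtype=float)
    c = np.asarray(profile["conc_ng_ml"], dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 profile points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if n_terminal < 2 or n_terminal > t.size:
        raise ValueError("n_terminal must be in [2, len(profile)]")

    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_last = float(np.trapezoid(c, t)) / 1000.0  # ng*min/mL -> ug*min/mL

    tail_t, tail_c = t[-n_terminal:], c[-n_terminal:]
    if np.any(tail_c <= 0):
        raise ValueError("terminal concentrations must be positive")
    lambda_z = -float(np.polyfit(tail_t, np.log(tail_c), 1)[0])
    if lambda_z <= 0:
        raise ValueError(f"non-positive terminal slope (lambda_z={lambda_z:.3g})")
    auc_inf = auc_last + float(c[-1]) / lambda_z / 1000.0
    return PkSummary(
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        auc_inf=auc_inf,
        cl=dose_per_kg / auc_inf,
        t_half=float(np.log(2.0) / lambda_z),
        lambda_z=lambda_z,
    )


def fold_errors(pred: PkSummary, obs: PkSummary) -> dict[str, float]:
    """Elementwise predicted/observed ratios for Cmax, AUCinf, CL, t1/2."""
    out = {}
    for name in _COMPARED:
        o = getattr(obs, name)
        if o <= 0:
            raise ValueError(f"observed {name} must be > 0")
        out[name] = getattr(pred, name) / o
    return out


def gmfe(pred, obs) -> float:
    """Geometric mean fold error with signed logs (can fall below 1)."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError("pred and obs must have equal length")
    if np.any(p <= 0) or np.any(o <= 0):
        raise ValueError("GMFE needs positive concentrations")
    return float(10.0 ** np.mean(np.log10(p / o)))


def rmse(pred, obs) -> float:
    """Root mean square error, in the concentration units of the inputs."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError("pred and obs must have equal length")
    return float(np.sqrt(np.mean((p - o) ** 2)))


@dataclass(frozen=True)
class AccuracyReport:
    """Fold errors plus profile-level accuracy for one prediction method."""

    fold: Mapping[str, float]
    gmfe: float
    rmse: float
    pass_2fold: Mapping[str, bool]


def validate_predictions(pred: PkSummary, obs: PkSummary,
                         pred_conc=None, obs_conc=None) -> AccuracyReport:
    """2-fold acceptance report: per-parameter ratios with inclusive
    [0.5, 2.0] bounds; GMFE/RMSE when paired profiles are supplied."""
    fold = fold_errors(pred, obs)
    passes = {k: FOLD_BOUNDS[0] <= v <= FOLD_BOUNDS[1] for k, v in fold.items()}
    g = gmfe(pred_conc, obs_conc) if pred_conc is not None else float("nan")
    r = rmse(pred_conc, obs_conc) if pred_conc is not None else float("nan")
    return AccuracyReport(fold=fold, gmfe=g, rmse=r, pass_2fold=passes)
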