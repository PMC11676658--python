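"""Virtual populations and one-at-a-time parameter sensitivity.

Population variability is modelled as independent, median-one lognormal
multipliers on organ intrinsic clearances, fu,p, tissue partition
coefficients, and organ blood flows (defaults: CV 30%, 20%, 20%, 15%
respectively -- conventional magnitudes for PBPK inter-individual
variability).  After flow sampling, cardiac output is re-derived as the
sum of the sampled systemic flows so every virtual subject satisfies flow
conservation.

Sensitivity scenarios multiply one parameter group by a fold factor and
report change/control ratios of Cmax, AUC_last, CL, and t1/2 from the
single-dose human regimen (10 mg, 1 h infusion).  Hepatic-blood-flow
scenarios scale the hepatic artery and the portal inflows (spleen,
stomach, intestine) jointly; the flow change is absorbed by the
rest-of-body flow as far as it can be without going negative, and any
remainder raises cardiac output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nca import pk_summary
from .parameters import ELIMINATING_ORGANS, PORTAL_TISSUES
from .pbpk import (
    SAMPLING_SCHEDULES,
    DoseRegimen,
    PbpkModel,
    TISSUE_ORDER,
    simulate,
)

__all__ = [
    "PopulationSpec",
    "SensitivityScenario",
    "STANDARD_SCENARIOS",
    "PercentileBands",
    "sample_population",
    "simulate_population",
    "percentile_bands",
    "coverage_fraction",
    "run_sensitivity",
]

_DEFAULT_CV = {"clint": 0.30, "fu_p": 0.20, "k_tp": 0.20, "flow": 0.15}


@dataclass(frozen=True)
class PopulationSpec:
    """Virtual-population design: subject count, per-group lognormal CVs
    ('clint', 'fu_p', 'k_tp', 'flow'), and the sampling seed."""

    n_subjects: int = 100
    cv_map: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_CV))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(cv < 0 for cv in self.cv_map.values()):
            raise ValueError("CVs must be >= 0")

    def cv(self, group: str) -> float:
        return float(self.cv_map.get(group, 0.0))


def _lognormal_multiplier(rng: np.random.Generator, cv: float, size=None):
    """Median-one lognormal with the requested coefficient of variation."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def sample_population(model: PbpkModel, spec: PopulationSpec) -> list[PbpkModel]:
    """Draw ``n_subjects`` perturbed copies of the reference model.

    Deterministic for a fixed seed.  Flows are re-balanced after sampling:
    hepatic outflow is re-derived from its sampled inflows and cardiac
    output from the sum of systemic flows.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for _ in range(spec.n_subjects):
        clint = {
            organ: model.clint_in_vivo[organ] * _lognormal_multiplier(rng, spec.cv("clint"))
            for organ in ELIMINATING_ORGANS
        }
        fu_p = min(model.fu_p * _lognormal_multiplier(rng, spec.cv("fu_p")), 1.0)
        k_tp = {
            t: model.k_tp[t] * _lognormal_multiplier(rng, spec.cv("k_tp"))
            for t in model.k_tp
        }
        flows = dict(model.flows)
        adipose_flow = model.adipose_flow
        q_hep_art = model.q_hep_art
        if spec.cv("flow") > 0:
            systemic = [t for t in TISSUE_ORDER if t not in ("lung", "liver")]
            for t in systemic:
                flows[t] = model.flows[t] * _lognormal_multiplier(rng, spec.cv("flow"))
            adipose_flow *= _lognormal_multiplier(rng, spec.cv("flow"))
            q_hep_art *= _lognormal_multiplier(rng, spec.cv("flow"))
            flows["liver"] = q_hep_art + sum(flows[t] for t in PORTAL_TISSUES)
            flows["lung"] = (sum(flows[t] for t in systemic) + adipose_flow
                             + q_hep_art)
        subjects.append(model.copy_with(
            clint_in_vivo=clint, fu_p=fu_p, k_tp=k_tp, flows=flows,
            adipose_flow=adipose_flow, q_hep_art=q_hep_art,
        ))
    return subjects


def simulate_population(subjects: Sequence[PbpkModel],
                        regimen: DoseRegimen | Sequence[DoseRegimen],
                        t_end: float,
                        t_eval: Sequence[float],
                        **simulate_kwargs) -> tuple[np.ndarray, np.ndarray]:
    """Plasma traces for every subject on a common grid.

    Returns (times, matrix) with matrix shape (n_subjects, n_times).
    """
    t_eval = np.asarray(t_eval, dtype=float)
    traces = []
    for subject in subjects:
        res = simulate(subject, regimen, t_end=t_end,
                       dt_out=t_end, t_eval=t_eval, **simulate_kwargs)
        traces.append(np.interp(t_eval, res.times, res.plasma))
    return t_eval, np.asarray(traces)


@dataclass(frozen=True)
class PercentileBands:
    times: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray


def percentile_bands(times: np.ndarray, profiles: np.ndarray,
                     lo: float = 5.0, hi: float = 95.0) -> PercentileBands:
    """Pointwise empirical percentile band plus the population mean."""
    times = np.asarray(times, dtype=float)
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need >= 2 profiles on a common grid")
    if profiles.shape[1] != times.size:
        raise ValueError("profile grid does not match the time grid")
    return PercentileBands(
        times=times,
        mean=profiles.mean(axis=0),
        lo=np.percentile(profiles, lo, axis=0),
        hi=np.percentile(profiles, hi, axis=0),
    )


def coverage_fraction(obs_times, obs_conc, bands: PercentileBands) -> float:
    """Fraction of observed points inside the (interpolated) band."""
    t = np.asarray(obs_times, dtype=float)
    c = np.asarray(obs_conc, dtype=float)
    if np.any(t < bands.times.min()) or np.any(t > bands.times.max()):
        raise ValueError("observation times fall outside the simulated span")
    lo = np.interp(t, bands.times, bands.lo)
    hi = np.interp(t, bands.times, bands.hi)
    return float(np.mean((c >= lo) & (c <= hi)))


# -- sensitivity analysis -----------------------------------------------

_SENSITIVITY_PARAMETERS = (
    "liver_metabolic_velocity",
    "kidney_metabolic_velocity",
    "fu_p",
    "k_adipose_plasma",
    "hepatic_blood_flow",
    "renal_blood_flow",
)


@dataclass(frozen=True)
class SensitivityScenario:
    parameter: str
    fold: float

    def __post_init__(self) -> None:
        if self.parameter not in _SENSITIVITY_PARAMETERS:
            raise ValueError(
                f"unknown parameter {self.parameter!r}; "
                f"choose from {_SENSITIVITY_PARAMETERS}"
            )
        if self.fold <= 0:
            raise ValueError("fold must be > 0")


#: The standard scenario grid: 10-fold on metabolic velocities, 2-fold on
#: fu,p, adipose partitioning, and blood flows, each up and down.
STANDARD_SCENARIOS = tuple(
    SensitivityScenario(p, f)
    for p, folds in (
        ("liver_metabolic_velocity", (10.0, 0.1)),
        ("kidney_metabolic_velocity", (10.0, 0.1)),
        ("fu_p", (2.0, 0.5)),
        ("k_adipose_plasma", (2.0, 0.5)),
        ("hepatic_blood_flow", (2.0, 0.5)),
        ("renal_blood_flow", (2.0, 0.5)),
    )
    for f in folds
)


def _rebalanced_flows(model: PbpkModel, scaled: Mapping[str, float],
                      q_hep_art: float) -> dict:
    """Recompute liver outflow; absorb the systemic-flow change into
    rest-of-body down to zero, letting cardiac output take the rest."""
    flows = dict(scaled)
    flows["liver"] = q_hep_art + sum(flows[t] for t in PORTAL_TISSUES)
    systemic = [t for t in TISSUE_ORDER if t not in ("lung", "liver", "rest_of_body")]
    delta = (sum(flows[t] for t in systemic) + q_hep_art
             - sum(model.flows[t] for t in systemic) - model.q_hep_art)
    flows["rest_of_body"] = max(model.flows["rest_of_body"] - delta, 0.0)
    flows["lung"] = (sum(flows[t] for t in systemic) + flows["rest_of_body"]
                     + model.adipose_flow + q_hep_art)
    return flows


def apply_scenario(model: PbpkModel, scenario: SensitivityScenario) -> PbpkModel:
    """Return the model with one parameter group scaled by the fold factor."""
    f = scenario.fold
    p = scenario.parameter
    if p == "liver_metabolic_velocity":
        return model.copy_with(clint_in_vivo={"liver": model.clint_in_vivo["liver"] * f})
    if p == "kidney_metabolic_velocity":
        return model.copy_with(clint_in_vivo={"kidney": model.clint_in_vivo["kidney"] * f})
    if p == "fu_p":
        return model.copy_with(fu_p=model.fu_p * f)
    if p == "k_adipose_plasma":
        return model.copy_with(k_tp={"adipose": model.k_tp["adipose"] * f})
    if p == "hepatic_blood_flow":
        scaled = dict(model.flows)
        for t in PORTAL_TISSUES:
            scaled[t] = model.flows[t] * f
        q_hep_art = model.q_hep_art * f
        return model.copy_with(flows=_rebalanced_flows(model, scaled, q_hep_art),
                               q_hep_art=q_hep_art)
    if p == "renal_blood_flow":
        scaled = dict(model.flows)
        scaled["kidney"] = model.flows["kidney"] * f
        return model.copy_with(flows=_rebalanced_flows(model, scaled, model.q_hep_art))
    raise AssertionError(p)


def _endpoints(model: PbpkModel, regimen, schedule: np.ndarray,
               dose_per_kg: float) -> dict[str, float]:
    res = simulate(model, regimen, t_end=float(schedule.max()),
                   dt_out=float(schedule.max()), t_eval=schedule)
    profile = pd.DataFrame({
        "time_min": schedule,
        "conc_ng_ml": np.interp(schedule, res.times, res.plasma),
    })
    s = pk_summary(profile, dose_per_kg=dose_per_kg)
    return {"cmax": s.cmax, "auc_last": s.auc_last, "cl": s.cl, "t_half": s.t_half}


def run_sensitivity(model: PbpkModel,
                    regimen: DoseRegimen | None = None,
                    scenarios: Sequence[SensitivityScenario] = STANDARD_SCENARIOS,
                    schedule: Sequence[float] | None = None) -> pd.DataFrame:
    """Change/control endpoint ratios, one row per scenario.

    Defaults to the single-dose human regimen (10 mg, 1 h infusion)
    sampled on the human schedule; endpoints are Cmax, AUC_last at the
    sampling horizon, CL (from AUCinf), and terminal t1/2.
    """
    if regimen is None:
        regimen = DoseRegimen("iv_infusion", 10_000.0, infusion_duration=60.0)
    if schedule is None:
        schedule = SAMPLING_SCHEDULES.get(model.species, SAMPLING_SCHEDULES["human"])
    schedule = np.asarray(schedule, dtype=float)
    regimens = [regimen] if isinstance(regimen, DoseRegimen) else list(regimen)
    dose_per_kg = sum(r.dose * r.n_doses for r in regimens) / model.body_weight

    reference = _endpoints(model, regimen, schedule, dose_per_kg)
    rows = []
    for scenario in scenarios:
        perturbed = _endpoints(apply_scenario(model, scenario), regimen,
                               schedule, dose_per_kg)
        rows.append({
            "parameter": scenario.parameter,
            "fold": scenario.fold,
            **{k: perturbed[k] / reference[k] for k in reference},
        })
    return pd.DataFrame(rows)
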