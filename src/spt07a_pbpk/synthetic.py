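"""Synthetic-data generators emulating every measured input of the study.

Each generator reproduces one assay or in-vivo design so the whole
pipeline runs without external data:

* microsomal substrate-depletion time courses (first-order decay on the
  0/10/20/30/45/60 min incubation schedule, triplicate);
* equilibrium-dialysis (donor/receiver) and blood-partitioning
  (blood/plasma) assays at the study concentrations;
* plasma concentration-time tables from an analytic two-compartment
  truth, on the per-species sampling schedules;
* tissue concentration tables from a PBPK simulation at 5/30/90 min.

Measurement noise is multiplicative lognormal (median-one, CV default
10%, mimicking bioanalytical precision); with noise_cv = 0 every
generator's output fed through its matching estimator returns the true
parameters to numerical precision.  All randomness flows from the spec's
seed, so a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dedrick import TwoCompartmentFit, two_compartment_profile
from .ivive import DepletionAssay
from .pbpk import SAMPLING_SCHEDULES, DoseRegimen, PbpkModel, simulate

__all__ = [
    "SyntheticSpec",
    "DEPLETION_SCHEDULE_MIN",
    "DIALYSIS_CONCENTRATIONS_NG_ML",
    "PARTITION_CONCENTRATIONS_NG_ML",
    "TISSUE_SAMPLING_MIN",
    "gen_depletion_assay",
    "gen_binding_assays",
    "gen_plasma_ct",
    "gen_tissue_ct",
    "gen_allometric_family",
]

#: Incubation sampling times for depletion assays (min).
DEPLETION_SCHEDULE_MIN = (0.0, 10.0, 20.0, 30.0, 45.0, 60.0)

#: Equilibrium-dialysis test concentrations (ng/mL).
DIALYSIS_CONCENTRATIONS_NG_ML = (75.0, 150.0, 300.0, 600.0)

#: Blood-partitioning test concentrations (ng/mL).
PARTITION_CONCENTRATIONS_NG_ML = (100.0, 300.0, 900.0)

#: Tissue-distribution sacrifice times (min).
TISSUE_SAMPLING_MIN = (5.0, 30.0, 90.0)

_N_REPLICATES = 3


@dataclass(frozen=True)
class SyntheticSpec:
    """Seed, noise level, and sampling schedules for the generators."""

    seed: int = 0
    noise_cv: float = 0.10
    schedules: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(SAMPLING_SCHEDULES))

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for species, sched in self.schedules.items():
            if np.any(np.diff(sched) <= 0):
                raise ValueError(f"{species} schedule must be strictly increasing")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noise(rng: np.random.Generator, cv: float, size):
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(0.0, sigma, size)


def gen_depletion_assay(k_true: float, mic: float, fu_mic: float,
                        schedule: Sequence[float] = DEPLETION_SCHEDULE_MIN,
                        spec: SyntheticSpec = SyntheticSpec(),
                        c0: float = 100.0,
                        ) -> tuple[DepletionAssay, pd.DataFrame]:
    """First-order depletion C(t) = C0 exp(-k t), triplicate, with noise.

    Returns the assay built from the replicate means (the average
    concentration is what the log-linear fit uses) together with the raw
    replicate table (columns time_min, conc, replicate).
    """
    if k_true < 0:
        raise ValueError("k_true must be >= 0")
    t = np.asarray(schedule, dtype=float)
    rng = spec.rng()
    clean = c0 * np.exp(-k_true * t)
    reps = clean[None, :] * _noise(rng, spec.noise_cv, (_N_REPLICATES, t.size))
    frame = pd.DataFrame({
        "time_min": np.tile(t, _N_REPLICATES),
        "conc": reps.ravel(),
        "replicate": np.repeat(np.arange(1, _N_REPLICATES + 1), t.size),
    })
    assay = DepletionAssay(times=tuple(t), concentrations=tuple(reps.mean(axis=0)),
                           mic=mic, fu_mic=fu_mic)
    return assay, frame


def gen_binding_assays(fu_true: float, rb_true: float,
                       spec: SyntheticSpec = SyntheticSpec(),
                       ) -> dict[str, pd.DataFrame]:
    """Equilibrium-dialysis and blood-partitioning tables.

    'dialysis': donor/receiver pairs at the dialysis concentrations, whose
    receiver/donor ratio estimates fu.  'partition': blood/plasma pairs at
    the partitioning concentrations, whose ratio estimates Rb.  Triplicate
    with multiplicative noise on the measured (receiver/plasma) channel.
    """
    if not 0 < fu_true <= 1:
        raise ValueError("fu_true must lie in (0, 1]")
    if rb_true <= 0:
        raise ValueError("rb_true must be > 0")
    rng = spec.rng()

    rows = []
    for conc in DIALYSIS_CONCENTRATIONS_NG_ML:
        for rep in range(1, _N_REPLICATES + 1):
            receiver = conc * fu_true * _noise(rng, spec.noise_cv, None)
            rows.append({"nominal_ng_ml": conc, "replicate": rep,
                         "donor_ng_ml": conc, "receiver_ng_ml": float(receiver)})
    dialysis = pd.DataFrame(rows)

    rows = []
    for conc in PARTITION_CONCENTRATIONS_NG_ML:
        for rep in range(1, _N_REPLICATES + 1):
            plasma = conc / rb_true * _noise(rng, spec.noise_cv, None)
            rows.append({"nominal_ng_ml": conc, "replicate": rep,
                         "blood_ng_ml": conc, "plasma_ng_ml": float(plasma)})
    partition = pd.DataFrame(rows)
    return {"dialysis": dialysis, "partition": partition}


def gen_plasma_ct(truth: TwoCompartmentFit,
                  regimen: DoseRegimen | Sequence[DoseRegimen],
                  schedule: Sequence[float],
                  spec: SyntheticSpec = SyntheticSpec(),
                  ) -> pd.DataFrame:
    """Observed-style plasma table from an analytic two-compartment truth.

    Columns time_min, conc_ng_ml -- the layout every profile reader in the
    package consumes.
    """
    t = np.asarray(schedule, dtype=float)
    regimens = [regimen] if isinstance(regimen, DoseRegimen) else list(regimen)
    clean = two_compartment_profile(t, regimens, truth)
    noisy = clean * _noise(spec.rng(), spec.noise_cv, t.size)
    return pd.DataFrame({"time_min": t, "conc_ng_ml": noisy})


def gen_tissue_ct(model: PbpkModel,
                  regimen: DoseRegimen | Sequence[DoseRegimen],
                  times: Sequence[float] = TISSUE_SAMPLING_MIN,
                  spec: SyntheticSpec = SyntheticSpec(),
                  ) -> pd.DataFrame:
    """PBPK-simulated tissue concentrations at the sacrifice times.

    Long format: tissue, time_min, conc_ng_ml (adipose reported as the
    volume-weighted total of its two pools), with multiplicative noise.
    """
    t = np.asarray(times, dtype=float)
    res = simulate(model, regimen, t_end=float(t.max()), dt_out=float(t.max()),
                   t_eval=t)
    rng = spec.rng()
    rows = []
    tissues = [name for name in res.compartments
               if name not in ("adipose_vascular", "adipose_extravascular")]
    for tissue in tissues:
        clean = np.interp(t, res.times, res.compartments[tissue])
        noisy = clean * _noise(rng, spec.noise_cv, t.size)
        for ti, ci in zip(t, noisy):
            rows.append({"tissue": tissue, "time_min": float(ti),
                         "conc_ng_ml": float(ci)})
    return pd.DataFrame(rows)


def gen_allometric_family(normalized_truth: TwoCompartmentFit,
                          beta1: float, beta2: float,
                          species: Mapping[str, tuple[float, float]],
                          spec: SyntheticSpec = SyntheticSpec(),
                          ) -> dict[str, pd.DataFrame]:
    """Bolus profiles for an exactly allometric two-compartment family.

    ``species`` maps species name -> (body weight kg, bolus dose ug).
    Each species' rates are normalized_truth / W^(beta1-beta2) and central
    volume V1' * W^beta1, so CL scales exactly as W^beta2 and Vss as
    W^beta1 -- the closed-loop fixture for the scaling variants.
    """
    from .dedrick import rescale_fit  # local import: only needed here

    out = {}
    for name, (w, dose) in species.items():
        fit = rescale_fit(normalized_truth, w, beta1, beta2)
        schedule = spec.schedules.get(name, SAMPLING_SCHEDULES["rat"])
        out[name] = gen_plasma_ct(fit, DoseRegimen("iv_bolus", dose),
                                  schedule, spec=spec)
    return out
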