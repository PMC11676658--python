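"""In-vitro kinetics and in-vitro-to-in-vivo extrapolation (IVIVE).

The chain implemented here goes from a microsomal substrate-depletion time
course to whole-body organ blood clearances:

1. first-order depletion rate k from a log-linear fit of ln(C) vs t;
2. unbound microsomal intrinsic clearance CLint,u = k / (Mic * fu,mic),
   in uL/min/mg protein (Mic = microsomal protein concentration in the
   incubation, fu,mic = unbound fraction in the incubation);
3. whole-organ scaling CLint,in vivo,u = CLint,u * MPPGx * OW / 1000, in
   mL/min/kg (MPPGx = mg microsomal protein per g organ, OW = organ weight
   in g/kg);
4. well-stirred organ blood clearance
   CLb = Q * fu,b * CLint,in vivo,u / (Q + fu,b * CLint,in vivo,u),
   with fu,b = fu,p / Rb and Q the organ blood flow per kg;
5. fractional organ contributions f_i = CLb,i / sum(CLb) and extraction
   ratios ER = CLb / Q.

UGT isoform phenotyping uses the relative activity factor (RAF) method:
RAF = CLint,u(probe, microsomes) / CLint,u(probe, recombinant isoform),
and the isoform's fractional contribution in microsomes is
fm = RAF * CLint,u(drug, recombinant) / CLint,u(drug, microsomes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    ELIMINATING_ORGANS,
    SpeciesConfig,
    organ_weight,
)

__all__ = [
    "DepletionAssay",
    "ClearanceTable",
    "RafResult",
    "fit_depletion_rate",
    "clint_u",
    "scale_to_in_vivo",
    "well_stirred_cl",
    "organ_fractions",
    "extraction_ratio",
    "raf",
    "raf_contribution",
    "blood_plasma_ratio",
    "unbound_fraction",
    "mean_ratio",
    "build_clearance_table",
]


@dataclass(frozen=True)
class DepletionAssay:
    """A timed substrate-depletion incubation.

    times in min (strictly increasing, starting at 0), concentrations in
    any consistent unit (only ratios matter), mic = microsomal protein
    concentration in mg/mL, fu_mic = unbound fraction in the incubation.
    """

    times: tuple[float, ...]
    concentrations: tuple[float, ...]
    mic: float
    fu_mic: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size != c.size:
            raise ValueError("times and concentrations must have equal length")
        if t.size < 2:
            raise ValueError("a depletion assay needs at least 2 time points")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if self.mic <= 0:
            raise ValueError("mic must be > 0")
        if not 0 < self.fu_mic <= 1:
            raise ValueError("fu_mic must lie in (0, 1]")


def fit_depletion_rate(assay: DepletionAssay) -> float:
    """First-order depletion rate k (1/min).

    Ordinary least-squares slope of ln(C) versus t, negated.  A negative k
    (apparent concentration increase) is returned as-is with a warning so
    that screens can flag non-depleting isoforms.
    """
    t = np.asarray(assay.times, dtype=float)
    logc = np.log(np.asarray(assay.concentrations, dtype=float))
    slope = np.polyfit(t, logc, 1)[0]
    k = -float(slope)
    if k < 0:
        warnings.warn("negative depletion rate: substrate not depleting", stacklevel=2)
    return k


def clint_u(k: float, mic: float, fu_mic: float) -> float:
    """Unbound microsomal intrinsic clearance, uL/min/mg protein.

    CLint,u = k / (Mic * fu,mic); k in 1/min, Mic in mg/mL.  The division
    by Mic converts the first-order rate to a per-mg-protein clearance
    (mL/min/mg) and the result is expressed in uL/min/mg.
    """
    if mic <= 0:
        raise ValueError("mic must be > 0")
    if not 0 < fu_mic <= 1:
        raise ValueError("fu_mic must lie in (0, 1]")
    return 1000.0 * k / (mic * fu_mic)


def scale_to_in_vivo(clint_u_value: float, mppgx: float, ow: float) -> float:
    """Whole-organ unbound intrinsic clearance, mL/min/kg body weight.

    CLint,u (uL/min/mg) x MPPGx (mg/g) x OW (g/kg) / 1000.
    """
    if min(clint_u_value, mppgx, ow) < 0:
        raise ValueError("inputs must be >= 0")
    return clint_u_value * mppgx * ow / 1000.0


def well_stirred_cl(q: float, fu_b: float, clint_in_vivo_u: float) -> float:
    """Well-stirred organ blood clearance, mL/min/kg.

    CLb = Q * fu,b * CLint / (Q + fu,b * CLint); bounded above by the organ
    blood flow Q (both in mL/min/kg).
    """
    if q <= 0:
        raise ValueError("organ blood flow q must be > 0")
    x = fu_b * clint_in_vivo_u
    return q * x / (q + x)


def organ_fractions(cl_b: Mapping[str, float]) -> dict[str, float]:
    """Fractional contribution of each organ to total blood clearance."""
    if not cl_b:
        raise ValueError("need at least one organ")
    values = np.asarray(list(cl_b.values()), dtype=float)
    if np.any(values < 0):
        raise ValueError("blood clearances must be >= 0")
    total = values.sum()
    if total <= 0:
        raise ValueError("all organ clearances are zero")
    return {organ: float(v / total) for organ, v in zip(cl_b, values)}


def extraction_ratio(cl_b: float, q: float) -> float:
    """Organ extraction ratio ER = CLb / Q, in [0, 1)."""
    if q <= 0:
        raise ValueError("organ blood flow q must be > 0")
    if cl_b < 0 or cl_b > q:
        raise ValueError("cl_b must lie in [0, q] for a well-stirred organ")
    return cl_b / q


def raf(probe_clint_mic: float, probe_clint_rh: float) -> float:
    """Relative activity factor: probe clearance in microsomes over the
    same probe's clearance in the recombinant isoform."""
    if probe_clint_mic <= 0 or probe_clint_rh <= 0:
        raise ValueError("probe clearances must be > 0")
    return probe_clint_mic / probe_clint_rh


@dataclass(frozen=True)
class RafResult:
    """Isoform contribution via the RAF method.

    fm = RAF * rhCLint,u / CLint,u(microsomes); predicted_clint_u is the
    isoform's contribution RAF * rhCLint,u expressed on the microsomal
    scale (uL/min/mg).
    """

    raf: float
    fm: float
    predicted_clint_u: float


def raf_contribution(raf_value: float, rh_clint_u: float, mic_clint_u: float) -> RafResult:
    if mic_clint_u <= 0:
        raise ValueError("microsomal clint_u must be > 0")
    predicted = raf_value * rh_clint_u
    return RafResult(raf=raf_value, fm=predicted / mic_clint_u, predicted_clint_u=predicted)


# -- partitioning / binding utilities -----------------------------------


def blood_plasma_ratio(c_blood: float, c_plasma: float) -> float:
    """Blood-to-plasma concentration ratio Rb."""
    if c_blood <= 0 or c_plasma <= 0:
        raise ValueError("concentrations must be > 0")
    return c_blood / c_plasma


def unbound_fraction(c_receiver: float, c_donor: float) -> float:
    """Equilibrium-dialysis unbound fraction fu = receiver / donor."""
    if c_receiver <= 0 or c_donor <= 0:
        raise ValueError("concentrations must be > 0")
    return c_receiver / c_donor


def mean_ratio(numerators: Sequence[float], denominators: Sequence[float]) -> float:
    """Arithmetic mean of per-concentration ratios (multi-concentration
    Rb or fu determinations are averaged across tested concentrations)."""
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    if num.size != den.size or num.size == 0:
        raise ValueError("need equal, non-empty numerator/denominator series")
    if np.any(num <= 0) or np.any(den <= 0):
        raise ValueError("concentrations must be > 0")
    return float(np.mean(num / den))


# -- clearance table ----------------------------------------------------


@dataclass(frozen=True)
class ClearanceTable:
    """Per-organ, per-pathway clearances for one species.

    clint_u: organ -> pathway -> uL/min/mg.
    clint_in_vivo_u: organ -> pathway -> mL/min/kg (Eq 4 scaled).
    organ_clint_in_vivo_u: organ -> summed mL/min/kg.
    cl_b: organ -> well-stirred blood clearance, mL/min/kg.
    f_cl: organ -> fraction of total blood clearance.
    er: organ -> extraction ratio.
    cl_b_tot: total blood clearance, mL/min/kg.
    """

    species: str
    clint_u: Mapping[str, Mapping[str, float]]
    clint_in_vivo_u: Mapping[str, Mapping[str, float]]
    organ_clint_in_vivo_u: Mapping[str, float]
    cl_b: Mapping[str, float]
    f_cl: Mapping[str, float]
    er: Mapping[str, float]
    cl_b_tot: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table mirroring the per-species enzyme-kinetics layout."""
        rows = []
        for organ, pathways in self.clint_u.items():
            for pathway, value in pathways.items():
                rows.append({
                    "species": self.species,
                    "organ": organ,
                    "pathway": pathway,
                    "clint_u_ul_min_mg": value,
                    "clint_in_vivo_u_ml_min_kg": self.clint_in_vivo_u[organ][pathway],
                    "organ_total_clint_in_vivo_u_ml_min_kg": self.organ_clint_in_vivo_u[organ],
                    "cl_b_ml_min_kg": self.cl_b.get(organ, 0.0),
                    "f_cl": self.f_cl.get(organ, 0.0),
                    "extraction_ratio": self.er.get(organ, float("nan")),
                })
        return pd.DataFrame(rows)


_MPPG_BY_ORGAN = {"liver": "mppgl", "kidney": "mppgk", "intestine": "mppgi"}


def build_clearance_table(cfg: SpeciesConfig) -> ClearanceTable:
    """Assemble the full IVIVE chain for one species configuration.

    Organs whose summed microsomal clearance is zero (e.g. dog intestine,
    where no glucuronidation is observed) carry zero blood clearance and
    are excluded from the fractional contributions.
    """
    phys = cfg.physiology
    clint_in_vivo: dict[str, dict[str, float]] = {}
    organ_totals: dict[str, float] = {}
    cl_b: dict[str, float] = {}
    er: dict[str, float] = {}
    for organ in ELIMINATING_ORGANS:
        pathways = cfg.clearances.clint_u.get(organ, {})
        mppgx = getattr(phys, _MPPG_BY_ORGAN[organ])
        ow = organ_weight(phys, organ)
        clint_in_vivo[organ] = {
            p: scale_to_in_vivo(v, mppgx, ow) for p, v in pathways.items()
        }
        organ_totals[organ] = sum(clint_in_vivo[organ].values())
        q = phys.flow_per_kg(organ)
        cl_b[organ] = well_stirred_cl(q, phys.fu_b, organ_totals[organ])
        er[organ] = extraction_ratio(cl_b[organ], q)
    active = {o: v for o, v in cl_b.items() if v > 0}
    fractions = organ_fractions(active) if active else {}
    return ClearanceTable(
        species=phys.species,
        clint_u={o: dict(p) for o, p in cfg.clearances.clint_u.items()},
        clint_in_vivo_u=clint_in_vivo,
        organ_clint_in_vivo_u=organ_totals,
        cl_b=cl_b,
        f_cl={o: fractions.get(o, 0.0) for o in cl_b},
        er=er,
        cl_b_tot=float(sum(cl_b.values())),
    )
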