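"""Species physiology and drug-parameter registry.

Holds the whole-body physiology (tissue volumes, blood flows,
tissue-to-plasma partition coefficients), microsomal scaling factors
(MPPGL/MPPGK/MPPGI), blood partitioning (Rb, fu,p), and the drug-specific
microsomal intrinsic clearances for each of the three supported species
(rat 0.25 kg, dog 8.5 kg, human 70 kg).

Canonical internal units throughout the package: min, mL, kg body weight,
ng/mL for concentrations and ng for amounts.  Loaders validate flow
conservation (cardiac output equals the sum of systemic arterial flows,
hepatic outflow equals hepatic-arterial plus splanchnic inflows) before a
physiology object is handed to the model builder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "PERFUSED_TISSUES",
    "BLOOD_SPACES",
    "ELIMINATING_ORGANS",
    "SPECIES",
    "PhysiologyError",
    "TissueSpec",
    "SpeciesPhysiology",
    "DrugClearanceParams",
    "SpeciesConfig",
    "load_physiology",
    "load_species",
    "organ_weight",
    "registry_frame",
]

#: Tissues carrying a blood flow and a partition coefficient.
PERFUSED_TISSUES = (
    "lung", "heart", "brain", "muscle", "adipose", "skin", "kidney",
    "spleen", "stomach", "liver", "intestine", "rest_of_body",
)

#: Blood spaces carry volume only.
BLOOD_SPACES = ("vein", "artery")

#: Organs with metabolic elimination (UGT and/or CYP pathways).
ELIMINATING_ORGANS = ("liver", "kidney", "intestine")

#: Tissues whose venous outflow drains into the portal circulation (liver inflow).
PORTAL_TISSUES = ("spleen", "stomach", "intestine")

SPECIES = ("rat", "dog", "human")

#: Relative tolerance for the flow-conservation identities.
FLOW_BALANCE_RTOL = 0.005

#: Tissue density used for volume <-> weight conversion (mL and g used
#: interchangeably for soft tissue).
TISSUE_DENSITY_G_PER_ML = 1.0


class PhysiologyError(ValueError):
    """Raised when a physiology/drug configuration violates an invariant."""


@dataclass(frozen=True)
class TissueSpec:
    """One tissue row: volume (mL), absolute blood flow (mL/min), K_t:pl."""

    name: str
    volume: float
    blood_flow: float = 0.0
    k_tp: float | None = None

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise PhysiologyError(f"{self.name}: volume must be > 0, got {self.volume}")
        if self.blood_flow < 0:
            raise PhysiologyError(f"{self.name}: blood_flow must be >= 0")
        if self.name in PERFUSED_TISSUES:
            if self.k_tp is None or self.k_tp <= 0:
                raise PhysiologyError(f"{self.name}: perfused tissue needs k_tp > 0")
        elif self.name in BLOOD_SPACES:
            if self.k_tp is not None:
                raise PhysiologyError(f"{self.name}: blood space carries no k_tp")
        else:
            raise PhysiologyError(f"unknown tissue name {self.name!r}")


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Validated whole-body physiology for one species.

    ``organ_weights`` are the g/kg organ weights used for microsomal
    scaling; organs without an entry default to tissue volume x density
    divided by body weight.
    """

    species: str
    body_weight: float  # kg
    tissues: tuple[TissueSpec, ...]
    liver_arterial_flow: float  # mL/min, the hepatic-artery inflow
    mppgl: float
    mppgk: float
    mppgi: float
    r_b: float
    fu_p: float
    adipose_v1: float  # mL, vascular sub-volume
    adipose_v2: float  # mL, extravascular sub-volume
    organ_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise PhysiologyError("duplicate tissue entries")
        for required in (*PERFUSED_TISSUES, *BLOOD_SPACES):
            if required not in names:
                raise PhysiologyError(f"missing tissue {required!r}")
        if self.body_weight <= 0:
            raise PhysiologyError("body_weight must be > 0")
        if not 0 < self.fu_p <= 1:
            raise PhysiologyError(f"fu_p must lie in (0, 1], got {self.fu_p}")
        if self.r_b <= 0:
            raise PhysiologyError("r_b must be > 0")
        for name in ("mppgl", "mppgk", "mppgi"):
            if getattr(self, name) <= 0:
                raise PhysiologyError(f"{name} must be > 0")

        adipose = self.tissue("adipose")
        if abs(self.adipose_v1 + self.adipose_v2 - adipose.volume) > 1e-6 * adipose.volume:
            raise PhysiologyError(
                "adipose_v1 + adipose_v2 must equal the adipose volume "
                f"({self.adipose_v1} + {self.adipose_v2} != {adipose.volume})"
            )

        co = self.cardiac_output
        systemic = sum(
            self.tissue(t).blood_flow
            for t in PERFUSED_TISSUES
            if t not in ("lung", "liver")
        ) + self.liver_arterial_flow
        if abs(systemic - co) > FLOW_BALANCE_RTOL * co:
            raise PhysiologyError(
                f"cardiac output {co} does not balance systemic flows {systemic:.4g}"
            )

        hepatic_in = self.liver_arterial_flow + sum(
            self.tissue(t).blood_flow for t in PORTAL_TISSUES
        )
        hepatic_out = self.tissue("liver").blood_flow
        if abs(hepatic_in - hepatic_out) > FLOW_BALANCE_RTOL * hepatic_out:
            raise PhysiologyError(
                f"hepatic outflow {hepatic_out} does not balance inflows {hepatic_in:.4g}"
            )

    # -- lookups ---------------------------------------------------------

    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.name == name:
                return t
        raise PhysiologyError(f"unknown tissue {name!r}")

    @property
    def cardiac_output(self) -> float:
        """Total blood flow Q_total (mL/min) = lung blood flow."""
        return self.tissue("lung").blood_flow

    @property
    def fu_b(self) -> float:
        """Unbound fraction in blood, fu,b = fu,p / Rb."""
        return self.fu_p / self.r_b

    def flow_per_kg(self, organ: str) -> float:
        """Organ blood flow in mL/min/kg body weight."""
        return self.tissue(organ).blood_flow / self.body_weight

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = {
            t.name: {
                k: v
                for k, v in (("volume_ml", t.volume),
                             ("blood_flow_ml_min", t.blood_flow),
                             ("k_tp", t.k_tp))
                if not (t.name in BLOOD_SPACES and k in ("blood_flow_ml_min", "k_tp"))
            }
            for t in self.tissues
        }
        d["body_weight_kg"] = d.pop("body_weight")
        d["liver_arterial_flow_ml_min"] = d.pop("liver_arterial_flow")
        d["adipose_v1_ml"] = d.pop("adipose_v1")
        d["adipose_v2_ml"] = d.pop("adipose_v2")
        d["organ_weights_g_per_kg"] = dict(d.pop("organ_weights"))
        return d


@dataclass(frozen=True)
class DrugClearanceParams:
    """Drug-specific microsomal clearances and adipose permeability.

    ``clint_u`` maps organ -> pathway -> unbound microsomal intrinsic
    clearance in uL/min/mg protein.  ``ps`` is the adipose
    permeability-surface product in mL/min for this species, or ``None``
    when it should be obtained by calibration (rat) or body-weight scaling
    from the calibrated rat value (dog/human).
    """

    clint_u: Mapping[str, Mapping[str, float]]
    ps: float | None = None

    def __post_init__(self) -> None:
        for organ, pathways in self.clint_u.items():
            if organ not in ELIMINATING_ORGANS:
                raise PhysiologyError(f"clearance organ {organ!r} not in {ELIMINATING_ORGANS}")
            for pathway, value in pathways.items():
                if value < 0:
                    raise PhysiologyError(f"{organ}/{pathway}: clint_u must be >= 0")
        if self.ps is not None and self.ps <= 0:
            raise PhysiologyError("ps must be > 0 when given")

    def organ_total(self, organ: str) -> float:
        """Summed microsomal CLint,u (uL/min/mg) across pathways for one organ."""
        return float(sum(self.clint_u.get(organ, {}).values()))


@dataclass(frozen=True)
class SpeciesConfig:
    physiology: SpeciesPhysiology
    clearances: DrugClearanceParams


# -- loading ------------------------------------------------------------


def _physiology_from_dict(cfg: Mapping) -> SpeciesPhysiology:
    try:
        tissues = tuple(
            TissueSpec(
                name=name,
                volume=float(spec["volume_ml"]),
                blood_flow=float(spec.get("blood_flow_ml_min", 0.0)),
                k_tp=(float(spec["k_tp"]) if "k_tp" in spec and spec["k_tp"] is not None
                      else None),
            )
            for name, spec in cfg["tissues"].items()
        )
        return SpeciesPhysiology(
            species=cfg["species"],
            body_weight=float(cfg["body_weight_kg"]),
            tissues=tissues,
            liver_arterial_flow=float(cfg["liver_arterial_flow_ml_min"]),
            mppgl=float(cfg["mppgl"]),
            mppgk=float(cfg["mppgk"]),
            mppgi=float(cfg["mppgi"]),
            r_b=float(cfg["r_b"]),
            fu_p=float(cfg["fu_p"]),
            adipose_v1=float(cfg["adipose_v1_ml"]),
            adipose_v2=float(cfg["adipose_v2_ml"]),
            organ_weights=dict(cfg.get("organ_weights_g_per_kg", {})),
        )
    except KeyError as exc:
        raise PhysiologyError(f"missing physiology field {exc.args[0]!r}") from exc


def load_physiology(config: str | Path | Mapping) -> SpeciesPhysiology:
    """Build a validated :class:`SpeciesPhysiology` from JSON text, a path,
    or an already-parsed mapping."""
    return _physiology_from_dict(_as_mapping(config))


def _as_mapping(config: str | Path | Mapping) -> Mapping:
    if isinstance(config, Mapping):
        return config
    if isinstance(config, Path) or (isinstance(config, str) and "\n" not in config
                                    and not config.lstrip().startswith("{")):
        path = Path(config)
        if path.suffix == ".json" and path.exists():
            return json.loads(path.read_text())
        # fall through: treat as a shipped species name
        if isinstance(config, str) and config in SPECIES:
            ref = resources.files("spt07a_pbpk.data").joinpath(f"{config}.json")
            return json.loads(ref.read_text())
        raise PhysiologyError(f"no such config file or species {config!r}")
    return json.loads(str(config))


def load_species(config: str | Path | Mapping) -> SpeciesConfig:
    """Load physiology together with the drug clearance block.

    ``config`` is a shipped species name ("rat", "dog", "human"), a path to
    a JSON file in the same layout, JSON text, or a mapping.
    """
    cfg = _as_mapping(config)
    phys = _physiology_from_dict(cfg)
    cl = cfg.get("clearances", {})
    clearances = DrugClearanceParams(
        clint_u={o: dict(p) for o, p in cl.get("clint_u_ul_min_mg", {}).items()},
        ps=cl.get("ps_ml_min"),
    )
    for organ in ELIMINATING_ORGANS:
        if organ not in clearances.clint_u:
            raise PhysiologyError(f"missing clearance entry for {organ!r} (use 0 for none)")
    return SpeciesConfig(physiology=phys, clearances=clearances)


def organ_weight(phys: SpeciesPhysiology, organ: str) -> float:
    """Organ weight (g/kg body weight) used for microsomal scaling.

    Uses the configured per-species override when present; otherwise falls
    back to tissue volume x density / body weight.  Only the eliminating
    organs (liver, kidney, intestine) are supported.
    """
    if organ not in ELIMINATING_ORGANS:
        raise PhysiologyError(f"organ_weight: unsupported organ {organ!r}")
    if organ in phys.organ_weights:
        return float(phys.organ_weights[organ])
    return phys.tissue(organ).volume * TISSUE_DENSITY_G_PER_ML / phys.body_weight


def registry_frame(configs: list[SpeciesConfig] | None = None) -> pd.DataFrame:
    """Tidy per-tissue registry (one row per species x tissue) for CSV export."""
    if configs is None:
        configs = [load_species(s) for s in SPECIES]
    rows = []
    for cfg in configs:
        phys = cfg.physiology
        for t in phys.tissues:
            rows.append({
                "species": phys.species,
                "tissue": t.name,
                "volume_ml": t.volume,
                "blood_flow_ml_min": t.blood_flow if t.name not in BLOOD_SPACES else float("nan"),
                "k_tp": t.k_tp if t.k_tp is not None else float("nan"),
            })
    return pd.DataFrame(rows)
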