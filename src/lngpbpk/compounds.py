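"""Drug-specific parameter sets: victims (LNG, EE), perpetrators, formulations.

The packaged configs hold the final published LNG and EE parameter sets
field-for-field, plus reduced one-compartment perpetrator models with their
CYP3A4/SHBG interaction constants.  Everything is validated with pydantic;
concentrations are normalized to µmol/L, permeabilities to cm/min.
"""

from __future__ import annotations

import importlib.resources
import math
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "BindingSpec",
    "Formulation",
    "InteractionSpec",
    "PerpetratorPK",
    "CompoundParameters",
    "load_compound",
    "load_interaction",
    "list_perpetrators",
    "dissolution_rate_constant",
]

_VICTIM_FILES = {"LNG": "lng.yaml", "EE": "ee.yaml"}


class Mechanism(str, Enum):
    competitive = "competitive"
    mbi = "mbi"
    induction = "induction"


class BindingSpec(BaseModel):
    """Kinetic plasma-protein binding partner (albumin or SHBG)."""

    model_config = ConfigDict(frozen=True)

    partner: str  # "albumin" | "shbg"
    kd: float = Field(gt=0)  # µmol/L
    koff: float = Field(gt=0)  # 1/min

    @property
    def kon(self) -> float:
        """Association rate constant, 1/(µmol/L)/min."""
        return self.koff / self.kd


class Formulation(BaseModel):
    """Oral immediate-release formulation (first-order dissolution with lag)."""

    model_config = ConfigDict(frozen=True)

    dose_mg: float = Field(gt=0)
    route: str = "oral"  # "oral" | "iv_bolus"
    t80_dissolution_min: Optional[float] = None
    lag_time_min: float = 0.0

    @model_validator(mode="after")
    def _check(self):
        if self.route == "oral" and (
            self.t80_dissolution_min is None or self.t80_dissolution_min <= 0
        ):
            raise ValueError("oral formulations require t80_dissolution_min > 0")
        return self

    @property
    def dissolution_rate_1_min(self) -> float:
        return dissolution_rate_constant(self.t80_dissolution_min)


class InteractionSpec(BaseModel):
    """One perpetrator mechanism acting on CYP3A4 or SHBG synthesis."""

    model_config = ConfigDict(frozen=True)

    perpetrator: str = ""
    target: str  # "cyp3a4" | "shbg_synthesis"
    mechanism: Mechanism
    ki: Optional[float] = None  # µmol/L, competitive
    kinact: Optional[float] = None  # 1/h, MBI
    ki_mbi: Optional[float] = None  # µmol/L, MBI half-maximal inactivation
    emax_fold: Optional[float] = None  # maximal fold-change of synthesis
    ec50: Optional[float] = None  # µmol/L, induction
    variant: Optional[str] = None  # e.g. SHBG "net_lng_ee" vs "ee_alone"

    @model_validator(mode="after")
    def _check(self):
        m = self.mechanism
        if m == Mechanism.competitive and not (self.ki and self.ki > 0):
            raise ValueError("competitive mechanism requires ki > 0")
        if m == Mechanism.mbi and not (
            self.kinact and self.kinact > 0 and self.ki_mbi and self.ki_mbi > 0
        ):
            raise ValueError("mbi mechanism requires kinact > 0 and ki_mbi > 0")
        if m == Mechanism.induction and not (
            self.emax_fold and self.emax_fold >= 1 and self.ec50 and self.ec50 > 0
        ):
            raise ValueError("induction mechanism requires emax_fold >= 1, ec50 > 0")
        return self


class PerpetratorPK(BaseModel):
    """Reduced one-compartment PK block for perpetrator dosing."""

    model_config = ConfigDict(frozen=True)

    ka_1_h: float = Field(gt=0)
    v_l: float = Field(gt=0)
    cl_l_h: float = Field(gt=0)
    f_oral: float = Field(gt=0, le=1)
    fu: float = Field(gt=0, le=1)


class CompoundParameters(BaseModel):
    """Full drug parameter set for a victim or perpetrator compound."""

    model_config = ConfigDict(frozen=True)

    name: str
    molecular_weight: float = Field(gt=0)  # g/mol
    lipophilicity_logp: Optional[float] = None
    aqueous_solubility: Optional[float] = Field(default=None, gt=0)  # mg/L
    fassif_solubility: Optional[float] = Field(default=None, gt=0)  # mg/L
    binding_specs: tuple[BindingSpec, ...] = ()
    nonspecific_unbound_fraction: Optional[float] = Field(default=None, gt=0, le=1)
    cyp3a4_specific_clearance: Optional[float] = Field(default=None, ge=0)  # µL/min/pmol
    other_hepatic_clearance: Optional[float] = Field(default=None, ge=0)  # L/h/kg
    fm_cyp3a4: Optional[float] = Field(default=None, gt=0, lt=1)
    total_hepatic_clearance: Optional[float] = Field(default=None, ge=0)  # mL/min/kg
    specific_intestinal_permeability: Optional[float] = Field(default=None, ge=0)  # cm/min
    specific_organ_permeability: Optional[float] = Field(default=None, ge=0)  # cm/min
    formulations: tuple[Formulation, ...] = ()
    interactions: tuple[InteractionSpec, ...] = ()
    perpetrator_pk: Optional[PerpetratorPK] = None

    @model_validator(mode="after")
    def _clearance_route(self):
        specific = self.cyp3a4_specific_clearance is not None
        total = self.total_hepatic_clearance is not None
        if specific and total:
            raise ValueError(
                f"{self.name}: specify either the CYP3A4-specific + other hepatic "
                "clearance pair or a total hepatic clearance, not both"
            )
        return self

    def binding(self, partner: str) -> Optional[BindingSpec]:
        for spec in self.binding_specs:
            if spec.partner == partner:
                return spec
        return None

    def formulation_for_dose(self, dose_mg: float) -> Formulation:
        for f in self.formulations:
            if math.isclose(f.dose_mg, dose_mg, rel_tol=1e-9):
                return f
        if self.formulations:  # nearest packaged strength
            return min(self.formulations, key=lambda f: abs(f.dose_mg - dose_mg))
        raise ValueError(f"{self.name}: no packaged oral formulation")


def dissolution_rate_constant(t80_min: float) -> float:
    """First-order dissolution constant k with 1 - exp(-k*T80) = 0.80.

    The published dissolution parameterization gives only the time to 80%
    dissolved; a single-parameter first-order mapping k = ln(5)/T80 is
    exact at that defining point.
    """
    if t80_min is None or t80_min <= 0:
        raise ValueError("t80 must be positive")
    return math.log(5.0) / t80_min


def _data_text(fname: str) -> str:
    return importlib.resources.files("lngpbpk.data").joinpath(fname).read_text()


def _victim_from_dict(raw: dict) -> CompoundParameters:
    forms = []
    for block in raw.pop("formulations", []):
        for dose in block["doses_mg"]:
            forms.append(
                Formulation(
                    dose_mg=dose,
                    route="oral",
                    t80_dissolution_min=block["t80_dissolution_min"],
                    lag_time_min=block.get("lag_time_min", 0.0),
                )
            )
    binding = tuple(BindingSpec(**b) for b in raw.pop("binding", []))
    inter = tuple(
        InteractionSpec(perpetrator=raw["name"], **i)
        for i in raw.pop("interactions", [])
    )
    return CompoundParameters(
        **raw, formulations=tuple(forms), binding_specs=binding, interactions=inter
    )


def _perpetrator_from_dict(name: str, raw: dict) -> CompoundParameters:
    inter = tuple(
        InteractionSpec(perpetrator=name, **i) for i in raw.get("interactions", [])
    )
    return CompoundParameters(
        name=name,
        molecular_weight=raw["molecular_weight"],
        perpetrator_pk=PerpetratorPK(**raw["pk"]),
        interactions=inter,
    )


def load_compound(name_or_path: str | Path) -> CompoundParameters:
    """Load a packaged compound ("LNG", "EE", perpetrator name) or a YAML file."""
    key = str(name_or_path)
    if key in _VICTIM_FILES:
        return _victim_from_dict(yaml.safe_load(_data_text(_VICTIM_FILES[key])))
    perps = yaml.safe_load(_data_text("perpetrators.yaml"))
    if key in perps:
        return _perpetrator_from_dict(key, perps[key])
    path = Path(name_or_path)
    if path.exists():
        raw = yaml.safe_load(path.read_text())
        return _victim_from_dict(raw)
    raise KeyError(f"unknown compound {name_or_path!r}")


def list_perpetrators() -> list[str]:
    return sorted(yaml.safe_load(_data_text("perpetrators.yaml")))


def load_interaction(perpetrator: str) -> list[InteractionSpec]:
    """All interaction mechanisms exerted by a packaged perpetrator (or EE)."""
    if perpetrator == "EE":
        return list(load_compound("EE").interactions)
    perps = yaml.safe_load(_data_text("perpetrators.yaml"))
    if perpetrator not in perps:
        raise KeyError(
            f"unknown perpetrator {perpetrator!r}; packaged: {sorted(perps)} + ['EE']"
        )
    return list(load_compound(perpetrator).interactions)
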