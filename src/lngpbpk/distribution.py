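"""Tissue partitioning (Rodgers–Rowland) and plasma protein binding.

Two pieces of disposition physics live here:

* the competitive mass-action equilibrium of a steroid between free plasma
  water, albumin (high capacity, treated as non-depletable) and SHBG (low
  capacity, explicitly depletable), solved in closed form; and
* tissue-to-plasma partition coefficients for neutral lipophilic compounds
  per the Rodgers–Rowland composition scheme, with the vegetable-oil
  correction for adipose neutral lipid.

Both LNG and EE are treated as neutral steroids: no ionized-species terms.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compounds import CompoundParameters

__all__ = [
    "BindingState",
    "composition_table",
    "equilibrium_binding",
    "dilute_fu",
    "kpu_rodgers_rowland",
    "kp_rodgers_rowland",
    "permeability_surface_product",
    "ORGAN_EXCHANGE_AREA_CM2_PER_ML",
]

#: capillary/interfacial exchange area per mL of tissue used for the
#: permeability-surface-area product (single packaged constant; exchange is
#: perfusion-limited for both steroids at their published permeabilities).
ORGAN_EXCHANGE_AREA_CM2_PER_ML = 100.0

_COMP_CACHE: pd.DataFrame | None = None


def composition_table() -> pd.DataFrame:
    """Packaged fractional tissue composition keyed by organ."""
    global _COMP_CACHE
    if _COMP_CACHE is None:
        p = importlib.resources.files("lngpbpk.data").joinpath("tissue_composition.tsv")
        with importlib.resources.as_file(p) as fp:
            df = pd.read_csv(fp, sep="\t", comment="#").set_index("organ")
        bad = df[(df < 0).any(axis=1) | (df.sum(axis=1) > 1.0)]
        if len(bad):
            raise ValueError(f"invalid composition rows: {list(bad.index)}")
        _COMP_CACHE = df
    return _COMP_CACHE.copy()


@dataclass(frozen=True)
class BindingState:
    """Partition of total plasma ligand across free, albumin and SHBG pools."""

    free: float  # nmol/L
    albumin_bound: float  # nmol/L
    shbg_bound: float  # nmol/L
    fu: float  # fraction

    @property
    def total(self) -> float:
        return self.free + self.albumin_bound + self.shbg_bound


def dilute_fu(albumin_um: float, shbg_nm: float, kd_alb_um: float, kd_shbg_um: float) -> float:
    """Trace-ligand unbound fraction 1/(1 + Alb/Kd_alb + SHBG/Kd_shbg)."""
    return 1.0 / (1.0 + albumin_um / kd_alb_um + shbg_nm / (kd_shbg_um * 1e3))


def equilibrium_binding(
    total_ligand_nm: float,
    albumin_um: float,
    shbg_sites_nm: float,
    kd_alb_um: float,
    kd_shbg_um: float,
) -> BindingState:
    """Exact coupled albumin/SHBG binding equilibrium.

    Albumin (µmol/L, ~10^5-fold excess over nanomolar steroid) is treated
    as non-depletable; SHBG sites (nmol/L) are depletable and saturate at
    high ligand.  The free concentration solves the quadratic

        (1+a) F^2 + [(1+a) Kds + S - T] F - T Kds = 0,

    with a = Alb/Kd_alb, S total SHBG sites, Kds the SHBG dissociation
    constant (nmol/L) and T total ligand.  At T = 0 the unbound fraction is
    defined by its continuous dilute limit.
    """
    if min(total_ligand_nm, albumin_um, shbg_sites_nm) < 0:
        raise ValueError("concentrations must be non-negative")
    a = albumin_um / kd_alb_um
    kds = kd_shbg_um * 1e3  # nmol/L
    t = total_ligand_nm
    if t == 0.0:
        return BindingState(0.0, 0.0, 0.0, dilute_fu(albumin_um, shbg_sites_nm, kd_alb_um, kd_shbg_um))
    b = (1.0 + a) * kds + shbg_sites_nm - t
    # positive root of (1+a) x^2 + b x - t*kds = 0
    disc = b * b + 4.0 * (1.0 + a) * t * kds
    free = (-b + math.sqrt(disc)) / (2.0 * (1.0 + a))
    shbg_bound = shbg_sites_nm * free / (kds + free)
    alb_bound = a * free
    return BindingState(free, alb_bound, shbg_bound, free / t)


def kpu_rodgers_rowland(
    compound: CompoundParameters, comp: pd.DataFrame | None = None
) -> dict[str, float]:
    """Tissue-to-unbound-plasma partition coefficients (neutral scheme).

    Kpu = f_EW + f_IW + P * f_NL + (0.3 P + 0.7) * f_NP, with the
    vegetable-oil:water partition standing in for octanol in adipose
    (log P_vo = 1.115 log P - 1.35).
    """
    logp = compound.lipophilicity_logp
    if logp is None:
        raise ValueError(f"{compound.name}: lipophilicity required for partitioning")
    if comp is None:
        comp = composition_table()
    p_ow = 10.0**logp
    p_vow = 10.0 ** (1.115 * logp - 1.35)
    out: dict[str, float] = {}
    for organ, row in comp.iterrows():
        p_nl = p_vow if organ == "adipose" else p_ow
        out[organ] = (
            row["f_ew"]
            + row["f_iw"]
            + p_nl * row["f_nl"]
            + (0.3 * p_ow + 0.7) * row["f_np"]
        )
    return out


def kp_rodgers_rowland(
    compound: CompoundParameters,
    comp: pd.DataFrame | None = None,
    fu_plasma: float = 1.0,
) -> dict[str, float]:
    """Tissue-to-total-plasma partition coefficients: Kp = fu_plasma * Kpu."""
    if not 0 < fu_plasma <= 1:
        raise ValueError("fu_plasma must be in (0, 1]")
    return {o: fu_plasma * kpu for o, kpu in kpu_rodgers_rowland(compound, comp).items()}


def permeability_surface_product(p_spec_cm_min: float, organ_volume_l: float) -> float:
    """Permeability-surface-area product in L/h for one organ.

    PS = p_spec [cm/min] x interfacial area, with the packaged area constant
    of 100 cm^2 per mL tissue.  Doubling p_spec doubles PS; p_spec = 0 blocks
    vascular-tissue exchange entirely.
    """
    if p_spec_cm_min < 0:
        raise ValueError("p_spec must be >= 0")
    area_cm2 = ORGAN_EXCHANGE_AREA_CM2_PER_ML * organ_volume_l * 1e3
    return p_spec_cm_min * 60.0 * area_cm2 * 1e-3  # cm^3/h -> L/h
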