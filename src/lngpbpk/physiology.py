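"""Virtual female physiology: reference individual, BMI scaling, populations.

The reference woman is an ICRP-89-style 60 kg / 163 cm adult female whose
organ volumes, blood flows and tissue densities ship with the package as a
delimited table.  Obesity is handled by allocating the excess body mass over
the reference (at the same height) to adipose, skin and muscle, and scaling
cardiac output with body surface area.  Population sampling draws a BMI for
each woman first; the BMI-implied body weight positions her on the
deterministic scaling curve, and independent lognormal variability is then
applied on top (volumes, flows, enzyme abundance, binding-protein
baselines), so that all size-related parameters remain correlated through
body weight.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Population",
    "build_reference_individual",
    "scale_by_bmi",
    "sample_population",
    "reference_table",
    "REFERENCE_HEIGHT_CM",
    "REFERENCE_BMI",
    "SHBG_BASELINE_NORMAL_NM",
    "SHBG_BASELINE_OBESE_NM",
    "ALBUMIN_PLASMA_UM",
    "CYP3A4_LIVER_UM",
]

REFERENCE_HEIGHT_CM = 163.0
REFERENCE_WEIGHT_KG = 60.0
REFERENCE_BMI = REFERENCE_WEIGHT_KG / (REFERENCE_HEIGHT_CM / 100.0) ** 2
REFERENCE_CARDIAC_OUTPUT_L_H = 300.0  # whole blood, rest
REFERENCE_PLASMA_VOLUME_L = 2.4
REFERENCE_HEMATOCRIT = 0.39

#: plasma albumin, µmol/L (~43 g/L at 66.5 kDa)
ALBUMIN_PLASMA_UM = 650.0
#: SHBG baseline in normal-BMI women, nmol/L
SHBG_BASELINE_NORMAL_NM = 55.4
#: SHBG baseline used for the exploratory obese scenario, nmol/L
SHBG_BASELINE_OBESE_NM = 27.6
#: hepatic CYP3A4 concentration, µmol per L liver
CYP3A4_LIVER_UM = 4.32
#: total gut-wall CYP3A4 relative to total hepatic CYP3A4
GUT_CYP3A4_REL = 0.01

# mass fractions receiving the excess body mass over the reference
_EXCESS_MASS_SPLIT = {"adipose": 0.75, "muscle": 0.15, "skin": 0.10}

# Default sampling CVs (lognormal), by parameter class.  The enzyme CVs
# (CYP3A4 abundance and the independent phase-II pathway) are calibrated so
# the *predicted* interindividual clearance variability of the assembled
# model lands near the ~35% CV the analysis reports as an output; 60% is
# within the wide range published for hepatic CYP3A4 protein abundance.
DEFAULT_CV = {
    "organ_volume": 0.10,
    "organ_flow": 0.15,
    "cyp3a4": 0.60,
    "phase2": 0.60,
    "shbg": 0.30,
    "albumin": 0.05,
}


def _data_path(name: str):
    return importlib.resources.files("lngpbpk.data").joinpath(name)


_REFERENCE_CACHE: pd.DataFrame | None = None


def reference_table() -> pd.DataFrame:
    """Packaged reference-female organ table (volumes L, flow fractions, densities)."""
    global _REFERENCE_CACHE
    if _REFERENCE_CACHE is None:
        with importlib.resources.as_file(_data_path("physiology_female.tsv")) as p:
            _REFERENCE_CACHE = pd.read_csv(p, sep="\t", comment="#").set_index("organ")
    return _REFERENCE_CACHE.copy()


@dataclass(frozen=True)
class Individual:
    """One virtual woman: anatomy, flows, enzyme and binding-protein baselines."""

    age: float  # years
    body_weight: float  # kg
    height: float  # cm
    bmi: float  # kg/m^2
    organ_volumes: dict[str, float]  # L
    organ_blood_flows: dict[str, float]  # whole-blood, L/h
    cardiac_output: float  # L/h
    hematocrit: float
    plasma_volume: float  # L
    liver_cyp3a4_conc: float  # µmol per L liver
    gut_cyp3a4_rel: float  # fraction of total hepatic CYP3A4 amount
    albumin_plasma: float  # µmol/L
    shbg_baseline_plasma: float  # nmol/L
    #: lognormal individual scale on the non-CYP3A4 (phase II) hepatic pathway;
    #: independent of CYP3A4 abundance
    phase2_clearance_scale: float = 1.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.organ_volumes.values()):
            raise ValueError("all organ volumes must be positive")
        if any(q <= 0 for q in self.organ_blood_flows.values()):
            raise ValueError("all organ blood flows must be positive")
        regional = sum(
            q for organ, q in self.organ_blood_flows.items() if organ != "lung"
        )
        if regional > self.cardiac_output * (1 + 1e-9):
            raise ValueError("sum of regional blood flows exceeds cardiac output")
        if abs(self.bmi - self.body_weight / (self.height / 100.0) ** 2) > 1e-6:
            raise ValueError("bmi inconsistent with weight and height")
        if self.shbg_baseline_plasma <= 0:
            raise ValueError("shbg_baseline_plasma must be positive")

    @property
    def liver_cyp3a4_amount_umol(self) -> float:
        return self.liver_cyp3a4_conc * self.organ_volumes["liver"]

    @property
    def gut_cyp3a4_amount_umol(self) -> float:
        return self.gut_cyp3a4_rel * self.liver_cyp3a4_amount_umol


@dataclass(frozen=True)
class Population:
    """A seeded, reproducible collection of sampled individuals."""

    individuals: list[Individual]
    seed: int
    bmi_range: tuple[float, float]
    n: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n == 0:
            object.__setattr__(self, "n", len(self.individuals))
        if self.n != len(self.individuals):
            raise ValueError("n must equal the number of individuals")

    def __iter__(self):
        return iter(self.individuals)

    def __len__(self) -> int:
        return self.n


def _check_ranges(age: float, bmi: float) -> None:
    if not 18.0 <= age <= 65.0:
        raise ValueError(f"age {age} outside supported range [18, 65] years")
    if not 16.0 <= bmi <= 50.0:
        raise ValueError(f"bmi {bmi} outside supported range [16, 50] kg/m^2")


def build_reference_individual(
    age: float = 30.0,
    bmi: float = REFERENCE_BMI,
    *,
    obese_shbg: bool = False,
    shbg_baseline_nmol_l: float | None = None,
    height_cm: float = REFERENCE_HEIGHT_CM,
) -> Individual:
    """Deterministic reference woman, BMI-adjusted from the packaged table.

    ``obese_shbg`` selects the exploratory reduced SHBG baseline
    (27.6 nmol/L instead of 55.4 nmol/L); it is an explicit scenario flag,
    not an automatic BMI covariate.
    """
    _check_ranges(age, bmi)
    table = reference_table()
    shbg = shbg_baseline_nmol_l
    if shbg is None:
        shbg = SHBG_BASELINE_OBESE_NM if obese_shbg else SHBG_BASELINE_NORMAL_NM
    ind = Individual(
        age=age,
        body_weight=REFERENCE_WEIGHT_KG,
        height=height_cm,
        bmi=REFERENCE_WEIGHT_KG / (height_cm / 100.0) ** 2,
        organ_volumes=dict(zip(table.index, table["volume_l"])),
        organ_blood_flows={
            o: f * REFERENCE_CARDIAC_OUTPUT_L_H
            for o, f in zip(table.index, table["flow_frac"])
        },
        cardiac_output=REFERENCE_CARDIAC_OUTPUT_L_H,
        hematocrit=REFERENCE_HEMATOCRIT,
        plasma_volume=REFERENCE_PLASMA_VOLUME_L,
        liver_cyp3a4_conc=CYP3A4_LIVER_UM,
        gut_cyp3a4_rel=GUT_CYP3A4_REL,
        albumin_plasma=ALBUMIN_PLASMA_UM,
        shbg_baseline_plasma=shbg,
    )
    if abs(bmi - ind.bmi) < 1e-12:
        return ind
    return scale_by_bmi(ind, bmi)


def _bsa_m2(weight_kg: float, height_cm: float) -> float:
    # DuBois & DuBois
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def scale_by_bmi(ind: Individual, target_bmi: float) -> Individual:
    """Rescale an individual to a target BMI at fixed height.

    Excess mass relative to the current body goes to adipose (75%), muscle
    (15%) and skin (10%); cardiac output and plasma volume scale with body
    surface area; blood flows of the scaled organs follow their volumes.
    """
    _check_ranges(ind.age, target_bmi)
    if target_bmi == ind.bmi:
        return ind
    densities = dict(zip(reference_table().index, reference_table()["density_kg_l"]))
    h_m = ind.height / 100.0
    new_weight = target_bmi * h_m**2
    delta_mass = new_weight - ind.body_weight

    volumes = dict(ind.organ_volumes)
    for organ, frac in _EXCESS_MASS_SPLIT.items():
        dv = delta_mass * frac / densities[organ]
        volumes[organ] = max(volumes[organ] + dv, 0.25 * ind.organ_volumes[organ])

    bsa_ratio = _bsa_m2(new_weight, ind.height) / _bsa_m2(ind.body_weight, ind.height)
    cardiac_output = ind.cardiac_output * bsa_ratio
    flows = dict(ind.organ_blood_flows)
    for organ in _EXCESS_MASS_SPLIT:
        flows[organ] = flows[organ] * volumes[organ] / ind.organ_volumes[organ]
    regional = sum(q for o, q in flows.items() if o != "lung")
    if regional > cardiac_output:
        scale = cardiac_output / regional
        flows = {o: q * scale for o, q in flows.items()}

    return replace(
        ind,
        body_weight=new_weight,
        bmi=new_weight / h_m**2,
        organ_volumes=volumes,
        organ_blood_flows=flows,
        cardiac_output=cardiac_output,
        plasma_volume=ind.plasma_volume * bsa_ratio,
    )


def sample_population(
    n: int,
    age_range: tuple[float, float] = (18.0, 45.0),
    bmi_range: tuple[float, float] = (18.5, 25.0),
    seed: int = 0,
    cv_overrides: dict[str, float] | None = None,
    shbg_baseline_nmol_l: float | None = None,
    obese_shbg: bool = False,
) -> Population:
    """Draw ``n`` virtual women with correlated lognormal variability.

    BMI (hence weight) is drawn first and drives the deterministic organ
    scaling; independent lognormal deviates with the configured CVs are then
    applied per organ volume/flow, CYP3A4 abundance, albumin and SHBG
    baseline.  The same seed always reproduces the identical population.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    cv = dict(DEFAULT_CV)
    if cv_overrides:
        cv.update(cv_overrides)
    rng = np.random.default_rng(seed)

    def logn(c: float, size=None):
        if c <= 0:
            return np.ones(size) if size else 1.0
        sigma = np.sqrt(np.log(1 + c**2))
        return rng.lognormal(-0.5 * sigma**2, sigma, size)

    individuals = []
    for _ in range(n):
        age = rng.uniform(*age_range)
        bmi = rng.uniform(*bmi_range)
        height = float(np.clip(rng.normal(REFERENCE_HEIGHT_CM, 6.0), 145.0, 185.0))
        base = build_reference_individual(
            age,
            bmi,
            obese_shbg=obese_shbg,
            shbg_baseline_nmol_l=shbg_baseline_nmol_l,
            height_cm=height,
        )
        volumes = {o: v * float(logn(cv["organ_volume"])) for o, v in base.organ_volumes.items()}
        flows = {o: q * float(logn(cv["organ_flow"])) for o, q in base.organ_blood_flows.items()}
        regional = sum(q for o, q in flows.items() if o != "lung")
        cardiac_output = max(base.cardiac_output, regional)
        individuals.append(
            replace(
                base,
                organ_volumes=volumes,
                organ_blood_flows=flows,
                cardiac_output=cardiac_output,
                liver_cyp3a4_conc=base.liver_cyp3a4_conc * float(logn(cv["cyp3a4"])),
                phase2_clearance_scale=float(logn(cv["phase2"])),
                albumin_plasma=base.albumin_plasma * float(logn(cv["albumin"])),
                shbg_baseline_plasma=base.shbg_baseline_plasma * float(logn(cv["shbg"])),
            )
        )
    return Population(individuals=individuals, seed=seed, bmi_range=tuple(bmi_range))
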