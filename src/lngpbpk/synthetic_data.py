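"""Synthetic clinical observation sets for fitting and verification runs.

The packaged study roster mirrors the clinical datasets behind the model:
IV 0.09 mg LNG (n=18), oral 0.03/0.09/0.27 mg LNG, IV 0.06 mg EE (n=17),
oral 0.02 mg EE, the 21-day triphasic LNG-EE cycle, and 1.5 mg oral LNG in
obese women.  Exact clinical sampling schedules are not published with the
model, so schedules are reconstructed as dense-early/sparse-late grids
(0.25-96 h).  Each generated set simulates a seeded virtual population,
samples the predicted profiles, applies lognormal proportional residual
error (default 15% CV) and censors below the LLOQ, and is fully
reproducible from (descriptor, truth parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ddi_scenarios import triphasic_regimens
from .engine import DosingRegimen, assemble, simulate
from .physiology import sample_population

__all__ = ["StudyDescriptor", "ObservationSet", "generate", "packaged_studies"]

_DENSE_SPARSE_TIMES = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0, 72.0, 96.0)


@dataclass(frozen=True)
class StudyDescriptor:
    """Design of one synthetic study."""

    study_id: str
    compound: str  # observed analyte: "LNG" or "EE"
    route: str  # "iv_bolus" | "oral" | "triphasic"
    doses_mg: tuple[float, ...]
    n_subjects: int
    sampling_times_h: tuple[float, ...] = _DENSE_SPARSE_TIMES
    residual_cv: float = 0.15  # proportional, fraction
    additive_floor_ng_ml: float = 0.0
    lloq_ng_ml: Optional[float] = None
    obese: bool = False
    seed: int = 0

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.sampling_times_h, self.sampling_times_h[1:])):
            raise ValueError("sampling times must be increasing")
        if self.residual_cv < 0:
            raise ValueError("residual CV must be >= 0")

    def regimens(self) -> list[DosingRegimen]:
        if self.route == "triphasic":
            return triphasic_regimens()
        return [DosingRegimen.single(self.compound, self.doses_mg[0], route=self.route)]


@dataclass(frozen=True)
class ObservationSet:
    """Long-format records: (subject id, time h, concentration ng/mL, censored)."""

    study_id: str
    records: tuple[tuple[int, float, float, bool], ...]
    lloq_ng_ml: Optional[float] = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["subject", "time_h", "conc_ng_ml", "cens"])

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, study_id: str = "") -> "ObservationSet":
        df = pd.read_csv(path, sep="\t")
        recs = tuple(
            (int(r.subject), float(r.time_h), float(r.conc_ng_ml), bool(r.cens))
            for r in df.itertuples()
        )
        return cls(study_id=study_id or str(path), records=recs)


def generate(
    descriptor: StudyDescriptor,
    overrides: dict[str, float] | None = None,
    population=None,
    cv_overrides: dict[str, float] | None = None,
) -> ObservationSet:
    """Simulate the study and emit noisy, censored observations.

    ``overrides`` are multiplicative truth-parameter overrides passed to the
    engine (the fitting tests recover them); ``population`` substitutes a
    pre-built population (e.g. n=1 with no variability for noise-free
    checks).
    """
    rng = np.random.default_rng(descriptor.seed + 1_000_003)
    if population is None:
        bmi = (30.0, 40.0) if descriptor.obese else (18.5, 25.0)
        population = sample_population(
            descriptor.n_subjects,
            bmi_range=bmi,
            seed=descriptor.seed,
            cv_overrides=cv_overrides,
            obese_shbg=descriptor.obese,
        )
    regimens = descriptor.regimens()
    t_last_dose = max(max(r.times_h) for r in regimens)
    t_end = t_last_dose + descriptor.sampling_times_h[-1]
    times = t_last_dose + np.asarray(descriptor.sampling_times_h)

    sigma = np.sqrt(np.log(1 + descriptor.residual_cv**2)) if descriptor.residual_cv else 0.0
    records = []
    for sid, ind in enumerate(population, start=1):
        system = assemble(ind, regimens, overrides=overrides)
        res = simulate(system, t_end, output_dt=0.25)
        pred = np.interp(times, res.times_h, res.plasma_ng_ml(descriptor.compound))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=len(times)) if sigma else 1.0
        obs = pred * noise + (
            rng.normal(0.0, descriptor.additive_floor_ng_ml, size=len(times))
            if descriptor.additive_floor_ng_ml
            else 0.0
        )
        obs = np.maximum(obs, 0.0)
        for t, c in zip(times, obs):
            cens = descriptor.lloq_ng_ml is not None and c < descriptor.lloq_ng_ml
            records.append((sid, float(t - t_last_dose), float(c), bool(cens)))
    return ObservationSet(
        study_id=descriptor.study_id,
        records=tuple(records),
        lloq_ng_ml=descriptor.lloq_ng_ml,
    )


def packaged_studies(seed: int = 0) -> list[StudyDescriptor]:
    """The packaged study roster with default IIV and residual-error settings."""
    mk = lambda **kw: StudyDescriptor(seed=seed, **kw)
    return [
        mk(study_id="lng_iv_0p09", compound="LNG", route="iv_bolus", doses_mg=(0.09,), n_subjects=18),
        mk(study_id="lng_oral_0p03", compound="LNG", route="oral", doses_mg=(0.03,), n_subjects=18),
        mk(study_id="lng_oral_0p09", compound="LNG", route="oral", doses_mg=(0.09,), n_subjects=18),
        mk(study_id="lng_oral_0p27", compound="LNG", route="oral", doses_mg=(0.27,), n_subjects=18),
        mk(study_id="ee_iv_0p06", compound="EE", route="iv_bolus", doses_mg=(0.06,), n_subjects=17),
        mk(study_id="ee_oral_0p02", compound="EE", route="oral", doses_mg=(0.02,), n_subjects=17),
        mk(
            study_id="chc_triphasic_21d",
            compound="LNG",
            route="triphasic",
            doses_mg=(0.050, 0.075, 0.125),
            n_subjects=20,
        ),
        mk(
            study_id="lng_oral_1p5_obese",
            compound="LNG",
            route="oral",
            doses_mg=(1.5,),
            n_subjects=16,
            obese=True,
            # EE-style assay floor: LLOQ at roughly 20% of the typical Cmax
            lloq_ng_ml=None,
        ),
    ]
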