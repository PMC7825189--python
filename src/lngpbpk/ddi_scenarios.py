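"""Pre-built DDI and obesity scenario replications - the headline pipeline.

Each scenario pairs a victim contraceptive regimen (LNG-only or combined
LNG-EE at steady state, or a single emergency-contraception-style dose)
with a perpetrator regimen at its common therapeutic dose.  Perpetrators
are pre-dosed for eight days (>5 CYP3A4 turnover half-lives) before the
victim cycle so the enzyme pool is at its perturbed steady state, and the
endpoint AUC is taken over the final victim dosing interval ("after 21-day
treatment cycle"), in µmol·min/L to match the reporting convention of the
replicated analysis.

Scenarios run either on the deterministic reference woman or on a seeded
virtual population (mean and 95% CI endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .engine import DosingRegimen, assemble, simulate
from .metrics import auc_trapz, classify_ddi
from .physiology import Individual, Population, build_reference_individual, sample_population

__all__ = ["Scenario", "SCENARIOS", "run_scenario", "run_obesity_comparison", "triphasic_regimens"]

PRETREAT_H = 8 * 24.0  # perpetrator lead-in; >= 5 x CYP3A4 half-life (180 h)
CYCLE_DAYS = 21


def _victim(kind: str, start_h: float = PRETREAT_H) -> list[DosingRegimen]:
    if kind == "chc_150_30":
        return [
            DosingRegimen.repeated("LNG", 0.150, CYCLE_DAYS, 24.0, start_h=start_h),
            DosingRegimen.repeated("EE", 0.030, CYCLE_DAYS, 24.0, start_h=start_h),
        ]
    if kind == "chc_250_50":
        return [
            DosingRegimen.repeated("LNG", 0.250, CYCLE_DAYS, 24.0, start_h=start_h),
            DosingRegimen.repeated("EE", 0.050, CYCLE_DAYS, 24.0, start_h=start_h),
        ]
    if kind == "lng_only_150":
        return [DosingRegimen.repeated("LNG", 0.150, CYCLE_DAYS, 24.0, start_h=start_h)]
    if kind == "lng_only_30":
        return [DosingRegimen.repeated("LNG", 0.030, CYCLE_DAYS, 24.0, start_h=start_h)]
    if kind == "lng_single_750":
        return [DosingRegimen.single("LNG", 0.75, start_h + 3 * 24.0)]
    raise KeyError(f"unknown victim regimen {kind!r}")


def triphasic_regimens(start_h: float = 0.0) -> list[DosingRegimen]:
    """Standard 6/5/10-day triphasic cycle: 50/75/125 µg LNG + 30/40/30 µg EE.

    The replicated study used ascending LNG doses combined with EE over 21
    days; the exact per-phase strengths are not printed, so the standard
    triphasic strengths are packaged (a documented assumption).
    """
    regs = []
    phases = [(6, 0.050, 0.030), (5, 0.075, 0.040), (10, 0.125, 0.030)]
    day = 0
    for n_days, lng_mg, ee_mg in phases:
        t0 = start_h + day * 24.0
        regs.append(DosingRegimen.repeated("LNG", lng_mg, n_days, 24.0, start_h=t0))
        regs.append(DosingRegimen.repeated("EE", ee_mg, n_days, 24.0, start_h=t0))
        day += n_days
    return regs


@dataclass(frozen=True)
class Scenario:
    """One perpetrator-victim replication."""

    id: str
    victim: str  # victim regimen kind
    perpetrator: Optional[str] = None
    perp_dose_mg: float = 0.0
    perp_interval_h: float = 24.0
    window: str = "last_interval"  # or "single_dose"
    description: str = ""

    @property
    def t_end_h(self) -> float:
        if self.window == "single_dose":
            return PRETREAT_H + 3 * 24.0 + 96.0  # 96 h post victim dose
        return PRETREAT_H + CYCLE_DAYS * 24.0

    def regimens(self, with_perpetrator: bool = True) -> list[DosingRegimen]:
        regs = _victim(self.victim)
        if with_perpetrator and self.perpetrator and self.perp_dose_mg > 0:
            n = int(np.ceil(self.t_end_h / self.perp_interval_h))
            regs.append(
                DosingRegimen.repeated(
                    self.perpetrator, self.perp_dose_mg, n, self.perp_interval_h
                )
            )
        return regs


SCENARIOS: dict[str, Scenario] = {
    s.id: s
    for s in [
        Scenario("CBZ600_LNG250_EE50", "chc_250_50", "carbamazepine", 600,
                 description="carbamazepine 600 mg q.d. vs 0.250 mg LNG + 0.05 mg EE"),
        Scenario("EFV600_LNG750_single", "lng_single_750", "efavirenz", 600,
                 window="single_dose",
                 description="efavirenz 600 mg q.d. vs single 0.75 mg LNG"),
        Scenario("RIF600_LNG30", "lng_only_30", "rifampicin", 600,
                 description="rifampicin 600 mg q.d. (CYP3A4 + SHBG induction) vs 0.03 mg LNG"),
        Scenario("CBZ400_CHC", "chc_150_30", "carbamazepine", 400),
        Scenario("CBZ400_LNG150", "lng_only_150", "carbamazepine", 400),
        Scenario("EFV600_CHC", "chc_150_30", "efavirenz", 600),
        Scenario("EFV600_LNG150", "lng_only_150", "efavirenz", 600),
        Scenario("RIF600_CHC", "chc_150_30", "rifampicin", 600),
        Scenario("RIF600_LNG150", "lng_only_150", "rifampicin", 600),
        Scenario("ITZ100_CHC", "chc_150_30", "itraconazole", 100),
        Scenario("ITZ200_CHC", "chc_150_30", "itraconazole", 200),
        Scenario("ITZ100_LNG150", "lng_only_150", "itraconazole", 100),
        Scenario("CLA250_CHC", "chc_150_30", "clarithromycin", 250, perp_interval_h=12.0),
        Scenario("CLA500_CHC", "chc_150_30", "clarithromycin", 500, perp_interval_h=12.0),
        Scenario("CLA500_LNG150", "lng_only_150", "clarithromycin", 500, perp_interval_h=12.0),
    ]
}


def _population_for(population: str | Population | None, n: int, seed: int):
    if population is None or isinstance(population, Individual):
        return population
    if isinstance(population, Population):
        return population
    if population == "normal":
        return sample_population(n, bmi_range=(18.5, 25.0), seed=seed)
    if population == "obese":
        return sample_population(n, bmi_range=(30.0, 40.0), seed=seed, obese_shbg=True)
    raise KeyError(f"unknown population spec {population!r}")


def _windows(scenario: Scenario):
    t_end = scenario.t_end_h
    if scenario.window == "single_dose":
        t_dose = PRETREAT_H + 3 * 24.0
        return t_dose, t_end
    return t_end - 24.0, t_end


def _endpoints_one(ind: Individual, scenario: Scenario, with_perp: bool, rtol: float):
    regs = scenario.regimens(with_perp)
    res = simulate(assemble(ind, regs), scenario.t_end_h, output_dt=0.5, rtol=rtol)
    w0, w1 = _windows(scenario)
    t = res.times_h
    m = (t >= w0 - 1e-9) & (t <= w1 + 1e-9)
    c_tot = res.plasma_total("LNG")
    c_u = res.plasma_unbound("LNG")
    auc_tot = auc_trapz(t[m], c_tot[m]) * 60.0  # µmol·min/L
    auc_u = auc_trapz(t[m], c_u[m]) * 60.0
    # steady-state convergence: compare to the preceding interval
    converged = True
    if scenario.window == "last_interval":
        m_prev = (t >= w0 - 24.0 - 1e-9) & (t <= w0 + 1e-9)
        prev = auc_trapz(t[m_prev], c_tot[m_prev]) * 60.0
        converged = abs(auc_tot - prev) / auc_tot <= 0.02 if auc_tot > 0 else True
    return SimpleNamespace(
        auc_total=auc_tot,
        auc_unbound=auc_u,
        cmax=float(c_tot[m].max()),
        converged=converged,
    )


def run_scenario(
    scenario: str | Scenario,
    seed: int = 0,
    population: str | Population | Individual | None = None,
    n: int = 20,
    rtol: float = 1e-6,
) -> SimpleNamespace:
    """Run one scenario with and without the perpetrator.

    Without a population spec the deterministic reference woman is used.
    Population runs report means with normal-theory 95% CIs across
    individuals.  A non-converged steady state (last-interval AUC drifting
    more than 2% from the previous cycle) raises a warning flag on the
    endpoint rather than an error.
    """
    s = SCENARIOS[scenario] if isinstance(scenario, str) else scenario
    if population is None:
        inds = [build_reference_individual()]
    elif isinstance(population, Individual):
        inds = [population]
    else:
        inds = list(_population_for(population, n, seed))

    arms = {}
    for label, with_perp in (("with", True), ("without", False)):
        per = [_endpoints_one(ind, s, with_perp, rtol) for ind in inds]
        auc = np.array([e.auc_total for e in per])
        auc_u = np.array([e.auc_unbound for e in per])
        ci = (
            stats.t.interval(0.95, len(auc) - 1, loc=auc.mean(), scale=stats.sem(auc))
            if len(auc) > 1
            else (auc[0], auc[0])
        )
        arms[label] = SimpleNamespace(
            auc_total_mean=float(auc.mean()),
            auc_total_ci=tuple(float(x) for x in ci),
            auc_unbound_mean=float(auc_u.mean()),
            cmax_mean=float(np.mean([e.cmax for e in per])),
            converged=all(e.converged for e in per),
            per_individual=per,
        )
    ratio = arms["with"].auc_total_mean / arms["without"].auc_total_mean
    ratio_u = arms["with"].auc_unbound_mean / arms["without"].auc_unbound_mean
    return SimpleNamespace(
        scenario=s.id,
        arms=arms,
        aucr=ratio,
        aucr_unbound=ratio_u,
        ddi_class=classify_ddi(ratio),
        warning=None if (arms["with"].converged and arms["without"].converged)
        else "steady-state drift > 2% between last two cycles",
    )


def run_obesity_comparison(
    perpetrators: Sequence[tuple[str, float]] = (("carbamazepine", 400.0), ("itraconazole", 100.0)),
    victims: Sequence[str] = ("chc_150_30", "lng_only_150"),
    seed: int = 0,
    n: int = 20,
    rtol: float = 1e-6,
) -> SimpleNamespace:
    """Paired normal-BMI vs obese endpoint grid with within-group fold changes.

    Reports total and unbound LNG AUC per arm, the within-group DDI fold
    change for every perpetrator, and a descriptive two-sample comparison
    (Welch t on log AUC) of the no-perpetrator arms between groups.
    """
    rows = []
    group_pops = {
        "normal": _population_for("normal", n, seed),
        "obese": _population_for("obese", n, seed + 1),
    }
    ref_aucs: dict[tuple[str, str], np.ndarray] = {}
    for group, pop in group_pops.items():
        for victim in victims:
            base = run_scenario(
                Scenario(f"{group}_{victim}_ref", victim, None), seed, pop, n, rtol
            )
            ref = base.arms["without"]
            ref_aucs[(group, victim)] = np.array(
                [e.auc_total for e in ref.per_individual]
            )
            rows.append(
                {
                    "group": group,
                    "victim": victim,
                    "perpetrator": "none",
                    "auc_total": ref.auc_total_mean,
                    "auc_unbound": ref.auc_unbound_mean,
                    "fold_change": 1.0,
                }
            )
            for perp, dose in perpetrators:
                sc = Scenario(f"{group}_{victim}_{perp}{int(dose)}", victim, perp, dose)
                out = run_scenario(sc, seed, pop, n, rtol)
                rows.append(
                    {
                        "group": group,
                        "victim": victim,
                        "perpetrator": f"{perp} {dose:g} mg",
                        "auc_total": out.arms["with"].auc_total_mean,
                        "auc_unbound": out.arms["with"].auc_unbound_mean,
                        "fold_change": out.aucr,
                    }
                )
    a = np.log(ref_aucs[("normal", victims[0])])
    b = np.log(ref_aucs[("obese", victims[0])])
    test = stats.ttest_ind(a, b, equal_var=False)
    return SimpleNamespace(
        table=rows,
        normal_vs_obese_log_auc_t=float(test.statistic),
        normal_vs_obese_p=float(test.pvalue),
    )
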