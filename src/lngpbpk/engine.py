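"""Whole-body PBPK assembly and integration.

The model couples, for each fully-resolved ("victim") compound:

* a gastrointestinal cascade (stomach, four small-intestine segments,
  colon) with first-order, solubility-capped dissolution, first-order
  transit and permeability-driven absorption into the gut wall;
* a perfusion-limited whole-body circulation (12 organs exchanging with a
  central plasma pool, portal routing gut/spleen -> liver, optional
  permeability-surface limitation);
* plasma protein binding to albumin and SHBG applied as an exact
  quasi-equilibrium inside the right-hand side (the published
  dissociation rates, 6.5-17.4/min, equilibrate three orders of magnitude
  faster than any PK process, so the stiff kinetic formulation is replaced
  by its algebraic limit; free/bound plasma series are reported at every
  output point and satisfy free + bound = total identically);
* hepatic metabolism split into a CYP3A4 pathway (unbound-referenced
  intrinsic clearance scaled by the dynamic enzyme pool and by competitive
  inhibition) and a lumped non-CYP3A4 pathway, plus gut-wall CYP3A4
  metabolism; and
* shared regulation pools: SHBG (turnover + induction) and hepatic/gut
  CYP3A4 (turnover + induction + mechanism-based inactivation).

Perpetrators (rifampicin, carbamazepine, efavirenz, itraconazole,
clarithromycin) run as reduced one-compartment models whose unbound plasma
concentrations drive the interaction terms.

Units: amounts µmol, volumes L, time h, concentrations µmol/L
(SHBG pool nmol/L).  Doses are events: state jumps at dose times with the
integrator restarted at each discontinuity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import distribution
from .compounds import CompoundParameters, Mechanism, dissolution_rate_constant, load_compound
from .physiology import Individual
from .regulation import (
    CYP3A4_GUT_HALF_LIFE_H,
    CYP3A4_LIVER_HALF_LIFE_H,
    SHBG_HALF_LIFE_H,
)

__all__ = ["DosingRegimen", "ModelSystem", "SimulationResult", "assemble", "simulate", "simulate_population"]

# ---------------------------------------------------------------------------
# gastrointestinal geometry (packaged constants)

GI_SEGMENTS = ("stomach", "si1", "si2", "si3", "si4", "colon")
GI_LUMEN_VOLUME_L = np.array([0.05, 0.04, 0.04, 0.04, 0.04, 0.20])
#: effective absorptive area per segment, cm^2.  The small-intestine value
#: contains the single global mucosal-amplification calibration factor of
#: the absorption model (fixed once so that a low-dose oral LNG dose is
#: nearly completely absorbed, F_a ~ 0.95, consistent with its clinical
#: near-complete oral bioavailability; frozen thereafter).
GI_AREA_CM2 = np.array([0.0, 1.0e4, 1.0e4, 1.0e4, 1.0e4, 2.0e3])
GASTRIC_EMPTYING_1_H = math.log(2.0) / 0.25  # t1/2 15 min fasted
SI_TRANSIT_1_H = 4.0 / 3.3  # 4 segments over ~3.3 h
COLON_EXIT_1_H = 1.0 / 18.0

_N_GI = len(GI_SEGMENTS)


@dataclass(frozen=True)
class DosingRegimen:
    """A sequence of identical doses of one compound."""

    compound: str
    dose_mg: float
    times_h: tuple[float, ...]
    route: str = "oral"  # "oral" | "iv_bolus"
    t80_min: Optional[float] = None  # override packaged formulation
    lag_min: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose must be >= 0")
        if any(b <= a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ValueError("dose_times must be strictly increasing")

    @classmethod
    def single(cls, compound: str, dose_mg: float, time_h: float = 0.0, **kw):
        return cls(compound, dose_mg, (time_h,), **kw)

    @classmethod
    def repeated(
        cls,
        compound: str,
        dose_mg: float,
        n_doses: int,
        interval_h: float = 24.0,
        start_h: float = 0.0,
        **kw,
    ):
        times = tuple(start_h + i * interval_h for i in range(n_doses))
        return cls(compound, dose_mg, times, **kw)


@dataclass
class SimulationResult:
    """Solved time courses and derived plasma species."""

    times_h: np.ndarray
    compounds: dict[str, SimpleNamespace]  # per-compound series
    shbg_nmol_l: np.ndarray
    e_liver_rel: np.ndarray
    e_gut_rel: np.ndarray
    individual: Individual
    mass_balance_rel_error: dict[str, float]

    def plasma_total(self, name: str) -> np.ndarray:
        """Total plasma concentration, µmol/L."""
        return self.compounds[name].plasma_total

    def plasma_unbound(self, name: str) -> np.ndarray:
        return self.compounds[name].plasma_free

    def plasma_ng_ml(self, name: str, unbound: bool = False) -> np.ndarray:
        mw = self.compounds[name].molecular_weight
        series = self.plasma_unbound(name) if unbound else self.plasma_total(name)
        return series * mw  # µmol/L * g/mol = µg/L = ng/mL


# ---------------------------------------------------------------------------
# assembly


def _ov(overrides: dict[str, float] | None, key: str, value: float) -> float:
    """Apply a multiplicative parameter override (sensitivity machinery)."""
    if overrides and key in overrides:
        return value * overrides[key]
    return value


def _victim_namespace(
    cmp: CompoundParameters,
    ind: Individual,
    regimen_doses: Sequence[DosingRegimen],
    organs: list[str],
    kpu_overrides_key: str,
    overrides: dict[str, float] | None,
) -> SimpleNamespace:
    v = SimpleNamespace()
    v.name = cmp.name
    v.mw = cmp.molecular_weight
    logp = _ov(overrides, f"{cmp.name}.lipophilicity_logp", cmp.lipophilicity_logp)
    tweaked = cmp.model_copy(update={"lipophilicity_logp": logp})
    kpu = distribution.kpu_rodgers_rowland(tweaked)
    v.kpu = np.array([kpu[o] for o in organs])

    # plasma binding
    alb_spec = cmp.binding("albumin")
    shbg_spec = cmp.binding("shbg")
    fu_scale = (overrides or {}).get("fu_scale", 1.0)
    v.fu_scale = fu_scale
    if shbg_spec is not None or alb_spec is not None:
        v.binding = "kinetic"
        v.kd_alb_um = alb_spec.kd if alb_spec else math.inf
        v.kd_shbg_nm = (shbg_spec.kd * 1e3) if shbg_spec else math.inf
        # binding capacities scaled reciprocally by fu_scale
        v.alb_um = ind.albumin_plasma / fu_scale
    else:
        v.binding = "constant"
        fu = cmp.nonspecific_unbound_fraction or 1.0
        v.fu_const = min(1.0, fu * fu_scale)

    # clearances (unbound-referenced intrinsic, L/h)
    v.clint_cyp_liver = 0.0
    v.clint_other = 0.0
    v.clint_cyp_gut = 0.0
    v.clint_total = 0.0
    if cmp.cyp3a4_specific_clearance is not None:
        clspec = _ov(
            overrides, f"{cmp.name}.cyp3a4_specific_clearance", cmp.cyp3a4_specific_clearance
        )
        # µL/min/pmol * pmol -> L/h
        liver_pmol = ind.liver_cyp3a4_amount_umol * 1e6
        gut_pmol = ind.gut_cyp3a4_amount_umol * 1e6
        v.clint_cyp_liver = clspec * 1e-6 * 60.0 * liver_pmol
        v.clint_cyp_gut = clspec * 1e-6 * 60.0 * gut_pmol
        if cmp.fm_cyp3a4 is not None:
            # Non-CYP3A4 (phase II) pathway anchored to the DDI-derived
            # CYP3A4 fraction at the population-typical enzyme abundance;
            # it varies with its own lognormal scale, independently of the
            # individual's CYP3A4 abundance, so fm itself carries IIV.
            from .physiology import CYP3A4_LIVER_UM

            ref_liver_pmol = CYP3A4_LIVER_UM * ind.organ_volumes["liver"] * 1e6
            v.clint_other = (
                clspec * 1e-6 * 60.0 * ref_liver_pmol
                * (1.0 / cmp.fm_cyp3a4 - 1.0)
                * ind.phase2_clearance_scale
            )
        v.clint_other = _ov(overrides, f"{cmp.name}.other_hepatic_clearance", v.clint_other)
    if cmp.total_hepatic_clearance is not None:
        cl_pl = (
            _ov(overrides, f"{cmp.name}.total_hepatic_clearance", cmp.total_hepatic_clearance)
            * ind.body_weight
            * 60.0
            / 1000.0
        )  # L/h plasma clearance
        v.cl_plasma_target = cl_pl
        v.clint_total = cl_pl  # converted to intrinsic in assemble (needs Q_h)

    # absorption / dissolution
    peff = cmp.specific_intestinal_permeability or 0.0
    peff = _ov(overrides, f"{cmp.name}.specific_intestinal_permeability", peff)
    v.kabs = peff * 60.0 * GI_AREA_CM2 / (GI_LUMEN_VOLUME_L * 1e3)  # 1/h per segment
    sol_aq = cmp.aqueous_solubility or math.inf
    sol_int = cmp.fassif_solubility or sol_aq
    v.sat_umol_l = np.array(
        [sol_aq] + [sol_int] * 5
    ) / cmp.molecular_weight * 1e3  # mg/L -> µmol/L

    # per-regimen dissolution constants
    v.regimens = []
    for reg in regimen_doses:
        if reg.route == "oral":
            form = cmp.formulation_for_dose(reg.dose_mg)
            t80 = reg.t80_min if reg.t80_min is not None else form.t80_dissolution_min
            t80 = _ov(overrides, f"{cmp.name}.t80", t80)
            lag = reg.lag_min if reg.lag_min is not None else form.lag_time_min
            kdiss = dissolution_rate_constant(t80) * 60.0  # 1/h
        else:
            kdiss, lag = 0.0, 0.0
        v.regimens.append((reg, kdiss, lag))
    return v


@dataclass
class ModelSystem:
    """Assembled ODE system (layout, parameters, dose events, RHS)."""

    individual: Individual
    victims: list[SimpleNamespace]
    perps: list[SimpleNamespace]
    organs: list[str]
    n_states: int
    dose_events: list[tuple[float, int, float, float]]  # (t, state_idx, amount, kdiss)
    dissolution_schedule: list  # per victim: list of (t_effective, kdiss)
    rhs: object = field(default=None, repr=False)
    assembly_inputs: dict = field(default_factory=dict, repr=False)

    def rebuild(self, overrides: dict[str, float]) -> "ModelSystem":
        """Re-assemble with multiplicative parameter overrides (for sensitivity)."""
        inputs = dict(self.assembly_inputs)
        merged = dict(inputs.pop("overrides") or {})
        merged.update(overrides)
        return assemble(overrides=merged, **inputs)


def assemble(
    individual: Individual,
    regimens: Sequence[DosingRegimen],
    compounds: dict[str, CompoundParameters] | None = None,
    shbg_variant: str | None = None,
    overrides: dict[str, float] | None = None,
) -> ModelSystem:
    """Build the coupled RHS for an individual, compounds and regimens.

    Victim compounds (those with full parameter sets: LNG, EE) receive the
    whole-body treatment; packaged perpetrators run as reduced models.  The
    SHBG induction variant follows the regimen type automatically: the net
    LNG:EE Emax when both hormones are dosed, the EE-alone Emax otherwise
    (the two are mutually exclusive).
    """
    if compounds is None:
        compounds = {}
    names = {r.compound for r in regimens}
    for n in names:
        compounds.setdefault(n, load_compound(n))

    victims_names = [n for n in ("LNG", "EE") if n in names]
    perp_names = sorted(n for n in names if n not in ("LNG", "EE"))
    organs = list(individual.organ_volumes)
    n_org = len(organs)
    i_gut, i_liver, i_spleen = (organs.index(o) for o in ("gut", "liver", "spleen"))

    ind = individual
    hct = ind.hematocrit
    q_plasma = np.array([ind.organ_blood_flows[o] * (1 - hct) for o in organs])
    vols = np.array([ind.organ_volumes[o] for o in organs])
    vp = ind.plasma_volume

    # exchange clearance: harmonic combination of plasma flow and PS product
    victims = []
    per_victim = 2 * _N_GI + 1 + n_org + 2  # GI solid+dissolved, plasma, organs, met/fecal
    for vn in victims_names:
        regs = [r for r in regimens if r.compound == vn]
        v = _victim_namespace(compounds[vn], ind, regs, organs, vn, overrides)
        ps_spec = compounds[vn].specific_organ_permeability
        if ps_spec is not None and ps_spec > 0:
            ps = np.array(
                [distribution.permeability_surface_product(ps_spec, vl) for vl in vols]
            )
            v.qx = q_plasma * ps / (q_plasma + ps)
        else:
            v.qx = q_plasma.copy()
        victims.append(v)

    q_ha = q_plasma[i_liver]
    q_gut = q_plasma[i_gut]
    q_spl = q_plasma[i_spleen]
    q_hv = q_ha + q_gut + q_spl

    # EE-style lumped clearance: invert the well-stirred relation so the
    # systemic plasma clearance of the assembled model matches the input
    for v in victims:
        if v.clint_total:
            cl = v.cl_plasma_target
            if cl >= q_hv:
                raise ValueError(f"{v.name}: plasma clearance exceeds hepatic plasma flow")
            fu = v.fu_const if v.binding == "constant" else 1.0
            v.clint_total = cl * q_hv / (q_hv - cl) / fu

    perps = []
    for pn in perp_names:
        cmp = compounds[pn]
        if cmp.perpetrator_pk is None:
            raise ValueError(f"{pn}: no perpetrator PK block packaged")
        p = SimpleNamespace(name=pn, mw=cmp.molecular_weight, pk=cmp.perpetrator_pk)
        p.regs = [r for r in regimens if r.compound == pn]
        perps.append(p)

    # ---- interactions ------------------------------------------------------
    # driver resolution: ("victim", index) unbound plasma or ("perp", index)
    def drivers_of(name):
        if name in victims_names:
            return ("victim", victims_names.index(name))
        return ("perp", perp_names.index(name))

    cyp_competitive = []  # (driver, ki)
    cyp_induction = []  # (driver, emax_fold, ec50)
    cyp_mbi = []  # (driver, kinact, ki_mbi)
    shbg_induction = []  # (driver, emax_fold, ec50)
    if shbg_variant is None:
        shbg_variant = "net_lng_ee" if ("LNG" in names and "EE" in names) else "ee_alone"
    for n in names:
        for spec in compounds[n].interactions:
            drv = drivers_of(n)
            if spec.target == "cyp3a4":
                if spec.mechanism == Mechanism.competitive:
                    ki = spec.ki
                    if n == "EE":
                        ki = _ov(overrides, "EE.ki_cyp3a4", ki)
                    cyp_competitive.append((drv, ki))
                elif spec.mechanism == Mechanism.induction:
                    cyp_induction.append((drv, spec.emax_fold, spec.ec50))
                elif spec.mechanism == Mechanism.mbi:
                    cyp_mbi.append((drv, spec.kinact, spec.ki_mbi))
            elif spec.target == "shbg_synthesis":
                if spec.variant is not None and spec.variant != shbg_variant:
                    continue
                shbg_induction.append((drv, spec.emax_fold, spec.ec50))

    # ---- state layout ------------------------------------------------------
    offsets = {}
    off = 0
    for v in victims:
        offsets[v.name] = off
        off += per_victim
    perp_off = {}
    for p in perps:
        perp_off[p.name] = off
        off += 2
    i_shbg, i_el, i_eg = off, off + 1, off + 2
    n_states = off + 3

    kdeg_shbg = math.log(2.0) / SHBG_HALF_LIFE_H
    kdeg_el = math.log(2.0) / CYP3A4_LIVER_HALF_LIFE_H
    kdeg_eg = math.log(2.0) / CYP3A4_GUT_HALF_LIFE_H
    shbg0 = ind.shbg_baseline_plasma

    # ---- dose events -------------------------------------------------------
    # (time, kind, victim/perp index, amount µmol, kdiss) ; oral doses are
    # deposited into stomach solid at t + lag (lag implemented as arrival shift)
    events = []
    for v in victims:
        base = offsets[v.name]
        for reg, kdiss, lag in v.regimens:
            amount = reg.dose_mg / v.mw * 1e3  # µmol
            for t in reg.times_h:
                if reg.route == "iv_bolus":
                    events.append((t, base + 2 * _N_GI, amount, 0.0))
                else:
                    events.append((t + lag / 60.0, base, amount, kdiss))
    for p in perps:
        base = perp_off[p.name]
        for reg in p.regs:
            amount = reg.dose_mg / p.mw * 1e3 * p.pk.f_oral
            for t in reg.times_h:
                events.append((t, base, amount, 0.0))
    events.sort(key=lambda e: e[0])

    # dissolution constants are per-formulation; with one oral formulation
    # per victim per scenario the constant is unique.  Guard against mixes.
    for v in victims:
        ks = {kd for _, kd, _ in v.regimens if kd > 0}
        v.kdiss = ks.pop() if ks else 0.0
        if ks:
            raise ValueError(f"{v.name}: mixed oral formulations in one scenario")

    # ---- RHS ---------------------------------------------------------------
    n_gi = _N_GI
    kt = np.array([GASTRIC_EMPTYING_1_H, SI_TRANSIT_1_H, SI_TRANSIT_1_H, SI_TRANSIT_1_H, SI_TRANSIT_1_H, COLON_EXIT_1_H])
    lumen_v = GI_LUMEN_VOLUME_L
    direct = np.array([i for i in range(n_org) if i not in (i_gut, i_liver, i_spleen)])

    victim_idx = {v.name: k for k, v in enumerate(victims)}

    def unbound_conc(kind_idx, y, victim_fu):
        kind, j = kind_idx
        if kind == "victim":
            v = victims[j]
            base = offsets[v.name]
            cp = max(y[base + 2 * n_gi], 0.0) / vp
            return victim_fu[j] * cp
        p = perps[j]
        a_c = max(y[perp_off[p.name] + 1], 0.0)
        return p.pk.fu * a_c / p.pk.v_l

    def rhs(t, y):
        dy = np.zeros_like(y)

        # perpetrators first (simple, also needed as drivers)
        for p in perps:
            b = perp_off[p.name]
            a_g, a_c = max(y[b], 0.0), max(y[b + 1], 0.0)
            ka = p.pk.ka_1_h
            dy[b] = -ka * a_g
            dy[b + 1] = ka * a_g - p.pk.cl_l_h * a_c / p.pk.v_l

        shbg = max(y[i_shbg], 0.0)
        e_l = max(y[i_el], 0.0)
        e_g = max(y[i_eg], 0.0)

        # per-victim unbound fractions (needed for cross-compound drivers)
        victim_fu = []
        for v in victims:
            base = offsets[v.name]
            cp = max(y[base + 2 * n_gi], 0.0) / vp
            if v.binding == "constant":
                victim_fu.append(v.fu_const)
            else:
                shbg_eff = shbg / v.fu_scale
                fu = _fast_fu(cp * 1e3, v.alb_um, shbg_eff, v.kd_alb_um, v.kd_shbg_nm)
                victim_fu.append(fu)

        # competitive CYP3A4 factor (shared by liver and gut pathways)
        s = 0.0
        for drv, ki in cyp_competitive:
            s += unbound_conc(drv, y, victim_fu) / ki
        phi = 1.0 / (1.0 + s)

        # regulation pools
        m_shbg = 1.0
        for drv, emax, ec50 in shbg_induction:
            c = unbound_conc(drv, y, victim_fu)
            m_shbg *= 1.0 + (emax - 1.0) * c / (ec50 + c)
        dy[i_shbg] = kdeg_shbg * shbg0 * m_shbg - kdeg_shbg * shbg

        m_cyp = 1.0
        for drv, emax, ec50 in cyp_induction:
            c = unbound_conc(drv, y, victim_fu)
            m_cyp *= 1.0 + (emax - 1.0) * c / (ec50 + c)
        mbi = 0.0
        for drv, kinact, ki in cyp_mbi:
            c = unbound_conc(drv, y, victim_fu)
            mbi += kinact * c / (ki + c)
        dy[i_el] = kdeg_el * m_cyp - (kdeg_el + mbi) * e_l
        dy[i_eg] = kdeg_eg * m_cyp - (kdeg_eg + mbi) * e_g

        for k, v in enumerate(victims):
            base = offsets[v.name]
            sol = np.maximum(y[base : base + n_gi], 0.0)
            dis = np.maximum(y[base + n_gi : base + 2 * n_gi], 0.0)
            a_p = max(y[base + 2 * n_gi], 0.0)
            a_t = np.maximum(y[base + 2 * n_gi + 1 : base + 2 * n_gi + 1 + n_org], 0.0)

            cp = a_p / vp
            fu_t = victim_fu[k]
            kp = np.maximum(fu_t * v.kpu, 1e-12)

            # --- GI: dissolution (solubility-limited), transit, absorption.
            # The (1 - C/Csat) driving force is left unclipped: it vanishes
            # smoothly at saturation and lets transient supersaturation relax
            # back to the solid (precipitation), avoiding a discontinuous
            # switching surface in the RHS.
            c_lumen = dis / lumen_v
            cap = 1.0 - c_lumen / v.sat_umol_l
            r_diss = v.kdiss * sol * cap
            d_sol = -r_diss - kt * sol
            d_sol[1:] += kt[:-1] * sol[:-1]
            r_abs = v.kabs * dis
            d_dis = r_diss - kt * dis - r_abs
            d_dis[1:] += kt[:-1] * dis[:-1]
            absorbed = r_abs.sum()
            fecal = kt[-1] * (sol[-1] + dis[-1])

            # --- metabolism
            cu_liver = a_t[i_liver] / vols[i_liver] / v.kpu[i_liver]
            cu_gut = a_t[i_gut] / vols[i_gut] / v.kpu[i_gut]
            if v.clint_total:
                met_liver = v.clint_total * cu_liver
                met_gut = 0.0
            else:
                met_liver = (v.clint_cyp_liver * e_l * phi + v.clint_other) * cu_liver
                met_gut = v.clint_cyp_gut * e_g * phi * cu_gut

            # --- circulation
            c_out = a_t / vols / kp  # equilibrated venous concentration
            d_t = np.zeros(n_org)
            d_t[direct] = v.qx[direct] * (cp - c_out[direct])
            d_t[i_spleen] = q_spl * (cp - c_out[i_spleen])
            d_t[i_gut] = q_gut * (cp - c_out[i_gut]) + absorbed - met_gut
            d_t[i_liver] = (
                q_ha * cp
                + q_gut * c_out[i_gut]
                + q_spl * c_out[i_spleen]
                - q_hv * c_out[i_liver]
                - met_liver
            )
            d_p = (
                -(v.qx[direct].sum() + q_ha + q_gut + q_spl) * cp
                + (v.qx[direct] * c_out[direct]).sum()
                + q_hv * c_out[i_liver]
            )

            dy[base : base + n_gi] = d_sol
            dy[base + n_gi : base + 2 * n_gi] = d_dis
            dy[base + 2 * n_gi] = d_p
            dy[base + 2 * n_gi + 1 : base + 2 * n_gi + 1 + n_org] = d_t
            dy[base + per_victim - 2] = met_liver + met_gut  # cumulative eliminated
            dy[base + per_victim - 1] = fecal
        return dy

    # ---- compiled RHS (numerically identical; removes Python overhead) ----
    from ._kernel import rhs_kernel

    def _kind_code(drv):
        return 0 if drv[0] == "victim" else 1

    def _ia(lst, *fields):
        kinds = np.array([_kind_code(e[0]) for e in lst], dtype=np.int64)
        idxs = np.array([e[0][1] for e in lst], dtype=np.int64)
        cols = [np.array([e[i + 1] for e in lst], dtype=np.float64) for i in range(fields[0])]
        return (kinds, idxs, *cols)

    nv = len(victims)
    pack = dict(
        n_gi=n_gi,
        per_victim=per_victim,
        v_off=np.array([offsets[v.name] for v in victims], dtype=np.int64),
        p_off=np.array([perp_off[p.name] for p in perps], dtype=np.int64),
        i_gut=i_gut,
        i_liver=i_liver,
        i_spleen=i_spleen,
        i_shbg=i_shbg,
        i_el=i_el,
        i_eg=i_eg,
        vp=vp,
        vols=vols,
        q_ha=q_ha,
        q_gut=q_gut,
        q_spl=q_spl,
        q_hv=q_hv,
        kt=kt,
        lumen_v=np.asarray(lumen_v, dtype=np.float64),
        v_mode=np.array([0 if v.binding == "constant" else 1 for v in victims], dtype=np.int8),
        v_fu_const=np.array([getattr(v, "fu_const", 0.0) for v in victims]),
        v_alb_ratio=np.array(
            [
                (v.alb_um / v.kd_alb_um if v.binding == "kinetic" and math.isfinite(v.kd_alb_um) else 0.0)
                for v in victims
            ]
        ),
        v_kd_shbg_nm=np.array(
            [
                (v.kd_shbg_nm if v.binding == "kinetic" and math.isfinite(v.kd_shbg_nm) else -1.0)
                for v in victims
            ]
        ),
        v_inv_fu_scale=np.array([1.0 / v.fu_scale for v in victims]),
        v_kpu=np.vstack([v.kpu for v in victims]) if nv else np.zeros((0, n_org)),
        v_qx=np.vstack([v.qx for v in victims]) if nv else np.zeros((0, n_org)),
        v_sat=np.vstack([v.sat_umol_l for v in victims]) if nv else np.zeros((0, n_gi)),
        v_kabs=np.vstack([v.kabs for v in victims]) if nv else np.zeros((0, n_gi)),
        v_kdiss=np.array([v.kdiss for v in victims]),
        v_clint_cyp_l=np.array([v.clint_cyp_liver for v in victims]),
        v_clint_other=np.array([v.clint_other for v in victims]),
        v_clint_cyp_g=np.array([v.clint_cyp_gut for v in victims]),
        v_clint_total=np.array([v.clint_total for v in victims]),
        p_ka=np.array([p.pk.ka_1_h for p in perps]),
        p_cl=np.array([p.pk.cl_l_h for p in perps]),
        p_v=np.array([p.pk.v_l for p in perps]),
        p_fu=np.array([p.pk.fu for p in perps]),
        kdeg_shbg=kdeg_shbg,
        shbg0=shbg0,
        kdeg_el=kdeg_el,
        kdeg_eg=kdeg_eg,
    )
    ck, ci_, cki = _ia(cyp_competitive, 1) if cyp_competitive else (
        np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0))
    ik, ii, iem, iec = _ia(cyp_induction, 2) if cyp_induction else (
        np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0), np.zeros(0))
    mk, mi, mka, mki = _ia(cyp_mbi, 2) if cyp_mbi else (
        np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0), np.zeros(0))
    sk, si, sem, sec = _ia(shbg_induction, 2) if shbg_induction else (
        np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0), np.zeros(0))
    pack.update(
        comp_kind=ck, comp_idx=ci_, comp_ki=cki,
        ci_kind=ik, ci_idx=ii, ci_emax=iem, ci_ec50=iec,
        mb_kind=mk, mb_idx=mi, mb_kinact=mka, mb_ki=mki,
        si_kind=sk, si_idx=si, si_emax=sem, si_ec50=sec,
    )
    pack_values = tuple(pack.values())

    def rhs_compiled(t, y):
        dy = np.empty_like(y)
        rhs_kernel(y, dy, *pack_values)
        return dy

    system = ModelSystem(
        individual=individual,
        victims=victims,
        perps=perps,
        organs=organs,
        n_states=n_states,
        dose_events=events,
        dissolution_schedule=[],
        rhs=rhs_compiled,
        assembly_inputs={
            "individual": individual,
            "regimens": tuple(regimens),
            "compounds": compounds,
            "shbg_variant": shbg_variant,
            "overrides": overrides,
        },
    )
    system.rhs_python = rhs  # reference implementation, kept for cross-checks
    system._layout = SimpleNamespace(
        offsets=offsets,
        perp_off=perp_off,
        per_victim=per_victim,
        i_shbg=i_shbg,
        i_el=i_el,
        i_eg=i_eg,
        vp=vp,
        n_org=n_org,
        shbg0=shbg0,
    )
    return system


def _fast_fu(cp_nm: float, alb_um: float, shbg_nm: float, kd_alb_um: float, kd_shbg_nm: float) -> float:
    """Closed-form unbound fraction (albumin excess, SHBG depletable)."""
    a = alb_um / kd_alb_um if math.isfinite(kd_alb_um) else 0.0
    if not math.isfinite(kd_shbg_nm):
        return 1.0 / (1.0 + a)
    if cp_nm <= 0.0:
        return 1.0 / (1.0 + a + shbg_nm / kd_shbg_nm)
    b = (1.0 + a) * kd_shbg_nm + shbg_nm - cp_nm
    disc = b * b + 4.0 * (1.0 + a) * cp_nm * kd_shbg_nm
    free = (-b + math.sqrt(disc)) / (2.0 * (1.0 + a))
    return free / cp_nm


def simulate(
    system: ModelSystem,
    t_end: float,
    rtol: float = 1e-6,
    atol: float = 1e-12,
    output_dt: float = 0.25,
    t_start: float = 0.0,
) -> SimulationResult:
    """Integrate the assembled system with dose events as state jumps.

    Uses LSODA (stiffness-switching) piecewise between dose discontinuities;
    output is sampled on a regular grid.  Mass balance (absorbed + remaining
    GI + body + eliminated vs. administered) is audited per compound.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    lay = system._layout
    y = np.zeros(system.n_states)
    y[lay.i_shbg] = lay.shbg0
    y[lay.i_el] = 1.0
    y[lay.i_eg] = 1.0

    t_grid = np.arange(t_start, t_end + output_dt * 0.5, output_dt)
    out = np.empty((len(t_grid), system.n_states))

    for t_e, _idx, _amount, _ in system.dose_events:
        if t_e < t_start:
            raise ValueError("dose events before t_start are not supported")
    events = [e for e in system.dose_events if t_start <= e[0] <= t_end]
    breakpoints = sorted({t_end, *[e[0] for e in events if e[0] > t_start]})

    def apply_events(t_at: float) -> None:
        for e in events:
            if abs(e[0] - t_at) < 1e-12:
                y[e[1]] += e[2]

    apply_events(t_start)
    out[0] = y
    gi = 1  # next output row; grid points at dose times get the pre-dose state
    t_cur = t_start
    for t_next in breakpoints:
        lo = np.searchsorted(t_grid, t_cur, side="right")
        hi = np.searchsorted(t_grid, t_next + 1e-12, side="right")
        t_eval = t_grid[lo:hi]
        sol = solve_ivp(
            system.rhs,
            (t_cur, t_next),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            t_eval=t_eval if len(t_eval) else None,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={sol.t[-1] if sol.t.size else t_cur:.3f} h: "
                f"{sol.message}; state snapshot: {y}"
            )
        if len(t_eval):
            out[lo:hi] = sol.y.T
            gi = hi
        y = sol.y[:, -1].copy()
        apply_events(t_next)
        t_cur = t_next
    if gi < len(t_grid):
        out[gi:] = y
    out = np.maximum(out, 0.0)

    # ---- derive per-compound series ---------------------------------------
    compounds = {}
    mass_err = {}
    vp = lay.vp
    shbg_series = out[:, lay.i_shbg]
    for v in system.victims:
        base = lay.offsets[v.name]
        gi = out[:, base : base + 2 * _N_GI].sum(axis=1)
        a_p = out[:, base + 2 * _N_GI]
        tissues = out[:, base + 2 * _N_GI + 1 : base + 2 * _N_GI + 1 + lay.n_org]
        met = out[:, base + lay.per_victim - 2]
        fec = out[:, base + lay.per_victim - 1]
        cp = a_p / vp
        free = np.empty_like(cp)
        alb_b = np.empty_like(cp)
        shbg_b = np.empty_like(cp)
        if v.binding == "constant":
            free = v.fu_const * cp
            alb_b = (1.0 - v.fu_const) * cp
            shbg_b = np.zeros_like(cp)
        else:
            for i, (c, s) in enumerate(zip(cp, shbg_series)):
                fu = _fast_fu(c * 1e3, v.alb_um, s / v.fu_scale, v.kd_alb_um, v.kd_shbg_nm)
                free[i] = fu * c
                shbg_tot = s / v.fu_scale
                kds = v.kd_shbg_nm
                f_nm = free[i] * 1e3
                shbg_b[i] = (shbg_tot * f_nm / (kds + f_nm)) / 1e3 if f_nm > 0 else 0.0
                alb_b[i] = c - free[i] - shbg_b[i]
        dosed = sum(
            amt
            for (t_e, idx, amt, _k) in system.dose_events
            if base <= idx < base + lay.per_victim and t_e <= t_grid[-1] + 1e-9
        )
        accounted = gi[-1] + a_p[-1] + tissues[-1].sum() + met[-1] + fec[-1]
        mass_err[v.name] = abs(accounted - dosed) / dosed if dosed > 0 else 0.0
        compounds[v.name] = SimpleNamespace(
            molecular_weight=v.mw,
            plasma_total=cp,
            plasma_free=free,
            albumin_bound=alb_b,
            shbg_bound=shbg_b,
            gi_amount=gi,
            tissue_amounts=tissues,
            metabolized=met,
            fecal=fec,
            fu=np.divide(free, cp, out=np.full_like(cp, np.nan), where=cp > 0),
        )
    for p in system.perps:
        b = lay.perp_off[p.name]
        c_tot = out[:, b + 1] / p.pk.v_l
        compounds[p.name] = SimpleNamespace(
            molecular_weight=p.mw,
            plasma_total=c_tot,
            plasma_free=p.pk.fu * c_tot,
            albumin_bound=(1 - p.pk.fu) * c_tot,
            shbg_bound=np.zeros_like(c_tot),
            fu=np.full_like(c_tot, p.pk.fu),
        )

    return SimulationResult(
        times_h=t_grid,
        compounds=compounds,
        shbg_nmol_l=shbg_series,
        e_liver_rel=out[:, lay.i_el],
        e_gut_rel=out[:, lay.i_eg],
        individual=system.individual,
        mass_balance_rel_error=mass_err,
    )


def simulate_population(
    population,
    regimens: Sequence[DosingRegimen],
    t_end: float,
    compounds: dict[str, CompoundParameters] | None = None,
    shbg_variant: str | None = None,
    overrides: dict[str, float] | None = None,
    output_dt: float = 0.5,
    rtol: float = 1e-6,
) -> tuple[list[SimulationResult], dict[str, SimpleNamespace]]:
    """Per-individual assembly + simulation, with pointwise summary bands.

    Returns the individual results and, per compound, mean and 5th-95th
    percentile bands of the total plasma concentration on the shared grid.
    """
    results = []
    for i, ind in enumerate(population):
        try:
            system = assemble(
                ind,
                regimens,
                compounds=dict(compounds) if compounds else None,
                shbg_variant=shbg_variant,
                overrides=overrides,
            )
            results.append(simulate(system, t_end, output_dt=output_dt, rtol=rtol))
        except Exception as exc:  # annotate with run id, then re-raise
            raise RuntimeError(f"individual {i}: {exc}") from exc
    summary = {}
    for name in results[0].compounds:
        stack = np.vstack([r.plasma_total(name) for r in results])
        summary[name] = SimpleNamespace(
            times_h=results[0].times_h,
            mean=stack.mean(axis=0),
            p5=np.percentile(stack, 5, axis=0),
            p95=np.percentile(stack, 95, axis=0),
        )
    return results, summary
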