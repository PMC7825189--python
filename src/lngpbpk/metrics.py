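"""Noncompartmental analysis, DDI ratios and local sensitivity coefficients.

NCA uses the linear-up/log-down trapezoid, a log-linear terminal fit (the
last five points or the span of three terminal half-lives, whichever is
longer) and the standard moment estimators: CL = D/AUC_inf,
Vss = D*AUMC/AUC^2 (exact for IV bolus; reported as *apparent* for oral
data, where it carries bioavailability and absorption-time inflation).
DDI magnitude is classified with the regulatory bins (inhibition: weak
[1.25, 2), moderate [2, 5), strong >= 5; induction: weak 20-50%, moderate
50-80%, strong > 80% AUC reduction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import ModelSystem, SimulationResult, simulate

__all__ = [
    "PKMetrics",
    "SensitivityResult",
    "auc_trapz",
    "nca",
    "nca_from_arrays",
    "aucr",
    "classify_ddi",
    "local_sensitivity",
]


@dataclass(frozen=True)
class PKMetrics:
    auc_0_t: float  # conc*h
    auc_0_inf: Optional[float]
    cmax: float
    tmax: float
    t_half: Optional[float]  # h; None when no valid terminal slope
    cl: Optional[float]  # L/h (apparent for oral)
    vss_l: Optional[float]
    vss_l_kg: Optional[float]

    def __post_init__(self):
        if self.auc_0_inf is not None and self.auc_0_inf < self.auc_0_t * (1 - 1e-9):
            raise ValueError("AUC(0-inf) must be >= AUC(0-t)")


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    sensitivity: float  # (dAUC/AUC) / (dp/p), central over +/-perturbation
    perturbation: float
    auc_base: float


def auc_trapz(t: np.ndarray, c: np.ndarray, moment: bool = False) -> float:
    """Linear-up/log-down trapezoidal AUC (or AUMC with ``moment``)."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    y = t * c if moment else c
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    y1, y2 = y[:-1], y[1:]
    lin = 0.5 * (y1 + y2) * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.log(c1 / c2) / dt
        logdown = np.where(moment, (y1 - y2) / k - 0.0, (c1 - c2) / k)
        if moment:
            # AUMC log segment: int t*c = (t1*c1 - t2*c2)/k + (c1 - c2)/k^2
            logdown = (t[:-1] * c1 - t[1:] * c2) / k + (c1 - c2) / k**2
    use_log = (c2 < c1) & (c2 > 0) & np.isfinite(logdown)
    seg = np.where(use_log, logdown, lin)
    return float(seg.sum())


def _terminal_fit(t: np.ndarray, c: np.ndarray) -> tuple[Optional[float], int]:
    """Log-linear terminal slope; returns (lambda_z, n_points_used)."""
    pos = c > 0
    if pos.sum() < 3:
        return None, 0
    i_max = int(np.argmax(c))
    # candidate: last 5 positive points after Cmax
    idx = np.where(pos)[0]
    idx = idx[idx > i_max]
    if len(idx) < 3:
        return None, 0
    sel = idx[-5:] if len(idx) >= 5 else idx
    lam = _slope(t[sel], c[sel])
    if lam is not None and lam > 0:
        # extend window to >= 3 terminal half-lives if data allow
        span = 3.0 * math.log(2.0) / lam
        sel2 = idx[t[idx] >= t[idx[-1]] - span]
        if len(sel2) > len(sel):
            lam2 = _slope(t[sel2], c[sel2])
            if lam2 is not None and lam2 > 0:
                return lam2, len(sel2)
        return lam, len(sel)
    return None, len(sel)


def _slope(t, c) -> Optional[float]:
    if len(t) < 3:
        return None
    coef = np.polyfit(t, np.log(c), 1)
    lam = -coef[0]
    return lam if np.isfinite(lam) else None


def nca_from_arrays(
    t: np.ndarray,
    c: np.ndarray,
    dose: float,
    route: str = "iv_bolus",
    interval_h: Optional[float] = None,
    body_weight_kg: Optional[float] = None,
) -> PKMetrics:
    """NCA on a concentration-time profile.

    ``dose`` must be expressed in (concentration unit) x L so that
    CL = dose/AUC comes out in L/h.  With ``interval_h`` the AUC(0-t) is
    computed over the final dosing interval (steady-state usage).
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if interval_h is not None:
        mask = t >= t[-1] - interval_h - 1e-9
        auc_t = auc_trapz(t[mask], c[mask])
    else:
        auc_t = auc_trapz(t, c)
    cmax = float(c.max())
    tmax = float(t[int(np.argmax(c))])

    lam, _ = _terminal_fit(t, c)
    t_half = math.log(2.0) / lam if lam else None
    auc_inf = aumc_inf = None
    cl = vss = vss_kg = None
    if lam and interval_h is None:
        c_last = float(c[c > 0][-1])
        t_last = float(t[c > 0][-1])
        auc_inf = auc_trapz(t, c) + c_last / lam
        aumc_inf = auc_trapz(t, c, moment=True) + c_last * t_last / lam + c_last / lam**2
        if dose > 0:
            cl = dose / auc_inf
            vss = dose * aumc_inf / auc_inf**2
            if body_weight_kg:
                vss_kg = vss / body_weight_kg
    elif interval_h is not None and dose > 0:
        cl = dose / auc_t  # steady-state clearance over the interval
    return PKMetrics(
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        cmax=cmax,
        tmax=tmax,
        t_half=t_half,
        cl=cl,
        vss_l=vss,
        vss_l_kg=vss_kg,
    )


def nca(
    result: SimulationResult,
    compound: str,
    dose_mg: float,
    route: str = "iv_bolus",
    interval_h: Optional[float] = None,
    unbound: bool = False,
) -> PKMetrics:
    """NCA on a simulated profile (internal µmol/L scale; CL in L/h)."""
    mw = result.compounds[compound].molecular_weight
    c = result.plasma_unbound(compound) if unbound else result.plasma_total(compound)
    dose_umol = dose_mg / mw * 1e3
    return nca_from_arrays(
        result.times_h,
        c,
        dose=dose_umol,
        route=route,
        interval_h=interval_h,
        body_weight_kg=result.individual.body_weight,
    )


def classify_ddi(ratio: float) -> str:
    if ratio >= 5:
        return "strong inhibition"
    if ratio >= 2:
        return "moderate inhibition"
    if ratio >= 1.25:
        return "weak inhibition"
    reduction = 1.0 - ratio
    if reduction > 0.8:
        return "strong induction"
    if reduction > 0.5:
        return "moderate induction"
    if reduction > 0.2:
        return "weak induction"
    return "none"


def aucr(with_perp: PKMetrics | float, without_perp: PKMetrics | float) -> tuple[float, str]:
    """AUC ratio with/without perpetrator plus its regulatory DDI class."""
    a = with_perp.auc_0_t if isinstance(with_perp, PKMetrics) else float(with_perp)
    b = without_perp.auc_0_t if isinstance(without_perp, PKMetrics) else float(without_perp)
    ratio = a / b
    return ratio, classify_ddi(ratio)


def local_sensitivity(
    system: ModelSystem,
    parameter: str,
    compound: str = "LNG",
    t_end: float = 120.0,
    perturbation: float = 0.10,
    output_dt: float = 0.25,
    dose_mg: Optional[float] = None,
) -> SensitivityResult:
    """Central-difference local sensitivity of AUC(0-inf) to one parameter.

    S = ((AUC(p(1+d)) - AUC(p(1-d))) / AUC(p)) / (2d); S = 1 means a 10%
    parameter increase produces a 10% AUC increase.  The parameter is
    addressed by its override key (e.g. ``fu_scale``,
    ``LNG.cyp3a4_specific_clearance``); an unknown key leaves the model
    unchanged and yields S = 0, a parameter-not-found error is raised
    instead.
    """
    known = {"fu_scale", "EE.ki_cyp3a4"}
    prefixes = (
        ".lipophilicity_logp",
        ".cyp3a4_specific_clearance",
        ".other_hepatic_clearance",
        ".total_hepatic_clearance",
        ".specific_intestinal_permeability",
        ".t80",
    )
    if parameter not in known and not parameter.endswith(prefixes):
        raise KeyError(f"parameter {parameter!r} is not addressable")

    def auc_for(factor: float) -> float:
        sys_f = system.rebuild({parameter: factor}) if factor != 1.0 else system
        res = simulate(sys_f, t_end, output_dt=output_dt)
        m = nca(res, compound, dose_mg or 0.0, route="oral")
        return m.auc_0_inf if m.auc_0_inf else m.auc_0_t

    base = auc_for(1.0)
    if base <= 0:
        raise ValueError("base AUC must be positive")
    hi = auc_for(1.0 + perturbation)
    lo = auc_for(1.0 - perturbation)
    s = ((hi - lo) / base) / (2.0 * perturbation)
    return SensitivityResult(parameter=parameter, sensitivity=s, perturbation=perturbation, auc_base=base)
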