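"""Dynamic regulation pools: SHBG and CYP3A4 turnover, induction, MBI.

Both regulated species follow zero-order synthesis / first-order
degradation turnover.  Inducers scale the synthesis rate with an Emax
function of their unbound driver concentration (multiple inducers combine
multiplicatively); mechanism-based inactivators add a concentration-
dependent first-order loss to the degradation of CYP3A4.  Competitive
inhibitors never touch the enzyme pool — they scale the CYP3A4-mediated
metabolic rate through :func:`competitive_inhibition_factor`.

Default turnover half-lives: SHBG ~7 days (postpartum decay estimate);
hepatic CYP3A4 36 h and gut-wall CYP3A4 23 h (standard values, the source
analysis does not report its own).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "TurnoverPool",
    "InductionEffect",
    "synthesis_multiplier",
    "combined_induction",
    "shbg_rhs",
    "cyp3a4_rhs",
    "mbi_inactivation_rate",
    "competitive_inhibition_factor",
    "SHBG_HALF_LIFE_H",
    "CYP3A4_LIVER_HALF_LIFE_H",
    "CYP3A4_GUT_HALF_LIFE_H",
]

SHBG_HALF_LIFE_H = 7.0 * 24.0
CYP3A4_LIVER_HALF_LIFE_H = 36.0
CYP3A4_GUT_HALF_LIFE_H = 23.0


@dataclass
class TurnoverPool:
    """Zero-order synthesis / first-order degradation pool."""

    baseline: float  # concentration (or relative amount)
    half_life_h: float
    current: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.half_life_h <= 0:
            raise ValueError("baseline and half_life must be positive")
        if self.current is None:
            self.current = self.baseline

    @property
    def kdeg(self) -> float:
        """Degradation rate constant, 1/h."""
        return math.log(2.0) / self.half_life_h

    @property
    def ksyn(self) -> float:
        """Synthesis rate (concentration/h) holding the unperturbed steady state."""
        return self.kdeg * self.baseline


@dataclass(frozen=True)
class InductionEffect:
    """Emax stimulation of synthesis by one driver compound."""

    emax_fold: float  # maximal FOLD-change of synthesis (>= 1)
    ec50: float  # driver concentration at half-maximal effect
    driver: str = ""

    def __post_init__(self) -> None:
        if self.emax_fold < 1:
            raise ValueError("emax_fold is a fold-change and must be >= 1")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")


def synthesis_multiplier(c_driver: float, eff: InductionEffect) -> float:
    """Fold-change of synthesis: M = 1 + (Emax_fold - 1) c / (EC50 + c).

    The published Emax of 2.3 is the maximal net fold-change of the SHBG
    steady state, hence the (Emax_fold - 1) increment form: a saturating
    driver shifts the pool to exactly Emax_fold x baseline.
    """
    if c_driver < 0:
        raise ValueError("driver concentration must be >= 0")
    return 1.0 + (eff.emax_fold - 1.0) * c_driver / (eff.ec50 + c_driver)


def combined_induction(
    effects: Sequence[InductionEffect], driver_concs: Sequence[float]
) -> float:
    """Multiplicative (order-independent) combination of induction effects."""
    m = 1.0
    for eff, c in zip(effects, driver_concs):
        m *= synthesis_multiplier(c, eff)
    return m


def shbg_rhs(
    pool: TurnoverPool,
    effects: Sequence[InductionEffect] = (),
    driver_concs: Sequence[float] = (),
) -> float:
    """d[SHBG]/dt = ksyn * prod(M_i) - kdeg * current  (concentration/h)."""
    return pool.ksyn * combined_induction(effects, driver_concs) - pool.kdeg * pool.current


def mbi_inactivation_rate(
    kinact_1_h: float, ki_mbi: float, c_unbound: float
) -> float:
    """First-order inactivation rate kinact * c / (KI + c), 1/h."""
    if c_unbound < 0:
        raise ValueError("concentration must be >= 0")
    return kinact_1_h * c_unbound / (ki_mbi + c_unbound)


def cyp3a4_rhs(
    pool: TurnoverPool,
    induction_effects: Sequence[InductionEffect] = (),
    induction_concs: Sequence[float] = (),
    mbi_terms: Iterable[tuple[float, float, float]] = (),
) -> float:
    """dE/dt for the CYP3A4 pool.

    dE/dt = ksyn * prod(M_ind) - (kdeg + sum kinact c/(KI+c)) * E.
    ``mbi_terms`` iterates (kinact_1_h, ki_mbi, c_unbound) triples.
    Competitive inhibitors do not appear here.
    """
    loss = pool.kdeg
    for kinact, ki, c in mbi_terms:
        loss += mbi_inactivation_rate(kinact, ki, c)
    return pool.ksyn * combined_induction(induction_effects, induction_concs) - loss * pool.current


def competitive_inhibition_factor(
    unbound_concs: Sequence[float], kis: Sequence[float]
) -> float:
    """Rate-scaling factor 1 / (1 + sum c_i/Ki_i) in (0, 1].

    Applied to the CYP3A4-mediated intrinsic clearance of the victim; with
    EE at steady-state therapeutic levels this reproduces the ~30% lower
    CYP3A4-mediated LNG clearance seen with combined formulations.
    """
    s = 0.0
    for c, ki in zip(unbound_concs, kis):
        if c < 0 or ki <= 0:
            raise ValueError("require conc >= 0 and ki > 0")
        s += c / ki
    return 1.0 / (1.0 + s)
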