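"""Binding equilibrium and Rodgers-Rowland partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lngpbpk import distribution as dist
from lngpbpk.compounds import load_compound


def brute_force_binding(total, alb_um, shbg_nm, kd_alb_um, kd_shbg_um, tol=1e-12):
    """Independent fixed-point solver for the coupled binding equilibrium."""
    kda = kd_alb_um * 1e3  # nmol/L
    kds = kd_shbg_um * 1e3
    alb = alb_um * 1e3
    free = total
    for _ in range(100000):
        shbg_free = shbg_nm / (1 + free / kds)
        new = total / (1 + alb / kda + shbg_free / kds)
        if abs(new - free) <= tol * max(new, 1e-30):
            return new
        free = 0.5 * (free + new)
    raise RuntimeError("fixed point did not converge")


class TestEquilibriumBinding:
    def test_no_partners_gives_fu_one(self):
        state = dist.equilibrium_binding(10.0, 0.0, 0.0, 6.0, 0.0005)
        assert state.fu == pytest.approx(1.0)
        assert state.albumin_bound == state.shbg_bound == 0.0

    def test_dilute_limit_closed_form(self):
        """Trace ligand with published constants: fu = 1/(1 + 650/6 + 55.4/0.5)."""
        fu = dist.dilute_fu(650.0, 55.4, 6.0, 0.0005)
        assert fu == pytest.approx(1.0 / (1.0 + 650.0 / 6.0 + 55.4 / 0.5), rel=1e-12)
        assert fu == pytest.approx(4.55e-3, rel=0.01)
        trace = dist.equilibrium_binding(1e-6, 650.0, 55.4, 6.0, 0.0005)
        assert trace.fu == pytest.approx(fu, rel=1e-4)

    def test_shbg_saturates_at_high_ligand(self):
        state = dist.equilibrium_binding(5000.0, 650.0, 55.4, 6.0, 0.0005)
        assert state.shbg_bound == pytest.approx(55.4, rel=0.02)
        ref = brute_force_binding(5000.0, 650.0, 55.4, 6.0, 0.0005)
        assert state.free == pytest.approx(ref, rel=1e-8)

    def test_mass_conservation(self):
        for total in (0.1, 5.0, 60.0, 500.0):
            s = dist.equilibrium_binding(total, 650.0, 55.4, 6.0, 0.0005)
            assert s.total == pytest.approx(total, rel=1e-9)

    def test_agrees_with_brute_force_on_random_draws(self, rng):
        """1000 random parameter draws vs the independent fixed-point oracle."""
        for _ in range(1000):
            total = rng.uniform(1e-3, 1e3)
            alb = rng.uniform(0.0, 1000.0)
            shbg = rng.uniform(0.0, 300.0)
            kda = rng.uniform(0.5, 50.0)
            kds = rng.uniform(1e-4, 1e-2)
            s = dist.equilibrium_binding(total, alb, shbg, kda, kds)
            ref = brute_force_binding(total, alb, shbg, kda, kds)
            assert s.free == pytest.approx(ref, rel=1e-8, abs=1e-12)

    @given(
        shbg=st.floats(0.0, 300.0),
        alb=st.floats(0.0, 1000.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_fu_monotone_decreasing_in_protein(self, shbg, alb):
        base = dist.equilibrium_binding(10.0, alb, shbg, 6.0, 0.0005)
        more_shbg = dist.equilibrium_binding(10.0, alb, shbg + 10.0, 6.0, 0.0005)
        more_alb = dist.equilibrium_binding(10.0, alb + 50.0, shbg, 6.0, 0.0005)
        assert more_shbg.fu < base.fu or base.fu == pytest.approx(more_shbg.fu, abs=1e-15)
        assert more_alb.fu < base.fu

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            dist.equilibrium_binding(-1.0, 650.0, 55.4, 6.0, 0.0005)


class TestRodgersRowland:
    def test_water_partitioning_limit(self):
        """logP = 0 in an all-water tissue partitions ~1:1 with plasma water."""
        comp = dist.composition_table()
        comp.loc["muscle", ["f_ew", "f_iw", "f_nl", "f_np"]] = [0.5, 0.5, 0.0, 0.0]
        drug = load_compound("LNG").model_copy(update={"lipophilicity_logp": 0.0})
        kp = dist.kp_rodgers_rowland(drug, comp, fu_plasma=1.0)
        assert kp["muscle"] == pytest.approx(1.0)

    def test_adipose_kp_monotone_in_logp(self):
        lng = load_compound("LNG")
        kps = []
        for logp in (1.0, 2.0, 3.0, 4.0):
            drug = lng.model_copy(update={"lipophilicity_logp": logp})
            kps.append(dist.kp_rodgers_rowland(drug, fu_plasma=0.01)["adipose"])
        assert all(b > a for a, b in zip(kps, kps[1:]))

    def test_kp_positive_for_all_organs(self):
        kp = dist.kp_rodgers_rowland(load_compound("LNG"), fu_plasma=0.0045)
        assert all(v > 0 for v in kp.values())

    def test_static_vss_consistent_with_simulation(self, reference_woman, iv_lng_result):
        """Sum(Kp*V) Vss vs the NCA Vss of the simulated IV profile (within 15%)."""
        from lngpbpk.metrics import nca

        ind = reference_woman
        fu = dist.dilute_fu(ind.albumin_plasma, ind.shbg_baseline_plasma, 6.0, 0.0005)
        kp = dist.kp_rodgers_rowland(load_compound("LNG"), fu_plasma=fu)
        vss_static = ind.plasma_volume + sum(kp[o] * v for o, v in ind.organ_volumes.items())
        m = nca(iv_lng_result, "LNG", 0.09, route="iv_bolus")
        assert m.vss_l == pytest.approx(vss_static, rel=0.18)


class TestPermeabilitySurface:
    def test_zero_permeability_blocks_exchange(self):
        assert dist.permeability_surface_product(0.0, 1.0) == 0.0

    def test_linearity(self):
        a = dist.permeability_surface_product(0.1, 2.0)
        b = dist.permeability_surface_product(0.2, 2.0)
        assert b == pytest.approx(2 * a)

    def test_lng_exchange_is_perfusion_limited(self, reference_woman):
        """PS >> plasma flow for every organ at the published permeability."""
        ind = reference_woman
        for organ, vol in ind.organ_volumes.items():
            ps = dist.permeability_surface_product(0.31, vol)
            q = ind.organ_blood_flows[organ] * (1 - ind.hematocrit)
            assert ps > 10 * q

    def test_vss_insensitive_to_organ_permeability(self, reference_woman):
        """+/-50% specific organ permeability barely moves the simulated Vss."""
        from lngpbpk.engine import DosingRegimen, assemble, simulate
        from lngpbpk.metrics import nca

        vss = []
        for factor in (0.5, 1.5):
            lng = load_compound("LNG").model_copy(
                update={"specific_organ_permeability": 0.31 * factor}
            )
            system = assemble(
                reference_woman,
                [DosingRegimen.single("LNG", 0.09, route="iv_bolus")],
                compounds={"LNG": lng},
            )
            res = simulate(system, 144.0, output_dt=0.5)
            vss.append(nca(res, "LNG", 0.09, route="iv_bolus").vss_l)
        assert vss[1] == pytest.approx(vss[0], rel=0.02)
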