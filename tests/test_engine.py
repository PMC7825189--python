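"""Whole-body model assembly, integration, conservation and linearity."""

import numpy as np
import pytest

from lngpbpk.engine import DosingRegimen, assemble, simulate, simulate_population
from lngpbpk.metrics import auc_trapz, nca
from lngpbpk.physiology import build_reference_individual, sample_population


class TestAssemblyAndEvents:
    def test_iv_bolus_initial_condition(self, iv_lng_result):
        """IV 0.09 mg appears in plasma at t=0; GI stays empty."""
        res = iv_lng_result
        c0 = res.plasma_total("LNG")[0]
        expected = 0.09 / 312.4 * 1e3 / res.individual.plasma_volume
        assert c0 == pytest.approx(expected, rel=1e-9)
        assert res.compounds["LNG"].gi_amount.max() == 0.0

    def test_oral_lag_delays_appearance(self, reference_woman):
        res = simulate(
            assemble(reference_woman, [DosingRegimen.single("LNG", 0.09, route="oral")]),
            2.0,
            output_dt=1.0 / 60.0,
        )
        t = res.times_h
        c = res.plasma_total("LNG")
        assert np.all(c[t < 10.0 / 60.0] == 0.0)
        assert c[t > 0.5].max() > 0.0

    def test_zero_dose_stays_zero(self, reference_woman):
        res = simulate(
            assemble(reference_woman, [DosingRegimen.single("LNG", 1e-30, route="oral")]),
            24.0,
            output_dt=1.0,
        )
        assert res.plasma_total("LNG").max() < 1e-20

    def test_strictly_increasing_dose_times_required(self):
        with pytest.raises(ValueError):
            DosingRegimen("LNG", 0.09, (0.0, 0.0))


class TestConservationAndConsistency:
    def test_mass_balance_closure_iv(self, iv_lng_result):
        assert iv_lng_result.mass_balance_rel_error["LNG"] < 1e-3

    def test_mass_balance_closure_oral(self, oral_lng_result):
        assert oral_lng_result.mass_balance_rel_error["LNG"] < 1e-3

    def test_plasma_species_sum_to_total(self, iv_lng_result):
        s = iv_lng_result.compounds["LNG"]
        total = s.plasma_free + s.albumin_bound + s.shbg_bound
        np.testing.assert_allclose(total, s.plasma_total, rtol=1e-6)

    def test_tolerance_convergence(self, reference_woman):
        """Tenfold tighter integrator tolerances move the AUC by < 0.1%."""
        reg = [DosingRegimen.single("LNG", 0.09, route="iv_bolus")]
        a = []
        for rtol, atol in ((1e-6, 1e-12), (1e-7, 1e-13)):
            res = simulate(assemble(reference_woman, reg), 96.0, rtol=rtol, atol=atol, output_dt=0.5)
            a.append(auc_trapz(res.times_h, res.plasma_total("LNG")))
        assert a[1] == pytest.approx(a[0], rel=1e-3)

    def test_deterministic_given_fixed_inputs(self, reference_woman):
        reg = [DosingRegimen.single("LNG", 0.09, route="oral")]
        r1 = simulate(assemble(reference_woman, reg), 48.0, output_dt=0.5)
        r2 = simulate(assemble(reference_woman, reg), 48.0, output_dt=0.5)
        np.testing.assert_array_equal(r1.plasma_total("LNG"), r2.plasma_total("LNG"))


class TestLinearity:
    def test_iv_dose_proportionality_in_linear_regime(self, reference_woman):
        """At trace doses (SHBG far from saturation) AUC doubles with dose."""
        aucs = []
        for dose in (1e-5, 2e-5):
            res = simulate(
                assemble(reference_woman, [DosingRegimen.single("LNG", dose, route="iv_bolus")]),
                96.0,
                output_dt=0.5,
            )
            aucs.append(auc_trapz(res.times_h, res.plasma_total("LNG")))
        assert aucs[1] / aucs[0] == pytest.approx(2.0, rel=1e-4)

    def test_oral_dose_proportionality_with_shbg_saturation(self, reference_woman):
        """Therapeutic oral doses: mild SHBG saturation keeps it within ~2%."""
        aucs = []
        for dose in (0.03, 0.06):
            res = simulate(
                assemble(reference_woman, [DosingRegimen.single("LNG", dose, route="oral")]),
                144.0,
                output_dt=0.5,
            )
            aucs.append(auc_trapz(res.times_h, res.plasma_total("LNG")))
        assert aucs[1] / aucs[0] == pytest.approx(2.0, rel=0.02)

    def test_steady_state_superposition(self, reference_woman):
        """AUC(0-tau) at steady state matches single-dose AUC(0-inf) within 2%."""
        single = simulate(
            assemble(reference_woman, [DosingRegimen.single("LNG", 0.03, route="oral")]),
            240.0,
            output_dt=0.25,
        )
        m = nca(single, "LNG", 0.03, route="oral")
        multi = simulate(
            assemble(reference_woman, [DosingRegimen.repeated("LNG", 0.03, 12, 24.0)]),
            12 * 24.0,
            output_dt=0.25,
        )
        t, c = multi.times_h, multi.plasma_total("LNG")
        mask = t >= t[-1] - 24.0
        auc_tau = auc_trapz(t[mask], c[mask])
        assert auc_tau == pytest.approx(m.auc_0_inf, rel=0.03)


class TestInteractionsInEngine:
    def test_ee_coadministration_raises_lng_exposure(self, reference_woman):
        """EE competitively inhibits CYP3A4 and induces SHBG -> higher LNG AUC."""
        t_end = 10 * 24.0
        lng_only = simulate(
            assemble(reference_woman, [DosingRegimen.repeated("LNG", 0.15, 10, 24.0)]),
            t_end,
            output_dt=0.5,
        )
        chc = simulate(
            assemble(
                reference_woman,
                [
                    DosingRegimen.repeated("LNG", 0.15, 10, 24.0),
                    DosingRegimen.repeated("EE", 0.03, 10, 24.0),
                ],
            ),
            t_end,
            output_dt=0.5,
        )

        def last24(res):
            t, c = res.times_h, res.plasma_total("LNG")
            m = t >= t[-1] - 24
            return auc_trapz(t[m], c[m])

        assert last24(chc) > 1.2 * last24(lng_only)

    def test_shbg_pool_rises_under_ee(self, reference_woman):
        res = simulate(
            assemble(reference_woman, [DosingRegimen.repeated("EE", 0.03, 10, 24.0)]),
            10 * 24.0,
            output_dt=1.0,
        )
        assert res.shbg_nmol_l[-1] > 1.2 * res.shbg_nmol_l[0]

    def test_mbi_depletes_cyp3a4_pool(self, reference_woman):
        res = simulate(
            assemble(
                reference_woman,
                [DosingRegimen.repeated("clarithromycin", 500, 14, 12.0)],
            ),
            7 * 24.0,
            output_dt=1.0,
        )
        assert res.e_liver_rel[-1] < 0.5


class TestCompiledKernel:
    def test_compiled_rhs_matches_reference_implementation(self, reference_woman):
        """The numba kernel reproduces the pure-Python RHS on random states."""
        regs = [
            DosingRegimen.repeated("LNG", 0.15, 3, 24.0),
            DosingRegimen.repeated("EE", 0.03, 3, 24.0),
            DosingRegimen.repeated("rifampicin", 600, 3, 24.0),
            DosingRegimen.repeated("clarithromycin", 250, 3, 12.0),
            DosingRegimen.repeated("itraconazole", 100, 3, 24.0),
        ]
        system = assemble(reference_woman, regs)
        rng = np.random.default_rng(7)
        for _ in range(50):
            y = rng.uniform(0, 1, system.n_states) * rng.choice(
                [1e-6, 1e-3, 1.0, 100.0], system.n_states
            )
            np.testing.assert_allclose(
                system.rhs(0.0, y), system.rhs_python(0.0, y), rtol=1e-12
            )


class TestPopulationSimulation:
    def test_single_individual_summary_equals_trajectory(self, reference_woman):
        from lngpbpk.physiology import Population

        pop = Population([reference_woman], seed=0, bmi_range=(18.5, 25.0))
        results, summary = simulate_population(
            pop, [DosingRegimen.single("LNG", 0.09, route="iv_bolus")], 48.0
        )
        np.testing.assert_allclose(summary["LNG"].mean, results[0].plasma_total("LNG"))
        np.testing.assert_allclose(summary["LNG"].p5, summary["LNG"].p95)

    def test_population_bands_reproducible(self):
        pop = sample_population(3, seed=5)
        reg = [DosingRegimen.single("LNG", 0.09, route="iv_bolus")]
        _, s1 = simulate_population(pop, reg, 48.0)
        _, s2 = simulate_population(sample_population(3, seed=5), reg, 48.0)
        np.testing.assert_array_equal(s1["LNG"].mean, s2["LNG"].mean)
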