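"""fm back-calculation arithmetic and Monte-Carlo fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lngpbpk import estimation as est


class TestFmArithmetic:
    def test_no_interaction_means_no_cyp_contribution(self):
        assert est.fm_from_aucr(1.0) == 0.0

    def test_telithromycin_observed_ratio(self):
        """1.5-fold AUC increase -> ~33% CYP3A4 contribution."""
        assert est.fm_from_aucr(1.5) == pytest.approx(1 / 3, rel=1e-9)

    def test_net_ratio_after_availability_correction(self):
        assert est.fm_from_aucr(2.1) == pytest.approx(0.524, abs=5e-4)

    def test_correct_aucr_published_chain(self):
        """Observed 1.5 corrected for the 70% available pathway -> 2.1."""
        net = est.correct_aucr(1.5, 0.7)
        assert round(net, 1) == 2.1

    @pytest.mark.parametrize("aucr,frac,expected", [(2.0, 0.5, 4.0), (3.0, 1.0, 3.0)])
    def test_correct_aucr_arithmetic(self, aucr, frac, expected):
        assert est.correct_aucr(aucr, frac) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            est.fm_from_aucr(0.8)
        with pytest.raises(ValueError):
            est.correct_aucr(1.5, 0.0)
        with pytest.raises(ValueError):
            est.correct_aucr(1.5, 1.2)

    @given(st.floats(1.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_fm_aucr_inverse_identity(self, aucr):
        fm = est.fm_from_aucr(aucr)
        assert 1.0 / (1.0 - fm) == pytest.approx(aucr, rel=1e-9)

    def test_back_calculate_fm_bundles_the_chain(self):
        r = est.back_calculate_fm(1.5, 0.7)
        assert r.aucr_net == pytest.approx(1.5 / 0.7)
        assert r.fm == pytest.approx(1 - 0.7 / 1.5)


class TestMonteCarloFit:
    @staticmethod
    def _quadratic_predict(params):
        x = np.linspace(0.0, 5.0, 12)
        return params["a"] * np.exp(-params["b"] * x)

    def test_zero_extra_iterations_returns_initial(self):
        spec = est.FitSpec(bounds={"a": (1.0, 4.0)}, iterations=1, seed=0)
        obs = self._quadratic_predict({"a": 2.0, "b": 1.0})
        out = est.fit(lambda p: self._quadratic_predict({**p, "b": 1.0}), obs, spec)
        assert out.trace[0][0] == 0

    def test_same_seed_identical_trace(self):
        spec = est.FitSpec(bounds={"a": (1.0, 4.0), "b": (0.2, 3.0)}, iterations=50, seed=3)
        obs = self._quadratic_predict({"a": 2.0, "b": 1.0})
        o1 = est.fit(self._quadratic_predict, obs, spec)
        o2 = est.fit(self._quadratic_predict, obs, spec)
        assert o1.trace == o2.trace
        assert o1.estimates == o2.estimates

    def test_objective_monotone_nonincreasing(self):
        spec = est.FitSpec(bounds={"a": (1.0, 4.0), "b": (0.2, 3.0)}, iterations=80, seed=1)
        obs = self._quadratic_predict({"a": 2.5, "b": 0.7})
        out = est.fit(self._quadratic_predict, obs, spec)
        vals = [v for _, v in out.trace]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_noise_free_recovery_on_closed_form(self):
        spec = est.FitSpec(bounds={"a": (0.5, 8.0), "b": (0.1, 5.0)}, iterations=400, seed=7)
        truth = {"a": 2.0, "b": 1.3}
        out = est.fit(self._quadratic_predict, self._quadratic_predict(truth), spec)
        assert out.estimates["a"] == pytest.approx(truth["a"], rel=0.05)
        assert out.estimates["b"] == pytest.approx(truth["b"], rel=0.05)

    def test_simulation_failures_are_skipped(self):
        calls = {"n": 0}

        def flaky(params):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("integrator blew up")
            return self._quadratic_predict({**params, "b": 1.0})

        spec = est.FitSpec(bounds={"a": (1.0, 4.0)}, iterations=30, seed=5)
        out = est.fit(flaky, self._quadratic_predict({"a": 2.0, "b": 1.0}), spec)
        assert out.n_failed > 0
        assert np.isfinite(out.objective)

    def test_pbpk_parameter_recovery_noise_free(self, reference_woman):
        """Recover a clearance scale from noise-free simulated IV data."""
        from lngpbpk.engine import DosingRegimen, assemble, simulate

        reg = [DosingRegimen.single("LNG", 0.09, route="iv_bolus")]
        times = np.array([0.5, 1, 2, 4, 8, 12, 24, 48, 72])

        def predict(params):
            system = assemble(
                reference_woman,
                reg,
                overrides={"LNG.cyp3a4_specific_clearance": params["cl_scale"],
                           "LNG.other_hepatic_clearance": params["cl_scale"]},
            )
            res = simulate(system, 72.0, output_dt=0.5)
            return np.interp(times, res.times_h, res.plasma_total("LNG"))

        truth = predict({"cl_scale": 1.4})
        spec = est.FitSpec(bounds={"cl_scale": (0.3, 3.0)}, iterations=40, seed=11, step_log10=0.12)
        out = est.fit(predict, truth, spec)
        assert out.estimates["cl_scale"] == pytest.approx(1.4, rel=0.05)
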