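"""Packaged compound parameter sets and their validation."""

import math

import pytest
from pydantic import ValidationError

from lngpbpk import compounds as cp


@pytest.fixture(scope="module")
def lng():
    return cp.load_compound("LNG")


@pytest.fixture(scope="module")
def ee():
    return cp.load_compound("EE")


class TestPackagedLng:
    def test_published_physicochemistry(self, lng):
        assert lng.molecular_weight == pytest.approx(312.4)
        assert lng.lipophilicity_logp == pytest.approx(4.00)
        assert lng.aqueous_solubility == pytest.approx(2.05)
        assert lng.fassif_solubility == pytest.approx(14.0)

    def test_published_binding_kinetics(self, lng):
        alb = lng.binding("albumin")
        shbg = lng.binding("shbg")
        assert (alb.kd, alb.koff) == (6.0, 6.50)
        assert (shbg.kd, shbg.koff) == (0.0005, 17.4)
        assert alb.kon == pytest.approx(6.50 / 6.0)

    def test_published_clearances_and_permeabilities(self, lng):
        assert lng.cyp3a4_specific_clearance == pytest.approx(1.45)
        assert lng.other_hepatic_clearance == pytest.approx(0.10)
        assert lng.specific_intestinal_permeability == pytest.approx(0.0002)
        assert lng.specific_organ_permeability == pytest.approx(0.31)

    @pytest.mark.parametrize(
        "dose,t80,lag",
        [(0.03, 30, 10), (0.09, 30, 10), (0.15, 30, 10), (0.27, 30, 10), (0.75, 75, 0), (1.50, 180, 0)],
    )
    def test_published_dissolution_by_strength(self, lng, dose, t80, lag):
        f = lng.formulation_for_dose(dose)
        assert f.t80_dissolution_min == t80
        assert f.lag_time_min == lag


class TestPackagedEe:
    def test_published_parameters(self, ee):
        assert ee.molecular_weight == pytest.approx(296.4)
        assert ee.lipophilicity_logp == pytest.approx(3.6)
        assert ee.nonspecific_unbound_fraction == pytest.approx(0.015)
        assert ee.total_hepatic_clearance == pytest.approx(4.1)
        assert ee.aqueous_solubility == pytest.approx(3.9)

    def test_intestinal_permeability_normalized_to_cm_min(self, ee):
        # published as 1.0e-4 cm/s
        assert ee.specific_intestinal_permeability == pytest.approx(1.0e-4 * 60)

    def test_competitive_cyp3a4_ki(self, ee):
        comp = [i for i in ee.interactions if i.mechanism == cp.Mechanism.competitive]
        assert len(comp) == 1
        assert comp[0].ki == pytest.approx(2e-6)  # 2 pmol/L in µmol/L

    def test_shbg_emax_variants_are_alternatives(self, ee):
        shbg = {i.variant: i for i in ee.interactions if i.target == "shbg_synthesis"}
        assert shbg["net_lng_ee"].emax_fold == pytest.approx(2.3)
        assert shbg["ee_alone"].emax_fold == pytest.approx(2.25)
        assert all(i.ec50 == pytest.approx(1e-6) for i in shbg.values())


class TestDissolution:
    def test_rate_constant_definition(self):
        k = cp.dissolution_rate_constant(30.0)
        assert k == pytest.approx(math.log(5) / 30)
        assert 1 - math.exp(-k * 30.0) == pytest.approx(0.80)

    @pytest.mark.parametrize("t80,expected", [(30, 0.05365), (180, 0.008941)])
    def test_published_strengths(self, t80, expected):
        assert cp.dissolution_rate_constant(t80) == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_t80_rejected(self, bad):
        with pytest.raises(ValueError):
            cp.dissolution_rate_constant(bad)


class TestInteractions:
    def test_rifampicin_induces_cyp3a4_and_shbg(self):
        specs = cp.load_interaction("rifampicin")
        targets = {(s.target, s.mechanism.value) for s in specs}
        assert ("cyp3a4", "induction") in targets
        assert ("shbg_synthesis", "induction") in targets
        shbg = next(s for s in specs if s.target == "shbg_synthesis")
        assert shbg.emax_fold == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "perp,mechanisms",
        [
            ("itraconazole", {"competitive"}),
            ("clarithromycin", {"mbi"}),
            ("carbamazepine", {"induction"}),
            ("efavirenz", {"induction"}),
        ],
    )
    def test_mechanism_per_perpetrator(self, perp, mechanisms):
        specs = [s for s in cp.load_interaction(perp) if s.target == "cyp3a4"]
        assert {s.mechanism.value for s in specs} >= mechanisms

    def test_unknown_perpetrator_rejected(self):
        with pytest.raises(KeyError):
            cp.load_interaction("grapefruit")


class TestValidation:
    def test_negative_kd_rejected(self):
        with pytest.raises(ValidationError):
            cp.BindingSpec(partner="albumin", kd=-1.0, koff=1.0)

    def test_clearance_routes_mutually_exclusive(self):
        with pytest.raises(ValidationError):
            cp.CompoundParameters(
                name="bad",
                molecular_weight=300.0,
                cyp3a4_specific_clearance=1.0,
                total_hepatic_clearance=4.0,
            )

    def test_induction_requires_emax_and_ec50(self):
        with pytest.raises(ValidationError):
            cp.InteractionSpec(target="cyp3a4", mechanism="induction", emax_fold=2.0)

    def test_round_trip_serialization(self):
        lng = cp.load_compound("LNG")
        clone = cp.CompoundParameters.model_validate(lng.model_dump())
        assert clone == lng
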