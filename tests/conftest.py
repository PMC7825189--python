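import numpy as np
import pytest

from lngpbpk.engine import DosingRegimen, assemble, simulate
from lngpbpk.physiology import build_reference_individual, sample_population


@pytest.fixture(scope="session")
def reference_woman():
    return build_reference_individual()


@pytest.fixture(scope="session")
def iv_lng_result(reference_woman):
    """IV bolus 0.09 mg LNG in the reference woman, 144 h."""
    system = assemble(
        reference_woman, [DosingRegimen.single("LNG", 0.09, route="iv_bolus")]
    )
    return simulate(system, 144.0, output_dt=0.25)


@pytest.fixture(scope="session")
def oral_lng_result(reference_woman):
    """Oral 0.09 mg LNG in the reference woman, 144 h."""
    system = assemble(reference_woman, [DosingRegimen.single("LNG", 0.09, route="oral")])
    return simulate(system, 144.0, output_dt=0.25)


@pytest.fixture(scope="session")
def small_population():
    return sample_population(5, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231115)
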