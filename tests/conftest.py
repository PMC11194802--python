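import hypothesis
import numpy as np
import pytest

hypothesis.settings.register_profile(
    "grekin", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("grekin")


@pytest.fixture(scope="session")
def es_records():
    from grekin import canonical_barriers

    return canonical_barriers("ES")


@pytest.fixture()
def field_axis():
    from grekin import field_center_from_g

    center = field_center_from_g(2.0034, 9.4)
    return np.linspace(center - 6.0, center + 6.0, 1024)


@pytest.fixture()
def epr_bases(field_axis):
    from grekin import SpectrumModel, simulate_spectrum

    model_h = SpectrumModel(nucleus="H")
    model_d = SpectrumModel(nucleus="D")
    return simulate_spectrum(model_h, field_axis), simulate_spectrum(model_d, field_axis)
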