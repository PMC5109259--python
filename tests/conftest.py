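import numpy as np
import pytest

from rpra.exposure import ExposureContext, MetalProperties, load_metal_properties
from rpra.params import ParameterSpec, read_parameter_table
from rpra.synthetic import load_concentration_summaries

from importlib import resources


@pytest.fixture(scope="session")
def metal_props():
    return load_metal_properties()


@pytest.fixture(scope="session")
def exposure_specs():
    return read_parameter_table(
        resources.files("rpra.data") / "exposure_parameters_default.csv"
    )


@pytest.fixture(scope="session")
def summaries():
    return load_concentration_summaries()


@pytest.fixture
def point_ctx():
    """Deterministic adult receptor: every parameter a point value."""
    return ExposureContext(
        ed=24.0, bw=60.0, at=8760.0,
        ir_s=100.0, ir_sd=50.0, ir_w=2.0, ir_v=0.3, ir_a=15.0,
        ef_ia=350.0, ef_oa=225.0, ef_sw=30.0, et_sw=1.0,
        sa_o=0.5, sa_sw=1.8, af_sa=0.2, af_sd=0.5,
        theta_v=0.9, theta_w=0.3, rho_b=1.5, df=20.0, pef=1.36e9,
    )


@pytest.fixture
def simple_props():
    """Round-number metal properties for hand calculations."""
    return MetalProperties(
        metal="As", rfd_oral=3e-4, rfd_dermal=1e-4, rfd_inhalation=8.57e-5,
        kd=250.0, puf=0.1, kp=1e-3, abs_f=0.03,
    )
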