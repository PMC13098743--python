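import numpy as np
import pytest
from hypothesis import settings

from hybriddo.forward import MediumGeometry, OpticalProperties
from hybriddo.inversion import load_extinction_table
from hybriddo.io import load_reference_cohort
from hybriddo.synthetic import EffectSpec, InstrumentSpec, ProtocolSpec

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ext_table():
    return load_extinction_table()


@pytest.fixture(scope="session")
def reference_cohort():
    return load_reference_cohort()


@pytest.fixture(scope="session")
def trs_geometry():
    return MediumGeometry(rho=30.0, n_tissue=1.4, n_outside=1.0)


@pytest.fixture(scope="session")
def dcs_geometry():
    return MediumGeometry(rho=25.0, n_tissue=1.4, n_outside=1.0)


@pytest.fixture(scope="session")
def props_785():
    return OpticalProperties(785.0, 0.012, 0.95)


@pytest.fixture
def short_protocol():
    """Time-compressed protocol preserving the pre/post window structure."""
    return ProtocolSpec(
        baseline_min=10.0, transfusion_min=30.0, post_min=10.0, draw_offset_min=5.0
    )


@pytest.fixture
def instrument_10s():
    return InstrumentSpec(acq_period_s=10.0)


def quiet_effects(**overrides) -> EffectSpec:
    """EffectSpec with zero between-subject spread unless overridden."""
    base = dict(
        bf_change_sd={"cerebral": 0.0, "peripheral": 0.0},
        oef_change_sd={"cerebral": 0.0, "peripheral": 0.0},
        dhhb_sd={"cerebral": 0.0, "peripheral": 0.0},
        hct_change_sd=0.0,
        hct_pre_sd=0.0,
        paco2_sd=0.0,
        paco2_change_sd=0.0,
        baseline_cv=0.0,
        sto2_baseline_sd=0.0,
        noise_scale=0.0,
    )
    base.update(overrides)
    return EffectSpec(**base)
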