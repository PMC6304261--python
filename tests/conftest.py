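import numpy as np
import pytest

from msdgrf import (
    CohortConfig,
    DeviceModel,
    NaturalParameters,
    ScaledParameters,
    SimulationConfig,
    generate_cohort,
    to_scaled,
)


@pytest.fixture
def demo_natural() -> NaturalParameters:
    """Hand-checkable physical parameter set: lam=3, omega1^2=600,
    omega2^2=3600, zeta=0.36 for a 76 kg runner."""
    return NaturalParameters.from_masses(m1=57.0, m2=19.0, k1=34200.0, k2=68400.0, c=820.8)


@pytest.fixture
def demo_params(demo_natural) -> ScaledParameters:
    return to_scaled(demo_natural, p1=0.0, p2=0.0, v1=-1.0, v2=-0.02)


@pytest.fixture
def stance_cfg() -> SimulationConfig:
    return SimulationConfig(duration=0.3)


@pytest.fixture(scope="session")
def noiseless_trials():
    """Eight noiseless, artifact-free trials (2 subjects x 4 speeds)."""
    cfg = CohortConfig(n_subjects=2, trials_per_speed=1, seed=91)
    return generate_cohort(cfg, DeviceModel.ideal())


def draw_params(rng: np.random.Generator, m_lo=40.0, m_hi=110.0) -> ScaledParameters:
    """A random valid parameter set spanning the physical fitting region."""
    return ScaledParameters(
        p1=rng.uniform(-0.10, 0.05),
        p2=rng.uniform(-0.10, 0.05),
        v1=rng.uniform(-4.0, 1.0),
        v2=rng.uniform(-4.0, 1.0),
        omega1_sq=rng.uniform(50.0, 2000.0),
        omega2_sq=rng.uniform(500.0, 8000.0),
        lam=rng.uniform(0.3, 10.0),
        zeta=rng.uniform(0.0, 1.2),
        M=rng.uniform(m_lo, m_hi),
    )
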