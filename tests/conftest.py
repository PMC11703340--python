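import numpy as np
import pytest

from foammech.mechanics import StressStrainTrace
from foammech.protocol import ProtocolSpec
from foammech.synthetic import PronyMaterial, prony_stress, simulate_dma_protocol


@pytest.fixture(scope="session")
def sls_material() -> PronyMaterial:
    """Standard-linear-solid: E_inf=20 kPa, one arm E1=40 kPa, tau1=10 s."""
    return PronyMaterial(20e3, ((40e3, 10.0),), noise_sd=0.0)


@pytest.fixture(scope="session")
def spring_material() -> PronyMaterial:
    """Pure elastic spring, 50 kPa."""
    return PronyMaterial(50e3, (), noise_sd=0.0)


@pytest.fixture(scope="session")
def protocol() -> ProtocolSpec:
    return ProtocolSpec()


@pytest.fixture(scope="session")
def sls_trace(sls_material, protocol):
    return simulate_dma_protocol(sls_material, protocol, seed=11)


@pytest.fixture(scope="session")
def spring_trace(spring_material, protocol):
    return simulate_dma_protocol(spring_material, protocol, seed=11)


def make_ramp_hold_trace(material: PronyMaterial, ramp: float = 1.2,
                         hold: float = 120.0, target: float = 0.12,
                         sample_rate: float = 500.0) -> StressStrainTrace:
    """Ramp-to-hold ('step strain') trace with no preconditioning history."""
    n_r = int(ramp * sample_rate)
    n_h = int(hold * sample_rate)
    t = np.arange(n_r + n_h + 1) / sample_rate
    eps = np.minimum(t / ramp, 1.0) * target
    sig = prony_stress(material, t, eps)
    labels = np.where(t < ramp, "ramp", "relaxation").astype(object)
    return StressStrainTrace(t, sig, eps, labels)
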