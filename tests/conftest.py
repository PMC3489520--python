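import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import telqpcr as tq

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def exactness_config(**overrides) -> tq.SimulationConfig:
    """Noiseless plate whose plateau never binds: an exact analytic oracle.

    With all noise terms zero and the plateau far above any attainable
    signal, growth is pure geometric, so every downstream estimate has a
    closed form (Cq spacing log_E(fold), N0 round trips, method identities).
    """
    params = dict(
        seed=3, batches=1, n_unknowns=4, noise_sd=0.0, baseline_sd=0.0,
        cq_sd=0.0, cq_shared_sd=0.0, plateau=1e12,
    )
    params.update(overrides)
    return tq.SimulationConfig(**params)


@pytest.fixture(scope="session")
def exact_sim():
    return tq.simulate_plate(exactness_config())


@pytest.fixture(scope="session")
def exact_results(exact_sim):
    return tq.TelomereAssay.from_simulation(exact_sim).fit()


@pytest.fixture(scope="session")
def noisy_sim():
    """Small realistic plate: default noise figures, two batches."""
    cfg = tq.SimulationConfig(seed=11, batches=2, n_unknowns=6)
    return tq.simulate_plate(cfg)


@pytest.fixture(scope="session")
def noisy_results(noisy_sim):
    return tq.TelomereAssay.from_simulation(noisy_sim).fit()


def pure_exponential_trace(
    n0=1e-4, efficiency=2.0, baseline=5.0, cycles=40, **meta
) -> tq.FluorescenceTrace:
    c = np.arange(1, cycles + 1, dtype=float)
    defaults = dict(batch="B1", well="W001", role="unknown",
                    target="telomere", sample="s", replicate=1,
                    expected_ng=None)
    defaults.update(meta)
    return tq.FluorescenceTrace(
        readings=baseline + n0 * efficiency**c, **defaults
    )
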