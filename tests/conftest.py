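import numpy as np
import pytest

from itspower import (
    ErrorModelSpec,
    InterventionSpec,
    ScenarioConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def simple_scenario(
    t=60,
    k=30,
    effect=1.0,
    kind="step",
    ar=(0.5,),
    noise_sd=1.0,
    n_sims=200,
    seed=42,
    **kwargs,
):
    """A minimal scenario: intercept 0, no covariate, no trend."""
    return ScenarioConfig(
        t=t,
        k=k,
        intervention=InterventionSpec(kind=kind, effect_size=effect),
        error_model=ErrorModelSpec(ar_coefs=ar, noise_sd=noise_sd),
        n_sims=n_sims,
        seed=seed,
        **kwargs,
    )
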