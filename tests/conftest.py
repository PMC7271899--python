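import numpy as np
import pytest

from kaiac.params import FREE_DELTA_NAMES, RateParameterSet
from kaiac.synth import SyntheticDesign, default_truth, generate


@pytest.fixture(scope="session")
def truth_params() -> RateParameterSet:
    return default_truth().params


@pytest.fixture(scope="session")
def small_dataset():
    """A 2-condition, low-noise synthetic dataset for likelihood tests."""
    design = SyntheticDesign(
        kaiA_levels=(0.75, 3.0),
        pctATP_levels=(100.0,),
        include_dephos=True,
        include_hydrolysis=False,
    )
    return generate(design, default_truth(noise_sd=1.0), seed=11)


def random_delta_log10(rng: np.random.Generator, scale: float = 2.0) -> dict:
    """Random free modifiers, uniform in [-scale, scale] decades."""
    return {n: float(rng.uniform(-scale, scale)) for n in FREE_DELTA_NAMES}


def perturbed_params(rng: np.random.Generator, spread: float = 0.3) -> RateParameterSet:
    """A 'random valid parameter set': the reference truth with log-space
    jitter, guaranteed integrable on the protocols used in tests."""
    base = default_truth().params
    vec = base.to_vector()
    vec[:41] = vec[:41] + rng.normal(0.0, spread, size=41)  # rates/modifiers/sigma2
    return RateParameterSet.from_vector(vec)
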