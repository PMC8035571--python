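import warnings

import numpy as np
import pytest

from needlefind import (PhantomSliceSpec, PlantedLineSpec, RansacConfig,
                        generate_phantom_slice, generate_planted_points)

# local-optimisation fallbacks are expected behaviour in stress tests
warnings.filterwarnings("ignore", message="local optimization did not improve")


@pytest.fixture(scope="session")
def planted_half():
    """One planted-line dataset at 50% contamination."""
    return generate_planted_points(PlantedLineSpec(outlier_ratio=0.5, rng_seed=42))


@pytest.fixture(scope="session")
def phantom_single():
    """A clean single-needle phantom slice with its ground truth."""
    spec = PhantomSliceSpec(n_needles=1, insertion_angles=(30.0,),
                            insertion_depths=(80.0,), rng_seed=5)
    return generate_phantom_slice(spec)


@pytest.fixture
def cfg():
    return RansacConfig(rng_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
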