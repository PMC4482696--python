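import numpy as np
import pytest
from hypothesis import settings

import vegmosaic as vm

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")
from vegmosaic.landscape import PREDICTOR_NAMES


@pytest.fixture(scope="session")
def small_landscape():
    """60x60 grid, 4 types: shared by fast tests."""
    cfg = vm.LandscapeConfig(grid_rows=60, grid_cols=60, n_types=4, seed=42)
    env = vm.generate_environment(cfg)
    spec = vm.build_spec(PREDICTOR_NAMES, env.samples())
    truth = vm.generate_true_model(4, spec, seed=42)
    vegmap = vm.sample_vegetation(env, truth, seed=42)
    return {"config": cfg, "env": env, "spec": spec, "truth": truth, "vegmap": vegmap}


@pytest.fixture(scope="session")
def fitted_small(small_landscape):
    """A model fitted on the small landscape plus its design matrix."""
    env, spec, vegmap = (small_landscape[k] for k in ("env", "spec", "vegmap"))
    design = vm.expand(spec, env.samples())
    model = vm.fit(design, vegmap.labels.ravel())
    return {**small_landscape, "design": design, "model": model}


@pytest.fixture(scope="session")
def small_suite(small_landscape):
    """Default-structured scenario ensemble (16 members for speed)."""
    return vm.generate_scenarios(small_landscape["env"], n_scenarios=16, seed=7)


def rng(seed=0):
    return np.random.default_rng(seed)
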