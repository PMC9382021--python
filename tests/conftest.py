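import warnings

import pytest

from habitomics.phantom import PhantomSpec, generate_case, generate_cohort
from habitomics.habitat import build_partition
from habitomics.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_cohort():
    """Six noisy two-habitat phantoms with outcome labels."""
    return generate_cohort(6, effect_size=0.0, seed=11)


@pytest.fixture(scope="session")
def small_partition(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_partition(small_cohort.cases, seed=3)


@pytest.fixture(scope="session")
def flat_zero_noise_cases():
    """Single-slice, noise-free phantoms: the exactly separable limit."""
    spec = lambda s: PhantomSpec(
        grid_shape=(64, 64, 3),
        voxel_spacing_mm=(0.359, 0.359, 20.0),
        tumor_radius_mm=8.0,
        core_sd=0.0,
        rim_sd=0.0,
        seed=s,
    )
    return [generate_case(spec(s), f"flat{s}") for s in range(6)]


def _run_e2e(effect_size: float):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            PipelineConfig(n_cases=40, effect_size=effect_size, seed=7)
        )


@pytest.fixture(scope="session")
def e2e_effect2():
    """Full pipeline on a 40-case cohort with a planted rim-texture effect."""
    return _run_e2e(2.0)


@pytest.fixture(scope="session")
def e2e_effect2_repeat():
    """Identical configuration re-run, for byte-reproducibility checks."""
    return _run_e2e(2.0)


@pytest.fixture(scope="session")
def e2e_null():
    """Full pipeline under the null (no class effect)."""
    return _run_e2e(0.0)
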