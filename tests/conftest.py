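import numpy as np
import pytest

from turpeval import (
    NoiseModel,
    PhantomSpec,
    SkillProfile,
    build_phantom,
    render_ultrasound,
    simulate_resection,
)

# Coarse grid shared by most tests: full-size organ, 0.2 mm pixels, 20 slices.
SMALL = dict(pixel_spacing_mm=0.2, n_slices=20)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(**SMALL)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def noise_free():
    return NoiseModel(speckle_variance=0.0, blur_sigma_mm=0.0)


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def small_render_clean(small_phantom, noise_free):
    return render_ultrasound(small_phantom, noise_free)


@pytest.fixture(scope="session")
def small_render_noisy(small_phantom, default_noise):
    return render_ultrasound(small_phantom, default_noise)


@pytest.fixture(scope="session")
def disc_resection(small_phantom):
    """Degenerate skill profile: centered disc cavity in every slice."""
    post, record = simulate_resection(small_phantom, SkillProfile(seed=7))
    return post, record


def dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / float(denom) if denom else 1.0
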