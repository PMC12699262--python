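import numpy as np
import pytest

from dermakit import SyntheticSkinParams, generate_sample

# canonical H&E stain directions (unit norm, hematoxylin then eosin)
HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
HEMATOXYLIN = HEMATOXYLIN / np.linalg.norm(HEMATOXYLIN)
EOSIN = np.array([0.070, 0.990, 0.110])
EOSIN = EOSIN / np.linalg.norm(EOSIN)


def beer_lambert_render(stain_matrix: np.ndarray, concentrations: np.ndarray, shape) -> np.ndarray:
    """Forward Beer-Lambert model: OD = M @ C, I = 256 * 10^-OD - 1."""
    od = (stain_matrix @ concentrations).T.reshape(*shape, 3)
    return np.clip(np.rint(256.0 * np.power(10.0, -od) - 1.0), 0, 255).astype(np.uint8)


def he_concentration_mixture(rng: np.random.Generator, n: int) -> np.ndarray:
    """H&E-like concentrations with near-pure hematoxylin (nuclei), near-pure
    eosin (stroma) and mixed pixels — no channel saturation."""
    kind = rng.integers(0, 3, n)
    major = rng.uniform(0.8, 1.4, n)
    minor = rng.uniform(0.02, 0.08, n)
    mixed1 = rng.uniform(0.4, 1.0, n)
    mixed2 = rng.uniform(0.4, 1.0, n)
    c = np.empty((2, n))
    c[0] = np.where(kind == 0, major, np.where(kind == 1, minor, mixed1))
    c[1] = np.where(kind == 1, major, np.where(kind == 0, minor, mixed2))
    return c


@pytest.fixture(scope="session")
def flat_sample():
    """Amplitude-0 sample: the epidermis is an exact 40-px horizontal band."""
    return generate_sample(SyntheticSkinParams(
        image_height=512, image_width=512, corneum_thickness=30,
        epidermis_thickness=40, ridge_amplitude=0.0, seed=1,
    ))


@pytest.fixture(scope="session")
def sinus_sample():
    """Sinusoidal-EB sample (amplitude 10, wavelength 128)."""
    return generate_sample(SyntheticSkinParams(
        image_height=512, image_width=512, corneum_thickness=30,
        epidermis_thickness=60, ridge_amplitude=10.0, ridge_wavelength=128.0, seed=2,
    ))


@pytest.fixture(scope="session")
def band_sample():
    """Small default-size sample used by segmentation/superpixel tests."""
    return generate_sample(SyntheticSkinParams(seed=5))
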