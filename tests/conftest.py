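import numpy as np
import pytest

from tilmorph import BiomarkerConfig, LabelMask, PhantomSpec, generate_phantom
from tilmorph.io import STROMA, TUMOR


def make_mask(pixels: np.ndarray, spacing_um: float = 2.0) -> LabelMask:
    return LabelMask(pixels=np.asarray(pixels, dtype=np.uint8), spacing_um=spacing_um)


@pytest.fixture(scope="session")
def default_config() -> BiomarkerConfig:
    return BiomarkerConfig()


@pytest.fixture(scope="session")
def convex_phantom():
    """Single convex tumor nest at 2 um spacing, with lymphocytes and mitoses."""
    spec = PhantomSpec(
        n_cores=1,
        core_length_um=3000,
        tumor_nest_count=1,
        lymphocyte_fraction_in_bulk=0.12,
        mitosis_density_per_mm2=8,
        seed=3,
    )
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom():
    """Fast two-core phantom at 4 um spacing (one core tumor-free)."""
    spec = PhantomSpec(
        n_cores=2,
        core_length_um=2500,
        tumor_nest_count=2,
        tumor_nest_diameter_um=500,
        lymphocyte_fraction_in_bulk=0.15,
        mitosis_density_per_mm2=5,
        spacing_um=4,
        seed=7,
    )
    return spec, generate_phantom(spec)


def stroma_canvas(shape: tuple[int, int]) -> np.ndarray:
    """All-stroma tissue canvas to drop tumor/lymphocyte shapes onto."""
    pix = np.zeros(shape, dtype=np.uint8)
    pix[:, :] = STROMA
    return pix


def add_tumor_rect(pix: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> None:
    pix[r0:r1, c0:c1] = TUMOR
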