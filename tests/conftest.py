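import numpy as np
import pytest

from memfrac import imaging_io, synthetic


@pytest.fixture(scope="session")
def noiseless_spec():
    """Matched-PSF noiseless cell with a 20% membrane fraction in the POI."""
    return (
        synthetic.SyntheticSpec(
            seed=1,
            poisson=False,
            frames=1,
            background={r: 0.0 for r in imaging_io.ROLES},
        )
        .matched_psfs()
        .with_pm_peak("POI", 20.0)
    )


@pytest.fixture(scope="session")
def noiseless_stack(noiseless_spec):
    stack, truth = synthetic.make_cell_stack(noiseless_spec)
    return stack, truth


@pytest.fixture(scope="session")
def smooth_image():
    """A band-limited test image (blurred random field) for registration."""
    rng = np.random.default_rng(42)
    from scipy import ndimage

    img = ndimage.gaussian_filter(rng.normal(size=(128, 128)), 3.0)
    return img - img.min()
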