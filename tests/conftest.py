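import numpy as np
import pytest

from sarcospace import StriationScene, axis_roi, generate_striation_image


@pytest.fixture
def noiseless_scene() -> StriationScene:
    """Ten clean bands at 2.0 μm with equal amplitudes: exact ground truth."""
    return StriationScene(
        true_spacing=2.0, band_amplitudes=(1000.0,) * 10, seed=0
    )


@pytest.fixture
def noiseless_case(noiseless_scene):
    image, truth = generate_striation_image(noiseless_scene)
    return image, truth, axis_roi(noiseless_scene)


def make_profile_arrays(
    centers, amplitudes, sigmas, a=5.0, b=100.0, span=(0.0, 27.0), step=0.27
):
    """Analytic multipeak profile for fitting tests, no generator involved."""
    x = np.arange(span[0], span[1] + step / 2, step)
    y = a * x + b
    for c, amp, s in zip(centers, amplitudes, sigmas):
        y = y + amp * np.exp(-((x - c) ** 2) / (2 * s**2))
    return x, y
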