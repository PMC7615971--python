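import warnings

import numpy as np
import pytest

import flimfret as ff

# scikit-image 0.26 deprecation chatter from morphology helpers is not
# actionable here
warnings.filterwarnings("ignore", category=FutureWarning, module="skimage")


@pytest.fixture(scope="session")
def edges_256():
    """Standard time axis: 12.5 ns window, 256 bins."""
    return np.linspace(0.0, 12.5, 257)


@pytest.fixture(scope="session")
def gradient_scene():
    """One shared gradient scene (tau rising 0.005 ns/px from the membrane)."""
    spec = ff.SceneSpec(
        width=130,
        height=130,
        center=(65.0, 65.0),
        semi_axes=(12.0, 9.0),
        tau_field=ff.linear_tau_field(2.0, 0.005),
        hydrogel_rate=300.0,
        interior_rate=15.0,
        seed=7,
    )
    return ff.simulate_scene(spec)


@pytest.fixture(scope="session")
def flat_scene():
    """One shared constant-lifetime scene."""
    spec = ff.SceneSpec(
        width=130,
        height=130,
        center=(65.0, 65.0),
        semi_axes=(12.0, 9.0),
        tau_field=2.0,
        hydrogel_rate=300.0,
        interior_rate=15.0,
        seed=11,
    )
    return ff.simulate_scene(spec)


def segment_scene(image):
    """Run the standard segmentation front-end on a scene image."""
    inverted = ff.invert_normalize(image.intensity())
    enhanced = ff.tophat_enhance(inverted)
    edge_map = ff.canny_edges(enhanced)
    return ff.extract_primary_contour(edge_map)
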