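import warnings

import numpy as np
import pytest

from cardiohomog.phantom import (
    CONTROL_FRACTIONS,
    REGION1_FRACTIONS,
    PhantomSpec,
    generate_labels,
    render_channels,
)


def _simple_targets(myo=70.0, ecs=30.0, cleft=4.0):
    return {"myocyte": myo, "extracellular": ecs, "cleft": cleft,
            "vessel": 0.0, "fibroblast": 0.0, "myofibroblast": 0.0}


@pytest.fixture(scope="session")
def simple_targets():
    return _simple_targets()


@pytest.fixture(scope="session")
def small_phantom():
    """Myocyte/ECS/cleft phantom on a coarse grid: fast, cleft mid-window."""
    # x extent = one lattice period (23 μm) so no sliver bricks at borders
    spec = PhantomSpec(grid_shape=(46, 96, 96), voxel_size=500.0,
                       target_fractions=_simple_targets(), seed=21)
    return generate_labels(spec)


@pytest.fixture(scope="session")
def small_stack(small_phantom):
    return render_channels(small_phantom, seed=21)


def _roundtrip_case(targets, seed):
    spec = PhantomSpec(grid_shape=(160, 128, 256), voxel_size=200.0,
                       target_fractions=targets, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        truth = generate_labels(spec)
        stack = render_channels(truth, seed=seed)
    return spec, truth, stack


@pytest.fixture(scope="session")
def control_roundtrip():
    """Full-size control phantom with a noiseless rendered stack."""
    return _roundtrip_case(CONTROL_FRACTIONS, seed=3)


@pytest.fixture(scope="session")
def region1_roundtrip():
    """Full-size infarct border-zone (region 1) phantom and stack."""
    return _roundtrip_case(REGION1_FRACTIONS, seed=4)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
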