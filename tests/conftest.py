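import numpy as np
import pytest

from habitatomics.images import ImageVolume, TumorMask
from habitatomics.synthetic import generate_phantom_pair


@pytest.fixture(scope="session")
def phantom():
    """Default three-class phantom pair (seeded, shared across tests)."""
    return generate_phantom_pair(seed=7)


@pytest.fixture(scope="session")
def low_noise_phantom():
    """Nearly noise-free phantom with equal planted fractions."""
    return generate_phantom_pair(
        seed=7,
        fractions_pre=(1 / 3, 1 / 3, 1 / 3),
        class_means=(300, 200, 100),
        class_sds=(1, 1, 1),
        noise_sd=1,
    )


@pytest.fixture(scope="session")
def sphere():
    """20 mm diameter... radius-10-voxel sphere mask at 1 mm spacing, with a
    homogeneous noisy volume."""
    rng = np.random.default_rng(0)
    zz, yy, xx = np.indices((40, 40, 40))
    m = (zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 100
    vol = ImageVolume(rng.normal(200.0, 5.0, (40, 40, 40)))
    return vol, TumorMask(m)


@pytest.fixture(scope="session")
def full_panel_row(phantom):
    """One patient's full 9784-feature row (both timepoints, K=3 habitats)."""
    from habitatomics.habitats import compute_habitat_pair
    from habitatomics.radiomics import FeaturePanelConfig, extract_patient_features

    pv, pm, mv, mm, truth = phantom
    hp, hm = compute_habitat_pair(pv, pm, mv, mm, k=3, seed=0)
    row = extract_patient_features(pv, pm, hp, mv, mm, hm, FeaturePanelConfig())
    return row
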