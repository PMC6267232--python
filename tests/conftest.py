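import numpy as np
import pytest

from mnc.io import AtlasDefinition
from mnc.spectral import DEFAULT_BANDS

THETA = DEFAULT_BANDS[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20180915)


@pytest.fixture
def toy_atlas():
    """Four ROIs: DMN = {A, B, C}, FPN_left = {C, D}, FPN_right = {A, D}."""
    return AtlasDefinition(
        roi_labels=("A", "B", "C", "D"),
        rsn_memberships={
            "DMN": ("A", "B", "C"),
            "FPN_left": ("C", "D"),
            "FPN_right": ("A", "D"),
        },
        name="toy4",
    )


@pytest.fixture
def atlas16_dmn12():
    """16 ROIs with a 12-member DMN: preserves the default atlas's RSN size
    (the coupling operating range scales with RSN membership) at a fraction
    of the simulation cost."""
    labels = tuple(f"roi{i:02d}" for i in range(16))
    return AtlasDefinition(
        roi_labels=labels,
        rsn_memberships={
            "DMN": labels[:12],
            "FPN_left": labels[12:14],
            "FPN_right": labels[14:16],
        },
        name="toy16dmn12",
    )
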