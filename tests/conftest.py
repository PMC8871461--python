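import numpy as np
import pytest

from octagree.core import INTERFACES, LayerModel
from octagree.synth import SceneSpec, generate_pair

#: SceneSpec overrides that switch off noise and any EDI/conventional
#: rendering difference, so both modes render the scene identically.
NOISELESS_NEUTRAL = dict(
    speckle_contrast=0.0,
    edi_depth_gain=1.0,
    edi_inner_contrast=1.0,
    conv_depth_attenuation=1.0,
)


def flat_layers(width: int, overrides: dict | None = None,
                axial_scale: float = 3.9, lateral_scale: float = 11.0) -> LayerModel:
    """Layer model with constant (flat) interface depths, in pixels."""
    rows = {
        "ILM": 26.0, "RNFL_posterior": 41.0, "ELM": 154.0, "EZ_center": 164.0,
        "RPE_center": 182.0, "choroid_anterior": 190.0, "choroid_scleral": 267.0,
    }
    if overrides:
        rows.update(overrides)
    return LayerModel(
        {name: np.full(width, rows[name]) for name in INTERFACES},
        axial_scale, lateral_scale,
    )


@pytest.fixture(scope="session")
def speckled_pair():
    """Default-noise pair with a known shift and 12 foci (shared fixture)."""
    spec = SceneSpec(n_foci=12, n_cysts=1, mode_shift=(3, 5), seed=42)
    edi, conv, gt = generate_pair(spec)
    return spec, edi, conv, gt


@pytest.fixture(scope="session")
def noiseless_pair():
    spec = SceneSpec(n_foci=12, n_cysts=0, mode_shift=(0, 0), seed=7,
                     **NOISELESS_NEUTRAL)
    edi, conv, gt = generate_pair(spec)
    return spec, edi, conv, gt
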