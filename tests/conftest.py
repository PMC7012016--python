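import numpy as np
import pytest

from petquant.core import TimeActivityCurve, UNIT_KBQ_ML, VoxelMask
from petquant.kinetics import expconv_uniform, fine_grid
from petquant.synthdata import (
    InputModelParams,
    RegionKinetics,
    build_phantom,
    default_phantom_spec,
    default_schedule,
    plasma_curve,
)

REF_K1, REF_K2 = 0.4, 0.1
TRUE_SRTM = {"R1": 1.2, "k2": 0.15, "BP_ND": 1.5}


@pytest.fixture(scope="session")
def schedule90():
    return default_schedule("dynamic_90")


@pytest.fixture(scope="session")
def plasma90(schedule90):
    tf = fine_grid(schedule90.end_min[-1])
    return plasma_curve(InputModelParams(), tf)


@pytest.fixture(scope="session")
def cr_dense(plasma90):
    """Reference-tissue curve (1TCM, no specific binding) on the fine grid."""
    t = plasma90.t
    dt = t[1] - t[0]
    vals = REF_K1 * expconv_uniform(plasma90.cp, dt, REF_K2)
    return TimeActivityCurve(t_mid=t[1:], value=vals[1:], unit=UNIT_KBQ_ML,
                             frame_dur=np.full(t.size - 1, dt))


@pytest.fixture(scope="session")
def phantom30():
    """Noiseless 30^3 phantom: reference sphere 8, SRTM targets 17 (BP 1.5)
    and 18 (BP 0), occipital-proxy box 1011, ventricle boxes 4/43."""
    spec = default_phantom_spec(seed=1, noise_scale=0.0, grid_shape=(30, 30, 30))
    ref = RegionKinetics(label=8, model="1tcm", params={"K1": REF_K1, "k2": REF_K2})
    targets = [
        RegionKinetics(label=17, model="srtm", params=dict(TRUE_SRTM)),
        RegionKinetics(label=18, model="srtm",
                       params={"R1": 1.0, "k2": 0.12, "BP_ND": 0.0}),
        RegionKinetics(label=1011, model="1tcm", params={"K1": 0.45, "k2": 0.11}),
    ]
    image, labels, truth, plasma = build_phantom(spec, ref, targets)
    return {"image": image, "labels": labels, "truth": truth, "plasma": plasma}


def region_mask(labels, code):
    return VoxelMask(voxels=labels.voxels == code, affine=labels.affine)
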