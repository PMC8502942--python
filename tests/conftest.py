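import math

import pytest

from thzvol import (
    AcquisitionConfig,
    PhantomSpec,
    TumorRegion,
    build_phantom,
    calibrate_skin_background,
    compute_absorbance,
    simulate_scan,
)

SKIN_OD = 0.05


@pytest.fixture
def tumor_spec() -> PhantomSpec:
    """Default study phantom: 10x10 mm field at 0.1 mm pitch, fatty
    baseline 1.42 mm^-1, one 1.5 mm-radius tumor disc of excess
    0.160 mm^-1 under a skin layer of optical depth 0.05."""
    return PhantomSpec(
        tumor_regions=(TumorRegion(5.0, 5.0, 1.5, 0.160),),
        skin_optical_depth=SKIN_OD,
    )


@pytest.fixture
def flat_spec() -> PhantomSpec:
    return PhantomSpec(skin_optical_depth=SKIN_OD)


def noiseless_alpha_map(spec: PhantomSpec, skin_corrected: bool = True):
    """Simulate one noise-free scan and invert it back to alpha."""
    tissue = build_phantom(spec)
    raster = simulate_scan(
        tissue, AcquisitionConfig(snr=math.inf, n_replicates=1)
    )[0]
    amap = compute_absorbance(raster, tissue.thickness_mm)
    if skin_corrected:
        amap = calibrate_skin_background(amap, spec.skin_optical_depth)
    return tissue, amap
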