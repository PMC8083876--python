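import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vasculometry as vm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """60-vessel ground-truth population in a 20000 um^2 region."""
    spec = vm.VesselSpec(n_vessels=60)
    return vm.generate_vessel_population(spec, 20_000.0, seed=11)


@pytest.fixture(scope="session")
def small_image(small_truth):
    """Noiseless rendering of the 60-vessel population at 0.2 um/px."""
    side = int(round(np.sqrt(20_000.0) / 0.2))
    spec = vm.ImageSpec(
        width_px=side, height_px=side, pixel_size_um=0.2, noise_sd=0.0, seed=12
    )
    img, sidecar = vm.render_cross_section(small_truth, spec)
    return img, sidecar


@pytest.fixture(scope="session")
def three_ellipse_image():
    """Three well-separated ellipses, noiseless, with known geometry."""
    import pandas as pd

    vessels = pd.DataFrame(
        {
            "vessel_id": [1, 2, 3],
            "cx_px": [30.0, 90.0, 60.0],
            "cy_px": [30.0, 30.0, 90.0],
            "cx_um": [6.0, 18.0, 12.0],
            "cy_um": [6.0, 6.0, 18.0],
            "a_um": [3.0, 4.0, 2.5],
            "b_um": [2.0, 4.0, 2.0],
            "theta_rad": [0.3, 0.0, 1.2],
            "d_um": [vm.idealized_diameter(3, 2), 8.0, vm.idealized_diameter(2.5, 2)],
            "lumen_area_um2": [np.pi * 6, np.pi * 16, np.pi * 5],
        }
    )
    truth = vm.GroundTruth(
        vessels=vessels,
        region_area_um2=24.0 * 24.0,
        pixel_size_um=0.2,
        d_h=vm.hydraulically_weighted_diameter(vessels["d_um"]),
        VD=vm.vessel_density(3, 576.0),
        A_lumen_rel=float(vessels["lumen_area_um2"].sum() / 576.0),
        K=vm.conductivity(vessels["d_um"], 576.0),
    )
    spec = vm.ImageSpec(width_px=120, height_px=120, pixel_size_um=0.2, noise_sd=0.0)
    img, sidecar = vm.render_cross_section(truth, spec)
    return img, truth
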