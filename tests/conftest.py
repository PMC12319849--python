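import numpy as np
import pytest

from psoctpipe import phantom


@pytest.fixture
def uniform_spec():
    """1x1 lateral grid, 200 depth pixels, 4.2 um axial pitch."""
    return phantom.PhantomSpec(grid_shape=(1, 1, 200), regions=())


def uniform_ascan(theta_deg, dn=5e-4, mu_s=4.0, nz=200, axial_um=4.2,
                  noise_sd=0.0, seed=0):
    """Noise-controllable uniform-axis A-line plus its spec."""
    spec = phantom.PhantomSpec(
        grid_shape=(1, 1, nz), axial_pixel_um=axial_um, regions=()
    )
    a = phantom.simulate_ascan(
        np.full(nz, mu_s), np.full(nz, dn), np.full(nz, theta_deg),
        spec, noise_sd=noise_sd, seed=seed,
    )
    return a, spec


def folded_retardance_deg(gamma_rad):
    """Round-trip retardance folded into [0, 90] degrees, as the arctan
    estimator reports it."""
    return np.degrees(
        np.arctan2(np.abs(np.sin(gamma_rad)), np.abs(np.cos(gamma_rad)))
    )


@pytest.fixture(scope="session")
def demo_mosaic():
    """Reconstructed + stitched parameter maps for one small specimen."""
    from psoctpipe.config import load_config
    from psoctpipe import pipeline

    cfg = load_config(**{
        "phantom.nx": 150, "phantom.ny": 150, "phantom.nz": 96,
        "phantom.tile_px": 90, "phantom.n_ages": 1,
        "enface.depth_range": (0, 48),
    })
    sample = pipeline.simulate_age(cfg, 0)
    sample = pipeline.reconstruct_and_stitch(cfg, sample)
    return cfg, sample
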