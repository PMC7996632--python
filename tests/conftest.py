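import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from interiorct.geometry import FanBeamGeometry, MisalignmentParams
from interiorct.phantom import AttenuationImage
from interiorct.study import CompensationStudy, StudyConfig

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def disk_image(radius=10.0, mu=0.2, n=512, pixel=0.05, center=(0.0, 0.0), supersample=4):
    """Anti-aliased uniform disk, the analytic projector/FBP oracle phantom."""
    m = n * supersample
    sub = pixel / supersample
    k = (np.arange(m) - (m - 1) / 2.0) * sub
    X2 = (k[None, :] - center[0]) ** 2
    Y2 = (k[:, None] - center[1]) ** 2
    vals = np.where(X2 + Y2 <= radius * radius, mu, 0.0)
    vals = vals.reshape(n, supersample, n, supersample).mean(axis=(1, 3))
    return AttenuationImage(vals, pixel)


@pytest.fixture
def disk():
    return disk_image()


@pytest.fixture
def disk_geometry():
    # magnification 2, fan comfortably covering the 20 mm disk
    return FanBeamGeometry(200.0, 200.0, 0.25, 240, 360)


def tiny_config(**overrides):
    """Desk-scale-in-miniature study configuration for fast functional tests.

    Same anatomy and protocol structure as the default study, with coarse
    grids, few views and wide (but still sub-ROI) bar patterns.
    """
    base = dict(
        seed=7,
        hr_grid=288,
        hr_pixel=0.2,
        lr_grid=256,
        lr_pixel=1.0,
        bar_widths_um=(500.0, 800.0),
        global_pitch=2.0,
        global_views=180,
        local_pitch=0.5,
        local_views=360,
        bg_lr_pitch=2.0,
        bg_lr_views=90,
        recon_grid=128,
        recon_pixel=0.4,
        global_recon_grid=256,
        global_recon_pixel=1.0,
        bar_patch_grid=96,
        bar_patch_pixel=0.2,
        isocenter_n=4,
        angle_half_n=1,
        mag_half_n=1,
    )
    base.update(overrides)
    return StudyConfig(**base)


@pytest.fixture
def small_study():
    return CompensationStudy(tiny_config())


# ---------------------------------------------------------------------------
# the full default-scale study is expensive; build it once per session and
# share it between the acceptance suite and the end-to-end invariant tests


@pytest.fixture(scope="session")
def study():
    return CompensationStudy(StudyConfig())


@pytest.fixture(scope="session")
def reference(study):
    return study.reference()


@pytest.fixture(scope="session")
def aligned_run(study):
    return study.run(MisalignmentParams(), label="aligned")
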