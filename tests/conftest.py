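import numpy as np
import pytest

import foveametry as fm
from foveametry import Group, Layer


@pytest.fixture(scope="session")
def table1():
    return fm.load_table1_fixture()


@pytest.fixture()
def control_inl():
    """Noise-free INL control profile on the default grid."""
    return fm.make_control_profile(Layer.INL)


@pytest.fixture()
def constant_profile():
    """Constant 40 µm thickness on a 0-1000 µm grid."""
    e = np.linspace(0.0, 1000.0, 41)
    return fm.LayerProfile(layer=Layer.GCL_IPL, eccentricity_um=e,
                           thickness_um=np.full_like(e, 40.0))


def warp_recovery_errors(warp, seed, smoothing="gcv",
                         eccentricities=(300.0, 500.0, 700.0, 900.0)):
    """Max |estimated − true| retardation for a control-vs-itself-warped
    cohort with shared segmentation noise (sd 2 µm, 25 µm grid)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for layer in Layer:
        ctrl = fm.make_control_profile(layer, noise_sd_um=2.0, rng=rng)
        cum_c = fm.cumulative_curve(ctrl, smoothing=smoothing)
        warped = fm.apply_retardation_warp(ctrl, warp)
        cum_pg = fm.cumulative_curve(warped.profile, smoothing=smoothing)
        for est in fm.retardation_profile(cum_c, cum_pg, eccentricities):
            assert est.ok, est.error
            err = abs(est.retardation_um - warp.true_retardation(est.eccentricity_um))
            worst = max(worst, err)
    return worst
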