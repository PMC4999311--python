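import numpy as np
import pytest

import whiskerglm as wg


@pytest.fixture(scope="session")
def geometry():
    return wg.WhiskerGeometry()


@pytest.fixture(scope="session")
def basis():
    return wg.make_basis()


@pytest.fixture(scope="session")
def passive_trial(geometry):
    """A short manual-deflection trial shared across tests."""
    protocol = wg.gen_passive_protocol(geometry, n_deflections=8, seed=101)
    return wg.render_trial(protocol, geometry)


@pytest.fixture(scope="session")
def passive_predictors(passive_trial):
    return wg.predictors_from_trial(passive_trial)


@pytest.fixture(scope="session")
def active_trial(geometry):
    protocol = wg.gen_active_protocol(geometry, whisk_freq_hz=8.0, duration_s=2.0, seed=55)
    return wg.render_trial(protocol, geometry)


@pytest.fixture(scope="session")
def noise_predictors():
    return wg.gen_noise_predictors(60_000, seed=7)


@pytest.fixture(scope="session")
def contact_tangent():
    """Helper: unit tangent of a deflected shape at a given arc position."""

    def _tangent(result, geometry):
        ds = geometry.ds_mm
        k = min(int(result.contact_arc_mm / ds), geometry.n_nodes - 2)
        seg = result.shape_mm[k + 1] - result.shape_mm[k]
        return seg / np.hypot(*seg)

    return _tangent
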