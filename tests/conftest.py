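import numpy as np
import pytest

from xedwi import DWVolumeSet, PhantomConfig, build_phantom, simulate_signal

B_VALUES = (0.0, 12.0, 20.0, 30.0)


def small_phantom_config(**overrides):
    """A 16x16x18 phantom that keeps per-test fits cheap."""
    defaults = dict(
        shape=(16, 16, 18),
        voxel_size_mm=(4.0, 4.0, 4.0),
        centers=((4.6, 7.75, 8.5), (11.4, 7.75, 8.5)),
        semiaxes=((3.0, 4.5, 7.0), (3.0, 4.5, 7.0)),
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def phantom():
    """Default full-size phantom with texture."""
    return build_phantom()


@pytest.fixture(scope="session")
def noiseless_dw(phantom):
    return simulate_signal(phantom, B_VALUES, noiseless=True)


@pytest.fixture(scope="session")
def small_phantom():
    return build_phantom(small_phantom_config())


@pytest.fixture(scope="session")
def small_noiseless_dw(small_phantom):
    return simulate_signal(small_phantom, B_VALUES, noiseless=True)


def synthetic_voxels(ddc, alpha, s0=1.0, b=B_VALUES, shape=None, snr=None, seed=0):
    """Build a DWVolumeSet from explicit per-voxel truth arrays.

    ``ddc``/``alpha`` broadcast to ``shape`` (default: their common shape
    padded to 3-D). Optional Rician noise at the given SNR.
    """
    b = np.asarray(b, float)
    ddc = np.atleast_3d(np.asarray(ddc, float))
    alpha = np.broadcast_to(np.atleast_3d(alpha), ddc.shape)
    s0 = np.broadcast_to(np.atleast_3d(s0), ddc.shape)
    if shape is None:
        shape = ddc.shape
    bd = b[None, None, None, :] * ddc[..., None]
    expo = np.zeros_like(bd)
    pos = bd > 0
    al = np.broadcast_to(alpha[..., None], bd.shape)
    expo[pos] = bd[pos] ** al[pos]
    sig = s0[..., None] * np.exp(-expo)
    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = float(s0.mean()) / snr
        sig = np.sqrt((sig + rng.normal(0, sigma, sig.shape)) ** 2
                      + rng.normal(0, sigma, sig.shape) ** 2)
    return DWVolumeSet(sig, b, np.diag([4.0, 4.0, 4.0, 1.0]))
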