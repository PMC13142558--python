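import numpy as np
import pytest

from cestkit.core import AcquisitionParams, OffsetImageStack
from cestkit.zspec import lorentzian


@pytest.fixture
def offsets61():
    """Dense symmetric Z-spectrum axis spanning beyond +/-4 ppm."""
    return np.linspace(-6.0, 6.0, 61)


def forward_zspectrum(offsets, amide_A=0.05, amide_g=1.0, amide_w=3.5,
                      water=(0.9, 1.4, 0.0), mt=(0.1, 25.0, -2.5),
                      b0=0.0):
    """Ground-truth Lorentzian-sum spectrum used as the fitting oracle."""
    dw = offsets - b0
    z = 1.0 - lorentzian(*water, dw) - lorentzian(*mt, dw)
    if amide_A:
        z = z - lorentzian(amide_A, amide_g, amide_w, dw)
    return z


@pytest.fixture
def forward_z():
    return forward_zspectrum


def raw_stack(offsets, z_cube, m0_value=1000.0):
    """Wrap normalized per-pixel spectra (offsets, r, c) into a raw-unit
    stack with one far-off-resonance M0 frame prepended."""
    z_cube = np.asarray(z_cube, dtype=float)
    full_off = np.concatenate([[-300.0], offsets])
    data = np.concatenate([np.ones((1, *z_cube.shape[1:])), z_cube]) * m0_value
    params = AcquisitionParams(offsets_ppm=full_off, sat_b1_uT=1.1,
                               sat_time_s=2.0, field_MHz=300.33)
    return OffsetImageStack(data=data, offsets_ppm=full_off, params=params,
                            frame_times_s=np.arange(full_off.size) * 8.0)


@pytest.fixture
def make_raw_stack():
    return raw_stack
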