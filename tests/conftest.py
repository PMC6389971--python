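import numpy as np
import pytest

from cardimu.simulate import (
    REFERENCE_PARAMS,
    Geometry,
    NoiseConfig,
    simulate_subject,
)

FS = 700.0


@pytest.fixture(scope="session")
def baseline_noiseless():
    """Noiseless supine baseline recording (rotation 9.6 deg, circumferential
    displacement 6.0 mm, HR 108 bpm), 10 cycles."""
    return simulate_subject(
        REFERENCE_PARAMS["baseline"],
        geometry=Geometry(inclination_deg=90.0),
        noise=NoiseConfig.NOISELESS,
        n_cycles=10,
        seed=1,
    )


@pytest.fixture(scope="session")
def rotation_only_noiseless():
    """Noiseless supine recording with rotation but zero translation."""
    from dataclasses import replace

    params = replace(
        REFERENCE_PARAMS["baseline"], disp_esm_mm=0.0, disp_long_mm=0.0, disp_rad_mm=0.0
    )
    return simulate_subject(
        params,
        geometry=Geometry(inclination_deg=90.0),
        noise=NoiseConfig.NOISELESS,
        n_cycles=5,
        seed=1,
    )


def first_cycle(rec):
    """(acc, gyro) arrays of the first whole cycle of a recording."""
    n0, n1 = rec.r_peaks[0], rec.r_peaks[1]
    return rec.acc[:, n0:n1], rec.gyro[:, n0:n1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
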