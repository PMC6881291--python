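"""Shared fixtures.

The session-scoped microbeam simulation is the one expensive fixture: a 3 T,
1.053 mm BDA microbeam field with the multi-slit collimator engaged,
transported at a size large enough to resolve the lateral profile at 20 mm
depth.  Several tests (geometry propagation, PVDR behaviour, valley deficits)
share it so the Monte Carlo runs once.
"""

import numpy as np
import pytest

from mrtsim import phantom, pipeline, source
from mrtsim.config import RunConfig

MB_SIM_PRIMARIES = 6_000_000
MB_SIM_SEED = 11


@pytest.fixture(scope="session")
def machine():
    return source.MachineConfig()


@pytest.fixture(scope="session")
def wiggler3():
    return source.WigglerConfig(peak_field=3.0)


@pytest.fixture(scope="session")
def wiggler2():
    return source.WigglerConfig(peak_field=2.0)


@pytest.fixture(scope="session")
def mb_sim_grid():
    """3 T microbeam dose grid at production-like statistics (session-wide)."""
    cfg = RunConfig.from_preset("3T_bda1.053_mb", n_primaries=MB_SIM_PRIMARIES, seed=MB_SIM_SEED)
    psf, _ = pipeline.build_phase_space(cfg, cfg.n_primaries, cfg.seed)
    return phantom.transport(psf, cfg.phantom, cfg.mesh, cfg.scan,
                             n=cfg.n_primaries, seed=MB_SIM_SEED)


def make_comb_profile(peak=10.0, valley=0.5, width_um=50.0, pitch_um=400.0,
                      n_peaks=5, step_um=1.0):
    """Ideal rectangular microbeam comb profile (y_um, dose)."""
    half_span = (n_peaks // 2) * pitch_um + pitch_um / 2
    y = np.arange(-half_span, half_span + step_um / 2, step_um)
    v = np.full_like(y, valley, dtype=float)
    for k in range(-(n_peaks // 2), n_peaks // 2 + 1):
        v[np.abs(y - k * pitch_um) < width_um / 2] = peak
    return y, v
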