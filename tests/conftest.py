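"""Shared fixtures: small phantoms and one cached paired scan.

Everything is generated programmatically at fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from mstar import ArtifactConfig, FoamSpec
from mstar.experiment import simulate_paired_scan


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def foam_spec_small():
    return FoamSpec(
        grid_size=48, n_bubbles=40, bubble_radius_range=(2.0, 6.0), seed=7
    )


@pytest.fixture(scope="session")
def paired_scan_small(foam_spec_small):
    """48^3 foam, 24 corrupted LQ angles / 96 clean HQ angles (factor 4)."""
    art = ArtifactConfig(I0=100.0, P_ring=0.1, P_zinger=0.001, P_proj=0.1, seed=11)
    scan, vol = simulate_paired_scan(foam_spec_small, 24, 4, art)
    return scan, vol
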