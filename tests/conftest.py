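"""Shared fixtures: expensive sweeps are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from cplscat.diagram import sweep_expected_s3, sweep_mc_curves

M_BASELINE = 1.59 / 1.33  # polystyrene-like particle in water


@pytest.fixture(scope="session")
def s3_sweep_curve():
    """Exact single-scattering <S3>(X) at m=1.195 on X in [1, 30], step 0.05."""
    grid = np.round(np.arange(1.0, 30.0 + 1e-9, 0.05), 10)
    return sweep_expected_s3(M_BASELINE, grid)


@pytest.fixture(scope="session")
def mc_xsweep():
    """Reflection/transmission MC curves, X in [6, 14] step 0.5, 2e4 photons/point."""
    grid = np.arange(6.0, 14.0 + 1e-9, 0.5)
    return sweep_mc_curves(grid, photons=20_000, seed=20240621)
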