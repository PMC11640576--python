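"""Shared fixtures: small optical configurations and reusable artifacts.

Everything is generated programmatically; expensive artifacts (derivative
arrays, MSR models) are session scoped so multiple tests share them.
"""

import numpy as np
import pytest

from octsim import (ApproximationParams, MirrorSpec, OpticalSystem,
                    ScanGeometry, ScattererSet)
from octsim.msr_engine import compute_bound_B, fit_msr
from octsim.taylor_engine import build_source_grid, compute_derivative_array

SPECTRUM = dict(lambda_min_nm=1170.0, lambda_max_nm=1408.0)


@pytest.fixture(scope="session")
def sys_small():
    """Low-NA system with a short spectrum grid and a small mirror grid,
    cheap enough for rigorous per-test use (depths up to ~200 µm)."""
    return OpticalSystem(na=0.1, eta=1.0, nk=64, zf_um=100.0,
                         mirror=MirrorSpec(n_points=33), **SPECTRUM)


@pytest.fixture(scope="session")
def sys_deep():
    """Reference configuration for deep samples (1 mm, 256 wavenumbers)."""
    return OpticalSystem(na=0.1, eta=1.0, nk=256, zf_um=300.0,
                         mirror=MirrorSpec(n_points=65), **SPECTRUM)


@pytest.fixture(scope="session")
def scan_single():
    return ScanGeometry([0.0], [0.0], rho_max_um=70.0)


@pytest.fixture(scope="session")
def cloud_small(sys_small):
    """50 scatterers within the small system's rigorous comfort zone."""
    rng = np.random.default_rng(123)
    n = 50
    r = 60.0 * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return ScattererSet(r * np.cos(th), r * np.sin(th),
                        rng.uniform(0.0, 200.0, n))


@pytest.fixture(scope="session")
def deriv_small(sys_small):
    """Derivative array over the small system's full k grid, recommended
    orders, covering rho <= 70 µm and z in [0, 200] µm."""
    grid = build_source_grid(70.0, 200.0 - sys_small.zf_um, 28.0, 190.0,
                             d_rho=20, d_z=8, d_z0=3,
                             z_min=-sys_small.zf_um)
    return compute_derivative_array(grid, sys_small, sys_small.k_grid)


@pytest.fixture(scope="session")
def msr_small(sys_small):
    bound = compute_bound_B(70.0, 200.0, sys_small.na, sys_small.eta, 15.0)
    return fit_msr(sys_small, 20, bound, 15.0)


@pytest.fixture(scope="session")
def approx_recommended():
    return ApproximationParams()
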