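import numpy as np
import pytest

from dtialps import PhantomSpec, default_gradient_table, make_phantom, simulate_dwi


@pytest.fixture(scope="session")
def gtab():
    """The default 1 b0 + 13-direction, b = 1000 s/mm^2 scheme."""
    return default_gradient_table()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry phantom with a 0.4e-3 mm^2/s perivascular boost,
    forward-simulated without noise."""
    spec = PhantomSpec(perivascular_boost=0.4e-3)
    truth, rois = make_phantom(spec)
    dwi = simulate_dwi(truth, default_gradient_table(), s0=spec.s0)
    return spec, truth, rois, dwi


def forward_signal(elements, gtab, s0=1000.0):
    """Closed-form single-voxel signal S = s0 exp(-b g^T D g), written out
    scalar-by-scalar so it is independent of the package's design matrix."""
    dxx, dyy, dzz, dxy, dxz, dyz = elements
    out = []
    for b, (gx, gy, gz) in zip(gtab.bvals, gtab.bvecs):
        quad = (
            dxx * gx * gx + dyy * gy * gy + dzz * gz * gz
            + 2 * dxy * gx * gy + 2 * dxz * gx * gz + 2 * dyz * gy * gz
        )
        out.append(s0 * np.exp(-b * quad))
    return np.array(out)


def random_spd_elements(rng, scale=1e-3):
    """Random symmetric positive-definite tensor in element order
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
    A = rng.standard_normal((3, 3))
    m = A @ A.T * scale / 3.0 + np.eye(3) * 0.1 * scale
    return np.array([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]])
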