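"""Per-voxel diffusion-tensor estimation and derived scalar maps.

The single-tensor model relates the diffusion-weighted signal S to the
symmetric tensor D through ``S = S0 * exp(-b g^T D g)``.  Taking logs makes
the model linear in the seven unknowns (ln S0 and the six unique tensor
elements), so estimation is ordinary least squares on the log-signal.

Axis diffusivities Dxx, Dyy, Dzz are the tensor's *diagonal elements in the
anatomical frame*, not eigenvalues: unlike FA they are not rotation
invariant, which is exactly the property the perivascular-space index
exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, ValidationError
from .io_formats import DWIDataset, GradientTable

log = logging.getLogger(__name__)

__all__ = [
    "DiffusionTensor",
    "TensorField",
    "design_matrix",
    "fit_tensor_voxel",
    "fit_tensor_volume",
    "fa",
    "md",
    "axis_diffusivities",
    "color_fa",
    "tensor_to_matrix",
]

#: Parameter order of the log-linear design: (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
TENSOR_ELEMENTS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")

#: Relative floor applied to non-positive signals before taking logs.
SIGNAL_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class DiffusionTensor:
    """One voxel's fitted tensor: six unique elements (mm^2/s) plus the
    extrapolated non-diffusion-weighted signal s0 (scanner units).

    Diagonal elements are reported exactly as fitted — under noise they may
    be slightly negative, and downstream ratio computations consume the raw
    values.  FA computation clips negative eigenvalues instead.
    """

    dxx: float
    dyy: float
    dzz: float
    dxy: float
    dxz: float
    dyz: float
    s0: float

    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.dxx, self.dxy, self.dxz],
                [self.dxy, self.dyy, self.dyz],
                [self.dxz, self.dyz, self.dzz],
            ]
        )


def tensor_to_matrix(elements: np.ndarray) -> np.ndarray:
    """Map (..., 6) element arrays (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to
    (..., 3, 3) symmetric matrices."""
    e = np.asarray(elements, dtype=float)
    m = np.empty(e.shape[:-1] + (3, 3))
    m[..., 0, 0] = e[..., 0]
    m[..., 1, 1] = e[..., 1]
    m[..., 2, 2] = e[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = e[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = e[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = e[..., 5]
    return m


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """Log-linear encoding matrix: one row per volume mapping the parameter
    vector (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to ln S.

    Expanding ``-b g^T D g`` gives coefficients ``-b gx^2`` etc. for the
    diagonal elements and ``-2 b gx gy`` etc. for the cross terms; rows with
    b = 0 carry only the intercept.
    """
    b = gtab.bvals
    g = gtab.bvecs
    X = np.empty((len(gtab), 7))
    X[:, 0] = 1.0
    X[:, 1] = -b * g[:, 0] ** 2
    X[:, 2] = -b * g[:, 1] ** 2
    X[:, 3] = -b * g[:, 2] ** 2
    X[:, 4] = -2.0 * b * g[:, 0] * g[:, 1]
    X[:, 5] = -2.0 * b * g[:, 0] * g[:, 2]
    X[:, 6] = -2.0 * b * g[:, 1] * g[:, 2]
    return X


def _checked_design(gtab: GradientTable) -> np.ndarray:
    if not np.any(gtab.b0_mask):
        raise ValidationError("gradient table has no b = 0 volume")
    n_dirs = gtab.n_unique_directions()
    if n_dirs < 6:
        raise EstimationError(
            f"only {n_dirs} distinct non-collinear directions; the 6 tensor "
            "degrees of freedom are underdetermined"
        )
    X = design_matrix(gtab)
    if np.linalg.matrix_rank(X) < 7:
        raise EstimationError(
            "rank-deficient diffusion-encoding design: the "
            f"{n_dirs} distinct directions do not span the 6 tensor "
            "degrees of freedom"
        )
    return X


def _clamp_log_signal(signals: np.ndarray) -> np.ndarray:
    """Floor non-positive signals at a small fraction of the maximum before
    taking logs; the clamped count is logged."""
    floor = SIGNAL_FLOOR_FRACTION * float(np.max(signals))
    if floor <= 0:
        raise ValidationError("all signals are zero; nothing to fit")
    n_clamped = int(np.sum(signals < floor))
    if n_clamped:
        log.info("clamped %d non-positive/low signal values to %.3g", n_clamped, floor)
    return np.log(np.maximum(signals, floor))


def fit_tensor_voxel(signals, gtab: GradientTable) -> DiffusionTensor:
    """Ordinary least squares tensor fit for a single voxel."""
    signals = np.asarray(signals, dtype=float).ravel()
    if signals.shape[0] != len(gtab):
        raise ValidationError(
            f"{signals.shape[0]} signals but gradient table has {len(gtab)}"
        )
    X = _checked_design(gtab)
    y = _clamp_log_signal(signals)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return DiffusionTensor(
        dxx=beta[1], dyy=beta[2], dzz=beta[3],
        dxy=beta[4], dxz=beta[5], dyz=beta[6],
        s0=float(np.exp(beta[0])),
    )


@dataclass
class TensorField:
    """Per-voxel tensors over a mask, with the derived scalar maps the ALPS
    method reads.

    ``tensors`` has shape (X, Y, Z, 6) in the element order
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz); voxels outside ``mask`` hold NaN.
    """

    tensors: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    # --- derived maps ----------------------------------------------------

    @property
    def dxx(self) -> np.ndarray:
        return self.tensors[..., 0]

    @property
    def dyy(self) -> np.ndarray:
        return self.tensors[..., 1]

    @property
    def dzz(self) -> np.ndarray:
        return self.tensors[..., 2]

    @property
    def md(self) -> np.ndarray:
        return (self.dxx + self.dyy + self.dzz) / 3.0

    @property
    def fa(self) -> np.ndarray:
        return _fa_from_elements(self.tensors)

    @property
    def color_fa(self) -> np.ndarray:
        """(X, Y, Z, 3) map FA * (|e1_x|, |e1_y|, |e1_z|)."""
        out = np.full(self.grid_shape + (3,), np.nan)
        idx = np.argwhere(self.mask)
        mats = tensor_to_matrix(self.tensors[self.mask])
        favals = _fa_from_elements(self.tensors[self.mask])
        vals, vecs = np.linalg.eigh(mats)
        e1 = vecs[..., -1]  # eigh sorts eigenvalues ascending
        rgb = np.abs(e1) * favals[:, None]
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = rgb
        return out

    def tensor_at(self, index) -> DiffusionTensor:
        i, j, k = index
        if not self.mask[i, j, k]:
            raise ValidationError(f"voxel {index} is outside the mask")
        e = self.tensors[i, j, k]
        return DiffusionTensor(*e, s0=float(self.s0[i, j, k]))


def _fa_from_elements(elements: np.ndarray) -> np.ndarray:
    mats = tensor_to_matrix(elements)
    ev = np.linalg.eigvalsh(mats)
    ev = np.clip(ev, 0.0, None)  # negative eigenvalues are noise artefacts
    mean_ev = ev.mean(axis=-1)
    num = np.sum((ev - mean_ev[..., None]) ** 2, axis=-1)
    den = np.sum(ev**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa_val = np.sqrt(1.5 * num / den)
    fa_val = np.where(den > 0, fa_val, 0.0)  # all-zero tensor -> FA := 0
    nan_in = np.isnan(elements).any(axis=-1)
    fa_val = np.where(nan_in, np.nan, np.clip(fa_val, 0.0, 1.0))
    return fa_val


def fit_tensor_volume(dataset: DWIDataset, mask=None) -> TensorField:
    """Fit a tensor at every masked voxel of a 4D acquisition.

    The fit is a single vectorised least-squares solve over all masked
    voxels (the design matrix is shared), so large grids are cheap.
    """
    shape = dataset.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValidationError(f"mask shape {mask.shape} does not match grid {shape}")
    if not mask.any():
        raise EstimationError("empty mask: no voxels to fit")

    X = _checked_design(dataset.gtab)
    signals = dataset.signal[mask]  # (V, N)
    y = _clamp_log_signal(signals)
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (7, V)

    tensors = np.full(shape + (6,), np.nan)
    s0 = np.full(shape, np.nan)
    tensors[mask] = beta[1:].T
    s0[mask] = np.exp(beta[0])
    return TensorField(
        tensors=tensors,
        s0=s0,
        mask=mask,
        voxel_size=dataset.voxel_size,
        origin=dataset.origin,
    )


# ---------------------------------------------------------------------------
# scalar measures on a single tensor
# ---------------------------------------------------------------------------

def fa(tensor: DiffusionTensor) -> float:
    """Fractional anisotropy: normalised eigenvalue dispersion in [0, 1].

    Negative eigenvalues (possible in noisy fits) are clipped to zero first;
    the all-zero tensor maps to FA = 0.
    """
    elements = np.array(
        [tensor.dxx, tensor.dyy, tensor.dzz, tensor.dxy, tensor.dxz, tensor.dyz]
    )
    return float(_fa_from_elements(elements))


def md(tensor: DiffusionTensor) -> float:
    """Mean diffusivity = trace / 3 (mm^2/s)."""
    return (tensor.dxx + tensor.dyy + tensor.dzz) / 3.0


def axis_diffusivities(tensor: DiffusionTensor) -> tuple[float, float, float]:
    """(Dxx, Dyy, Dzz): diagonal elements in the anatomical frame."""
    return (tensor.dxx, tensor.dyy, tensor.dzz)


def color_fa(tensor: DiffusionTensor) -> tuple[float, float, float]:
    """Directionally-encoded colour: FA * |principal eigenvector|, giving
    red for x-dominant, green for y-dominant and blue for z-dominant
    tensors."""
    vals, vecs = np.linalg.eigh(tensor.matrix())
    e1 = vecs[:, -1]
    rgb = fa(tensor) * np.abs(e1)
    return (float(rgb[0]), float(rgb[1]), float(rgb[2]))
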