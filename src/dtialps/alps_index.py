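"""ALPS-index: diffusivity along the perivascular space from ROI-sampled
axis diffusivities.

At the level of the lateral ventricle body the perivascular spaces of the
medullary vessels run right-left (x-axis), perpendicular both to the
projection fibres (z-dominant) and to the association fibres (y-dominant).
Water movement along the perivascular space therefore inflates the x-axis
diffusivity in both fibre regions, while the reference diffusivities
perpendicular to it (Dyy in the projection area, Dzz in the association
area) are unaffected.  The index is the ratio

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

with arithmetic means; a value near 1 means no measurable perivascular
contribution, larger values mean freer flow.  Measurements follow the
left-hemisphere convention; ROIs centred on the right half of the grid are
flagged with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import DWIDataset, ROISpec, voxel_centers_world
from .tensor_pipeline import TensorField, fit_tensor_volume, tensor_to_matrix

log = logging.getLogger(__name__)

__all__ = [
    "ROIDiffusivities",
    "SubjectALPS",
    "sphere_voxels",
    "roi_axis_means",
    "dominance_check",
    "alps_index",
    "compute_subject_alps",
    "alps_table",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: Tolerance for the inclusive sphere boundary (squared-mm), guarding against
#: floating-point representation of voxel-centre distances.
_BOUNDARY_EPS = 1e-9


@dataclass(frozen=True)
class ROIDiffusivities:
    """The four diffusivity means feeding the ALPS ratio (mm^2/s), with the
    voxel counts and fibre-dominance QC flags of the two ROIs."""

    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float
    voxel_counts: dict
    dominance_ok: dict


@dataclass(frozen=True)
class SubjectALPS:
    """Per-subject result: the index, its four inputs, and overall QC."""

    subject_id: str
    alps: float
    roi_diffusivities: ROIDiffusivities
    qc_pass: bool


def sphere_voxels(grid_shape, voxel_size, origin, center_mm, diameter_mm,
                  roi_name="ROI") -> np.ndarray:
    """Indices (n, 3) of all voxels whose centres lie within
    ``diameter_mm / 2`` of ``center_mm`` (inclusive boundary).

    Raises if the centre falls outside the volume or no voxel centre is
    selected.
    """
    voxel_size = np.asarray(voxel_size, dtype=float)
    origin = np.asarray(origin, dtype=float)
    center_mm = np.asarray(center_mm, dtype=float).ravel()
    if center_mm.shape != (3,):
        raise ValidationError(f"{roi_name}: center must be a 3-vector")
    lo = origin - voxel_size / 2.0
    hi = origin + voxel_size * (np.asarray(grid_shape) - 0.5)
    if np.any(center_mm < lo) or np.any(center_mm > hi):
        raise ValidationError(
            f"{roi_name}: center {center_mm.tolist()} mm lies outside the "
            f"volume extent [{lo.tolist()}, {hi.tolist()}] mm"
        )
    xs, ys, zs = voxel_centers_world(grid_shape, voxel_size, origin)
    d2 = (
        (xs[:, None, None] - center_mm[0]) ** 2
        + (ys[None, :, None] - center_mm[1]) ** 2
        + (zs[None, None, :] - center_mm[2]) ** 2
    )
    r2 = (diameter_mm / 2.0) ** 2
    idx = np.argwhere(d2 <= r2 + _BOUNDARY_EPS)
    if idx.shape[0] == 0:
        raise ValidationError(
            f"{roi_name}: no voxel centre within {diameter_mm / 2} mm of "
            f"{center_mm.tolist()}"
        )
    return idx


def _roi_mean_tensor(field: TensorField, idx: np.ndarray, roi_name: str) -> np.ndarray:
    inside = field.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    if not inside.any():
        raise ValidationError(f"{roi_name}: ROI lies entirely outside the mask")
    if not inside.all():
        log.warning(
            "%s: %d of %d ROI voxels outside the mask are excluded",
            roi_name, int((~inside).sum()), len(inside),
        )
    idx = idx[inside]
    return field.tensors[idx[:, 0], idx[:, 1], idx[:, 2]]


def dominance_check(field: TensorField, roi: ROISpec) -> bool:
    """True iff the principal eigenvector of the ROI-mean tensor points
    mostly along the ROI's expected fibre axis.

    Exact ties (e.g. an isotropic ROI) conservatively fail the check, with
    a logged warning.
    """
    idx = sphere_voxels(
        field.grid_shape, field.voxel_size, field.origin,
        roi.center, roi.diameter, roi_name=roi.name,
    )
    elements = _roi_mean_tensor(field, idx, roi.name)
    mean_tensor = tensor_to_matrix(elements.mean(axis=0))
    vals, vecs = np.linalg.eigh(mean_tensor)
    e1 = np.abs(vecs[:, -1])
    want = _AXIS_INDEX[roi.expected_dominant_axis]
    others = [a for a in range(3) if a != want]
    if np.isclose(vals[-1], vals[0]):
        log.warning("%s: ROI-mean tensor is (near-)isotropic; dominance "
                    "undefined, flagged not-ok", roi.name)
        return False
    if any(np.isclose(e1[want], e1[o]) for o in others):
        log.warning("%s: principal-direction tie; flagged not-ok", roi.name)
        return False
    return bool(all(e1[want] > e1[o] for o in others))


def roi_axis_means(field: TensorField, roi_specs) -> ROIDiffusivities:
    """Mean Dxx over the projection and association ROIs, mean Dyy over the
    projection ROI and mean Dzz over the association ROI, with dominance QC.

    A subcortical ROI, if present, is dominance-checked (x-axis) but does
    not enter the index.
    """
    by_name = {roi.name: roi for roi in roi_specs}
    for required in ("projection", "association"):
        if required not in by_name:
            raise ValidationError(f"missing required ROI: {required}")

    means: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    dominance: dict[str, bool] = {}
    for name, roi in by_name.items():
        if roi.center[0] > 0:
            log.warning(
                "%s ROI centre x = %.1f mm is on the right half of the grid; "
                "the ALPS convention measures the left hemisphere only",
                name, roi.center[0],
            )
        idx = sphere_voxels(
            field.grid_shape, field.voxel_size, field.origin,
            roi.center, roi.diameter, roi_name=name,
        )
        elements = _roi_mean_tensor(field, idx, name)
        means[name] = elements.mean(axis=0)
        counts[name] = elements.shape[0]
        dominance[name] = dominance_check(field, roi)

    rd = ROIDiffusivities(
        dxx_proj=float(means["projection"][0]),
        dxx_assoc=float(means["association"][0]),
        dyy_proj=float(means["projection"][1]),
        dzz_assoc=float(means["association"][2]),
        voxel_counts=counts,
        dominance_ok=dominance,
    )
    for v in (rd.dxx_proj, rd.dxx_assoc, rd.dyy_proj, rd.dzz_assoc):
        if not np.isfinite(v):
            raise ValidationError("non-finite ROI diffusivity mean")
    return rd


def alps_index(rd: ROIDiffusivities) -> float:
    """ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)."""
    num = (rd.dxx_proj + rd.dxx_assoc) / 2.0
    den = (rd.dyy_proj + rd.dzz_assoc) / 2.0
    if den <= 0:
        raise ValidationError(
            f"non-positive denominator diffusivity mean ({den:.3g} mm^2/s); "
            "ROI placement or fit quality is suspect"
        )
    return num / den


def compute_subject_alps(dataset: DWIDataset, roi_specs, mask=None,
                         subject_id="subject") -> SubjectALPS:
    """End-to-end per-subject pipeline: tensor fit, ROI sampling, index."""
    field = fit_tensor_volume(dataset, mask)
    rd = roi_axis_means(field, roi_specs)
    qc = all(rd.dominance_ok.get(n, False) for n in ("projection", "association"))
    return SubjectALPS(
        subject_id=str(subject_id),
        alps=alps_index(rd),
        roi_diffusivities=rd,
        qc_pass=qc,
    )


def alps_table(results) -> pd.DataFrame:
    """Collect SubjectALPS results into the per-subject report table."""
    rows = []
    for r in results:
        rd = r.roi_diffusivities
        rows.append(
            {
                "subject": r.subject_id,
                "alps": r.alps,
                "dxx_proj": rd.dxx_proj,
                "dxx_assoc": rd.dxx_assoc,
                "dyy_proj": rd.dyy_proj,
                "dzz_assoc": rd.dzz_assoc,
                "n_voxels_proj": rd.voxel_counts.get("projection"),
                "n_voxels_assoc": rd.voxel_counts.get("association"),
                "qc_pass": r.qc_pass,
            }
        )
    return pd.DataFrame(rows)
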