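"""Readers and writers for the imaging and tabular formats the pipeline touches.

Volumes are NIfTI-1 (via nibabel), gradient tables are FSL-dialect
``.bval``/``.bvec`` text files, ROI definitions are small YAML/JSON
configs, and cohorts travel as CSV.

The anatomical frame is fixed throughout the package: x = right-left,
y = anterior-posterior, z = inferior-superior.  Images are assumed to
already be in this orientation; no reorientation is attempted.  The world
coordinate of voxel (i, j, k) is ``voxel_size * (i, j, k) + origin``, with
the origin defaulting to the grid's geometric centre so that phantom ROIs
can be placed symmetrically around zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, SchemaError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "GradientTable",
    "DWIDataset",
    "ROISpec",
    "read_dwi",
    "write_dwi",
    "read_roi_specs",
    "write_roi_specs",
    "read_cohort",
    "write_results",
    "validate_cohort",
    "COHORT_COLUMNS",
    "GROUPS",
    "HY_LEVELS",
]

GROUPS = ("NC", "PDN", "PD-MCI", "PDD")

#: Modified Hoehn & Yahr stages: 0, then half steps from 1 to 5.
HY_LEVELS = (0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)

_ROI_NAMES = ("projection", "association", "subcortical")
_ROI_DOMINANT_AXIS = {"projection": "z", "association": "y", "subcortical": "x"}


# ---------------------------------------------------------------------------
# gradient tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientTable:
    """Diffusion-encoding design: one b-value (s/mm^2) and one unit gradient
    direction per volume.

    Directions with b > 0 are normalised to unit length at construction;
    directions with b = 0 are forced to the zero vector.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __init__(self, bvals, bvecs):
        bvals = np.asarray(bvals, dtype=float).ravel()
        bvecs = np.asarray(bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (N, 3); got shape {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise FormatError(
                f"{bvals.shape[0]} b-values but {bvecs.shape[0]} directions"
            )
        if np.any(bvals < 0):
            raise ValidationError("negative b-value")
        bvecs = bvecs.copy()
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(norms == 0):
            raise ValidationError("zero-length gradient direction with b > 0")
        bvecs[dw] /= norms[:, None]
        bvecs[~dw] = 0.0
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def n_unique_directions(self) -> int:
        """Number of distinct non-collinear diffusion-weighted directions
        (antipodal pairs count once)."""
        dirs = self.bvecs[self.bvals > 0]
        kept: list[np.ndarray] = []
        for g in dirs:
            if all(abs(float(g @ h)) < 1.0 - 1e-6 for h in kept):
                kept.append(g)
        return len(kept)

    def validate_for_fit(self) -> None:
        """Raise unless the table supports a tensor fit: at least one b0
        volume and >= 6 distinct non-collinear nonzero directions."""
        if not np.any(self.b0_mask):
            raise ValidationError("gradient table has no b = 0 volume")
        n = self.n_unique_directions()
        if n < 6:
            raise ValidationError(
                f"only {n} distinct non-collinear directions; >= 6 required "
                "for tensor estimation"
            )


# ---------------------------------------------------------------------------
# DWI datasets
# ---------------------------------------------------------------------------

@dataclass
class DWIDataset:
    """A 4D diffusion-weighted acquisition: signal (x, y, z, volume) in
    arbitrary scanner units plus its gradient table and voxel geometry."""

    signal: np.ndarray
    gtab: GradientTable
    voxel_size: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValidationError(f"signal must be 4D; got {self.signal.ndim}D")
        if np.any(self.signal < 0):
            raise ValidationError("signal contains negative values")
        if self.signal.shape[3] != len(self.gtab):
            raise FormatError(
                f"image has {self.signal.shape[3]} volumes but gradient table "
                f"has {len(self.gtab)}"
            )
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValidationError("voxel_size must be 3 strictly positive lengths")
        if self.origin is None:
            self.origin = grid_center_origin(self.signal.shape[:3], self.voxel_size)
        else:
            self.origin = np.asarray(self.origin, dtype=float).ravel()

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def affine(self) -> np.ndarray:
        aff = np.diag(np.append(self.voxel_size, 1.0))
        aff[:3, 3] = self.origin
        return aff


def grid_center_origin(shape, voxel_size) -> np.ndarray:
    """Origin placing world (0,0,0) at the geometric centre of the grid."""
    shape = np.asarray(shape, dtype=float)
    voxel_size = np.asarray(voxel_size, dtype=float)
    return -voxel_size * (shape - 1) / 2.0


def voxel_centers_world(shape, voxel_size, origin) -> tuple[np.ndarray, ...]:
    """Per-axis arrays of voxel-centre world coordinates."""
    return tuple(
        origin[a] + voxel_size[a] * np.arange(shape[a]) for a in range(3)
    )


# ---------------------------------------------------------------------------
# NIfTI + bval/bvec I/O
# ---------------------------------------------------------------------------

def _read_fsl_vector_file(path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            rows.append([float(tok) for tok in line.split()])
    if not rows:
        raise FormatError(f"{path}: empty gradient file")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged rows")
    return np.array(rows)


def read_bvals_bvecs(bval_path, bvec_path) -> GradientTable:
    """Read an FSL-dialect .bval/.bvec pair.

    The canonical bvec layout is 3 rows x N columns; an N x 3 layout is
    auto-detected by shape and transposed with a logged warning.
    """
    bvals = _read_fsl_vector_file(bval_path).ravel()
    bvecs = _read_fsl_vector_file(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] == 3 and bvecs.shape[0] != 3:
        log.warning(
            "%s: N x 3 bvec layout detected; transposing to FSL convention",
            bvec_path,
        )
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # ambiguous; FSL convention wins
    else:
        raise FormatError(f"{bvec_path}: shape {bvecs.shape} is not a bvec table")
    return GradientTable(bvals, bvecs)


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIDataset:
    """Load a 4D DWI NIfTI with its gradient table; validates volume counts,
    normalises directions and requires a b0 volume."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{nifti_path}: expected a 4D image, got {data.ndim}D")
    gtab = read_bvals_bvecs(bval_path, bvec_path)
    if data.shape[3] != len(gtab):
        raise FormatError(
            f"{nifti_path} has {data.shape[3]} volumes but the gradient "
            f"table has {len(gtab)}"
        )
    if not np.any(gtab.b0_mask):
        raise ValidationError(f"{bval_path}: no b = 0 volume")
    voxel_size = np.array(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return DWIDataset(signal=data, gtab=gtab, voxel_size=voxel_size, origin=origin)


def write_dwi(dataset: DWIDataset, nifti_path, bval_path, bvec_path) -> None:
    """Write a DWIDataset so that :func:`read_dwi` round-trips it."""
    img = nib.Nifti1Image(dataset.signal.astype(np.float64), dataset.affine())
    img.header.set_zooms(tuple(dataset.voxel_size) + (1.0,))
    nib.save(img, str(nifti_path))
    fmt = "%.10g"
    Path(bval_path).write_text(
        " ".join(fmt % b for b in dataset.gtab.bvals) + "\n"
    )
    rows = dataset.gtab.bvecs.T  # 3 rows x N columns
    Path(bvec_path).write_text(
        "\n".join(" ".join(fmt % x for x in row) for row in rows) + "\n"
    )


# ---------------------------------------------------------------------------
# ROI specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROISpec:
    """A spherical region of interest, specified in world millimetres.

    ``expected_dominant_axis`` encodes which fibre population should
    dominate the ROI (z for projection, y for association, x for
    subcortical fibres) and drives the dominance QC check.
    """

    name: str
    center: np.ndarray
    diameter: float = 5.0
    expected_dominant_axis: str = ""

    def __init__(self, name, center, diameter=5.0, expected_dominant_axis=None):
        if name not in _ROI_NAMES:
            raise ValidationError(
                f"unknown ROI name {name!r}; expected one of {_ROI_NAMES}"
            )
        center = np.asarray(center, dtype=float).ravel()
        if center.shape != (3,):
            raise ValidationError(f"ROI {name}: center must be a 3-vector (mm)")
        diameter = float(diameter)
        if diameter <= 0:
            raise ValidationError(f"ROI {name}: diameter must be > 0")
        expected = _ROI_DOMINANT_AXIS[name]
        if expected_dominant_axis not in (None, expected):
            raise ValidationError(
                f"ROI {name}: expected_dominant_axis must be {expected!r}"
            )
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "diameter", diameter)
        object.__setattr__(self, "expected_dominant_axis", expected)


def read_roi_specs(path) -> list[ROISpec]:
    """Read ROI definitions from a YAML/JSON config.

    Accepted layouts: a top-level list, or a mapping with key ``rois``.
    Each entry needs ``name`` and ``center_mm``; ``diameter_mm`` defaults
    to 5.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if isinstance(doc, dict):
        doc = doc.get("rois")
    if not isinstance(doc, list):
        raise FormatError(f"{path}: expected a list of ROI entries")
    specs = []
    for entry in doc:
        if "name" not in entry:
            raise ValidationError(f"{path}: ROI entry without a name")
        if "center_mm" not in entry:
            raise ValidationError(f"{path}: ROI {entry['name']!r} missing center_mm")
        specs.append(
            ROISpec(
                name=entry["name"],
                center=entry["center_mm"],
                diameter=entry.get("diameter_mm", 5.0),
            )
        )
    return specs


def write_roi_specs(specs, path) -> None:
    doc = {
        "rois": [
            {
                "name": s.name,
                "center_mm": [float(c) for c in s.center],
                "diameter_mm": float(s.diameter),
            }
            for s in specs
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

#: Required cohort columns and whether they must be numeric.
COHORT_COLUMNS = {
    "id": False,
    "group": False,
    "age": True,
    "sex": False,
    "disease_duration": True,
    "updrs1": True,
    "updrs2": True,
    "updrs3": True,
    "updrs_total": True,
    "hy": True,
    "se_adl": True,
    "mmse": True,
    "casi": True,
    "z_attention": True,
    "z_executive": True,
    "z_language": True,
    "z_memory": True,
    "z_visuospatial": True,
    "nuclear_dna": True,
    "mito_dna": True,
    "alps": True,
}

DOMAIN_Z_COLUMNS = (
    "z_attention",
    "z_executive",
    "z_language",
    "z_memory",
    "z_visuospatial",
)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the schema; returns a typed copy.

    Unknown columns are preserved (and ignored by the statistics battery).
    Disease columns may be missing (NA) on NC rows.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table missing required columns: {missing}")
    out = table.copy()
    for col, numeric in COHORT_COLUMNS.items():
        if not numeric:
            continue
        try:
            out[col] = pd.to_numeric(out[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} is not numeric: {exc}") from None
    bad_groups = set(out["group"].unique()) - set(GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")
    bad_sex = set(out["sex"].unique()) - {"M", "F"}
    if bad_sex:
        raise ValidationError(f"sex coded outside {{M, F}}: {sorted(bad_sex)}")
    mmse = out["mmse"].dropna()
    if ((mmse < 0) | (mmse > 30)).any():
        raise ValidationError("MMSE outside [0, 30]")
    hy = out["hy"].dropna()
    if not hy.isin(HY_LEVELS).all():
        raise ValidationError(f"HY stage outside {HY_LEVELS}")
    for col in ("nuclear_dna", "mito_dna"):
        vals = out[col].dropna()
        if (vals < 0).any():
            raise ValidationError(f"{col} must be >= 0")
    return out


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (UTF-8, header row)."""
    table = pd.read_csv(path)
    return validate_cohort(table)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results/cohort table as UTF-8 CSV with a header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
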