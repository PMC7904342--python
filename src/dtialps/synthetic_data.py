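"""Synthetic inputs with known ground truth.

Two generators make every downstream stage testable without any data
download:

* a block **phantom** whose compartments carry the fibre geometry the
  perivascular-space index assumes (z-dominant projection fibres,
  y-dominant association fibres, x-dominant subcortical fibres, isotropic
  CSF), with a tunable perivascular boost ``delta`` added to the x-axis
  diffusivity of both fibre compartments — exactly the quantity the ALPS
  ratio senses, so the ground-truth index is analytic:
  ``(Dxx_perp + delta) / Dxx_perp``;

* a simulated **cohort** of NC / PDN / PD-MCI / PDD subjects whose
  marginal means and SDs follow the study's demographic tables and whose
  rank correlations between the ALPS-index, plasma DNA and cognition are
  imposed through a Gaussian copula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError
from .io_formats import (
    DWIDataset,
    GradientTable,
    ROISpec,
    grid_center_origin,
    validate_cohort,
)
from .tensor_pipeline import TensorField, design_matrix

log = logging.getLogger(__name__)

__all__ = [
    "DIRECTIONS_13",
    "default_gradient_table",
    "PhantomSpec",
    "make_phantom",
    "analytic_alps",
    "simulate_dwi",
    "GroupSpec",
    "CohortSpec",
    "simulate_cohort",
]

#: Thirteen non-collinear unit directions from electrostatic-repulsion
#: minimisation on the antipodally-symmetrised sphere (condition number 1.61
#: for the 6-parameter tensor design at b = 1000 s/mm^2).
DIRECTIONS_13 = np.array(
    [
        [-0.415569681572, -0.406583832229, 0.813628555993],
        [0.195070563929, -0.086775348667, 0.976942943038],
        [-0.034776179666, -0.887434453682, 0.459620177697],
        [-0.685026052736, 0.235416730587, 0.689433296289],
        [0.124394896099, 0.952829926442, 0.276841183895],
        [-0.493135666220, 0.851857496652, 0.176510679845],
        [0.547654002071, 0.555767076562, 0.625458272490],
        [-0.638775275661, -0.759913878185, 0.120403674968],
        [-0.123886358489, 0.529245464410, 0.839375606378],
        [-0.947384584358, -0.226855153587, 0.225829999361],
        [0.854230355290, 0.021693556302, 0.519441902157],
        [0.911933137666, -0.410338794509, 0.000161703071],
        [0.524868868305, -0.594308218170, 0.609352453757],
    ]
)


def default_gradient_table(b: float = 1000.0) -> GradientTable:
    """One b0 volume followed by 13 diffusion-weighted directions at the
    given b-value (s/mm^2), matching a single-shell clinical scheme."""
    bvals = np.concatenate([[0.0], np.full(13, float(b))])
    bvecs = np.vstack([np.zeros(3), DIRECTIONS_13])
    return GradientTable(bvals, bvecs)


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

def _diag(dx, dy, dz):
    return np.array([dx, dy, dz, 0.0, 0.0, 0.0])


#: Compartment tensors (mm^2/s) in element order (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
DEFAULT_COMPARTMENT_TENSORS = {
    "projection": _diag(0.6e-3, 0.6e-3, 1.7e-3),   # z-dominant
    "association": _diag(0.6e-3, 1.7e-3, 0.6e-3),  # y-dominant
    "subcortical": _diag(1.7e-3, 0.6e-3, 0.6e-3),  # x-dominant
    "csf": _diag(3.0e-3, 3.0e-3, 3.0e-3),          # isotropic, fast
    "background": _diag(0.8e-3, 0.8e-3, 0.8e-3),   # isotropic parenchyma
}


@dataclass(frozen=True)
class PhantomSpec:
    """Layout and acquisition parameters of the block phantom.

    ``perivascular_boost`` is the additive Dxx increment (mm^2/s) applied in
    the projection and association compartments; with the default tensors
    the analytic ALPS-index is ``(0.6e-3 + boost) / 0.6e-3``.
    """

    grid_shape: tuple = (16, 16, 12)
    voxel_size: tuple = (2.0, 2.0, 2.5)
    compartment_tensors: dict = field(
        default_factory=lambda: {
            k: v.copy() for k, v in DEFAULT_COMPARTMENT_TENSORS.items()
        }
    )
    perivascular_boost: float = 0.0
    s0: float = 1000.0
    noise_sigma: float = 0.0
    nex: int = 3
    seed: int = 0

    def isotropic(self) -> "PhantomSpec":
        """Variant with every compartment isotropic at the parenchymal
        diffusivity — the no-anisotropy, no-perivascular-flow baseline."""
        iso = {k: _diag(0.8e-3, 0.8e-3, 0.8e-3) for k in self.compartment_tensors}
        return replace(self, compartment_tensors=iso, perivascular_boost=0.0)


def _blocks(grid_shape):
    """Disjoint rectangular compartments in the left half of the grid
    (x < 0 under the centred origin), with a one-voxel background margin."""
    nx, ny, nz = grid_shape
    qx = slice(1, nx // 2)
    y_lo, y_hi = slice(1, ny // 2), slice(ny // 2, ny - 1)
    z_lo, z_hi = slice(1, nz // 2), slice(nz // 2, nz - 1)
    return {
        "projection": (qx, y_lo, z_lo),
        "association": (qx, y_hi, z_lo),
        "subcortical": (qx, y_lo, z_hi),
        "csf": (qx, y_hi, z_hi),
    }


def _block_center_voxel(block):
    return tuple((s.start + s.stop - 1) // 2 for s in block)


def _check_spd(elements, name):
    m = np.array(
        [
            [elements[0], elements[3], elements[4]],
            [elements[3], elements[1], elements[5]],
            [elements[4], elements[5], elements[2]],
        ]
    )
    if np.any(np.linalg.eigvalsh(m) <= 0):
        raise ValidationError(f"compartment {name!r}: tensor is not positive definite")


def make_phantom(spec: PhantomSpec) -> tuple[TensorField, list[ROISpec]]:
    """Ground-truth tensor field plus the matching ROI configuration.

    A 5 mm sphere is centred inside each of the projection, association and
    subcortical blocks; blocks that cannot contain such a sphere (fewer than
    three voxel centres across in any axis) raise.
    """
    if spec.perivascular_boost < 0:
        raise ValidationError("perivascular_boost must be >= 0")
    grid = tuple(int(n) for n in spec.grid_shape)
    voxel_size = np.asarray(spec.voxel_size, dtype=float)
    origin = grid_center_origin(grid, voxel_size)
    blocks = _blocks(grid)

    roi_blocks = ("projection", "association", "subcortical")
    for name in roi_blocks:
        widths = [s.stop - s.start for s in blocks[name]]
        # the 5 mm sphere selects a centre voxel plus face neighbours: needs
        # 3 voxel centres across in every axis
        if any(w < 3 for w in widths):
            raise ValidationError(
                f"block {name!r} spans {widths} voxels; a 5 mm spherical ROI "
                "needs at least 3 voxels in each axis"
            )

    tensors = np.empty(grid + (6,))
    tensors[...] = spec.compartment_tensors["background"]
    boost = np.array([spec.perivascular_boost, 0, 0, 0, 0, 0])
    for name, block in blocks.items():
        t = np.asarray(spec.compartment_tensors[name], dtype=float).copy()
        if name in ("projection", "association"):
            t = t + boost
        _check_spd(t, name)
        tensors[block] = t
    _check_spd(spec.compartment_tensors["background"], "background")

    rois = []
    for name in roi_blocks:
        ijk = np.array(_block_center_voxel(blocks[name]), dtype=float)
        center = origin + voxel_size * ijk
        rois.append(ROISpec(name=name, center=center, diameter=5.0))

    ground_truth = TensorField(
        tensors=tensors,
        s0=np.full(grid, float(spec.s0)),
        mask=np.ones(grid, dtype=bool),
        voxel_size=voxel_size,
        origin=origin,
    )
    return ground_truth, rois


def analytic_alps(spec: PhantomSpec) -> float:
    """Closed-form ALPS-index of the phantom's compartment tensors."""
    proj = spec.compartment_tensors["projection"]
    assoc = spec.compartment_tensors["association"]
    num = (proj[0] + spec.perivascular_boost + assoc[0] + spec.perivascular_boost) / 2
    den = (proj[1] + assoc[2]) / 2
    return num / den


def simulate_dwi(ground_truth: TensorField, gtab: GradientTable,
                 s0: float = 1000.0, noise_sigma: float = 0.0,
                 nex: int = 3, seed: int = 0) -> DWIDataset:
    """Forward-simulate the acquisition ``S = s0 exp(-b g^T D g)``.

    Rician noise with scale ``noise_sigma`` (defined on the two complex
    channels) is applied independently per excitation and the ``nex``
    excitations are averaged, emulating multi-NEX magnitude averaging.
    """
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    if nex < 1:
        raise ValidationError("nex must be >= 1")
    X = design_matrix(gtab)[:, 1:]  # (N, 6): coefficients of -b g^T D g
    elements = ground_truth.tensors.reshape(-1, 6)
    log_atten = elements @ X.T  # (V, N)
    clean = float(s0) * np.exp(log_atten)
    if noise_sigma == 0:
        signal = clean
    else:
        rng = np.random.default_rng(seed)
        acc = np.zeros_like(clean)
        for _ in range(int(nex)):
            re = clean + rng.normal(0.0, noise_sigma, clean.shape)
            im = rng.normal(0.0, noise_sigma, clean.shape)
            acc += np.hypot(re, im)
        signal = acc / nex
    signal = signal.reshape(ground_truth.grid_shape + (len(gtab),))
    return DWIDataset(
        signal=signal,
        gtab=gtab,
        voxel_size=ground_truth.voxel_size,
        origin=ground_truth.origin,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: Variables drawn jointly through the copula; everything else is
#: independent within group.  ``alps`` must come first.
COPULA_VARIABLES = ("alps", "nuclear_dna", "mito_dna", "mmse", "casi", "updrs_total")

#: Variables supported on [0, inf): their marginals are moment-matched
#: zero-truncated (or zero-censored, when the target CV exceeds what a
#: truncated normal can reach) normals.
NONNEGATIVE_VARIABLES = ("nuclear_dna", "mito_dna")

#: Variables absent (NA) for the normal-control group.
PD_ONLY_VARIABLES = (
    "disease_duration", "updrs1", "updrs2", "updrs3", "updrs_total",
    "hy", "se_adl",
)

DOMAIN_Z = ("z_attention", "z_executive", "z_language", "z_memory",
            "z_visuospatial")

HY_GRID = np.array([0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0])


@dataclass(frozen=True)
class GroupSpec:
    """Marginal means/SDs for one cohort group plus its size and sex mix."""

    n: int
    male_fraction: float
    means: dict
    sds: dict

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError("each group needs n >= 2")
        if not 0 <= self.male_fraction <= 1:
            raise ValidationError("male_fraction must be in [0, 1]")
        if any(s < 0 for s in self.sds.values()):
            raise ValidationError("SDs must be >= 0")


def _default_groups() -> dict:
    """Study-sized default cohort: group sizes, demographics, severity,
    cognition, plasma DNA and ALPS marginals (mean, SD) per group."""
    common_keys = ("age", "mmse", "casi", "nuclear_dna", "mito_dna", "alps")

    def g(n, male_frac, **kw):
        means = {k: v[0] for k, v in kw.items()}
        sds = {k: v[1] for k, v in kw.items()}
        return GroupSpec(n=n, male_fraction=male_frac, means=means, sds=sds)

    return {
        "NC": g(
            47, 15 / 47,
            age=(61.53, 4.75), mmse=(27.21, 2.06), casi=(88.76, 6.47),
            nuclear_dna=(19.34, 14.76), mito_dna=(31.54, 33.86),
            alps=(1.55, 0.15),
            z_attention=(0.0, 0.8), z_executive=(0.0, 0.8),
            z_language=(0.0, 0.8), z_memory=(0.0, 0.8),
            z_visuospatial=(0.0, 0.8),
        ),
        "PDN": g(
            25, 15 / 25,
            age=(60.08, 10.07), mmse=(27.92, 1.78), casi=(92.87, 3.80),
            nuclear_dna=(31.35, 26.18), mito_dna=(39.89, 31.04),
            alps=(1.48, 0.15),
            disease_duration=(2.49, 1.91),
            updrs1=(3.16, 2.29), updrs2=(8.40, 6.31), updrs3=(19.56, 13.14),
            updrs_total=(31.12, 20.26), hy=(1.86, 1.25), se_adl=(83.6, 20.99),
            z_attention=(0.0, 0.8), z_executive=(0.0, 0.8),
            z_language=(0.0, 0.8), z_memory=(0.0, 0.8),
            z_visuospatial=(0.0, 0.8),
        ),
        "PD-MCI": g(
            25, 8 / 25,
            age=(63.8, 8.70), mmse=(27.08, 1.32), casi=(86.62, 7.79),
            nuclear_dna=(32.03, 21.40), mito_dna=(45.36, 38.70),
            alps=(1.42, 0.15),
            disease_duration=(3.07, 2.67),
            updrs1=(3.76, 3.00), updrs2=(9.48, 7.50), updrs3=(24.76, 15.41),
            updrs_total=(38.00, 24.25), hy=(2.16, 1.26), se_adl=(82.00, 22.55),
            z_attention=(-2.0, 0.5), z_executive=(-2.0, 0.5),
            z_language=(-0.5, 0.5), z_memory=(-0.5, 0.5),
            z_visuospatial=(-0.5, 0.5),
        ),
        "PDD": g(
            38, 11 / 38,
            age=(65.76, 8.00), mmse=(20.00, 4.53), casi=(69.62, 15.66),
            nuclear_dna=(46.13, 33.67), mito_dna=(43.04, 31.17),
            alps=(1.38, 0.15),
            disease_duration=(3.64, 4.28),
            updrs1=(3.76, 3.07), updrs2=(11.55, 8.17), updrs3=(27.47, 14.47),
            updrs_total=(42.79, 23.98), hy=(1.88, 0.84), se_adl=(85.26, 11.32),
            z_attention=(-2.5, 0.5), z_executive=(-2.5, 0.5),
            z_language=(-2.0, 0.5), z_memory=(-2.5, 0.5),
            z_visuospatial=(-2.0, 0.5),
        ),
    }


#: Default within-group Spearman targets of each copula variable with the
#: ALPS-index, mirroring the reported correlation structure.
DEFAULT_SPEARMAN_TARGETS = {
    "nuclear_dna": -0.278,
    "mito_dna": -0.201,
    "mmse": 0.222,
    "casi": 0.178,
    "updrs_total": -0.307,
}


@dataclass(frozen=True)
class CohortSpec:
    """Four-group cohort specification with copula rank-correlation targets.

    ``spearman_targets`` maps copula variables to their within-group
    Spearman correlation with the ALPS-index; unlisted pairs are
    conditionally independent given ALPS is not implied — they are simply
    uncorrelated in the latent Gaussian.
    """

    groups: dict = field(default_factory=_default_groups)
    spearman_targets: dict = field(
        default_factory=lambda: dict(DEFAULT_SPEARMAN_TARGETS)
    )
    seed: int = 0

    def __post_init__(self):
        for var, rho in self.spearman_targets.items():
            if var not in COPULA_VARIABLES or var == "alps":
                raise ValidationError(f"no copula slot for variable {var!r}")
            if not -1 < rho < 1:
                raise ValidationError(f"target correlation for {var!r} out of (-1, 1)")
        _latent_correlation(self.spearman_targets)  # fail fast if not PD


def _latent_correlation(spearman_targets: dict) -> np.ndarray:
    """Latent Gaussian correlation matrix hitting the Spearman targets
    (Pearson r = 2 sin(pi * rho_s / 6) for a Gaussian copula)."""
    k = len(COPULA_VARIABLES)
    R = np.eye(k)
    for var, rho_s in spearman_targets.items():
        j = COPULA_VARIABLES.index(var)
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        R[0, j] = R[j, 0] = r
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ValidationError("correlation-target matrix is not positive definite")
    return R


def _match_truncated_normal(mean: float, sd: float):
    """Parameters (mu, sigma) of a zero-truncated normal whose truncated
    mean/SD equal the targets.  Requires CV = sd/mean below the truncated
    normal's supremum of 1."""

    def moments(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a = (0.0 - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(moments, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise ValidationError(
            f"cannot moment-match a zero-truncated normal to mean={mean}, sd={sd}"
        )
    return sol.x[0], float(np.exp(sol.x[1]))


def _match_censored_normal(mean: float, sd: float):
    """Parameters (mu, sigma) of a normal censored at zero (mass collapses
    onto 0) whose censored mean/SD equal the targets; reaches CV > 1."""

    def moments(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a = mu / sigma
        phi, Phi = stats.norm.pdf(a), stats.norm.cdf(a)
        m = mu * Phi + sigma * phi
        m2 = (mu**2 + sigma**2) * Phi + mu * sigma * phi
        v = m2 - m**2
        return [m - mean, np.sqrt(max(v, 0.0)) - sd]

    sol = optimize.root(moments, x0=[mean - sd, np.log(sd)], method="hybr")
    if not sol.success:
        raise ValidationError(
            f"cannot moment-match a zero-censored normal to mean={mean}, sd={sd}"
        )
    return sol.x[0], float(np.exp(sol.x[1]))


def _nonnegative_from_uniform(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Monotone transform of uniforms to a nonnegative marginal with the
    target mean/SD.

    Uses a zero-truncated normal (continuous, rank-preserving) whenever the
    target CV allows it, else a zero-censored normal (point mass at 0).
    """
    if sd == 0:
        return np.full_like(u, mean)
    if sd / mean < 0.995:
        mu, sigma = _match_truncated_normal(mean, sd)
        a = (0.0 - mu) / sigma
        return stats.truncnorm.ppf(u, a, np.inf, loc=mu, scale=sigma)
    mu, sigma = _match_censored_normal(mean, sd)
    return np.maximum(stats.norm.ppf(u, loc=mu, scale=sigma), 0.0)


def _gaussian_from_uniform(u, mean, sd, lo=None, hi=None):
    if sd == 0:
        x = np.full_like(u, float(mean))
    else:
        x = stats.norm.ppf(u, loc=mean, scale=sd)
    if lo is not None or hi is not None:
        x = np.clip(x, lo, hi)
    return x


def _round_to_hy(x: np.ndarray) -> np.ndarray:
    idx = np.argmin(np.abs(x[:, None] - HY_GRID[None, :]), axis=1)
    return HY_GRID[idx]


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table from the group marginals and the copula.

    Within each group the copula variables (ALPS, plasma DNA, MMSE, CASI,
    UPDRS total) share a Gaussian copula with the target rank correlations;
    all marginal transforms are monotone, so the Spearman targets carry over
    to the generated columns.  Remaining variables are independent
    Gaussians; HY stages are snapped to the modified-scale grid, MMSE is
    clipped to [0, 30], SE-ADL to [0, 100], and severity scores to >= 0.
    """
    R = _latent_correlation(spec.spearman_targets)
    chol = np.linalg.cholesky(R)
    rng = np.random.default_rng(spec.seed)
    frames = []
    for gname, grp in spec.groups.items():
        n = grp.n
        z = rng.standard_normal((n, len(COPULA_VARIABLES))) @ chol.T
        u = stats.norm.cdf(z)
        cols: dict[str, np.ndarray] = {}
        for j, var in enumerate(COPULA_VARIABLES):
            if var not in grp.means:
                continue
            m, s = grp.means[var], grp.sds[var]
            if var in NONNEGATIVE_VARIABLES:
                cols[var] = _nonnegative_from_uniform(u[:, j], m, s)
            elif var == "mmse":
                cols[var] = _gaussian_from_uniform(u[:, j], m, s, lo=0.0, hi=30.0)
            elif var == "casi":
                cols[var] = _gaussian_from_uniform(u[:, j], m, s, lo=0.0, hi=100.0)
            elif var == "updrs_total":
                cols[var] = _gaussian_from_uniform(u[:, j], m, s, lo=0.0)
            else:
                cols[var] = _gaussian_from_uniform(u[:, j], m, s)

        for var, (lo, hi) in {
            "age": (None, None),
            "disease_duration": (0.0, None),
            "updrs1": (0.0, None),
            "updrs2": (0.0, None),
            "updrs3": (0.0, None),
            "se_adl": (0.0, 100.0),
        }.items():
            if var in grp.means:
                draw = rng.standard_normal(n)
                cols[var] = np.clip(
                    grp.means[var] + grp.sds[var] * draw,
                    lo if lo is not None else -np.inf,
                    hi if hi is not None else np.inf,
                )
        for var in DOMAIN_Z:
            draw = rng.standard_normal(n)
            cols[var] = grp.means[var] + grp.sds[var] * draw
        if "hy" in grp.means:
            raw = grp.means["hy"] + grp.sds["hy"] * rng.standard_normal(n)
            cols["hy"] = _round_to_hy(np.clip(raw, 0.0, 5.0))

        frame = pd.DataFrame(cols)
        frame.insert(0, "id", [f"{gname}{i + 1:04d}" for i in range(n)])
        frame.insert(1, "group", gname)
        frame.insert(
            2, "sex",
            np.where(rng.random(n) < grp.male_fraction, "M", "F"),
        )
        for var in PD_ONLY_VARIABLES:
            if var not in frame.columns:
                frame[var] = np.nan
        frames.append(frame)

    cohort = pd.concat(frames, ignore_index=True)
    order = ["id", "group", "age", "sex", "disease_duration", "updrs1",
             "updrs2", "updrs3", "updrs_total", "hy", "se_adl", "mmse",
             "casi", *DOMAIN_Z, "nuclear_dna", "mito_dna", "alps"]
    return validate_cohort(cohort[order])
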