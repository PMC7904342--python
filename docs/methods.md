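# Methods

## Signal model and tensor estimation

Each voxel's diffusion-weighted signal follows the single-tensor model
S = S0 · exp(−b gᵀ D g), with D a symmetric 3×3 tensor (mm²/s), b the
diffusion weighting (s/mm²) and g the unit gradient direction. Taking logs
gives a model linear in (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz); estimation
is ordinary least squares on the log-signal, solved as one vectorised
least-squares problem over all masked voxels (the design matrix is shared
across voxels). OLS rather than weighted or nonlinear variants is a
deliberate choice: it is deterministic, cheap, and exactly checkable
against closed-form forward simulations — the trade-off is mild bias at
low SNR relative to WLS, which is irrelevant to the noiseless oracles and
secondary to the index's contrast.

Numerical choices:

* signals ≤ 0 (possible under magnitude noise averaging) are floored at
  1e-6 × max(signal) before the log; the clamped count is logged;
* a fit requires at least one b = 0 volume and ≥ 6 distinct non-collinear
  diffusion directions (antipodal pairs counted once, collinearity
  threshold |cos| > 1 − 1e-6); rank-deficient designs raise an estimation
  error;
* negative fitted diagonal elements under noise are reported **as-is**,
  because the ALPS ratio consumes raw diagonals; FA clips negative
  eigenvalues to 0 first and the all-zero tensor is assigned FA = 0;
* axis diffusivities are the tensor's diagonal elements in the fixed
  anatomical frame (x = right–left, y = anterior–posterior, z =
  inferior–superior). They are intentionally *not* rotation invariant —
  that frame-dependence is the signal the index reads.

## ROI sampling and the index

ROIs are spheres specified in world millimetres (default diameter 5 mm).
A voxel belongs to the sphere when its *centre* lies within the radius,
boundary inclusive (with a 1e-9 mm² guard against floating-point
representation); this makes selections reproducible and independent of
any partial-volume convention. World coordinates place the origin at the
grid's geometric centre, so phantom ROIs are symmetric around zero, and
measurements follow the left-hemisphere convention: an ROI centred at
x > 0 triggers a warning.

The index is computed with arithmetic means,
ALPS = (Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc) after cancelling
the common factor ½. Each ROI carries a fibre-dominance QC flag: the
principal eigenvector of the ROI-mean tensor must have its largest
absolute component on the expected axis (z for projection, y for
association, x for subcortical). Ties — including isotropic ROIs — fail
the flag conservatively. The subcortical ROI is QC'd but never enters the
ratio. A non-positive denominator raises rather than returning a
meaningless index.

## The phantom

The phantom is a rectangular grid (default 16×16×12 voxels of
2×2×2.5 mm) whose left half holds four disjoint blocks: projection
(diag(0.6, 0.6, 1.7)e-3 mm²/s, z-dominant), association
(diag(0.6, 1.7, 0.6)e-3, y-dominant), subcortical (x-dominant), and
isotropic CSF (3.0e-3); everything else is isotropic parenchyma
(0.8e-3). The perivascular effect is modelled as an additive Dxx
increment δ applied in both fibre blocks — not as an explicit sub-voxel
perivascular compartment — because the index senses exactly this diagonal
increment, keeping the ground truth analytic:
ALPS = (0.6e-3 + δ)/0.6e-3 with the default tensors. The `isotropic()`
variant sets every compartment to 0.8e-3, the equal-numerator/denominator
baseline whose index is exactly 1.

Acquisition defaults mirror a single-shell clinical scheme: one b0 plus 13
non-collinear directions at b = 1000 s/mm², 2×2×2.5 mm voxels, three
excitations. The direction set is a fixed table obtained by
electrostatic-repulsion minimisation on the antipodally symmetrised
sphere (design condition number 1.61); any 13 non-collinear unit vectors
would serve, but freezing one keeps every simulation bit-reproducible.
Noise is Rician: per excitation the clean signal is the magnitude of a
complex Gaussian perturbation with per-channel scale σ, and the NEX = 3
excitations are averaged — the standard magnitude-MR noise model, which
reduces to Gaussian at high SNR and reproduces the positive noise floor
at low SNR. What the phantom does *not* emulate: real anatomy,
partial-volume mixing at block boundaries, eddy currents, motion, or
susceptibility distortion; passing tests therefore validate the
estimator and the index algebra, not robustness to acquisition artefacts.

## The cohort simulator

Subjects are drawn per group (NC n=47, PDN n=25, PD-MCI n=25, PDD n=38 by
default) with marginal means/SDs for age, sex ratio, disease duration,
UPDRS subscales and total, modified Hoehn–Yahr stage, SE-ADL, MMSE, CASI,
five cognitive-domain z-scores, plasma nuclear and mitochondrial DNA
(ng/mL), and the ALPS-index. The published summary tables provide all
marginals except the ALPS-index itself, which the source reports only
graphically; the defaults (NC 1.55, PDN 1.48, PD-MCI 1.42, PDD 1.38, SD
0.15) are field-typical values chosen once to reproduce the qualitative
significance pattern (PD-MCI and PDD below NC; PDN not separable).

Dependence is imposed through a Gaussian copula within each group over
(ALPS, nuclear DNA, mito DNA, MMSE, CASI, UPDRS total): the latent
correlation uses the exact Gaussian-copula inversion
r = 2·sin(π·ρ_s/6) of the target Spearman coefficients (defaults −0.278,
−0.201, +0.222, +0.178, −0.307 against ALPS; other latent pairs
uncorrelated). All marginal transforms are monotone, so rank correlations
survive the marginals exactly (up to ties introduced by clipping).

Marginal families:

* unbounded variables are Gaussian;
* plasma DNA is nonnegative: it uses a **moment-matched zero-truncated
  normal** (parameters solved so the truncated distribution has exactly
  the target mean and SD — plain truncation or censoring of a normal with
  the target parameters would shift the mean by several percent). A
  truncated normal cannot exceed a coefficient of variation of 1, so
  targets with CV ≥ 1 (e.g. mitochondrial DNA in controls) fall back to a
  moment-matched zero-censored normal, which places a point mass at 0;
  the resulting ties mildly attenuate that variable's rank correlations;
* MMSE is clipped to [0, 30], CASI to [0, 100], SE-ADL to [0, 100],
  severity scores to ≥ 0 (plain clipping — these have no
  moment-faithfulness contract);
* HY stages are snapped to the modified scale {0, 1, 1.5, …, 5};
* sex is Bernoulli with the group's male fraction.

Group labels are assigned from the generating group, and each PD group's
mean domain-z/MMSE profile classifies to its own label under the
subgrouping rules, so classification is consistent in expectation (and
exact when all SDs are zero). Known limitations: UPDRS subscales are
drawn independently of the total (no adding-up constraint); only pairwise
correlations with ALPS are controlled — the full joint dependence of
cognition, DNA and the index is not reported anywhere and the copula is
this package's modelling assumption.

## Cognitive subgrouping

A domain is impaired when its z-score is ≤ −1.5 (boundary impaired).
PDD requires impairment in more than one domain **and** MMSE < 26 (MMSE
exactly 26 is not demented); otherwise ≥ 2 impaired domains give PD-MCI;
otherwise PDN. Read literally, these rules leave single-domain impairment
in PDN and make PD-MCI require multi-domain impairment — single-domain
MCI is not representable; the classifier implements the rules as stated
rather than the broader consensus variants. Disease staging splits PD
into early (HY ≤ 2, boundary early) and late (HY > 2).

## Statistics

Age is compared by one-way ANOVA and sex by Pearson chi-square without
continuity correction. Every other outcome uses ANCOVA — the linear model
outcome ~ group + age + sex with no interaction terms — with the group
effect tested by the extra-sum-of-squares (Type II) F; with no
interactions this equals the two-nested-model F, which is how the test
oracles verify it. Adjusted group means are the model's predictions at
the covariate means (sex entering as an indicator evaluated at its sample
proportion). Constant covariates are dropped with a log note, reducing
the test to one-way ANOVA; rows missing a variable are dropped from that
test only, with a logged count.

Post hoc comparisons are all pairwise contrasts of adjusted means, t-tested
on the model covariance, with Bonferroni correction p_adj = min(1, m·p)
over the family of the m pairs *within one outcome* (m = 6 for four
groups) — no correction is applied across outcomes, matching the
reporting convention the battery emulates. Spearman correlations use
average ranks with the t approximation (df = n − 2) for p; an exact
permutation mode (n ≤ 10) exists as a slow oracle. The fixed 2×4
male/female-by-group count table used in testing reproduces its published
p-value of 0.056 exactly.

Simulation sizes in the test suite (1000 replicates for type-I
calibration with an acceptance band of 3–7% at α = 0.05, 200 seeds for
power/sign-recovery checks, n = 10000 for copula-target recovery within
±0.03) were chosen so that binomial/sampling error is comfortably inside
each asserted band.

## Command-line interface

The CLI is a thin layer over the library: `phantom`, `alps`, `cohort`,
`stats` and `full` write their outputs plus a `manifest.json` recording
the seed, package version and a parameter hash; existing non-empty output
directories are refused without `--force`. All randomness descends from
the single `--seed`; the `full` chain derives stage seeds by fixed
offsets, so identical configurations give byte-identical CSVs.
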