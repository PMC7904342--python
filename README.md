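# dtialps

Diffusion-tensor **a**nalysis a**l**ong the **p**erivascular **s**pace
(DTI-ALPS) for studying glymphatic function, packaged as a tested,
end-to-end pipeline with synthetic ground truth.

The glymphatic system clears interstitial waste through perivascular
channels. At the level of the lateral ventricle body, the perivascular
spaces of the medullary vessels run right–left (the x-axis), perpendicular
both to the projection fibres (mainly z) and to the association fibres
(mainly y). Water movement along the perivascular space therefore shows up
as extra x-axis diffusivity in both fibre regions, while the diffusivities
perpendicular to it within the same regions (D<sub>yy</sub> in the
projection area, D<sub>zz</sub> in the association area) are unaffected.
The ALPS-index quantifies this:

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

where the D's are diagonal elements of the per-voxel diffusion tensor in
the anatomical frame (not eigenvalues), averaged over 5 mm spherical ROIs
placed in the left-hemisphere projection- and association-fibre areas.
An index near 1 means no measurable perivascular contribution; larger
values mean freer perivascular diffusion. Lower values have been associated
with cognitive decline in Parkinson's disease and other
neurodegenerative conditions.

The package is aimed at imaging methodologists who want a reproducible,
oracle-checked reference implementation of the index and of the
accompanying cross-sectional statistics (ANCOVA with age/sex covariates,
Bonferroni post hoc contrasts, Spearman correlations with plasma-DNA and
cognitive measures), exercisable entirely on synthetic data.

## What is inside

| module | contents |
| --- | --- |
| `dtialps.io_formats` | NIfTI + FSL bval/bvec + ROI YAML + cohort CSV readers/writers with validation |
| `dtialps.tensor_pipeline` | log-linear OLS tensor fit; FA, MD, axis-diffusivity and colour-FA maps |
| `dtialps.alps_index` | spherical ROI sampling, fibre-dominance QC, the ALPS ratio |
| `dtialps.synthetic_data` | block phantoms with analytic ALPS ground truth; Gaussian-copula cohort simulator |
| `dtialps.group_stats` | cognitive subgrouping (PDN / PD-MCI / PDD), ANOVA / chi-square / ANCOVA / Bonferroni / Spearman battery |
| `dtialps.cli` | `dtialps phantom | alps | cohort | stats | full` subcommands |

## Worked example

A noiseless phantom whose fibre compartments share a perpendicular
diffusivity of 0.6e-3 mm²/s, with a perivascular boost of 0.4e-3 mm²/s
added to D<sub>xx</sub> in both fibre blocks:

```python
from dtialps import (PhantomSpec, make_phantom, simulate_dwi,
                     default_gradient_table, compute_subject_alps)

spec = PhantomSpec(perivascular_boost=0.4e-3)
truth, rois = make_phantom(spec)
dwi = simulate_dwi(truth, default_gradient_table(), s0=spec.s0)
res = compute_subject_alps(dwi, rois)
print(f"ALPS-index: {res.alps:.6f} (QC pass: {res.qc_pass})")
```

prints

```
ALPS-index: 1.666667 (QC pass: True)
```

which is exactly the analytic ratio (0.6e-3 + 0.4e-3) / 0.6e-3: the ROI
means recover D<sub>xx</sub> = 1.0e-3 in both fibre areas against the
unchanged perpendicular references of 0.6e-3. The QC flag confirms that the
principal eigenvector in each ROI points along the expected fibre axis.

Simulating a study-sized cohort (47 controls, 25 PDN, 25 PD-MCI, 38 PDD)
and running the battery:

```python
from dtialps import CohortSpec, simulate_cohort, run_group_analysis

results = run_group_analysis(simulate_cohort(CohortSpec(seed=1)))
print(results["posthoc"].query("variable == 'alps'")[["contrast", "p_adj"]])
```

gives Bonferroni-adjusted ALPS contrasts such as

```
  contrast         p_adj
 PD-MCI-NC  4.101922e-05
    PDD-NC  6.062468e-08
    PDN-NC  2.240099e-01
```

i.e. at this seed the PD-MCI and PDD groups have significantly lower
covariate-adjusted ALPS-index than controls while PDN does not — the
qualitative pattern the simulator is parameterised to produce. The
`spearman` table in the same bundle reports the rank correlations of the
index with plasma nuclear/mitochondrial DNA, MMSE, CASI and (within PD)
UPDRS scores.

The same chain is available from the shell:

```sh
dtialps full --seed 1 --out runs/demo
```

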