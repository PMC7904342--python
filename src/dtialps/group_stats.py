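"""Cognitive-subgroup classification and the group-comparison battery.

The battery mirrors a standard cross-sectional movement-disorders design:
age compared by one-way ANOVA, sex by Pearson chi-square, and every
clinical / cognitive / plasma-DNA / imaging outcome by ANCOVA with age and
sex as covariates, followed by Bonferroni-corrected pairwise contrasts of
the covariate-adjusted group means.  Correlations between the ALPS-index
and the other measures use Spearman's rank coefficient.

Cognitive subgrouping follows the consensus rules: a cognitive domain is
impaired when its z-score is at or below -1.5; dementia (PDD) requires
impairment in more than one domain together with MMSE below 26; mild
cognitive impairment (PD-MCI) requires impairment in two or more domains
without dementia; otherwise cognition is classed as normal (PDN).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import EstimationError, SchemaError, ValidationError
from .io_formats import DOMAIN_Z_COLUMNS

log = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "AncovaResult",
    "classify_cognitive_status",
    "hy_split",
    "anova_oneway",
    "chi_square_independence",
    "ancova",
    "bonferroni_posthoc",
    "spearman",
    "run_group_analysis",
]

#: Domain z-scores at or below this value count as impaired.
IMPAIRMENT_Z = -1.5

#: MMSE strictly below this value is in the dementia range.
DEMENTIA_MMSE = 26


@dataclass(frozen=True)
class StatResult:
    """One test's outcome; ``p_adj`` is set only for post hoc contrasts and
    ``estimates`` carries (covariate-adjusted) group means where they exist."""

    test: str
    statistic: float
    df: tuple
    p: float
    p_adj: float | None = None
    contrast: str | None = None
    estimates: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# classification and staging
# ---------------------------------------------------------------------------

def classify_cognitive_status(domain_z, mmse: float) -> str:
    """Assign PDN / PD-MCI / PDD from five domain z-scores and the MMSE.

    Boundary conventions: z exactly -1.5 is impaired; MMSE exactly 26 is
    not in the dementia range.
    """
    z = np.asarray(domain_z, dtype=float).ravel()
    if z.shape != (5,) or not np.all(np.isfinite(z)):
        raise ValidationError("domain_z must be 5 finite z-scores")
    impaired = int(np.sum(z <= IMPAIRMENT_Z))
    if impaired > 1 and mmse < DEMENTIA_MMSE:
        return "PDD"
    if impaired >= 2:
        return "PD-MCI"
    return "PDN"


def hy_split(cohort: pd.DataFrame) -> pd.Series:
    """Label PD subjects as early (HY <= 2) or late (HY > 2) disease.

    Returns a Series indexed like the PD rows; a PD row without an HY stage
    raises.
    """
    pd_rows = cohort[cohort["group"] != "NC"]
    if pd_rows["hy"].isna().any():
        bad = pd_rows.loc[pd_rows["hy"].isna(), "id"].tolist()
        raise ValidationError(f"PD subjects missing HY stage: {bad}")
    return pd.Series(
        np.where(pd_rows["hy"] <= 2.0, "early", "late"),
        index=pd_rows.index,
        name="hy_stage",
    )


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def _drop_missing(frame: pd.DataFrame, cols, context: str) -> pd.DataFrame:
    complete = frame.dropna(subset=list(cols))
    n_dropped = len(frame) - len(complete)
    if n_dropped:
        log.info("%s: dropped %d rows with missing values", context, n_dropped)
    return complete


def anova_oneway(values, groups) -> StatResult:
    """One-way ANOVA: F on df (k - 1, N - k)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValidationError("every group needs n >= 2")
    f_val, p_val = stats.f_oneway(*samples)
    k, n_total = len(samples), len(values)
    return StatResult(
        test="anova",
        statistic=float(f_val),
        df=(k - 1, n_total - k),
        p=float(p_val),
        estimates={str(g): float(np.mean(s)) for g, s in zip(labels, samples)},
    )


def chi_square_independence(contingency) -> StatResult:
    """Pearson chi-square on an r x c count table, without continuity
    correction, df = (r - 1)(c - 1)."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValidationError("contingency must be a 2D non-negative table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("contingency table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return StatResult(test="chi_square", statistic=float(chi2), df=(dof,), p=float(p))


# ---------------------------------------------------------------------------
# ANCOVA and post hoc contrasts
# ---------------------------------------------------------------------------

@dataclass
class AncovaResult:
    """ANCOVA group-effect test plus everything the post hoc step needs."""

    result: StatResult
    fit: object
    group_levels: list
    covariate_means: dict


def _prepare_ancova_frame(data, outcome, group, covariates):
    frame = pd.DataFrame(
        {"_y": np.asarray(data[outcome], dtype=float), "_g": data[group]}
    )
    cov_cols = []
    for cov in covariates:
        col = data[cov]
        if col.dtype == object or str(col.dtype) == "category":
            # binary categorical covariate -> indicator of the second level
            levels = sorted(pd.unique(col.dropna()))
            if len(levels) > 2:
                raise ValidationError(
                    f"categorical covariate {cov!r} has more than 2 levels"
                )
            frame[f"_c_{cov}"] = (col == levels[-1]).astype(float)
        else:
            frame[f"_c_{cov}"] = np.asarray(col, dtype=float)
        cov_cols.append(f"_c_{cov}")
    return frame, cov_cols


def ancova(data: pd.DataFrame, outcome: str, group: str = "group",
           covariates=("age", "sex")) -> AncovaResult:
    """Linear model ``outcome ~ group + covariates`` (no interactions); the
    group effect is the extra-sum-of-squares (Type II) F of the group
    factor.  Adjusted group means are evaluated at the covariate means.

    Constant covariates are dropped with a logged note (the test then
    reduces to one-way ANOVA); rows missing any involved variable are
    dropped from this test only.
    """
    frame, cov_cols = _prepare_ancova_frame(data, outcome, group, covariates)
    frame = _drop_missing(frame, frame.columns, f"ancova[{outcome}]")
    kept = []
    for c in cov_cols:
        if np.ptp(frame[c].to_numpy()) == 0:
            log.info("ancova[%s]: covariate %s is constant; dropped", outcome, c)
        else:
            kept.append(c)
    levels = sorted(pd.unique(frame["_g"]))
    if len(levels) < 2:
        raise ValidationError("ANCOVA needs at least 2 groups")

    rhs = " + ".join(["C(_g)"] + kept) if kept else "C(_g)"
    fit = smf.ols(f"_y ~ {rhs}", data=frame).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise EstimationError("collinear ANCOVA design")
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(_g)"]
    df_num = int(row["df"])
    df_den = int(table.loc["Residual", "df"])

    cov_means = {c: float(frame[c].mean()) for c in kept}
    at = pd.DataFrame({"_g": levels})
    for c, m in cov_means.items():
        at[c] = m
    adjusted = dict(zip(levels, map(float, fit.predict(at))))

    result = StatResult(
        test="ancova",
        statistic=float(row["F"]),
        df=(df_num, df_den),
        p=float(row["PR(>F)"]),
        estimates=adjusted,
    )
    return AncovaResult(
        result=result, fit=fit, group_levels=levels, covariate_means=cov_means
    )


def bonferroni_posthoc(ancova_result: AncovaResult, pairs=None) -> list[StatResult]:
    """Pairwise contrasts of adjusted group means with Bonferroni-adjusted
    p-values, ``p_adj = min(1, m p)`` over the family of all pairs tested."""
    fit = ancova_result.fit
    levels = ancova_result.group_levels
    if pairs is None:
        pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    names = list(fit.params.index)

    def coef_vector(level):
        v = np.zeros(len(names))
        term = f"C(_g)[T.{level}]"
        if term in names:
            v[names.index(term)] = 1.0
        return v

    out = []
    for a, b in pairs:
        contrast = coef_vector(b) - coef_vector(a)
        tt = fit.t_test(contrast)
        p_raw = float(tt.pvalue)
        out.append(
            StatResult(
                test="bonferroni_contrast",
                statistic=float(np.ravel(tt.tvalue)[0]),
                df=(int(fit.df_resid),),
                p=p_raw,
                p_adj=min(1.0, m * p_raw),
                contrast=f"{b}-{a}",
                estimates={
                    str(a): ancova_result.result.estimates[a],
                    str(b): ancova_result.result.estimates[b],
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(x, y, method: str = "t") -> StatResult:
    """Spearman rank correlation on average ranks.

    ``method="t"`` (default) uses the t approximation with df = n - 2;
    ``method="exact"`` enumerates all rank permutations (n <= 10) for a
    two-sided permutation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("spearman needs paired 1D samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("spearman inputs must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValidationError("a sample has zero rank variance")
    n = len(x)
    rho, p_t = stats.spearmanr(x, y)
    if method == "t":
        return StatResult(test="spearman", statistic=float(rho), df=(n - 2,),
                          p=float(p_t))
    if method != "exact":
        raise ValidationError(f"unknown spearman method {method!r}")
    if n > 10:
        raise ValidationError("exact permutation p is limited to n <= 10")
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
    observed = abs(np.sum(rx_c * ry_c) / denom)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        r = np.sum(rx_c[list(perm)] * ry_c) / denom
        count += abs(r) >= observed - 1e-12
        total += 1
    return StatResult(test="spearman", statistic=float(rho), df=(n - 2,),
                      p=count / total)


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

#: Outcomes analysed by ANCOVA across all four groups.
ANCOVA_ALL_GROUPS = ("mmse", "casi", *DOMAIN_Z_COLUMNS,
                     "nuclear_dna", "mito_dna", "alps")

#: Outcomes defined only within PD (ANCOVA across the three PD subgroups).
ANCOVA_PD_ONLY = ("disease_duration", "updrs1", "updrs2", "updrs3",
                  "updrs_total", "hy", "se_adl")

#: Correlation battery: (x, y, subset) pairs.
SPEARMAN_ALL = ("nuclear_dna", "mito_dna", "mmse", "casi")
SPEARMAN_PD = ("updrs2", "updrs3", "updrs_total")


def _result_row(variable, r: StatResult) -> dict:
    return {
        "test": r.test,
        "variable": variable,
        "contrast": r.contrast,
        "statistic": r.statistic,
        "df": "/".join(str(d) for d in r.df),
        "p": r.p,
        "p_adj": r.p_adj,
    }


def run_group_analysis(cohort: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Run the full battery on a cohort table.

    Returns a dict of DataFrames: ``demographics`` (age ANOVA + sex
    chi-square), ``ancova`` (group effects per outcome), ``posthoc``
    (Bonferroni pairwise contrasts per outcome, including the
    NC/early/late staging comparison of the ALPS-index), ``adjusted_means``
    and ``spearman``.
    """
    if "alps" not in cohort.columns:
        raise SchemaError("cohort table has no 'alps' column")
    demo_rows = []
    age = _drop_missing(cohort, ["age"], "anova[age]")
    demo_rows.append(_result_row("age", anova_oneway(age["age"], age["group"])))
    sex_table = pd.crosstab(cohort["sex"], cohort["group"]).to_numpy()
    demo_rows.append(_result_row("sex", chi_square_independence(sex_table)))

    ancova_rows, posthoc_rows, mean_rows = [], [], []

    def run_ancova(frame, outcome, label, group_col="group"):
        res = ancova(frame, outcome, group=group_col)
        ancova_rows.append(_result_row(label, res.result))
        for c in bonferroni_posthoc(res):
            posthoc_rows.append(_result_row(label, c))
        for grp, mean in res.result.estimates.items():
            mean_rows.append(
                {"variable": label, "group": grp, "adjusted_mean": mean}
            )

    for outcome in ANCOVA_ALL_GROUPS:
        run_ancova(cohort, outcome, outcome)
    pd_only = cohort[cohort["group"] != "NC"]
    for outcome in ANCOVA_PD_ONLY:
        run_ancova(pd_only, outcome, outcome)

    # ALPS by disease stage: NC vs early PD vs late PD
    staged = cohort.copy()
    stage = hy_split(cohort)
    staged["stage"] = "NC"
    staged.loc[stage.index, "stage"] = stage
    run_ancova(staged, "alps", "alps_by_stage", group_col="stage")

    sp_rows = []
    for var in SPEARMAN_ALL:
        sub = _drop_missing(cohort, ["alps", var], f"spearman[{var}]")
        sp_rows.append(_result_row(f"alps~{var}", spearman(sub["alps"], sub[var])))
    for var in SPEARMAN_PD:
        sub = _drop_missing(pd_only, ["alps", var], f"spearman[{var}]")
        sp_rows.append(
            _result_row(f"alps~{var} (PD)", spearman(sub["alps"], sub[var]))
        )

    results = {
        "demographics": pd.DataFrame(demo_rows),
        "ancova": pd.DataFrame(ancova_rows),
        "posthoc": pd.DataFrame(posthoc_rows),
        "adjusted_means": pd.DataFrame(mean_rows),
        "spearman": pd.DataFrame(sp_rows),
    }
    for name, frame in results.items():
        if "p" in frame.columns:
            if "p_adj" in frame.columns:
                padj = pd.to_numeric(frame["p_adj"], errors="coerce")
                pcol = padj.where(padj.notna(), frame["p"])
            else:
                pcol = frame["p"]
            frame["significant"] = pcol < alpha
    return results
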