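import numpy as np
import pandas as pd
import pytest

from dtialps import (
    CohortSpec,
    ValidationError,
    ancova,
    anova_oneway,
    bonferroni_posthoc,
    chi_square_independence,
    classify_cognitive_status,
    hy_split,
    run_group_analysis,
    simulate_cohort,
    spearman,
)
from dtialps.errors import SchemaError


# ---------------------------------------------------------------------------
# from-scratch oracles
# ---------------------------------------------------------------------------

def anova_oracle(samples):
    """Explicit sums-of-squares one-way ANOVA."""
    allv = np.concatenate(samples)
    grand = allv.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(np.sum((s - s.mean()) ** 2) for s in samples)
    df1 = len(samples) - 1
    df2 = len(allv) - len(samples)
    return (ssb / df1) / (ssw / df2)

def chi2_oracle(table):
    """Explicit sum of (O - E)^2 / E over all cells."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(np.sum((table - expected) ** 2 / expected))

def rank_average(v):
    """Average ranks, written from the definition."""
    v = np.asarray(v, dtype=float)
    out = np.empty(len(v))
    for i, x in enumerate(v):
        less = np.sum(v < x)
        equal = np.sum(v == x)
        out[i] = less + (equal + 1) / 2.0
    return out

def spearman_oracle(x, y):
    """Pearson correlation of average ranks."""
    rx, ry = rank_average(x), rank_average(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))

def ancova_group_f_oracle(y, group, covs):
    """Extra-sum-of-squares F of the group factor from two nested linear
    models solved by the normal equations."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    levels = sorted(set(group))
    dummies = np.column_stack(
        [np.asarray(group) == lv for lv in levels[1:]]
    ).astype(float)
    covs = np.column_stack(covs) if covs else np.empty((n, 0))
    X_red = np.column_stack([np.ones(n), covs])
    X_full = np.column_stack([np.ones(n), dummies, covs])

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    df_num = len(levels) - 1
    df_den = n - X_full.shape[1]
    return ((rss(X_red) - rss(X_full)) / df_num) / (rss(X_full) / df_den)


# ---------------------------------------------------------------------------
# classification and staging
# ---------------------------------------------------------------------------

class TestClassification:
    @pytest.mark.parametrize(
        "z, mmse, label",
        [
            ((0, 0, 0, 0, 0), 28, "PDN"),
            ((-2, -2, 0, 0, 0), 27, "PD-MCI"),
            ((-2, -2, 0, 0, 0), 25, "PDD"),
            ((-1.5, -1.5, 0, 0, 0), 28, "PD-MCI"),  # boundary z counts
            ((-2, -2, 0, 0, 0), 26, "PD-MCI"),      # MMSE 26 not demented
            ((-2, 0, 0, 0, 0), 20, "PDN"),          # single domain stays PDN
            ((-1.4999, -2, 0, 0, 0), 28, "PDN"),
        ],
    )
    def test_consensus_rules(self, z, mmse, label):
        assert classify_cognitive_status(z, mmse) == label

    def test_nonfinite_z_rejected(self):
        with pytest.raises(ValidationError):
            classify_cognitive_status((np.nan, 0, 0, 0, 0), 28)


class TestHySplit:
    def test_boundary_inclusive_at_two(self):
        cohort = pd.DataFrame(
            {
                "id": ["a", "b", "c", "d"],
                "group": ["PDN", "PDN", "PDD", "NC"],
                "hy": [2.0, 2.5, 0.0, np.nan],
            }
        )
        out = hy_split(cohort)
        assert list(out) == ["early", "late", "early"]

    def test_missing_hy_on_pd_row_rejected(self):
        cohort = pd.DataFrame(
            {"id": ["a"], "group": ["PDN"], "hy": [np.nan]}
        )
        with pytest.raises(ValidationError):
            hy_split(cohort)


# ---------------------------------------------------------------------------
# elementary tests vs oracles
# ---------------------------------------------------------------------------

class TestAnova:
    def test_identical_groups_give_f_zero(self):
        r = anova_oneway([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_toy_data_matches_hand_sums_of_squares(self):
        # {1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4, MSW = 1 -> F = 13.5
        r = anova_oneway([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert r.statistic == pytest.approx(13.5, rel=1e-12)
        assert r.df == (1, 4)

    def test_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            samples = [rng.normal(size=rng.integers(3, 12)) for _ in range(4)]
            values = np.concatenate(samples)
            groups = np.repeat(np.arange(4), [len(s) for s in samples])
            r = anova_oneway(values, groups)
            assert r.statistic == pytest.approx(anova_oracle(samples), rel=1e-10)


class TestChiSquare:
    def test_sex_by_group_table_reproduces_printed_p(self):
        r = chi_square_independence([[15, 15, 8, 11], [32, 10, 17, 27]])
        assert r.df == (3,)
        assert round(r.p, 3) == 0.056

    def test_uniform_table_gives_zero(self):
        r = chi_square_independence([[10, 10], [10, 10]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_matches_expected_count_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            table = rng.integers(1, 40, size=(2, rng.integers(2, 5)))
            r = chi_square_independence(table)
            assert r.statistic == pytest.approx(chi2_oracle(table), rel=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_independence([[0, 0], [3, 4]])


def twelve_row_fixture():
    """Deterministic 12-row ANCOVA dataset: 3 groups x 4 subjects, age and
    sex covariates, group effect entangled with age."""
    return pd.DataFrame(
        {
            "group": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
            "age": [55, 60, 65, 70, 52, 58, 66, 73, 50, 61, 64, 75],
            "sex": ["M", "F", "M", "F", "F", "F", "M", "M", "M", "F", "F", "M"],
            "y": [1.52, 1.48, 1.43, 1.40, 1.45, 1.44, 1.36, 1.30,
                  1.38, 1.33, 1.31, 1.25],
        }
    )


class TestAncova:
    def test_matches_two_model_rss_oracle_on_fixture(self):
        data = twelve_row_fixture()
        res = ancova(data, "y", covariates=("age", "sex"))
        sex_ind = (data["sex"] == "M").astype(float).to_numpy()
        f_ref = ancova_group_f_oracle(
            data["y"], data["group"], [data["age"].to_numpy(), sex_ind]
        )
        assert res.result.statistic == pytest.approx(f_ref, rel=1e-10)
        assert res.result.df == (2, 7)  # 12 rows - 5 model parameters

    def test_constant_covariates_reduce_to_anova(self):
        data = twelve_row_fixture()
        data["age"] = 60.0
        data["sex"] = "F"
        res = ancova(data, "y", covariates=("age", "sex"))
        ref = anova_oneway(data["y"], data["group"])
        assert res.result.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.result.df == ref.df

    def test_adjusted_means_at_covariate_means(self):
        data = twelve_row_fixture()
        res = ancova(data, "y", covariates=("age", "sex"))
        # adjusted means from the oracle: full-model coefficients evaluated
        # at the mean age and mean sex indicator
        y = data["y"].to_numpy()
        sex_ind = (data["sex"] == "M").astype(float).to_numpy()
        d_b = (data["group"] == "B").astype(float).to_numpy()
        d_c = (data["group"] == "C").astype(float).to_numpy()
        X = np.column_stack(
            [np.ones(12), d_b, d_c, data["age"].to_numpy(), sex_ind]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        base = beta[0] + beta[3] * data["age"].mean() + beta[4] * sex_ind.mean()
        assert res.result.estimates["A"] == pytest.approx(base, rel=1e-10)
        assert res.result.estimates["B"] == pytest.approx(base + beta[1], rel=1e-10)
        assert res.result.estimates["C"] == pytest.approx(base + beta[2], rel=1e-10)

    def test_rows_with_missing_values_dropped_from_test_only(self):
        data = twelve_row_fixture()
        data.loc[0, "y"] = np.nan
        res = ancova(data, "y", covariates=("age", "sex"))
        assert res.result.df == (2, 6)


class TestBonferroni:
    def test_adjustment_is_capped_monotone_scaling(self):
        data = twelve_row_fixture()
        res = ancova(data, "y", covariates=("age", "sex"))
        contrasts = bonferroni_posthoc(res)
        assert len(contrasts) == 3
        raws = [c.p for c in contrasts]
        adjs = [c.p_adj for c in contrasts]
        for raw, adj in zip(raws, adjs):
            assert adj == pytest.approx(min(1.0, 3 * raw), rel=1e-12)
            assert adj >= raw
        # ordering preserved
        assert np.argsort(raws).tolist() == np.argsort(adjs).tolist()

    def test_family_of_six_pairs_for_four_groups(self):
        cohort = simulate_cohort(CohortSpec(seed=4))
        res = ancova(cohort, "alps")
        contrasts = bonferroni_posthoc(res)
        assert len(contrasts) == 6
        assert all(
            c.p_adj == pytest.approx(min(1.0, 6 * c.p), rel=1e-12)
            for c in contrasts
        )


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        assert spearman([1, 2, 3], [10, 20, 30]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10]).statistic == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self):
        x = [1, 2, 2, 4]
        y = [1, 3, 2, 4]
        r = spearman(x, y)
        assert r.statistic == pytest.approx(spearman_oracle(x, y), rel=1e-10)

    def test_matches_oracle_on_random_data_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.integers(0, 6, size=15).astype(float)
            y = rng.integers(0, 6, size=15).astype(float) + 0.5 * x
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r = spearman(x, y)
            assert r.statistic == pytest.approx(spearman_oracle(x, y), rel=1e-10)

    def test_exact_permutation_p_close_to_t_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=7)
        y = x + rng.normal(size=7)
        exact = spearman(x, y, method="exact")
        approx = spearman(x, y, method="t")
        assert exact.statistic == approx.statistic
        assert abs(exact.p - approx.p) < 0.12

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1], [1, 2, 3])


@pytest.fixture(scope="module")
def results():
    cohort = simulate_cohort(CohortSpec(seed=7))
    return run_group_analysis(cohort)


class TestBattery:
    def test_all_output_families_present(self, results):
        assert set(results) == {
            "demographics", "ancova", "posthoc", "adjusted_means", "spearman"
        }

    def test_demographics_contains_age_anova_and_sex_chisq(self, results):
        demo = results["demographics"]
        assert list(demo["variable"]) == ["age", "sex"]
        assert list(demo["test"]) == ["anova", "chi_square"]

    def test_every_outcome_has_six_or_three_contrasts(self, results):
        counts = results["posthoc"].groupby("variable").size()
        # four-group outcomes -> 6 pairs; PD-only outcomes -> 3 pairs;
        # NC/early/late staging -> 3 pairs
        assert counts["alps"] == 6
        assert counts["updrs_total"] == 3
        assert counts["alps_by_stage"] == 3

    def test_spearman_battery_covers_reported_pairs(self, results):
        pairs = set(results["spearman"]["variable"])
        assert {"alps~nuclear_dna", "alps~mito_dna", "alps~mmse",
                "alps~casi", "alps~updrs2 (PD)", "alps~updrs3 (PD)",
                "alps~updrs_total (PD)"} <= pairs

    def test_p_values_are_probabilities(self, results):
        for frame in results.values():
            if "p" in frame.columns:
                p = frame["p"].dropna()
                assert ((p >= 0) & (p <= 1)).all()

    def test_missing_alps_column_is_schema_error(self):
        cohort = simulate_cohort(CohortSpec(seed=7)).drop(columns=["alps"])
        with pytest.raises(SchemaError):
            run_group_analysis(cohort)
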