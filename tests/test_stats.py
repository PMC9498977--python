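import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from hapticube.errors import ValidationError
from hapticube.stats import (
    accuracy_bayes_factor,
    aggregate_by_participant,
    analyze,
    benjamini_hochberg,
    lda_fit,
    manova_roy,
    one_tailed_pearson,
    univariate_followup,
)


def _random_table(rng, n_per_group=8, p=2, shift=None):
    rows = []
    for gi, g in enumerate(["A", "B", "C"]):
        x = rng.normal(size=(n_per_group, p))
        if shift is not None:
            x += shift[gi]
        for row in x:
            rows.append({"group": g, **{f"v{j}": row[j] for j in range(p)}})
    return pd.DataFrame(rows)


class TestManovaRoy:
    def test_zero_between_group_scatter(self):
        base = np.array([[0.0, 1.0], [1.0, 0.0], [-1.0, -1.0], [0.5, -0.5]])
        rows = []
        for g in ["A", "B", "C"]:
            for row in base:  # identical group distributions -> identical means
                rows.append({"group": g, "v0": row[0], "v1": row[1]})
        res = manova_roy(pd.DataFrame(rows), ["v0", "v1"])
        assert res.roy == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_generalized_eigenvalue_oracle(self, rng):
        for _ in range(20):
            table = _random_table(rng)
            res = manova_roy(table, ["v0", "v1"])
            x = table[["v0", "v1"]].to_numpy()
            g = table["group"].to_numpy()
            grand = x.mean(axis=0)
            b = np.zeros((2, 2))
            w = np.zeros((2, 2))
            for lv in np.unique(g):
                xi = x[g == lv]
                d = xi.mean(axis=0) - grand
                b += len(xi) * np.outer(d, d)
                w += (xi - xi.mean(axis=0)).T @ (xi - xi.mean(axis=0))
            expected = np.max(linalg.eigvals(b, w).real)
            assert res.roy == pytest.approx(expected, abs=1e-10)

    def test_matches_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        table = _random_table(rng, shift=[(0, 0), (0.8, 0), (0, 0.8)])
        res = manova_roy(table, ["v0", "v1"])
        sm = MANOVA.from_formula("v0 + v1 ~ group", data=table)
        sm_roy = sm.mv_test().results["group"]["stat"].loc["Roy's greatest root", "Value"]
        assert res.roy == pytest.approx(float(sm_roy), rel=1e-8)

    def test_permutation_null_band(self, rng):
        # under label permutation the analytic p should be roughly uniform:
        # its rank within the permutation distribution stays in the 95% band
        table = _random_table(rng, n_per_group=10)
        observed = manova_roy(table, ["v0", "v1"]).roy
        perms = []
        g = table["group"].to_numpy().copy()
        for _ in range(400):
            rng.shuffle(g)
            t = table.copy()
            t["group"] = g
            perms.append(manova_roy(t, ["v0", "v1"]).roy)
        rank = np.mean(np.asarray(perms) >= observed)
        assert 0.01 < rank  # the observed null table is not an outlier

    def test_singular_within_matrix_names_columns(self, rng):
        table = _random_table(rng)
        table["v2"] = table["v0"] * 2.0
        with pytest.raises(ValidationError, match="v"):
            manova_roy(table, ["v0", "v1", "v2"])


class TestLda:
    def test_two_groups_single_discriminant(self, rng):
        table = _random_table(rng, shift=[(0, 0), (3, 3), (0, 0)])
        table = table[table.group != "C"]
        res = lda_fit(table, ["v0", "v1"])
        assert res.coefficients.shape[1] == 1
        assert res.proportion[0] == pytest.approx(100.0)

    def test_collinear_group_means_kill_second_discriminant(self, rng):
        # three group means on one line: all separation lives in LD1
        table = _random_table(rng, n_per_group=60, shift=[(0, 0), (2, 2), (4, 4)])
        res = lda_fit(table, ["v0", "v1"])
        assert res.eigenvalues[1] < 0.05 * res.eigenvalues[0]

    def test_roy_equals_top_lda_eigenvalue(self, rng):
        table = _random_table(rng, shift=[(0, 0), (1, 0), (0, 1)])
        roy = manova_roy(table, ["v0", "v1"]).roy
        lam = lda_fit(table, ["v0", "v1"]).eigenvalues[0]
        assert roy == pytest.approx(lam, abs=1e-10)

    def test_matches_sklearn_discriminant_direction(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        table = _random_table(rng, n_per_group=30, shift=[(0, 0), (1.5, 0.5), (0.5, 1.5)])
        res = lda_fit(table, ["v0", "v1"])
        sk = LinearDiscriminantAnalysis(solver="eigen").fit(
            table[["v0", "v1"]].to_numpy(), table["group"].to_numpy()
        )
        # directions agree up to scale/sign
        for j in range(2):
            a = res.coefficients.iloc[:, j].to_numpy()
            b = sk.scalings_[:, j]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_within_group_score_variance_is_unit(self, rng):
        table = _random_table(rng, n_per_group=40, shift=[(0, 0), (2, 0), (0, 2)])
        res = lda_fit(table, ["v0", "v1"])
        pooled = []
        for g, sub in res.scores.groupby("group", observed=True):
            pooled.append(sub[["LD1", "LD2"]].to_numpy() - sub[["LD1", "LD2"]].mean().to_numpy())
        pooled = np.vstack(pooled)
        cov = pooled.T @ pooled / (len(pooled) - 3)
        assert np.allclose(cov, np.eye(2), atol=0.05)

    def test_proportions_sum_to_100(self, rng):
        table = _random_table(rng, shift=[(0, 0), (1, 0), (0, 1)])
        res = lda_fit(table, ["v0", "v1"])
        assert res.proportion.sum() == pytest.approx(100.0, abs=1e-6)


class TestUnivariateFollowup:
    def test_bh_hand_oracle(self):
        adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone(self, rng):
        # adjusted p is a non-decreasing function of raw p (ties allowed)
        p = rng.uniform(size=12)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all()

    def test_welch_t_squared_matches_f_for_two_groups(self, rng):
        # with equal group sizes and one variable, t^2 ~ F (exact for pooled t;
        # Welch agrees closely when variances match)
        x = rng.normal(size=40)
        table = pd.DataFrame({"group": ["A"] * 20 + ["B"] * 20, "v": x})
        res = univariate_followup(table, "v")
        t = res.posthoc["t"].iloc[0]
        assert t**2 == pytest.approx(res.anova_f, rel=0.05)

    def test_power_on_separated_groups(self, rng):
        hits = 0
        for _ in range(200):
            a = rng.normal(0.0, 1.0, 30)
            b = rng.normal(1.5, 1.0, 30)
            table = pd.DataFrame({"group": ["A"] * 30 + ["B"] * 30, "v": np.r_[a, b]})
            res = univariate_followup(table, "v")
            hits += bool(res.posthoc["significant"].iloc[0])
        assert hits / 200 > 0.9

    def test_group_with_single_row_rejected(self):
        table = pd.DataFrame({"group": ["A", "A", "B"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            univariate_followup(table, "v")


class TestAccuracyBayesFactor:
    def test_identical_groups_favor_null(self, rng):
        acc = np.clip(rng.normal(0.75, 0.1, 100), 0.05, 1.0)
        groups = np.array(["A"] * 50 + ["B"] * 50)
        bf01, _ = accuracy_bayes_factor(acc, groups)
        assert bf01 > 1.0

    def test_separated_groups_favor_alternative(self, rng):
        acc = np.r_[np.clip(rng.normal(0.55, 0.05, 50), 0.05, 1), np.clip(rng.normal(0.9, 0.05, 50), 0.05, 1)]
        groups = np.array(["A"] * 50 + ["B"] * 50)
        bf01, _ = accuracy_bayes_factor(acc, groups)
        assert bf01 < 0.01

    def test_normal_data_transform_is_nearly_affine(self, rng):
        acc = np.clip(rng.normal(0.6, 0.05, 400), 0.05, 1.0)
        groups = np.array(["A"] * 200 + ["B"] * 200)
        bf01, lmb = accuracy_bayes_factor(acc, groups)
        # untransformed BIC Bayes factor as reference
        from hapticube.stats import _ols_bic

        y = acc
        d = np.column_stack([np.ones_like(y), (groups == "B").astype(float)])
        ref = np.exp((_ols_bic(y, d) - _ols_bic(y, np.ones((len(y), 1)))) / 2)
        assert bf01 == pytest.approx(ref, rel=0.05)

    def test_constant_accuracy_rejected(self):
        with pytest.raises(ValidationError):
            accuracy_bayes_factor(np.full(10, 0.8), np.array(["A"] * 5 + ["B"] * 5))


class TestPearson:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, p = one_tailed_pearson(x, -x, "negative")
        assert r == pytest.approx(-1.0)
        assert p < 1e-10

    def test_direction_matters(self, rng):
        x = np.arange(30.0)
        y = x + rng.normal(0, 2.0, 30)
        r_pos, p_pos = one_tailed_pearson(x, y, "positive")
        _, p_neg = one_tailed_pearson(x, y, "negative")
        assert r_pos > 0 and p_pos < 0.01 and p_neg > 0.9

    def test_null_correlation_distribution(self, rng):
        hits = 0
        for _ in range(300):
            x = rng.normal(size=32)
            y = rng.normal(size=32)
            r, _ = one_tailed_pearson(x, y, "negative")
            hits += abs(r) < 0.35
        assert hits / 300 > 0.9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            one_tailed_pearson(np.ones(5), np.arange(5.0), "negative")


def test_analyze_end_to_end(cohort42_metrics):
    """The orchestrator produces a coherent report on the synthetic cohort."""
    report = analyze(cohort42_metrics, unit="trial")
    assert report["manova"].p_value < 0.05  # groups are planted to differ
    assert report["lda"].proportion.sum() == pytest.approx(100.0, abs=1e-6)
    assert len(report["followups"]) == 3
    assert report["correlations"] is not None


def test_participant_aggregation_reduces_rows(cohort42_metrics):
    part = aggregate_by_participant(cohort42_metrics, ["mean_active_cells"])
    assert len(part) == 32
    assert set(part.columns) == {"participant_id", "group", "mean_active_cells"}
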