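"""Imputation, phylogenetic PCA, axis retention and the inferential models."""

import numpy as np
import pandas as pd
import pytest

from mpmlife import (
    clonality_covariate_models,
    group_entropy_tests,
    impute_missing,
    make_yule_tree,
    ordinary_pca,
    phylo_pca,
    regress_entropy_on_scores,
    retain_axes_kaiser,
    simulate_bm_traits,
    tukey_by_mode,
)
from mpmlife.mpm_core import ContractViolation
from mpmlife.multivariate import PCAResult, phylo_covariance
from mpmlife.traits import TraitMatrix

from conftest import star_tree


def matrix_from(df: pd.DataFrame) -> TraitMatrix:
    return TraitMatrix(values=df, mask=df.isna())


def random_matrix(n=40, p=5, seed=0, missing_cols=(), missing_frac=0.1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    df = pd.DataFrame(
        X, index=[f"sp{i:03d}" for i in range(n)], columns=[f"t{j}" for j in range(p)]
    )
    for col in missing_cols:
        rows = rng.choice(n, size=int(missing_frac * n), replace=False)
        df.iloc[rows, df.columns.get_loc(col)] = np.nan
    return df


class TestImputation:
    def test_complete_matrix_unchanged(self):
        df = random_matrix()
        out = impute_missing(matrix_from(df), seed=1)
        pd.testing.assert_frame_equal(out.values, df)

    def test_linear_relation_recovered(self):
        # y = 2x + noise(sd=0.01): PMM imputations must land near truth
        rng = np.random.default_rng(5)
        n = 200
        x = rng.standard_normal(n)
        y = 2 * x + rng.normal(0, 0.01, n)
        z = rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y, "z": z},
                          index=[f"sp{i}" for i in range(n)])
        truth = df["y"].copy()
        masked_rows = rng.choice(n, size=20, replace=False)
        df.iloc[masked_rows, 1] = np.nan
        out = impute_missing(matrix_from(df), n_iter=10, donors=5, seed=7)
        imputed = out.values["y"].iloc[masked_rows]
        # oracle bound: the regression prediction is essentially exact
        # (noise sd 0.01), so each donor pool is the 5 observed y values
        # nearest the truth — the error can never exceed the distance to the
        # 5th-nearest observed value (plus noise slack)
        obs = truth.drop(truth.index[masked_rows]).to_numpy()
        for i in masked_rows:
            bound = np.sort(np.abs(obs - truth.iloc[i]))[4]
            assert abs(imputed.loc[truth.index[i]] - truth.iloc[i]) <= bound + 0.05
        assert np.corrcoef(imputed, truth.iloc[masked_rows])[0, 1] > 0.99

    def test_pmm_draws_observed_donor_values(self):
        df = random_matrix(missing_cols=("t1", "t3"), seed=3)
        observed = {c: set(df[c].dropna()) for c in df.columns}
        out = impute_missing(matrix_from(df), seed=11)
        for col in ("t1", "t3"):
            filled = out.values[col][df[col].isna()]
            assert all(v in observed[col] for v in filled)

    def test_deterministic_under_seed(self):
        df = random_matrix(missing_cols=("t0",), seed=4)
        a = impute_missing(matrix_from(df), seed=5)
        b = impute_missing(matrix_from(df), seed=5)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_too_few_observed_raises(self):
        df = random_matrix(n=10, p=6)
        df.iloc[:6, 0] = np.nan
        with pytest.raises(ContractViolation):
            impute_missing(matrix_from(df), seed=0)


class TestPhyloPCA:
    def test_star_tree_equals_ordinary_pca(self):
        df = random_matrix(n=30, p=6, seed=9)
        tree = star_tree(df.index)
        tm = matrix_from(df)
        p1 = phylo_pca(tm, tree)
        p2 = ordinary_pca(tm)
        np.testing.assert_allclose(p1.eigenvalues, p2.eigenvalues, atol=1e-8)
        np.testing.assert_allclose(
            np.abs(p1.loadings.to_numpy()), np.abs(p2.loadings.to_numpy()), atol=1e-8
        )

    def test_eigenvalue_sum_equals_trace(self):
        df = random_matrix(n=25, p=5, seed=10)
        tree = make_yule_tree(25, seed=2, labels=df.index)
        p = phylo_pca(matrix_from(df), tree)
        X = df.to_numpy()
        C = phylo_covariance(tree, list(df.index))
        Cinv = np.linalg.inv(C)
        one = np.ones((25, 1))
        a = (one.T @ Cinv @ X) / (one.T @ Cinv @ one)
        R = (X - a).T @ Cinv @ (X - a) / 24
        assert p.eigenvalues.sum() == pytest.approx(np.trace(R), abs=1e-8)

    def test_bm_two_factor_subspace_recovery(self):
        # traits generated under BM with a known rank-dominant covariance:
        # the leading 2-dim loading subspace must align with the truth
        rng = np.random.default_rng(21)
        B = rng.standard_normal((6, 2)) * 2.0
        cov = B @ B.T + 0.05 * np.eye(6)
        true_sub = np.linalg.svd(B)[0][:, :2]
        angles = []
        for rep in range(20):
            tree = make_yule_tree(64, seed=100 + rep)
            traits = simulate_bm_traits(tree, cov, seed=200 + rep)
            p = phylo_pca(matrix_from(traits), tree)
            est = p.loadings.to_numpy()[:, :2]
            sv = np.linalg.svd(true_sub.T @ np.linalg.qr(est)[0])[1]
            angles.append(np.degrees(np.arccos(np.clip(sv.min(), -1, 1))))
        assert max(angles) < 15.0

    def test_unmatched_tips_error(self):
        df = random_matrix(n=10, p=3)
        tree = star_tree([f"other{i}" for i in range(10)])
        with pytest.raises(ContractViolation):
            phylo_pca(matrix_from(df), tree)

    def test_incomplete_matrix_rejected(self):
        df = random_matrix(missing_cols=("t0",))
        with pytest.raises(ContractViolation):
            phylo_pca(matrix_from(df), star_tree(df.index))


class TestKaiser:
    def make(self, eigenvalues):
        k = len(eigenvalues)
        return PCAResult(
            loadings=pd.DataFrame(np.eye(k)),
            scores=pd.DataFrame(np.zeros((2, k))),
            eigenvalues=np.array(eigenvalues, dtype=float),
            pct_var=np.zeros(k),
        )

    def test_strictly_greater_than_one(self):
        assert retain_axes_kaiser(self.make([1.5, 1.2, 0.8, 0.1])) == [0, 1]
        assert retain_axes_kaiser(self.make([0.9, 0.5])) == []
        assert retain_axes_kaiser(self.make([1.0, 0.5])) == []  # boundary


class TestEntropyRegression:
    def scores(self, n=60, seed=14):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.standard_normal((n, 2)),
            index=[f"sp{i}" for i in range(n)],
            columns=["PC1", "PC2"],
        )

    def test_exact_linear_recovery(self):
        sc = self.scores()
        H = 1.0 + 0.1 * sc["PC1"]
        res = regress_entropy_on_scores(H, sc)
        est = res.table.set_index("term")["estimate"]
        assert est["PC1"] == pytest.approx(0.1, abs=1e-10)
        assert est["PC2"] == pytest.approx(0.0, abs=1e-10)
        assert est["PC1:PC2"] == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_on_orthogonal_design(self):
        # simple-regression coefficients from scratch on centered predictors
        sc = self.scores(seed=15)
        sc = sc - sc.mean()
        rng = np.random.default_rng(16)
        H = pd.Series(
            1 + 0.2 * sc["PC1"] - 0.1 * sc["PC2"] + rng.normal(0, 0.05, len(sc)),
            index=sc.index,
        )
        res = regress_entropy_on_scores(H, sc)
        est = res.table.set_index("term")["estimate"]
        X = np.column_stack(
            [np.ones(len(sc)), sc["PC1"], sc["PC2"], sc["PC1"] * sc["PC2"]]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ H.to_numpy())
        assert est["PC1"] == pytest.approx(beta[1], abs=1e-10)
        assert est["PC2"] == pytest.approx(beta[2], abs=1e-10)

    def test_coverage_simulation(self):
        # seeded coverage: estimates within 2 SE of the truth in >= 95% of
        # replicates (per coefficient)
        hits = tot = 0
        rng = np.random.default_rng(0)
        for _rep in range(100):
            sc = pd.DataFrame(
                rng.standard_normal((120, 2)), columns=["PC1", "PC2"],
                index=[f"sp{i}" for i in range(120)],
            )
            H = pd.Series(
                1 + 0.06 * sc["PC1"] + 0.07 * sc["PC2"] + rng.normal(0, 0.2, 120),
                index=sc.index,
            )
            res = regress_entropy_on_scores(H, sc).table.set_index("term")
            for term, beta in (("PC1", 0.06), ("PC2", 0.07)):
                tot += 1
                hits += abs(res.loc[term, "estimate"] - beta) <= 2 * res.loc[term, "SE"]
        assert hits / tot >= 0.95

    def test_constant_column_errors(self):
        sc = self.scores()
        sc["PC2"] = 1.0
        H = 1 + 0.1 * sc["PC1"]
        with pytest.raises((ContractViolation, Exception)):
            res = regress_entropy_on_scores(H, sc)
            if not np.isfinite(res.table["SE"]).all():
                raise ContractViolation("degenerate design")

    def test_subset_too_small(self):
        sc = self.scores(n=12)
        H = pd.Series(np.ones(12), index=sc.index)
        mask = pd.Series([True] * 5 + [False] * 7, index=sc.index)
        with pytest.raises(ContractViolation):
            regress_entropy_on_scores(H, sc, subset=mask)


class TestClonalityModels:
    def test_null_clonality_coefficient_near_zero(self):
        rng = np.random.default_rng(31)
        n = 120
        sc = pd.DataFrame(rng.standard_normal((n, 2)), columns=["PC1", "PC2"],
                          index=[f"sp{i}" for i in range(n)])
        H = pd.Series(1 + 0.05 * sc["PC1"] + rng.normal(0, 0.1, n), index=sc.index)
        clonal = pd.Series(rng.integers(0, 2, n).astype(float), index=sc.index)
        res = clonality_covariate_models(H, sc, clonal)
        row = res["A"].table.set_index("term")
        assert abs(row.loc["clonal", "estimate"]) <= 2 * row.loc["clonal", "SE"]

    def test_model_B_recovers_both_terms(self):
        rng = np.random.default_rng(32)
        n = 150
        sc = pd.DataFrame(rng.standard_normal((n, 2)), columns=["PC1", "PC2"],
                          index=[f"sp{i}" for i in range(n)])
        clonal = pd.Series((np.arange(n) % 2).astype(float), index=sc.index)
        H = pd.Series(
            1 + 0.05 * sc["PC1"] + 0.2 * clonal + rng.normal(0, 0.05, n),
            index=sc.index,
        )
        row = res = clonality_covariate_models(H, sc, clonal)["B"].table.set_index("term")
        assert row.loc["PC1", "estimate"] == pytest.approx(0.05, abs=2 * row.loc["PC1", "SE"])
        assert row.loc["clonal", "estimate"] == pytest.approx(0.2, abs=2 * row.loc["clonal", "SE"])

    def test_term_names_match_model_spec(self):
        rng = np.random.default_rng(33)
        n = 40
        sc = pd.DataFrame(rng.standard_normal((n, 2)), columns=["PC1", "PC2"],
                          index=[f"sp{i}" for i in range(n)])
        H = pd.Series(rng.normal(1, 0.1, n), index=sc.index)
        clonal = pd.Series((np.arange(n) % 2).astype(float), index=sc.index)
        res = clonality_covariate_models(H, sc, clonal)
        assert set(res["A"].table["term"]) == {
            "Intercept", "PC1", "PC2", "clonal", "PC1:clonal", "PC2:clonal"
        }
        assert set(res["C"].table["term"]) == {"Intercept", "PC2", "clonal", "PC2:clonal"}

    def test_single_class_clonality_errors(self):
        rng = np.random.default_rng(34)
        n = 30
        sc = pd.DataFrame(rng.standard_normal((n, 2)), columns=["PC1", "PC2"],
                          index=[f"sp{i}" for i in range(n)])
        H = pd.Series(np.ones(n), index=sc.index)
        with pytest.raises(ContractViolation):
            clonality_covariate_models(H, sc, pd.Series(np.ones(n), index=sc.index))


class TestGroupTests:
    def test_all_equal_to_threshold(self):
        H = pd.Series([1.0] * 5 + [1.0] * 4, index=[f"s{i}" for i in range(9)])
        modes = pd.Series(["a"] * 5 + ["b"] * 4, index=H.index)
        out = group_entropy_tests(H, modes)
        assert (out["t"] == 0).all()
        assert (out["P"] == 1).all()

    def test_hand_computed_t_statistic(self):
        H = pd.Series([0.5, 0.7, 1.0, 1.0], index=list("abcd"))
        modes = pd.Series(["g1", "g1", "g2", "g2"], index=H.index)
        row = group_entropy_tests(H, modes).set_index("mode").loc["g1"]
        assert row["mean"] == pytest.approx(0.6)
        assert row["SE"] == pytest.approx(0.1)
        assert row["t"] == pytest.approx(-4.0)
        assert row["df"] == 1

    def test_group_of_one_errors(self):
        H = pd.Series([0.5, 0.7, 0.9], index=list("abc"))
        modes = pd.Series(["g1", "g1", "g2"], index=H.index)
        with pytest.raises(ContractViolation):
            group_entropy_tests(H, modes)


class TestTukey:
    def test_null_groups_share_a_letter(self):
        rng = np.random.default_rng(41)
        shared = 0
        reps = 40
        for _ in range(reps):
            vals = pd.Series(rng.normal(0, 1, 60), index=[f"s{i}" for i in range(60)])
            modes = pd.Series(
                ["a"] * 20 + ["b"] * 20 + ["c"] * 20, index=vals.index
            )
            _, letters = tukey_by_mode(vals, modes)
            common = set(letters["a"]) & set(letters["b"]) & set(letters["c"])
            shared += bool(common)
        assert shared / reps >= 0.9

    def test_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(42)
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                               rng.normal(5, 1, 20)])
        s = pd.Series(vals, index=[f"s{i}" for i in range(60)])
        modes = pd.Series(["a"] * 20 + ["b"] * 20 + ["c"] * 20, index=s.index)
        _, letters = tukey_by_mode(s, modes)
        assert set(letters["c"]).isdisjoint(set(letters["a"]) | set(letters["b"]))
        assert set(letters["a"]) & set(letters["b"])

    def test_identical_groups_zero_difference(self):
        base = np.array([0.1, 0.5, 0.9, 1.3])
        s = pd.Series(np.concatenate([base, base]), index=[f"s{i}" for i in range(8)])
        modes = pd.Series(["a"] * 4 + ["b"] * 4, index=s.index)
        table, letters = tukey_by_mode(s, modes)
        assert float(table["meandiff"].iloc[0]) == pytest.approx(0.0)
        assert letters["a"] == letters["b"]

    def test_undersized_group_errors(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        modes = pd.Series(["a", "a", "b"], index=s.index)
        with pytest.raises(ContractViolation):
            tukey_by_mode(s, modes)
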