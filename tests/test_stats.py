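"""Trial statistics: model selection, compact letters, correlations,
PCA with spectator variables, and the stepwise R² decomposition —
each checked against an independent oracle where one exists."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from maizedig.stats import (
    StepwiseModel,
    contribution_shares,
    count_distinct_letters,
    fit_trait_anova,
    pca_illustrative,
    pearson_matrix,
    shapiro_check,
    stepwise_decompose,
    tukey_cld,
)


# ----------------------------------------------------------------- helpers


def balanced_table(rng, H=4, C=2, B=3, h_sd=0.0, c_eff=0.0, hc_sd=0.0, noise=1.0,
                   col_eff=0.0):
    h = rng.normal(0, h_sd, H) if h_sd else np.zeros(H)
    hc = rng.normal(0, hc_sd, (H, C)) if hc_sd else np.zeros((H, C))
    rows = []
    for i in range(H):
        for j in range(C):
            for b in range(B):
                rows.append(
                    {
                        "hybrid": f"H{i}",
                        "condition": f"C{j}",
                        "row": i + 1,
                        "col": j * B + b + 1,
                        "y": h[i] + c_eff * j + hc[i, j]
                        + col_eff * (j * B + b + 1)
                        + rng.normal(0, noise),
                    }
                )
    return pd.DataFrame(rows)


def orthonormal_design(rng, n, p):
    """Exactly orthonormal, zero-mean predictor columns."""
    X = rng.normal(size=(n, p + 1))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    return Q[:, :p]


def oracle_r2(y, cols):
    """Independent R² via normal equations on explicit residual sums."""
    n = len(y)
    A = np.column_stack([np.ones(n)] + list(cols)) if cols else np.ones((n, 1))
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    rss = float(((y - A @ beta) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 100.0 * (1 - rss / tss)


# ------------------------------------------------------------------ ANOVA


class TestAnova:
    def test_planted_interaction_retained(self, rng):
        df = balanced_table(rng, h_sd=1.0, c_eff=2.0, hc_sd=2.0, noise=0.3)
        res = fit_trait_anova(df, "y")
        assert res.model == "interaction"
        assert res.interaction_p < 0.05

    def test_additive_chosen_without_interaction(self, rng):
        df = balanced_table(rng, h_sd=2.0, c_eff=2.0, hc_sd=0.0, noise=0.5)
        res = fit_trait_anova(df, "y")
        assert res.model == "additive"
        assert "C(hybrid):C(condition)" not in res.table.index

    def test_column_gradient_screened_in(self, rng):
        df = balanced_table(rng, h_sd=0.5, c_eff=1.0, noise=0.3, col_eff=2.0)
        res = fit_trait_anova(df, "y")
        assert res.include_col

    def test_zero_residual_variance_errors(self):
        rows = [
            {"hybrid": h, "condition": c, "y": float(i + 2 * j)}
            for i, h in enumerate("AB")
            for j, c in enumerate("XY")
            for _ in range(3)
        ]
        with pytest.raises(ValueError):
            fit_trait_anova(pd.DataFrame(rows), "y")

    def test_single_condition_rejected(self, rng):
        df = balanced_table(rng, C=1)
        with pytest.raises(ValueError):
            fit_trait_anova(df, "y")


# ----------------------------------------------------------- Tukey letters


class TestCompactLetters:
    def test_identical_groups_share_one_letter(self, rng):
        df = pd.DataFrame(
            {
                "condition": np.repeat(list("ABCD"), 8),
                "y": rng.normal(0, 0.1, 32),
            }
        )
        cld = tukey_cld(df, "y")
        assert count_distinct_letters(cld) == 1

    def test_two_separated_clusters_get_two_letters(self, rng):
        df = pd.DataFrame(
            {
                "condition": np.repeat(list("ABCD"), 6),
                "y": np.concatenate(
                    [rng.normal(0, 1, 12), rng.normal(100, 1, 12)]
                ),
            }
        )
        cld = tukey_cld(df, "y")
        assert count_distinct_letters(cld) == 2
        assert set(cld.letters["A"]) == set(cld.letters["B"])
        assert set(cld.letters["C"]) == set(cld.letters["D"])
        assert not set(cld.letters["A"]) & set(cld.letters["C"])

    def test_letters_match_pairwise_significance_exhaustively(self, rng):
        """Letter sharing must mirror the Tukey significance matrix exactly."""
        for _ in range(30):
            k = int(rng.integers(2, 9))
            spread = rng.uniform(0.3, 3.0)
            means = rng.normal(0, spread, k)
            df = pd.DataFrame(
                {
                    "condition": np.repeat([f"g{i}" for i in range(k)], 6),
                    "y": np.concatenate([rng.normal(m, 1.0, 6) for m in means]),
                }
            )
            cld = tukey_cld(df, "y")
            # oracle: studentized-range p-values computed from scratch
            groups = [df.loc[df.condition == g, "y"].to_numpy() for g in cld.letters]
            names = list(cld.letters)
            nper = 6
            mse = np.mean([g.var(ddof=1) for g in groups])
            df_resid = k * (nper - 1)
            for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
                q = abs(groups[i].mean() - groups[j].mean()) / np.sqrt(mse / nper)
                p = sps.studentized_range.sf(q, k, df_resid)
                share = bool(set(cld.letters[a]) & set(cld.letters[b]))
                assert share == (p >= 0.05), (a, b, p)

    def test_single_group_rejected(self):
        df = pd.DataFrame({"condition": ["A"] * 5, "y": range(5)})
        with pytest.raises(ValueError):
            tukey_cld(df, "y")

    def test_distinct_letter_counts_from_printed_displays(self):
        assert count_distinct_letters(["ab", "c", "b", "a", "cd", "de", "e", "f"]) == 6
        assert count_distinct_letters(["a", "a", "a", "a", "b", "b", "b", "c"]) == 3
        assert count_distinct_letters({"only": "a"}) == 1


# ---------------------------------------------------------------- Pearson


class TestPearson:
    def test_exact_linear_relation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        r, p = pearson_matrix(df, ["x", "y"])
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert p.loc["x", "y"] < 1e-6

    def test_symmetric_unit_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        r, _ = pearson_matrix(df, list("abc"))
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_independent_normals_mostly_uncorrelated(self, rng):
        hits = 0
        for _ in range(40):
            df = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
            r, _ = pearson_matrix(df, ["a", "b"])
            hits += abs(r.loc["a", "b"]) < 0.1
        assert hits >= 38

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        with pytest.warns(UserWarning, match="constant"):
            r, _ = pearson_matrix(df, ["x", "y"])
        assert np.isnan(r.loc["x", "y"])

    def test_pairwise_complete_handling(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        df.loc[:5, "a"] = np.nan
        r, _ = pearson_matrix(df, ["a", "b"])
        sub = df.dropna()
        assert r.loc["a", "b"] == pytest.approx(np.corrcoef(sub.a, sub.b)[0, 1])


# -------------------------------------------------------------------- PCA


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_one_axis(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_illustrative(df, ["a", "b"])
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_variance_conservation(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 6)), columns=list("abcdef"))
        res = pca_illustrative(df, list("abcdef"))
        assert res.pct_variance.sum() == pytest.approx(100.0)
        assert res.eigenvalues.sum() == pytest.approx(6.0)
        assert (np.diff(res.eigenvalues) <= 1e-10).all()

    def test_eigenvalues_match_sklearn(self, rng):
        from sklearn.decomposition import PCA

        df = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
        res = pca_illustrative(df, list("abcde"))
        Z = (df - df.mean()) / df.std(ddof=1)
        sk = PCA().fit(Z.to_numpy())
        # ddof=1 standardisation makes sklearn's explained_variance_ the
        # eigenvalues of the correlation matrix
        assert np.allclose(res.eigenvalues, sk.explained_variance_, rtol=1e-8)

    def test_illustrative_duplicate_matches_loading(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        df["ghost"] = df["a"]
        res = pca_illustrative(df, list("abc"), illustrative_vars=["ghost"])
        assert np.allclose(
            res.illustrative.loc["ghost"], res.loadings.loc["a"], atol=1e-8
        )

    def test_sign_convention_dominant_variable_positive(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        res = pca_illustrative(df, list("abcd"))
        for pc in res.loadings.columns:
            dominant = res.loadings[pc].abs().idxmax()
            assert res.loadings.loc[dominant, pc] > 0

    def test_zero_variance_active_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="zero-variance"):
            pca_illustrative(df, ["a", "b"])


# ---------------------------------------------------------------- stepwise


class TestStepwise:
    def test_small_second_increment_is_cut(self, rng):
        Q = orthonormal_design(rng, 200, 3)
        y = np.sqrt(60) * Q[:, 0] + np.sqrt(3) * Q[:, 1] + np.sqrt(37) * Q[:, 2]
        df = pd.DataFrame({"y": y, "x1": Q[:, 0], "x2": Q[:, 1]})
        m = stepwise_decompose(df, response="y", candidates=["x1", "x2"])
        assert m.variables == ["x1"]
        assert m.increments[0] == pytest.approx(60.0, abs=1e-8)

    def test_orthogonal_increments_sum_to_r2(self, rng):
        Q = orthonormal_design(rng, 150, 3)
        y = np.sqrt(50) * Q[:, 0] + np.sqrt(30) * Q[:, 1] + np.sqrt(20) * Q[:, 2]
        df = pd.DataFrame({"y": y, "a": Q[:, 0], "b": Q[:, 1]})
        m = stepwise_decompose(df, response="y", candidates=["a", "b"])
        assert m.variables == ["a", "b"]
        assert m.increments == pytest.approx([50.0, 30.0], abs=1e-8)
        assert sum(m.increments) == pytest.approx(m.r_squared, abs=1e-8)

    def test_constant_response_rejected(self):
        df = pd.DataFrame({"y": [1.0] * 10, "x": range(10)})
        with pytest.raises(ValueError, match="constant"):
            stepwise_decompose(df, response="y", candidates=["x"])

    def test_no_qualifying_candidate_returns_empty_model(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=100), "x": rng.normal(size=100)})
        m = stepwise_decompose(df, response="y", candidates=["x"], delta_r2=50.0)
        assert m.variables == []
        assert m.warning is not None
        assert m.r_squared == 0.0

    def test_path_matches_independent_greedy_oracle(self, rng):
        for _ in range(10):
            n, p = 80, 6
            X = rng.normal(size=(n, p))
            beta = np.array([3.0, 2.0, 1.5, 0, 0, 0])
            y = X @ beta + rng.normal(0, 1.5, n)
            names = [f"v{i}" for i in range(p)]
            df = pd.DataFrame(X, columns=names)
            df["y"] = y
            m = stepwise_decompose(df, response="y", candidates=names)

            # oracle: greedy forward search with explicit RSS arithmetic
            entered, remaining, path = [], sorted(names), []
            r2_prev = 0.0
            rmse_prev = float(np.sqrt(((y - y.mean()) ** 2).mean()))
            while remaining:
                scored = []
                for c in remaining:
                    r2 = oracle_r2(y, [df[v].to_numpy() for v in entered + [c]])
                    rmse = np.sqrt(((y - y.mean()) ** 2).sum() * (1 - r2 / 100) / n)
                    scored.append((-round(r2, 10), round(rmse, 12), c, r2, rmse))
                scored.sort()
                _, _, c, r2, rmse = scored[0]
                if r2 - r2_prev < 4.0 or (rmse_prev - rmse) / rmse_prev < 0.01:
                    break
                entered.append(c)
                remaining.remove(c)
                path.append(r2 - r2_prev)
                r2_prev, rmse_prev = r2, rmse

            assert m.variables == entered
            assert m.increments == pytest.approx(path, abs=1e-7)

    def test_selected_set_is_best_subset_on_orthonormal_designs(self, rng):
        """On orthonormal candidates greedy selection must equal the
        exhaustive best subset of the same size."""
        for _ in range(5):
            n, p = 120, 8
            Q = orthonormal_design(rng, n, p + 1)
            w = np.array([45, 25, 12, 0, 0, 0, 0, 0], dtype=float)
            y = sum(np.sqrt(wi) * Q[:, i] for i, wi in enumerate(w))
            y = y + np.sqrt(100 - w.sum()) * Q[:, p]
            names = [f"v{i}" for i in range(p)]
            df = pd.DataFrame(Q[:, :p], columns=names)
            df["y"] = y
            m = stepwise_decompose(df, response="y", candidates=names)
            k = len(m.variables)
            best_r2, best_set = -1.0, None
            for subset in itertools.combinations(names, k):
                r2 = oracle_r2(y, [df[v].to_numpy() for v in subset])
                if r2 > best_r2:
                    best_r2, best_set = r2, set(subset)
            assert set(m.variables) == best_set
            assert m.r_squared == pytest.approx(best_r2, abs=1e-7)

    def test_rmse_path_nonincreasing(self, rng):
        X = rng.normal(size=(60, 5))
        y = X[:, 0] * 2 + X[:, 1] + rng.normal(0, 0.5, 60)
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(5)])
        df["y"] = y
        m = stepwise_decompose(df, response="y", candidates=list(df.columns[:-1]))
        assert (np.diff(m.rmse_path) <= 0).all()


class TestContributionShares:
    def _model(self, variables, increments):
        return StepwiseModel(
            response="cw",
            variables=variables,
            increments=increments,
            rmse_path=[1.0] * (len(variables) + 1),
            r_squared=sum(increments),
            coefficients={v: 0.0 for v in variables},
            intercept=0.0,
        )

    def test_shares_follow_published_humid_pattern(self):
        # four biochemical traits at 89 points and one histological at 5
        m = self._model(["pcest", "bo4", "feest", "spc", "blue_dig"], [67.0, 12.0, 6.0, 4.0, 5.0])
        shares = contribution_shares(
            m,
            {
                "pcest": "biochemistry",
                "bo4": "biochemistry",
                "feest": "biochemistry",
                "spc": "biochemistry",
                "blue_dig": "histology",
            },
        )
        assert shares["biochemistry"] == pytest.approx(89.0)
        assert shares["histology"] == pytest.approx(5.0)
        assert sum(shares.values()) == pytest.approx(m.r_squared)

    def test_single_variable_takes_all(self):
        m = self._model(["x"], [66.0])
        assert contribution_shares(m, {"x": "histology"}) == {"histology": 66.0}

    def test_shares_sum_to_r2_on_random_models(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 6))
            inc = rng.uniform(4, 30, k).tolist()
            vars_ = [f"v{i}" for i in range(k)]
            cats = {v: rng.choice(["biochemistry", "histology"]) for v in vars_}
            m = self._model(vars_, inc)
            assert sum(contribution_shares(m, cats).values()) == pytest.approx(m.r_squared)

    def test_uncategorized_variable_rejected(self):
        m = self._model(["x"], [10.0])
        with pytest.raises(KeyError):
            contribution_shares(m, {})


class TestShapiro:
    def test_normal_sample_p_uniformish(self, rng):
        ps = [shapiro_check(rng.normal(size=100))[1] for _ in range(200)]
        assert 0.4 < np.mean(ps) < 0.6

    def test_skewed_sample_rejected_with_power(self, rng):
        hits = sum(shapiro_check(rng.exponential(size=100))[1] < 0.05 for _ in range(30))
        assert hits >= 28

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            shapiro_check([3.0] * 10)

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_check([1.0, 2.0])
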