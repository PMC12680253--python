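"""Multi-environment trial statistics.

* two-way ANOVA (hybrid × condition) with interaction-model selection
  by F test and optional row/column field-position covariates,
* Tukey HSD condition comparisons rendered as a compact letter display,
* Pearson correlation matrices with p-values,
* correlation PCA with illustrative (spectator) variable projection,
* forward-stepwise decomposition of cell-wall digestibility into
  per-variable R² increments, with biochemistry vs histology shares.

The stepwise decomposition is the analytical core: at each step the
candidate maximising R² enters only if it adds at least ``delta_r2``
percentage points of R² *and* lowers the RMSE by at least a relative
``rmse_eps``; per-entry increments sum exactly to the final model R²,
and summing increments by trait category splits the explained variance
into a biochemical and a histological share.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaResult",
    "CompactLetters",
    "PCAResult",
    "StepwiseModel",
    "fit_trait_anova",
    "tukey_cld",
    "count_distinct_letters",
    "pearson_matrix",
    "pca_illustrative",
    "stepwise_decompose",
    "contribution_shares",
    "shapiro_check",
]


# ---------------------------------------------------------------- ANOVA


@dataclass
class AnovaResult:
    trait: str
    model: str  # "interaction" | "additive"
    table: pd.DataFrame  # statsmodels anova_lm output of the chosen model
    interaction_p: float
    include_row: bool
    include_col: bool
    alpha: float


def _anova_formula(interaction: bool, row: bool, col: bool) -> str:
    base = "y ~ C(hybrid) * C(condition)" if interaction else "y ~ C(hybrid) + C(condition)"
    if col:
        base += " + C(col)"
    if row:
        base += " + C(row)"
    return base


def fit_trait_anova(
    table: pd.DataFrame, trait: str, alpha: float = 0.05
) -> AnovaResult:
    """Fit the trial ANOVA for one trait and choose the model.

    The full model is hybrid + condition + hybrid:condition with field
    row/column covariates screened on the full model (kept only when
    their F-test p < alpha).  The interaction is then tested by its F
    test; when non-significant the additive model is refitted and
    reported.  Degenerate designs (no residual df, zero residual
    variance) raise rather than returning silent NaNs.
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in table")
    df = table[[c for c in ("hybrid", "condition", "row", "col") if c in table.columns]].copy()
    df["y"] = pd.to_numeric(table[trait], errors="coerce")
    df = df.dropna(subset=["y"])
    if df["hybrid"].nunique() < 2 or df["condition"].nunique() < 2:
        raise ValueError("need at least 2 hybrids and 2 conditions")

    have_row = "row" in df.columns and df["row"].nunique() > 1
    have_col = "col" in df.columns and df["col"].nunique() > 1

    def _fit(interaction, row, col):
        fit = smf.ols(_anova_formula(interaction, row, col), data=df).fit()
        if fit.df_resid <= 0:
            raise ValueError("design leaves no residual degrees of freedom")
        if fit.ssr <= 1e-12 and fit.centered_tss > 0:
            raise ValueError("zero residual variance: F tests undefined")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = sm.stats.anova_lm(fit, typ=2)
        return fit, tab

    # screening on the full (interaction + covariates) model
    include_row = include_col = False
    if have_row or have_col:
        _, full_tab = _fit(True, have_row, have_col)
        if have_row and "C(row)" in full_tab.index:
            include_row = bool(full_tab.loc["C(row)", "PR(>F)"] < alpha)
        if have_col and "C(col)" in full_tab.index:
            include_col = bool(full_tab.loc["C(col)", "PR(>F)"] < alpha)

    _, inter_tab = _fit(True, include_row, include_col)
    p_int = float(inter_tab.loc["C(hybrid):C(condition)", "PR(>F)"])
    if np.isnan(p_int):
        raise ValueError("interaction F test undefined for this design")

    if p_int < alpha:
        chosen, tab = "interaction", inter_tab
    else:
        chosen = "additive"
        _, tab = _fit(False, include_row, include_col)

    return AnovaResult(
        trait=trait,
        model=chosen,
        table=tab,
        interaction_p=p_int,
        include_row=include_row,
        include_col=include_col,
        alpha=alpha,
    )


# --------------------------------------------------- Tukey compact letters


@dataclass
class CompactLetters:
    letters: dict[str, str]  # group -> letter string, groups in mean order
    alpha: float
    means: dict[str, float]
    pvalues: pd.DataFrame  # symmetric pairwise Tukey p-value matrix


def _insert_absorb(groups: list[str], significant) -> list[set[str]]:
    """Piepho-style insert-and-absorb: columns of mutually NS groups."""
    cols: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if not significant(a, b):
            continue
        for col in [c for c in cols if a in c and b in c]:
            cols.remove(col)
            cols.append(col - {a})
            cols.append(col - {b})
        # absorb columns that became subsets of others
        cols = [c for c in cols if not any(c < d for d in cols)]
        # deduplicate
        uniq = []
        for c in cols:
            if c not in uniq:
                uniq.append(c)
        cols = uniq
    return cols


def tukey_cld(
    table: pd.DataFrame,
    trait: str,
    by: str = "condition",
    alpha: float = 0.05,
) -> CompactLetters:
    """Tukey HSD over the *by* groups with a compact letter display.

    Letters satisfy exactly: two groups share at least one letter iff
    their pairwise Tukey test is non-significant at *alpha*.  Letters
    are ordered with 'a' on the highest-mean group.
    """
    df = table[[by]].copy()
    df["y"] = pd.to_numeric(table[trait], errors="coerce")
    df = df.dropna(subset=["y"])
    groups = df.groupby(by)["y"]
    if groups.ngroups < 2:
        raise ValueError("need at least 2 groups for Tukey comparisons")
    means = groups.mean()
    order = list(means.sort_values(ascending=False).index)

    res = pairwise_tukeyhsd(df["y"].to_numpy(), df[by].astype(str).to_numpy(), alpha=alpha)
    names = [str(g) for g in res.groupsunique]
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (i, j), p in zip(itertools.combinations(range(len(names)), 2), res.pvalues):
        pmat.iloc[i, j] = pmat.iloc[j, i] = p

    def significant(a, b):
        return pmat.loc[str(a), str(b)] < alpha

    cols = _insert_absorb([str(g) for g in order], significant)
    # stable letter order: sort columns by the rank of their best group
    rank = {str(g): k for k, g in enumerate(order)}
    cols.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {str(g): "" for g in order}
    for k, col in enumerate(cols):
        for g in order:
            if str(g) in col:
                letters[str(g)] += alphabet[k % 26]
    return CompactLetters(
        letters=letters,
        alpha=alpha,
        means={str(g): float(means[g]) for g in order},
        pvalues=pmat,
    )


def count_distinct_letters(letters) -> int:
    """Number of distinct letters used across all groups.

    Accepts a :class:`CompactLetters` or any mapping/iterable of letter
    strings (so printed letter superscripts can be counted directly).
    """
    if isinstance(letters, CompactLetters):
        values = letters.letters.values()
    elif isinstance(letters, dict):
        values = letters.values()
    else:
        values = letters
    chars = set()
    for s in values:
        chars.update(s)
    if not chars:
        raise ValueError("empty letter display")
    return len(chars)


# -------------------------------------------------------------- Pearson


def pearson_matrix(
    table: pd.DataFrame, traits: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r and two-sided p matrices.

    Constant columns (undefined r) are flagged with NaN and a warning,
    never silently zeroed.
    """
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for a, b in itertools.combinations(traits, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete observations for ({a}, {b})")
        if sub[a].nunique() == 1 or sub[b].nunique() == 1:
            warnings.warn(f"constant column in pair ({a}, {b}): r undefined")
            rv, pv = np.nan, np.nan
        else:
            rv, pv = sps.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    return r, p


# ------------------------------------------------------------------ PCA


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # nonincreasing; sums to #active vars
    pct_variance: np.ndarray  # sums to 100 over all dims
    loadings: pd.DataFrame  # active var x PC correlation loadings
    illustrative: pd.DataFrame  # illustrative var x PC correlations
    scores: pd.DataFrame  # observation x PC


def pca_illustrative(
    table: pd.DataFrame,
    active_vars: list[str],
    illustrative_vars: list[str] = (),
    n_components: int = 6,
) -> PCAResult:
    """Correlation PCA with illustrative-variable projection.

    Active variables are standardised and the correlation matrix
    eigendecomposed; illustrative (spectator) variables do not shape
    the axes — they are projected afterwards as their correlation with
    each PC score.  Signs are fixed so each PC's largest-|loading|
    active variable loads positively.
    """
    X = table[list(active_vars)].dropna()
    if len(X) < 2:
        raise ValueError("need at least 2 complete observations")
    sds = X.std(ddof=1)
    if (sds == 0).any():
        raise ValueError(f"zero-variance active variables: {list(sds[sds == 0].index)}")
    Z = (X - X.mean()) / sds
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    k = min(n_components, len(active_vars))
    scores = Z.to_numpy() @ eigvec
    loadings = eigvec * np.sqrt(eigval)  # = corr(var, PC) in correlation PCA
    # sign convention: dominant active variable positive on each axis
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            eigvec[:, j] *= -1
            scores[:, j] *= -1

    pcs = [f"PC{j + 1}" for j in range(k)]
    loadings_df = pd.DataFrame(loadings[:, :k], index=list(active_vars), columns=pcs)
    scores_df = pd.DataFrame(scores[:, :k], index=X.index, columns=pcs)

    illus_rows = {}
    for v in illustrative_vars:
        col = pd.to_numeric(table.loc[X.index, v], errors="coerce")
        ok = col.notna()
        illus_rows[v] = [
            float(np.corrcoef(col[ok], scores_df[pc][ok])[0, 1]) if ok.sum() >= 3 else np.nan
            for pc in pcs
        ]
    illus_df = pd.DataFrame.from_dict(illus_rows, orient="index", columns=pcs)

    return PCAResult(
        eigenvalues=eigval,
        pct_variance=eigval / eigval.sum() * 100.0,
        loadings=loadings_df,
        illustrative=illus_df,
        scores=scores_df,
    )


# -------------------------------------------------------------- stepwise


@dataclass
class StepwiseModel:
    response: str
    variables: list[str]  # in entry order
    increments: list[float]  # R² percentage points per entry
    rmse_path: list[float]  # RMSE after each entry (index 0 = null model)
    r_squared: float  # final model R², percent
    coefficients: dict[str, float]
    intercept: float
    category_shares: dict[str, float] = field(default_factory=dict)
    warning: str | None = None

    def summary_frame(self, category_map: dict[str, str] | None = None) -> pd.DataFrame:
        """Step table: variable, category, increment, cumulative R², RMSE, coefficient."""
        rows = []
        cum = 0.0
        for k, v in enumerate(self.variables):
            cum += self.increments[k]
            rows.append(
                {
                    "step": k + 1,
                    "variable": v,
                    "category": (category_map or {}).get(v, ""),
                    "increment_r2": self.increments[k],
                    "cum_r2": cum,
                    "rmse": self.rmse_path[k + 1],
                    "coefficient": self.coefficients[v],
                }
            )
        return pd.DataFrame(rows)


def _ols_r2_rmse(y: np.ndarray, X: np.ndarray) -> tuple[float, float, np.ndarray]:
    """R² (percent) and RMSE of an OLS fit with intercept."""
    n = len(y)
    A = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 100.0 * (1.0 - rss / tss)
    return r2, float(np.sqrt(rss / n)), beta


def stepwise_decompose(
    data: pd.DataFrame,
    response: str = "cw_digestibility",
    candidates: list[str] | None = None,
    category_map: dict[str, str] | None = None,
    delta_r2: float = 4.0,
    rmse_eps: float = 0.01,
) -> StepwiseModel:
    """Forward-stepwise R² decomposition of a response, per environment.

    At each step the remaining candidate maximising model R² enters if
    it (1) raises R² by at least *delta_r2* percentage points and
    (2) lowers the RMSE by at least a relative *rmse_eps*.  Ties on R²
    break by lower RMSE, then lexicographic name.  Increments sum
    exactly to the final R² and the RMSE path is nonincreasing by
    construction.  If no candidate qualifies at step 1 an empty model
    with a warning is returned (not an error).
    """
    if candidates is None:
        candidates = [c for c in data.columns if c != response]
    sub = data[[response] + list(candidates)].dropna()
    y = sub[response].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("too few complete observations")
    if np.ptp(y) == 0:
        raise ValueError("response is constant: decomposition undefined")

    entered: list[str] = []
    increments: list[float] = []
    r2_prev = 0.0
    rmse_prev = float(np.sqrt(((y - y.mean()) ** 2).mean()))
    rmse_path = [rmse_prev]
    remaining = sorted(candidates)
    warning = None

    while remaining and len(entered) + 2 < len(y):
        best = None  # (r2, rmse, name)
        for c in remaining:
            X = sub[entered + [c]].to_numpy(dtype=float)
            r2, rmse, _ = _ols_r2_rmse(y, X)
            key = (-round(r2, 10), round(rmse, 12), c)
            if best is None or key < best[0]:
                best = (key, c, r2, rmse)
        _, name, r2, rmse = best
        gain = r2 - r2_prev
        rmse_drop = (rmse_prev - rmse) / rmse_prev if rmse_prev > 0 else 0.0
        if gain < delta_r2 or rmse_drop < rmse_eps:
            if not entered:
                warning = "no candidate met the entry cutoff at step 1"
            break
        entered.append(name)
        remaining.remove(name)
        increments.append(gain)
        r2_prev, rmse_prev = r2, rmse
        rmse_path.append(rmse)

    if entered:
        _, _, beta = _ols_r2_rmse(y, sub[entered].to_numpy(dtype=float))
        intercept = float(beta[0])
        coefs = {v: float(b) for v, b in zip(entered, beta[1:])}
    else:
        intercept = float(y.mean())
        coefs = {}

    model = StepwiseModel(
        response=response,
        variables=entered,
        increments=increments,
        rmse_path=rmse_path,
        r_squared=r2_prev,
        coefficients=coefs,
        intercept=intercept,
        warning=warning,
    )
    if category_map is not None and entered:
        model.category_shares = contribution_shares(model, category_map)
    return model


def contribution_shares(
    model: StepwiseModel, category_map: dict[str, str]
) -> dict[str, float]:
    """Per-category explained-variance shares (R² points).

    Sums each entered variable's R² increment into its category
    (biochemistry / histology); shares sum exactly to the model R².
    """
    shares: dict[str, float] = {}
    for v, inc in zip(model.variables, model.increments):
        if v not in category_map:
            raise KeyError(f"variable {v!r} has no category")
        shares[category_map[v]] = shares.get(category_map[v], 0.0) + inc
    return shares


def shapiro_check(values) -> tuple[float, float]:
    """Shapiro-Wilk normality statistic and p-value (3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: Shapiro-Wilk undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)
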