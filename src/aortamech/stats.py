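"""Cohort statistics: random-intercept models and ensemble variable selection.

The cohort table has one row per patient x aortic segment (x direction where
applicable); because several rows share a patient, every comparison is run
as a linear mixed-effects model with a per-patient random intercept.

Variable selection for the growth model runs in two stages:

1. multiple imputation by chained equations with predictive mean matching
   (PMM) produces ``m`` completed tables; an L1-penalized (LASSO) linear
   regression with a cross-validated penalty is fit on each, and a variable
   is retained when it is selected in at least 60% of the imputations with a
   consistent coefficient sign (>80% one sign among the selections);
2. the retained variables enter a pooled random-intercept model whose
   per-imputation fits are combined by Rubin's rules.

Histology-mechanics associations use backward elimination by information
criterion inside patient-clustered bootstrap replicates, reporting how often
each candidate survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import GroupKFold, KFold

Z95 = 1.959963984540054  # two-sided 95% normal quantile

DEFAULT_REFERENCES: dict[str, str] = {
    "segment": "root",
    "pathology": "no_aneurysm",
    "disease_class": "donor",
}


class RankDeficiencyError(ValueError):
    """The fixed-effects design is singular; `.aliased` names the culprit columns."""

    def __init__(self, aliased: Sequence[str]):
        super().__init__(f"singular fixed-effects design; aliased terms: {list(aliased)}")
        self.aliased = list(aliased)


class UnimputableColumnError(ValueError):
    """A column has no observed values and cannot be imputed."""


@dataclass(frozen=True)
class ModelFit:
    """A fitted random-intercept model summary.

    ``terms`` is indexed by fixed-effect term with columns
    ``estimate, se, ci_low, ci_high, p`` (Wald normal approximation,
    CI = estimate +/- 1.96 se, two-tailed p).
    """

    terms: pd.DataFrame
    re_var: float
    resid_var: float
    n_rows: int
    n_groups: int


@dataclass(frozen=True)
class PooledFit:
    """Rubin-combined fit across ``m`` imputations.

    ``terms`` additionally carries ``within_se`` (root mean within-imputation
    variance) and ``between_var``; pooled variance = W + (1 + 1/m) B.
    """

    terms: pd.DataFrame
    m: int
    re_var: float
    resid_var: float
    n_rows: int
    n_groups: int


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


def design_matrix(
    table: pd.DataFrame,
    candidates: Sequence[str],
    references: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Numeric design for a candidate list: dummies with a reference level.

    Returns the design and a map variable -> its design column names
    (one column for numerics, one per non-reference level for categoricals).
    """
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, list[str]] = {}
    for var in candidates:
        s = table[var]
        if _is_categorical(s):
            levels = list(pd.unique(s.dropna()))
            ref = refs.get(var, sorted(map(str, levels))[0])
            ordered = [lv for lv in levels if str(lv) == str(ref)] + sorted(
                (lv for lv in levels if str(lv) != str(ref)), key=str
            )
            names = []
            for lv in ordered[1:]:
                name = f"{var}[{lv}]"
                cols[name] = (s.astype(str) == str(lv)).to_numpy(dtype=float)
                names.append(name)
            groups[var] = names
        else:
            cols[var] = s.to_numpy(dtype=float)
            groups[var] = [var]
    return pd.DataFrame(cols, index=table.index), groups


def _wald_table(names: Sequence[str], est: np.ndarray, se: np.ndarray) -> pd.DataFrame:
    z = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - Z95 * se,
            "ci_high": est + Z95 * se,
            "p": p,
        },
        index=pd.Index(names, name="term"),
    )


def fit_random_intercept(
    table: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    group: str = "patient",
    references: Mapping[str, str] | None = None,
    reml: bool = True,
) -> ModelFit:
    """REML linear mixed model with a per-``group`` random intercept.

    Repeated segments and directions from one patient are correlated; the
    random intercept absorbs that patient-level correlation so the fixed
    effects compare within-patient where possible.
    """
    used = [response, group, *fixed]
    data = table[used]
    if data.isna().any().any():
        bad = data.columns[data.isna().any()].tolist()
        raise ValueError(f"missing values in model columns {bad}; impute first")
    if data[group].nunique() < 2:
        raise RankDeficiencyError([group])

    X, _ = design_matrix(data, fixed, references)
    exog = np.column_stack([np.ones(len(X)), X.to_numpy()])
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        aliased = _aliased_columns(exog, ["Intercept", *X.columns])
        raise RankDeficiencyError(aliased)

    exog_df = pd.DataFrame(exog, columns=["Intercept", *X.columns], index=data.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            endog=data[response].astype(float),
            exog=exog_df,
            groups=data[group].to_numpy(),
        )
        res = model.fit(reml=reml)

    est = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    terms = _wald_table(["Intercept", *X.columns], est, se)
    return ModelFit(
        terms=terms,
        re_var=float(np.asarray(res.cov_re)[0, 0]),
        resid_var=float(res.scale),
        n_rows=len(data),
        n_groups=int(data[group].nunique()),
    )


def _aliased_columns(exog: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns whose removal restores full rank (greedy scan)."""
    aliased = []
    keep = list(range(exog.shape[1]))
    target = np.linalg.matrix_rank(exog)
    for j in range(exog.shape[1] - 1, -1, -1):
        trial = [k for k in keep if k != j]
        if np.linalg.matrix_rank(exog[:, trial]) == target:
            aliased.append(names[j])
            keep = trial
            if len(keep) == target:
                break
    return aliased[::-1] or list(names)


# ---------------------------------------------------------------------------
# Multiple imputation with predictive mean matching


def impute_pmm(
    table: pd.DataFrame,
    m: int = 20,
    seed: int | None = 0,
    *,
    n_donors: int = 5,
    n_cycles: int = 10,
    exclude: Sequence[str] = (),
) -> list[pd.DataFrame]:
    """Chained-equations multiple imputation with predictive mean matching.

    For every incomplete column, a linear predictor is fit on the other
    columns (dummy-coded where categorical); each missing cell receives the
    *observed* value of one of the ``n_donors`` rows whose predicted mean is
    closest to its own prediction — so imputed values are always values the
    column actually took. Matching is "type 1": donor predictions use the
    least-squares fit while each missing cell is predicted under a posterior
    draw of the coefficients, giving the imputations proper
    between-imputation variability. Columns in ``exclude`` (identifiers
    only — the analysis response must stay in the imputation model, or
    imputed predictors lose their association with it) are never imputed
    nor used as predictors.

    Returns ``m`` completed copies; bit-reproducible for a given seed.
    """
    work_cols = [c for c in table.columns if c not in set(exclude)]
    incomplete = [c for c in work_cols if table[c].isna().any()]
    for c in incomplete:
        if table[c].isna().all():
            raise UnimputableColumnError(f"column {c!r} has no observed values")
    if not incomplete:
        return [table.copy() for _ in range(m)]
    if not any(table[c].notna().all() for c in work_cols):
        raise UnimputableColumnError("no fully observed column available as a predictor")

    seeds = np.random.SeedSequence(seed).spawn(m)
    return [_impute_once(table, work_cols, incomplete, np.random.default_rng(s),
                         n_donors, n_cycles) for s in seeds]


def _numeric_codes(s: pd.Series) -> tuple[np.ndarray, np.ndarray | None]:
    """Column as float codes; returns (codes, level array or None if numeric)."""
    if _is_categorical(s):
        codes, levels = pd.factorize(s, use_na_sentinel=True)
        out = codes.astype(float)
        out[codes < 0] = np.nan
        return out, np.asarray(levels, dtype=object)
    return s.to_numpy(dtype=float), None


def _impute_once(
    table: pd.DataFrame,
    work_cols: list[str],
    incomplete: list[str],
    rng: np.random.Generator,
    n_donors: int,
    n_cycles: int,
) -> pd.DataFrame:
    out = table.copy()
    masks = {c: table[c].isna().to_numpy() for c in incomplete}
    # initialize each hole with a random observed value of its column
    for c in incomplete:
        obs = table[c].dropna().to_numpy()
        fill = rng.choice(obs, size=int(masks[c].sum()), replace=True)
        out.loc[masks[c], c] = fill

    # complete columns never change across cycles: build their design once
    static_cols = [p for p in work_cols if p not in incomplete]
    Xstat = design_matrix(out, static_cols)[0].to_numpy(dtype=float)
    ones = np.ones((len(out), 1))
    y_true = {c: _numeric_codes(table[c])[0] for c in incomplete}
    col_values = {c: table[c].to_numpy() for c in incomplete}

    for _ in range(n_cycles):
        for c in incomplete:
            miss = masks[c]
            obs = ~miss
            others = [p for p in incomplete if p != c]
            parts = [ones, Xstat]
            if others:
                parts.append(design_matrix(out, others)[0].to_numpy(dtype=float))
            Xm = np.column_stack(parts)

            # ridge-stabilized least squares; tiny penalty guards collinearity
            A = Xm[obs]
            yo = y_true[c][obs]
            AtA = A.T @ A + 1e-8 * np.trace(A.T @ A) / A.shape[1] * np.eye(A.shape[1])
            beta = np.linalg.solve(AtA, A.T @ yo)
            # type-1 matching: donors matched on beta-hat predictions, targets
            # predicted under a posterior draw of (beta, sigma^2) so the
            # imputations carry proper between-imputation variability
            resid = yo - A @ beta
            dof = max(A.shape[0] - A.shape[1], 1)
            sigma2 = float(resid @ resid) / max(
                rng.chisquare(dof), 1e-12
            )
            cov = sigma2 * np.linalg.inv(AtA)
            beta_star = rng.multivariate_normal(beta, (cov + cov.T) / 2.0,
                                                method="cholesky")
            pred = Xm @ beta
            pred_miss_star = Xm @ beta_star

            # nearest donors live in a 2k window around each missing cell's
            # insertion point in the sorted donor predictions
            donor_rows = np.flatnonzero(obs)
            order = np.argsort(pred[donor_rows], kind="stable")
            donor_sorted = donor_rows[order]
            dp = pred[donor_sorted]
            k = min(n_donors, donor_sorted.size)
            mi = np.flatnonzero(miss)
            pos = np.searchsorted(dp, pred_miss_star[mi])
            lo = np.clip(pos - k, 0, max(dp.size - 2 * k, 0))
            win = np.clip(lo[:, None] + np.arange(2 * k)[None, :], 0, dp.size - 1)
            dist = np.abs(dp[win] - pred_miss_star[mi][:, None])
            nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
            pick = rng.integers(0, k, size=mi.size)
            chosen = win[np.arange(mi.size), nearest[np.arange(mi.size), pick]]
            out.iloc[mi, out.columns.get_loc(c)] = col_values[c][donor_sorted[chosen]]
    return out


# ---------------------------------------------------------------------------
# Per-imputation LASSO and the ensemble selection rule


def lasso_coefficients(
    table: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    cv_folds: int = 10,
    seed: int | None = 0,
    references: Mapping[str, str] | None = None,
    penalty: Literal["1se", "min"] = "1se",
    group: str | None = "patient",
    alpha: float | None = None,
) -> tuple[dict[str, float], float]:
    """L1-penalized linear regression with a cross-validated penalty.

    Candidates are standardized to unit variance (categoricals dummy-coded
    first). The penalty path is evaluated by ``cv_folds``-fold
    cross-validation — patient-grouped when ``group`` names a column, so a
    patient's correlated rows never straddle a train/test split — and the
    penalty is either the error-minimizing value (``min``) or the largest
    value within one standard error of it (``1se``, the default; the sparser
    choice). An explicit ``alpha`` bypasses cross-validation entirely
    (``alpha=0`` reduces to ordinary least squares on the standardized
    design). Returns (coefficients on the standardized design, penalty
    used); zero-variance candidates are dropped with a warning.
    """
    X, var_groups = design_matrix(table, candidates, references)
    keep_cols = []
    for var, cols in var_groups.items():
        live = [c for c in cols if X[c].std(ddof=0) > 0]
        if not live:
            warnings.warn(f"candidate {var!r} has zero variance; dropped", UserWarning,
                          stacklevel=2)
            continue
        keep_cols.extend(live)
    if not keep_cols:
        return {}, 0.0
    Xs = X[keep_cols].to_numpy(dtype=float)
    Xs = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0, ddof=0)
    y = table[response].to_numpy(dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if alpha is not None:
            if alpha == 0.0:
                fit = LinearRegression().fit(Xs, y)
            else:
                fit = Lasso(alpha=alpha, max_iter=50000).fit(Xs, y)
            return dict(zip(keep_cols, fit.coef_)), float(alpha)

        if group is not None and group in table.columns:
            n_splits = min(cv_folds, table[group].nunique())
            cv = list(
                GroupKFold(n_splits=n_splits).split(Xs, y, groups=table[group].to_numpy())
            )
        else:
            cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        path = LassoCV(cv=cv, random_state=seed, max_iter=20000).fit(Xs, y)
        if penalty == "min":
            best_alpha = float(path.alpha_)
            coefs = path.coef_
        else:
            mse = path.mse_path_  # (n_alphas, n_folds), alphas descending
            mean = mse.mean(axis=1)
            se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
            j_min = int(np.argmin(mean))
            j_1se = int(np.flatnonzero(mean <= mean[j_min] + se[j_min]).min())
            best_alpha = float(path.alphas_[j_1se])
            coefs = Lasso(alpha=best_alpha, max_iter=50000).fit(Xs, y).coef_
    return dict(zip(keep_cols, coefs)), best_alpha


def lasso_per_imputation(
    table: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    cv_folds: int = 10,
    seed: int | None = 0,
    references: Mapping[str, str] | None = None,
    penalty: Literal["1se", "min"] = "1se",
    group: str | None = "patient",
) -> dict[str, int]:
    """Variables a cross-validated LASSO keeps on one completed table.

    Returns ``{variable: sign}`` for variables with any nonzero coefficient;
    a categorical counts as selected when any of its levels is nonzero, with
    the sign of its largest-magnitude level. See :func:`lasso_coefficients`
    for the penalty rule.
    """
    coef, _ = lasso_coefficients(
        table, response, candidates, cv_folds, seed, references, penalty, group
    )
    _, var_groups = design_matrix(table, candidates, references)
    result: dict[str, int] = {}
    for var, cs in var_groups.items():
        vals = np.array([coef.get(c, 0.0) for c in cs])
        if vals.size and np.any(vals != 0.0):
            result[var] = int(np.sign(vals[np.argmax(np.abs(vals))]))
    return result


def ensemble_select(
    per_imputation: Sequence[Mapping[str, int]],
    inclusion_threshold: float = 0.6,
    sign_threshold: float = 0.8,
) -> pd.DataFrame:
    """Combine per-imputation LASSO picks into a final variable set.

    A variable is selected iff it appears in at least ``inclusion_threshold``
    of the imputations AND more than ``sign_threshold`` of its nonzero
    coefficients share a sign. Sign consistency is computed among the
    imputations where the variable was selected (a zero coefficient has no
    sign). Pure function of the input sets — imputation order is irrelevant.
    """
    m = len(per_imputation)
    counts: dict[str, dict[str, int]] = {}
    for picks in per_imputation:
        for var, sign in picks.items():
            rec = counts.setdefault(var, {"n": 0, "pos": 0, "neg": 0})
            rec["n"] += 1
            if sign > 0:
                rec["pos"] += 1
            elif sign < 0:
                rec["neg"] += 1
    rows = []
    for var in sorted(counts):
        rec = counts[var]
        frac = rec["n"] / m if m else 0.0
        consistency = max(rec["pos"], rec["neg"]) / rec["n"] if rec["n"] else 0.0
        rows.append(
            {
                "variable": var,
                "inclusion_count": rec["n"],
                "inclusion_fraction": frac,
                "n_positive": rec["pos"],
                "n_negative": rec["neg"],
                "sign_consistency": consistency,
                "selected": frac >= inclusion_threshold and consistency > sign_threshold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variable", "inclusion_count", "inclusion_fraction",
                 "n_positive", "n_negative", "sign_consistency", "selected"],
    ).set_index("variable")


# ---------------------------------------------------------------------------
# Rubin-pooled growth model


def pooled_growth_model(
    tables: Sequence[pd.DataFrame],
    response: str,
    fixed: Sequence[str],
    group: str = "patient",
    references: Mapping[str, str] | None = None,
) -> PooledFit:
    """Random-intercept growth model pooled over imputations by Rubin's rules.

    Each completed table is fit separately; estimates are averaged and the
    pooled variance is W + (1 + 1/m) B with W the mean within-imputation
    variance and B the between-imputation variance of the estimates.
    """
    if not tables:
        raise ValueError("need at least one completed table")
    fits = []
    term_index = None
    for t in tables:
        fit = fit_random_intercept(t, response, fixed, group, references)
        if term_index is None:
            term_index = fit.terms.index
        elif not term_index.equals(fit.terms.index):
            raise ValueError(
                "inconsistent term sets across imputations: "
                f"{list(term_index)} vs {list(fit.terms.index)}"
            )
        fits.append(fit)

    m = len(fits)
    est = np.vstack([f.terms["estimate"].to_numpy() for f in fits])
    var = np.vstack([f.terms["se"].to_numpy() ** 2 for f in fits])
    qbar = est.mean(axis=0)
    W = var.mean(axis=0)
    B = est.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    T = W + (1.0 + 1.0 / m) * B
    se = np.sqrt(T)

    terms = _wald_table(list(term_index), qbar, se)
    terms["within_se"] = np.sqrt(W)
    terms["between_var"] = B
    return PooledFit(
        terms=terms,
        m=m,
        re_var=float(np.mean([f.re_var for f in fits])),
        resid_var=float(np.mean([f.resid_var for f in fits])),
        n_rows=fits[0].n_rows,
        n_groups=fits[0].n_groups,
    )


# ---------------------------------------------------------------------------
# Bootstrap backward selection (histology associations)


def _ols_aic(y: np.ndarray, X: np.ndarray) -> float:
    n = y.size
    Xc = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    rss = float(resid @ resid)
    k = Xc.shape[1] + 1  # + error variance
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def _backward_eliminate(
    y: np.ndarray, X: pd.DataFrame, groups: Mapping[str, list[str]]
) -> list[str]:
    current = [v for v in groups if groups[v]]
    cols = lambda vs: X[[c for v in vs for c in groups[v]]].to_numpy()  # noqa: E731
    best_aic = _ols_aic(y, cols(current))
    improved = True
    while improved and current:
        improved = False
        drop_var, drop_aic = None, best_aic
        for v in current:
            trial = [w for w in current if w != v]
            a = _ols_aic(y, cols(trial))
            if a < drop_aic:
                drop_var, drop_aic = v, a
        if drop_var is not None:
            current.remove(drop_var)
            best_aic = drop_aic
            improved = True
    return current


def bootstrap_backward_selection(
    table: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    B: int = 100,
    seed: int | None = 0,
    group: str = "patient",
    references: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Selection frequency of each candidate under bootstrap backward elimination.

    Whole patients are resampled with replacement (clustered bootstrap, so
    the within-patient correlation travels with the rows); within each
    replicate, candidates are removed one at a time while the removal lowers
    the information criterion (AIC). Returns per-variable selection
    frequencies, sorted descending — the frequency-ranked model.
    """
    if len(table) <= len(candidates):
        raise ValueError(
            f"ill-posed: {len(candidates)} candidates for {len(table)} rows"
        )
    patients = pd.unique(table[group])
    rng = np.random.default_rng(seed)
    hits = {v: 0 for v in candidates}
    for _ in range(B):
        sampled = rng.choice(patients, size=patients.size, replace=True)
        parts = [table[table[group] == p] for p in sampled]
        boot = pd.concat(parts, ignore_index=True)
        X, groups_map = design_matrix(boot, candidates, references)
        live = {v: [c for c in cs if X[c].std(ddof=0) > 0]
                for v, cs in groups_map.items()}
        kept = _backward_eliminate(
            boot[response].to_numpy(dtype=float), X, live
        )
        for v in kept:
            hits[v] += 1
    freq = pd.DataFrame(
        {"frequency": {v: hits[v] / B for v in candidates}}
    )
    freq.index.name = "variable"
    return freq.sort_values("frequency", ascending=False)
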