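"""Linear modelling: OLS with interactions, stepwise AIC, adjustment and
tertile-stratified effect extraction.

Model formulas are given as term lists using the field's ``*`` (main
effects plus interaction) and ``:`` (interaction only) notation, e.g.
``["sex_male*neutered", "age_years"]``.  Sex and neuter status are coded
0/1 (female/entire = 0).  Stepwise selection is backward elimination on the
Akaike information criterion with a marginality constraint: a main effect
is never dropped while an interaction containing it remains.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import AliasingError, SchemaError


def expand_terms(terms) -> list[str]:
    """Expand ``a*b`` into ``a, b, a:b``; keep ``a:b`` interactions as is.

    Interaction components are sorted so ``a:b`` and ``b:a`` are the same
    term; order of first appearance is preserved, duplicates dropped.
    """
    out: list[str] = []
    for t in terms:
        t = t.replace(" ", "")
        if "*" in t:
            parts = t.split("*")
            atoms = list(parts)
            for k in range(2, len(parts) + 1):
                atoms += [":".join(sorted(c)) for c in itertools.combinations(parts, k)]
        else:
            atoms = [":".join(sorted(t.split(":"))) if ":" in t else t]
        for a in atoms:
            if a not in out:
                out.append(a)
    return out


@dataclass
class LinearFit:
    """An OLS fit with the bookkeeping needed for model comparison."""

    terms: list
    term_names: list            # design-column names
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    r_squared: float
    aic: float
    n: int
    residual_variance: float
    formula: str = ""
    result: object = field(default=None, repr=False, compare=False)

    def coef(self, name: str) -> float:
        """Coefficient by design-column name (exact match)."""
        try:
            return float(self.coefficients[self.term_names.index(name)])
        except ValueError:
            raise KeyError(f"no design column named {name!r}; have {self.term_names}") from None

    def to_json_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "term_names": list(self.term_names),
            "coefficients": self.coefficients.tolist(),
            "std_errors": self.std_errors.tolist(),
            "p_values": self.p_values.tolist(),
            "r_squared": float(self.r_squared),
            "aic": float(self.aic),
            "n": int(self.n),
            "residual_variance": float(self.residual_variance),
            "formula": self.formula,
        }


def _patsy_formula(response, atoms, relevel=None):
    relevel = relevel or {}

    def wrap(name):
        if name in relevel:
            return f"C({name}, Treatment('{relevel[name]}'))"
        return name

    rhs = " + ".join(":".join(wrap(p) for p in a.split(":")) for a in atoms) or "1"
    return f"{response} ~ {rhs}"


def _rstyle_aic(rss: float, n: int, k_params: int) -> float:
    """AIC on the ``n log(RSS/n) + 2(k+1)`` scale (constant across models)."""
    return n * math.log(rss / n) + 2.0 * (k_params + 1)


def fit_ols(terms, table: pd.DataFrame, response: str,
            relevel: dict | None = None) -> LinearFit:
    """Least-squares fit of ``response`` on the expanded term list.

    Raises :class:`~bst.errors.AliasingError` naming the aliased design
    columns if the design matrix is rank deficient.
    """
    atoms = expand_terms(terms)
    formula = _patsy_formula(response, atoms, relevel)
    model = smf.ols(formula, data=table)
    exog = model.exog
    names = list(model.exog_names)
    r = scipy.linalg.qr(exog, mode="r", pivoting=True)
    diag = np.abs(np.diag(r[0]))
    if diag.size and (diag < max(exog.shape) * np.finfo(float).eps * diag.max()).any():
        bad = diag < max(exog.shape) * np.finfo(float).eps * diag.max()
        raise AliasingError([names[r[1][i]] for i in np.flatnonzero(bad)])
    res = model.fit()
    n = int(res.nobs)
    rss = float(res.ssr)
    k = exog.shape[1]
    if n <= k:
        raise ValueError(f"n={n} does not exceed the {k} model terms")
    return LinearFit(
        terms=atoms,
        term_names=names,
        coefficients=np.asarray(res.params),
        std_errors=np.asarray(res.bse),
        p_values=np.asarray(res.pvalues),
        r_squared=float(res.rsquared),
        aic=_rstyle_aic(rss, n, k),
        n=n,
        residual_variance=rss / (n - k),
        formula=formula,
        result=res,
    )


def _droppable(atoms) -> list[str]:
    """Terms not marginal to any retained higher-order interaction."""
    comp = {a: frozenset(a.split(":")) for a in atoms}
    out = []
    for a in atoms:
        if any(comp[a] < comp[b] for b in atoms if b != a):
            continue
        out.append(a)
    return out


def stepwise_aic(initial_terms, table: pd.DataFrame, response: str,
                 relevel: dict | None = None) -> LinearFit:
    """Backward elimination by AIC with a marginality constraint.

    At each step every droppable term is removed in turn; the deletion with
    the lowest resulting AIC is accepted if it improves on the current
    model (ties broken alphabetically), stopping at a local AIC minimum.
    """
    atoms = expand_terms(initial_terms)
    current = fit_ols(atoms, table, response, relevel)
    while True:
        candidates = _droppable(current.terms)
        if not candidates:
            return current
        trials = []
        for t in sorted(candidates):
            reduced = [a for a in current.terms if a != t]
            if not reduced:
                fit = _intercept_fit(table, response)
            else:
                fit = fit_ols(reduced, table, response, relevel)
            trials.append((fit.aic, t, fit))
        best_aic, _, best_fit = min(trials, key=lambda x: (x[0], x[1]))
        if best_aic < current.aic - 1e-10:
            current = best_fit
        else:
            return current


def _intercept_fit(table, response) -> LinearFit:
    y = table[response].to_numpy(dtype=float)
    n = y.size
    rss = float(((y - y.mean()) ** 2).sum())
    return LinearFit(
        terms=[], term_names=["Intercept"],
        coefficients=np.array([y.mean()]),
        std_errors=np.array([np.sqrt(rss / (n - 1) / n)]),
        p_values=np.array([np.nan]),
        r_squared=0.0, aic=_rstyle_aic(rss, n, 1), n=n,
        residual_variance=rss / (n - 1), formula=f"{response} ~ 1",
    )


# ---------------------------------------------------------------------------
# breed-adjusted food motivation


def adjusted_fms(table: pd.DataFrame, fit: LinearFit, fms_col: str = "fms",
                 sex_col: str = "sex_male", neuter_col: str = "neutered",
                 breed_col: str = "breed") -> pd.Series:
    """Remove sex / neuter / sex:neuter composition effects breed-centred.

    ``adjusted_i = fms_i - b_sex (sex_i - mean_sex_breed)
                 - b_neuter (neuter_i - mean_neuter_breed)
                 - b_int (sex_i*neuter_i - mean_int_breed)``

    so a dog at its breed's covariate means keeps its raw score, and the
    adjustment vanishes when all three coefficients are zero.  Breed means
    come from the analysis table itself.
    """
    for col in (fms_col, sex_col, neuter_col, breed_col):
        if col not in table.columns:
            raise SchemaError("adjustment input lacks a required column", missing=[col])
    def coef_or_zero(*names):
        for name in names:
            if name in fit.term_names:
                return fit.coef(name)
        return 0.0  # term eliminated by model selection: no composition effect

    b_sex = coef_or_zero(sex_col)
    b_neu = coef_or_zero(neuter_col)
    b_int = coef_or_zero(f"{sex_col}:{neuter_col}", f"{neuter_col}:{sex_col}")

    sex = table[sex_col].to_numpy(dtype=float)
    neu = table[neuter_col].to_numpy(dtype=float)
    inter = sex * neu
    work = pd.DataFrame({"breed": table[breed_col].to_numpy(),
                         "sex": sex, "neu": neu, "inter": inter})
    means = work.groupby("breed").transform("mean")
    adj = (
        table[fms_col].to_numpy(dtype=float)
        - b_sex * (sex - means["sex"].to_numpy())
        - b_neu * (neu - means["neu"].to_numpy())
        - b_int * (inter - means["inter"].to_numpy())
    )
    return pd.Series(adj, index=table.index, name="adjusted_fms")


# ---------------------------------------------------------------------------
# tertile-stratified effect extraction

MANAGEMENT_TERMS = ("owner_intervention", "restriction_human_food", "exercise_taken")


def tertile_model_terms(tertile_col: str = "fm_tertile") -> list[str]:
    """The minimal interaction model for BCS with tertile-specific
    management, sex and neuter effects plus a common age slope."""
    terms = [f"{m}*{tertile_col}" for m in MANAGEMENT_TERMS]
    terms += [f"sex_male*{tertile_col}", f"neutered*{tertile_col}",
              "sex_male*neutered", "age_years"]
    return terms


def extract_tertile_effects(table: pd.DataFrame, response: str = "bcs_owner_9pt",
                            tertile_col: str = "fm_tertile",
                            terms=None) -> pd.DataFrame:
    """Within-tertile slopes by releveling the tertile factor.

    The interaction model is refit three times, once with each tertile as
    the reference level; the main-effect coefficient of each management /
    covariate term in a run is that tertile's within-group slope.  Fitted
    values are identical across runs (the model is a reparameterization);
    this is verified internally.
    """
    col = table[tertile_col]
    declared = (list(col.cat.categories) if isinstance(col.dtype, pd.CategoricalDtype)
                else sorted(set(col)))
    levels = [lv for lv in ("low", "medium", "high") if lv in declared]
    if len(levels) < 2:
        raise ValueError("tertile effect extraction needs >= 2 tertile groups")
    for lv in levels:
        if (col == lv).sum() == 0:
            raise ValueError(f"empty tertile group {lv!r}")
    if terms is None:
        terms = tertile_model_terms(tertile_col)
    varying = list(MANAGEMENT_TERMS) + ["sex_male", "neutered"]
    common = ["age_years"]

    rows = []
    fitted_ref = None
    for ref in levels:
        fit = fit_ols(terms, table, response, relevel={tertile_col: ref})
        fitted = np.asarray(fit.result.fittedvalues)
        if fitted_ref is None:
            fitted_ref = fitted
        elif not np.allclose(fitted, fitted_ref, atol=1e-8):
            raise RuntimeError("releveled fits disagree on fitted values")
        for term in varying + common:
            idx = fit.term_names.index(term)
            rows.append({
                "tertile": ref,
                "term": term,
                "beta": float(fit.coefficients[idx]),
                "se": float(fit.std_errors[idx]),
                "p_value": float(fit.p_values[idx]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# descriptive statistics


def pearson_cor(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-transform p-value.

    Pairs with a missing member are dropped; requires >= 3 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("pearson_cor requires at least 3 complete pairs")
    res = scipy.stats.pearsonr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups) -> tuple[float, float]:
    """One-way ANOVA F and p over a sequence of samples.

    Zero within-group variance with unequal means gives ``(inf, 0.0)``
    (flagged degenerate rather than an exception).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("one_way_anova requires >= 2 non-empty groups")
    grand = np.concatenate(arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ssb = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    df_b = len(arrays) - 1
    df_w = grand.size - len(arrays)
    if df_w <= 0:
        raise ValueError("one_way_anova requires residual degrees of freedom")
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), float(scipy.stats.f.sf(f, df_b, df_w))


def pooled_t_test(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test; pooled-variance by default (df = n1 + n2 - 2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    res = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def pairwise_t_holm(groups: dict, welch: bool = False) -> pd.DataFrame:
    """All pairwise two-sample t-tests with Holm-corrected p-values."""
    names = list(groups)
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        t, df, p = pooled_t_test(groups[g1], groups[g2], welch=welch)
        rows.append({"group1": g1, "group2": g2, "t": t, "df": df, "p_raw": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def compare_models(fits, names=None) -> pd.DataFrame:
    """R-squared / AIC comparison table, with deltas against the first fit."""
    fits = list(fits)
    if names is None:
        names = [f.formula or f"model_{i}" for i, f in enumerate(fits)]
    base = fits[0]
    return pd.DataFrame(
        {
            "model": names,
            "n": [f.n for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "aic": [f.aic for f in fits],
            "delta_r_squared": [f.r_squared - base.r_squared for f in fits],
            "delta_aic": [f.aic - base.aic for f in fits],
        }
    )
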