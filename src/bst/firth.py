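"""Firth bias-reduced logistic regression and the merged multinomial model.

Ordinary maximum-likelihood logistic regression produces infinite estimates
under separation (a predictor pattern perfectly splitting the outcome),
which happens routinely in sparse breed x age x sex cells.  Firth's
penalized likelihood maximises

    l*(beta) = l(beta) + 0.5 * log det I(beta),

where ``I(beta) = X' W X`` is the Fisher information and ``W =
diag(pi_i (1 - pi_i))``.  The stationarity condition is the modified score

    U*_j(beta) = sum_i (y_i - pi_i + h_i (0.5 - pi_i)) x_ij = 0,

with ``h_i`` the leverages (diagonal of ``W^{1/2} X I^{-1} X' W^{1/2}``).
The penalty (a Jeffreys prior) keeps every estimate finite, even under
complete separation.

A three-category body-condition model (underweight / ideal /
overweight-obese) is assembled from two such binomial fits against the
shared 'ideal' reference: with linear predictors ``eta_U`` and ``eta_O``,

    p_ideal = 1 / (1 + exp(eta_U) + exp(eta_O)),
    p_under = exp(eta_U) * p_ideal,   p_over = exp(eta_O) * p_ideal,

i.e. the two binomial predictors act as multinomial logits — the unique
merge that reproduces each binomial model conditionally.  Per-breed
probabilities are standardized over a reference covariate distribution
(the population age distribution, 50:50 sexes), and confidence intervals
come from simulating coefficient vectors from each fit's asymptotic normal
distribution and recomputing the standardized probabilities per draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import expit

from .errors import AliasingError, ConvergenceError, SchemaError

BCS_CATEGORIES = ("underweight", "ideal", "overweight_obese")


@dataclass
class FirthFit:
    """A converged (or diagnosed) penalized-likelihood logistic fit."""

    coefficients: np.ndarray
    covariance: np.ndarray          # inverse Fisher information at the estimate
    penalized_loglik: float
    n_iterations: int
    converged: bool
    term_names: list
    max_modified_score: float = np.nan
    pll_trace: list = field(default_factory=list)
    #: indices into a wider design when aliased columns were removed upstream
    design_indices: np.ndarray | None = None

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if self.design_indices is not None:
            X = X[:, self.design_indices]
        return X @ self.coefficients

    def to_json_dict(self) -> dict:
        return {
            "term_names": list(self.term_names),
            "coefficients": self.coefficients.tolist(),
            "covariance": self.covariance.tolist(),
            "penalized_loglik": float(self.penalized_loglik),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
        }


def _fullrank_column_indices(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    r, pivots = scipy.linalg.qr(X, mode="r", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0:
        return np.arange(X.shape[1])
    good = diag >= max(X.shape) * np.finfo(float).eps * diag.max()
    return np.sort(pivots[: int(good.sum())])


def _check_full_rank(X: np.ndarray, term_names) -> None:
    keep = _fullrank_column_indices(X)
    if keep.size < X.shape[1]:
        aliased = [term_names[i] for i in sorted(set(range(X.shape[1])) - set(keep))]
        raise AliasingError(aliased)


def _penalized_loglik(X, y, beta):
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    pi = expit(eta)
    w = pi * (1.0 - pi)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def fit_firth_logistic(
    design: np.ndarray,
    y: np.ndarray,
    term_names=None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> FirthFit:
    """Maximise the Firth-penalized log-likelihood by Newton iteration.

    Starts at ``beta = 0`` and takes modified-score Newton steps with
    step-halving whenever a step would decrease the penalized
    log-likelihood, declaring convergence when the largest modified-score
    component falls below ``tol``.  Non-convergence returns a flagged fit
    (``converged=False``) with full diagnostics rather than raising.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("design and response shapes are incompatible")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    _check_full_rank(X, term_names)

    beta = np.zeros(p)
    pll = _penalized_loglik(X, y, beta)
    trace = [pll]
    converged = False
    max_score = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        pi = expit(X @ beta)
        w = pi * (1.0 - pi)
        info = (X * w[:, None]).T @ X
        try:
            cho = scipy.linalg.cho_factor(info)
        except scipy.linalg.LinAlgError:
            break
        q = X * np.sqrt(w)[:, None]
        h = np.einsum("ij,ji->i", q, scipy.linalg.cho_solve(cho, q.T))
        score = X.T @ (y - pi + h * (0.5 - pi))
        max_score = float(np.abs(score).max())
        if max_score < tol:
            converged = True
            break
        step = scipy.linalg.cho_solve(cho, score)
        new_beta, new_pll = beta + step, -np.inf
        for _ in range(30):
            new_pll = _penalized_loglik(X, y, new_beta)
            if new_pll >= pll - 1e-10:
                break
            step = 0.5 * step
            new_beta = beta + step
        beta, pll = new_beta, new_pll
        trace.append(pll)

    pi = expit(X @ beta)
    w = pi * (1.0 - pi)
    info = (X * w[:, None]).T @ X
    covariance = np.linalg.inv(info)
    covariance = 0.5 * (covariance + covariance.T)
    return FirthFit(
        coefficients=beta,
        covariance=covariance,
        penalized_loglik=pll,
        n_iterations=n_iter,
        converged=converged,
        term_names=list(term_names),
        max_modified_score=max_score,
        pll_trace=trace,
    )


# ---------------------------------------------------------------------------
# design construction for the clinic-record model


@dataclass
class EhrDesign:
    """Treatment-coded design for Breed + YearOfAge + Sex (+ interactions).

    Reference levels are the alphabetically first breed and sex.  Age enters
    as a numeric whole-year term by default; with ``categorical_age`` the
    age main effect becomes dummy-coded while the breed:age interaction
    remains on the numeric scale to keep the design tractable.
    """

    breed_levels: list
    sex_levels: list
    age_levels: list
    categorical_age: bool = False
    include_interactions: bool = True
    term_names: list = field(default_factory=list)

    def __post_init__(self):
        if not self.term_names:
            names = ["(Intercept)"]
            names += [f"breed[{b}]" for b in self.breed_levels[1:]]
            if self.categorical_age:
                names += [f"age[{a}]" for a in self.age_levels[1:]]
            else:
                names += ["age"]
            names += [f"sex[{s}]" for s in self.sex_levels[1:]]
            if self.include_interactions:
                names += [f"breed[{b}]:sex[{self.sex_levels[1]}]"
                          for b in self.breed_levels[1:]]
                names += [f"breed[{b}]:age" for b in self.breed_levels[1:]]
            self.term_names = names

    @classmethod
    def from_records(cls, records: pd.DataFrame, categorical_age: bool = False,
                     include_interactions: bool = True) -> "EhrDesign":
        for col in ("breed", "sex", "age_years"):
            if col not in records.columns:
                raise SchemaError("EHR design lacks a required column", missing=[col])
        return cls(
            breed_levels=sorted(records["breed"].unique()),
            sex_levels=sorted(records["sex"].unique()),
            age_levels=sorted(records["age_years"].unique()),
            categorical_age=categorical_age,
            include_interactions=include_interactions,
        )

    def matrix(self, frame: pd.DataFrame) -> np.ndarray:
        breed = frame["breed"].to_numpy()
        unknown = set(breed) - set(self.breed_levels)
        if unknown:
            raise SchemaError(f"breed(s) absent from fit coding: {sorted(unknown)}")
        unknown_sex = set(frame["sex"]) - set(self.sex_levels)
        if unknown_sex:
            raise SchemaError(f"sex level(s) absent from fit coding: {sorted(unknown_sex)}")
        n = len(frame)
        cols = [np.ones(n)]
        breed_dummies = [(breed == b).astype(float) for b in self.breed_levels[1:]]
        cols += breed_dummies
        age = frame["age_years"].to_numpy(dtype=float)
        if self.categorical_age:
            cols += [(age == a).astype(float) for a in self.age_levels[1:]]
        else:
            cols += [age]
        sex = frame["sex"].to_numpy()
        sex_dummy = None
        for s in self.sex_levels[1:]:
            sex_dummy = (sex == s).astype(float)
            cols.append(sex_dummy)
        if self.include_interactions:
            if sex_dummy is None:
                sex_dummy = np.zeros(n)
            cols += [d * sex_dummy for d in breed_dummies]
            cols += [d * age for d in breed_dummies]
        return np.column_stack(cols)


def fit_category_models(records: pd.DataFrame, design: EhrDesign | None = None,
                        category_col: str = "bcs_category",
                        tol: float = 1e-8, max_iter: int = 50):
    """Fit the two reference-category binomials (underweight vs ideal,
    overweight/obese vs ideal) on one-visit-per-dog records.

    Columns aliased within a binomial subset (e.g. a breed x sex cell with
    no underweight or ideal dogs) are removed before fitting, so the design
    is full rank after aliased-column removal; each fit records the design
    columns it kept."""
    if design is None:
        design = EhrDesign.from_records(records)
    fits = {}
    for target in ("underweight", "overweight_obese"):
        sub = records[records[category_col].isin(["ideal", target])]
        X = design.matrix(sub)
        keep = _fullrank_column_indices(X)
        if keep.size < X.shape[1]:
            dropped = [design.term_names[i]
                       for i in sorted(set(range(X.shape[1])) - set(keep))]
            warnings.warn(
                f"dropping {len(dropped)} aliased column(s) from the "
                f"{target}-vs-ideal fit: {dropped[:5]}...", stacklevel=2)
        y = (sub[category_col] == target).to_numpy(dtype=float)
        fit = fit_firth_logistic(X[:, keep], y,
                                 term_names=[design.term_names[i] for i in keep],
                                 tol=tol, max_iter=max_iter)
        fit.design_indices = keep
        fits[target] = fit
    return fits["underweight"], fits["overweight_obese"], design


# ---------------------------------------------------------------------------
# merging, standardization, simulation CIs


def merge_binomials(eta_under, eta_over) -> np.ndarray:
    """Merge the two reference-category linear predictors into a
    (underweight, ideal, overweight_obese) probability array; the two
    predictors act as multinomial logits against 'ideal'.

    Accepts scalars or arrays (broadcast); the output's last axis has
    length 3 and sums to 1.
    """
    eta_u = np.asarray(eta_under, dtype=float)
    eta_o = np.asarray(eta_over, dtype=float)
    eta_u, eta_o = np.broadcast_arrays(eta_u, eta_o)
    # normalise through the log-sum-exp of (eta_u, 0, eta_o) for stability
    m = np.maximum.reduce([eta_u, np.zeros_like(eta_u), eta_o])
    zu = np.exp(eta_u - m)
    zi = np.exp(-m)
    zo = np.exp(eta_o - m)
    denom = zu + zi + zo
    return np.stack([zu / denom, zi / denom, zo / denom], axis=-1)


def _standardization_grid(design: EhrDesign, age_distribution: dict):
    ages = sorted(age_distribution)
    weights = np.array([age_distribution[a] for a in ages], dtype=float)
    if not np.isclose(weights.sum(), 1.0, atol=1e-8):
        raise ValueError("age distribution weights must sum to 1")
    sexes = design.sex_levels
    grid = pd.DataFrame(
        [
            (b, a, s)
            for b in design.breed_levels
            for a in ages
            for s in sexes
        ],
        columns=["breed", "age_years", "sex"],
    )
    cell_w = np.tile(np.repeat(weights, len(sexes)) / len(sexes),
                     len(design.breed_levels))
    return grid, cell_w


def standardized_breed_probabilities(
    fit_under: FirthFit,
    fit_over: FirthFit,
    design: EhrDesign,
    age_distribution: dict,
) -> pd.DataFrame:
    """Per-breed probabilities standardized to a common covariate mix.

    Each breed's probability triple is the ``age_weight x 0.5``-weighted
    average of the merged model over the age x sex grid, so breeds are
    compared at the population age distribution and a 50:50 sex ratio.
    """
    grid, cell_w = _standardization_grid(design, age_distribution)
    G = design.matrix(grid)
    probs = merge_binomials(fit_under.linear_predictor(G),
                            fit_over.linear_predictor(G))
    n_cells = len(grid) // len(design.breed_levels)
    per_breed = (probs * cell_w[:, None]).reshape(
        len(design.breed_levels), n_cells, 3
    ).sum(axis=1)
    out = pd.DataFrame(per_breed, columns=[f"p_{c}" for c in BCS_CATEGORIES])
    out.insert(0, "breed", design.breed_levels)
    return out


def _psd_cholesky(cov: np.ndarray) -> np.ndarray:
    eig = np.linalg.eigvalsh(cov)
    scale = max(eig.max(), 1.0)
    if eig.min() < -1e-8 * scale:
        raise ValueError("covariance matrix is not positive semi-definite")
    jitter = max(0.0, -eig.min()) + 1e-12 * scale
    return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))


def simulate_confidence_intervals(
    fit_under: FirthFit,
    fit_over: FirthFit,
    design: EhrDesign,
    age_distribution: dict,
    n_draws: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulation CIs for the standardized per-breed probabilities.

    Coefficient vectors are drawn from each fit's multivariate normal
    (mean = estimate, covariance = inverse Fisher information),
    independently for the two binomials; the standardized probabilities are
    recomputed per draw and the interval is the empirical (alpha/2,
    1 - alpha/2) quantile band.
    """
    if n_draws < 100:
        warnings.warn(f"n_draws={n_draws} is small; CIs will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    grid, cell_w = _standardization_grid(design, age_distribution)
    G = design.matrix(grid)
    n_breeds = len(design.breed_levels)
    n_cells = len(grid) // n_breeds

    etas = []
    for fit in (fit_under, fit_over):
        L = _psd_cholesky(fit.covariance)
        z = rng.standard_normal((fit.coefficients.size, n_draws))
        draws = fit.coefficients[:, None] + L @ z
        G_fit = G if fit.design_indices is None else G[:, fit.design_indices]
        etas.append(G_fit @ draws)
    eta_u, eta_o = etas           # cells x draws
    probs = merge_binomials(eta_u, eta_o)  # cells x draws x 3
    per_breed = (probs * cell_w[:, None, None]).reshape(
        n_breeds, n_cells, n_draws, 3
    ).sum(axis=1)                 # breeds x draws x 3
    alpha = 1.0 - level
    lo = np.quantile(per_breed, alpha / 2.0, axis=1)
    hi = np.quantile(per_breed, 1.0 - alpha / 2.0, axis=1)
    out = pd.DataFrame({"breed": design.breed_levels})
    for k, cat in enumerate(BCS_CATEGORIES):
        out[f"ci_low_{cat}"] = lo[:, k]
        out[f"ci_high_{cat}"] = hi[:, k]
    out["n_draws"] = n_draws
    return out


def breed_probability_table(
    fit_under: FirthFit,
    fit_over: FirthFit,
    design: EhrDesign,
    age_distribution: dict,
    n_draws: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Point standardized probabilities plus simulation CIs, one row per breed."""
    points = standardized_breed_probabilities(fit_under, fit_over, design,
                                              age_distribution)
    cis = simulate_confidence_intervals(fit_under, fit_over, design,
                                        age_distribution, n_draws=n_draws,
                                        level=level, seed=seed)
    return points.merge(cis, on="breed", validate="one_to_one")


def population_age_distribution(records: pd.DataFrame,
                                age_col: str = "age_years") -> dict:
    """Empirical whole-population age weights used for standardization."""
    counts = records[age_col].value_counts(normalize=True).sort_index()
    return {age: float(wi) for age, wi in counts.items()}
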