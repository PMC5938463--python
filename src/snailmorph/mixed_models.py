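"""Mixed models with haplotype and genotype-nested-in-haplotype random
intercepts: profiled-likelihood LMM, Laplace-approximate GLMMs, marginal and
conditional R-squared, type-II Wald tests, and backward model reduction.

The marginal covariance of the LMM is V = sigma^2 (I + g1 Z1 Z1' + g2 Z2 Z2')
with Z1, Z2 the indicator matrices of the two grouping factors.  Because the
combined random-effect design has only q = (number of haplotypes + number of
genotypes) columns, all determinants and solves use the Woodbury identity on
q x q matrices, so fits at n in the thousands are cheap.  Variance
components are constrained non-negative; boundary estimates are reported as
exact zeros with a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator


class NestingViolationError(ValueError):
    """A genotype level mapped to more than one haplotype."""


class ConvergenceError(RuntimeError):
    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

FLOW_LEVELS = {"none": 0, "low": 1, "high": 2}
TURBIDITY_LEVELS = {"clear": 0, "unclear": 1}


@dataclass
class ModelSpec:
    """Declarative model description.

    ``fixed`` lists covariate column names; ``ordinal`` maps categorical
    columns to their level ordering; ``interactions`` lists (a, b) product
    terms formed after standardization; ``random`` names the outer and the
    nested grouping columns.
    """

    response: str
    family: str = "gaussian"  # gaussian | binomial | poisson
    fixed: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    random: tuple[str, str] = ("haplotype", "genotype")
    ordinal: dict[str, dict[str, int]] = field(
        default_factory=lambda: {"flow": dict(FLOW_LEVELS), "turbidity": dict(TURBIDITY_LEVELS)}
    )
    standardize: bool = True


@dataclass
class DesignMatrices:
    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    terms: dict[str, list[int]]  # term -> coefficient column indices
    group_outer: np.ndarray  # haplotype index per row
    group_inner: np.ndarray  # genotype index per row (nested)
    outer_levels: list
    inner_levels: list
    n_excluded: int = 0
    spec: ModelSpec | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]


def build_design(data: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Build model matrices and nested grouping indices from a merged table.

    Continuous predictors are standardized to mean 0, sd 1; ordinal columns
    become integer scores; interaction columns are products formed after
    standardization.  Rows with missing response or grouping are excluded
    (the count is recorded).  Genotype levels appearing under more than one
    haplotype raise :class:`NestingViolationError`.
    """
    outer_col, inner_col = spec.random
    needed = [spec.response, outer_col, inner_col] + list(spec.fixed)
    df = data[needed].copy()
    before = len(df)
    df = df.dropna()
    n_excluded = before - len(df)
    if len(df) == 0:
        raise ValueError("no complete rows left after exclusions")

    nesting = df.groupby(inner_col)[outer_col].nunique()
    if (nesting > 1).any():
        bad = nesting[nesting > 1].index.tolist()
        raise NestingViolationError(f"genotype level(s) {bad} appear under multiple haplotypes")

    cols = {"Intercept": np.ones(len(df))}
    terms: dict[str, list[int]] = {"Intercept": [0]}
    std: dict[str, np.ndarray] = {}
    for name in spec.fixed:
        series = df[name]
        if name in spec.ordinal:
            vals = series.map(spec.ordinal[name])
            if vals.isna().any():
                raise ValueError(f"unknown level in ordinal column {name!r}")
            x = vals.to_numpy(float)
        else:
            x = pd.to_numeric(series).to_numpy(float)
        if x.std() == 0:
            raise ValueError(f"column {name!r} is constant")
        if spec.standardize:
            x = (x - x.mean()) / x.std(ddof=0)
        std[name] = x
        terms[name] = [len(cols)]
        cols[name] = x
    for a, b in spec.interactions:
        name = f"{a}:{b}"
        terms[name] = [len(cols)]
        cols[name] = std[a] * std[b]

    X = np.column_stack(list(cols.values()))
    y = pd.to_numeric(df[spec.response]).to_numpy(float)
    outer_levels = sorted(df[outer_col].unique().tolist())
    inner_levels = sorted(df[inner_col].unique().tolist())
    outer_idx = df[outer_col].map({g: i for i, g in enumerate(outer_levels)}).to_numpy()
    inner_idx = df[inner_col].map({g: i for i, g in enumerate(inner_levels)}).to_numpy()
    return DesignMatrices(
        X=X, y=y, columns=list(cols), terms=terms,
        group_outer=outer_idx, group_inner=inner_idx,
        outer_levels=outer_levels, inner_levels=inner_levels,
        n_excluded=n_excluded, spec=spec,
    )


def _indicator(idx: np.ndarray, n_levels: int) -> np.ndarray:
    z = np.zeros((len(idx), n_levels))
    z[np.arange(len(idx)), idx] = 1.0
    return z


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    """Coefficients, variance components and fit diagnostics of a mixed model."""

    coefficients: pd.Series
    standard_errors: pd.Series
    cov_params: np.ndarray
    variance_components: dict[str, float]
    log_likelihood: float
    method: str
    family: str
    design: DesignMatrices
    boundary: dict[str, bool] = field(default_factory=dict)
    converged: bool = True
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    wald_table: pd.DataFrame | None = None
    random_effects: dict[str, np.ndarray] = field(default_factory=dict)
    dispersion_note: str | None = None

    def fixed_linear_predictor(self) -> np.ndarray:
        return self.design.X @ self.coefficients.to_numpy()

    def effect_directions(self) -> pd.DataFrame:
        """Sign and plain-language direction per non-intercept coefficient."""
        rows = []
        for name, beta in self.coefficients.items():
            if name == "Intercept":
                continue
            sign = int(np.sign(beta))
            rows.append({
                "term": name, "coefficient": float(beta), "sign": sign,
                "direction": "positive" if sign > 0 else ("negative" if sign < 0 else "null"),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gaussian LMM by profiled likelihood
# ---------------------------------------------------------------------------

def _lmm_profile(theta, X, y, Z, q1, reml):
    """Profiled -2 log-likelihood at variance ratios exp(theta).

    Returns (neg2loglik, beta, cov_unscaled, sigma2, extras).
    """
    g1, g2 = np.exp(theta)
    n, p = X.shape
    scale = np.concatenate([np.full(q1, math.sqrt(g1)), np.full(Z.shape[1] - q1, math.sqrt(g2))])
    A = Z * scale  # n x q
    M = np.eye(Z.shape[1]) + A.T @ A
    M_chol = np.linalg.cholesky(M)
    logdet_v = 2 * np.log(np.diag(M_chol)).sum()

    def vinv(B):
        # (I + AA')^{-1} B via Woodbury
        AtB = A.T @ B
        return B - A @ np.linalg.solve(M, AtB)

    WX = vinv(X)
    Wy = vinv(y)
    XtWX = X.T @ WX
    XtWy = X.T @ Wy
    beta = np.linalg.solve(XtWX, XtWy)
    r = y - X @ beta
    rss = float(r @ vinv(r))
    if reml:
        sigma2 = rss / (n - p)
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        neg2 = ((n - p) * math.log(2 * math.pi * sigma2) + logdet_v
                + logdet_xwx + (n - p))
    else:
        sigma2 = rss / n
        neg2 = n * math.log(2 * math.pi * sigma2) + logdet_v + n
    return neg2, beta, np.linalg.inv(XtWX), sigma2, (A, M)


class LinearMixedModel(BaseEstimator):
    """Gaussian LMM with two independent (nested) random intercept factors.

    The likelihood is profiled over the variance ratios g_j = sigma_j^2 /
    sigma^2 and maximised numerically on the log-ratio scale with multiple
    starts; fixed effects follow by generalized least squares at the
    optimum.  Ratios collapsing to the boundary are reported as exact zero
    variance components with a flag.

    Parameters
    ----------
    method : "ml" or "reml"
    n_starts : int
        Multi-start count for the ratio optimization (guards local optima).
    """

    def __init__(self, method: str = "ml", n_starts: int = 3, boundary_tol: float = 1e-6):
        self.method = method
        self.n_starts = n_starts
        self.boundary_tol = boundary_tol

    def fit(self, design: DesignMatrices, y=None) -> "LinearMixedModel":
        X = design.X
        yv = design.y if y is None else np.asarray(y, float)
        n, p = X.shape
        if n <= p + 2:
            raise ValueError("too few observations for the fixed-effect structure")
        q1 = len(design.outer_levels)
        q2 = len(design.inner_levels)
        Z = np.hstack([_indicator(design.group_outer, q1),
                       _indicator(design.group_inner, q2)])
        reml = self.method == "reml"

        starts = [(-2.0, -2.0), (0.0, 0.0), (2.0, -1.0)][: self.n_starts]
        best = None
        for s in starts:
            res = optimize.minimize(
                lambda th: _lmm_profile(th, X, yv, Z, q1, reml)[0],
                x0=np.array(s), method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        if not best.success and best.fun == np.inf:
            raise ConvergenceError("LMM optimization failed", last_iterate=best.x)

        theta = best.x
        g = np.exp(theta)
        boundary = {"haplotype": False, "genotype_in_haplotype": False}
        # boundary handling: ratios driven to ~0 are re-evaluated at exactly 0
        for j, key in enumerate(boundary):
            if g[j] < self.boundary_tol:
                g[j] = 0.0
                boundary[key] = True
        theta_eff = np.log(np.where(g > 0, g, 1e-300))
        neg2, beta, cov_unscaled, sigma2, _ = _lmm_profile(theta_eff, X, yv, Z, q1, reml)

        vc = {
            "haplotype": float(g[0] * sigma2),
            "genotype_in_haplotype": float(g[1] * sigma2),
            "residual": float(sigma2),
        }
        cov = cov_unscaled * sigma2
        se = np.sqrt(np.diag(cov))
        self.fit_ = MixedModelFit(
            coefficients=pd.Series(beta, index=design.columns),
            standard_errors=pd.Series(se, index=design.columns),
            cov_params=cov,
            variance_components=vc,
            log_likelihood=-0.5 * neg2,
            method=self.method.upper(),
            family="gaussian",
            design=design,
            boundary=boundary,
            converged=bool(best.success),
        )
        return self

    def predict(self, design: DesignMatrices) -> np.ndarray:
        return design.X @ self.fit_.coefficients.to_numpy()


def fit_lmm(design: DesignMatrices, method: str = "ml") -> MixedModelFit:
    """Functional wrapper over :class:`LinearMixedModel`."""
    return LinearMixedModel(method=method).fit(design).fit_


# ---------------------------------------------------------------------------
# GLMM by Laplace approximation with PIRLS inner loop
# ---------------------------------------------------------------------------

def _family_funs(family):
    if family == "poisson":
        def loglik(y, eta):
            lam = np.exp(eta)
            return float((y * eta - lam - special.gammaln(y + 1)).sum())

        def mu_w(eta):
            lam = np.exp(np.clip(eta, -30, 30))
            return lam, lam
    elif family == "binomial":
        def loglik(y, eta):
            return float((y * eta - np.logaddexp(0.0, eta)).sum())

        def mu_w(eta):
            mu = special.expit(eta)
            return mu, np.clip(mu * (1 - mu), 1e-10, None)
    else:
        raise ValueError(f"unsupported family {family!r}")
    return loglik, mu_w


def _glmm_laplace(log_sig2, X, y, Z, q1, family):
    """Negative Laplace-approximate marginal log-likelihood; also returns the
    joint (beta, u) mode and its covariance pieces."""
    s1, s2 = np.exp(log_sig2)
    q = Z.shape[1]
    dinv = np.concatenate([np.full(q1, 1 / max(s1, 1e-12)),
                           np.full(q - q1, 1 / max(s2, 1e-12))])
    loglik, mu_w = _family_funs(family)
    n, p = X.shape
    C = np.hstack([X, Z])
    coef = np.zeros(p + q)
    pen = np.concatenate([np.zeros(p), dinv])
    prev = -np.inf
    for _ in range(100):
        eta = C @ coef
        mu, w = mu_w(eta)
        z = eta + (y - mu) / w
        cw = C * w[:, None]
        H = C.T @ cw
        H[np.arange(p + q), np.arange(p + q)] += pen
        coef_new = np.linalg.solve(H, cw.T @ z)
        # step-halving on the penalized objective
        for _ in range(20):
            eta_new = C @ coef_new
            obj = loglik(y, eta_new) - 0.5 * float((pen * coef_new**2).sum())
            if np.isfinite(obj) and obj >= prev - 1e-8:
                break
            coef_new = 0.5 * (coef_new + coef)
        if abs(obj - prev) < 1e-10 * (1 + abs(obj)):
            coef = coef_new
            break
        coef, prev = coef_new, obj
    eta = C @ coef
    mu, w = mu_w(eta)
    u = coef[p:]
    # Laplace: log L = ll(y|mode) - 0.5 u'D^-1 u - 0.5 log|I + D Z'WZ|
    zw = Z * w[:, None]
    ztwz = Z.T @ zw
    _, logdet = np.linalg.slogdet(np.eye(q) + ztwz * (1 / dinv)[None, :])
    ll = loglik(y, eta) - 0.5 * float((dinv * u**2).sum()) - 0.5 * logdet
    # covariance of beta at the mode (from the joint Hessian)
    cw = C * w[:, None]
    H = C.T @ cw
    H[np.arange(p + q), np.arange(p + q)] += pen
    cov_joint = np.linalg.inv(H)
    return -ll, coef[:p], u, cov_joint[:p, :p], eta


class GeneralizedLinearMixedModel(BaseEstimator):
    """Laplace-approximate GLMM (binomial-logit or poisson-log) with the same
    nested random-intercept structure as :class:`LinearMixedModel`.

    The inner loop is penalized iteratively reweighted least squares on the
    joint (beta, u) vector; the outer loop maximises the Laplace marginal
    likelihood over the two log-variances with multiple starts.
    """

    def __init__(self, family: str = "poisson", n_starts: int = 3,
                 boundary_tol: float = 1e-5):
        self.family = family
        self.n_starts = n_starts
        self.boundary_tol = boundary_tol

    def fit(self, design: DesignMatrices, y=None) -> "GeneralizedLinearMixedModel":
        X = design.X
        yv = design.y if y is None else np.asarray(y, float)
        if self.family == "binomial" and not set(np.unique(yv)) <= {0.0, 1.0}:
            raise ValueError("binomial family requires a 0/1 response")
        if self.family == "poisson" and np.any(yv < 0):
            raise ValueError("poisson family requires non-negative counts")
        q1 = len(design.outer_levels)
        q2 = len(design.inner_levels)
        Z = np.hstack([_indicator(design.group_outer, q1),
                       _indicator(design.group_inner, q2)])

        starts = [(-3.0, -3.0), (0.0, -1.0), (1.0, 0.0)][: self.n_starts]
        best = None
        for s in starts:
            res = optimize.minimize(
                lambda th: _glmm_laplace(th, X, yv, Z, q1, self.family)[0],
                x0=np.array(s), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 1000},
            )
            if best is None or res.fun < best.fun:
                best = res
        sig2 = np.exp(best.x)
        boundary = {"haplotype": False, "genotype_in_haplotype": False}
        for j, key in enumerate(boundary):
            if sig2[j] < self.boundary_tol:
                sig2[j] = 0.0
                boundary[key] = True
        log_eff = np.log(np.where(sig2 > 0, sig2, 1e-300))
        negll, beta, u, cov_beta, eta = _glmm_laplace(log_eff, X, yv, Z, q1, self.family)

        se = np.sqrt(np.diag(cov_beta))
        mu, w = _family_funs(self.family)[1](eta)
        if self.family == "binomial" and (np.min(w) < 1e-9 or np.max(np.abs(beta)) > 15):
            warnings.warn("possible complete separation: inflated standard errors",
                          RuntimeWarning)
        self.fit_ = MixedModelFit(
            coefficients=pd.Series(beta, index=design.columns),
            standard_errors=pd.Series(se, index=design.columns),
            cov_params=cov_beta,
            variance_components={
                "haplotype": float(sig2[0]),
                "genotype_in_haplotype": float(sig2[1]),
            },
            log_likelihood=-negll,
            method="Laplace",
            family=self.family,
            design=design,
            boundary=boundary,
            converged=bool(best.success),
            random_effects={"u": u},
        )
        return self


def fit_glmm(design: DesignMatrices, family: str = "poisson") -> MixedModelFit:
    """Functional wrapper over :class:`GeneralizedLinearMixedModel`."""
    return GeneralizedLinearMixedModel(family=family).fit(design).fit_


# ---------------------------------------------------------------------------
# Marginal / conditional R-squared
# ---------------------------------------------------------------------------

def r2_nakagawa(fit: MixedModelFit, poisson_method: str = "trigamma") -> tuple[float, float]:
    """Variance-partition R-squared for mixed models.

    R2_marginal = var(X beta) / (var(X beta) + sum(random variances) +
    distribution-specific variance); R2_conditional adds the random
    components to the numerator.  The distribution-specific variance is the
    residual variance (gaussian), pi^2/3 (binomial-logit), or the trigamma /
    lognormal approximation at the intercept-implied rate (poisson); the
    choice is recorded on the fit.
    """
    var_fixed = float(np.var(fit.fixed_linear_predictor()))
    vc = fit.variance_components
    var_random = sum(v for k, v in vc.items() if k != "residual")
    if fit.family == "gaussian":
        var_dist = vc["residual"]
    elif fit.family == "binomial":
        var_dist = math.pi**2 / 3
    elif fit.family == "poisson":
        beta0 = float(fit.coefficients.get("Intercept", 0.0))
        lam = math.exp(beta0 + 0.5 * var_random)
        if poisson_method == "trigamma":
            var_dist = float(special.polygamma(1, lam))
        else:
            var_dist = math.log1p(1.0 / lam)
        fit.dispersion_note = f"poisson distribution-specific variance: {poisson_method}"
    else:
        raise ValueError(f"unsupported family {fit.family!r}")
    total = var_fixed + var_random + var_dist
    if total <= 0:
        raise ValueError("zero total variance; R2 undefined")
    r2m = var_fixed / total
    r2c = (var_fixed + var_random) / total
    fit.r2_marginal, fit.r2_conditional = r2m, r2c
    return r2m, r2c


# ---------------------------------------------------------------------------
# Type-II Wald tests and backward reduction
# ---------------------------------------------------------------------------

def _interactions_containing(term: str, terms: dict[str, list[int]]) -> list[str]:
    return [t for t in terms if ":" in t and term in t.split(":") and t != term]


def _refit(design: DesignMatrices, keep_terms: list[str], fit: MixedModelFit) -> MixedModelFit:
    idx = sorted(i for t in keep_terms for i in design.terms[t])
    sub = DesignMatrices(
        X=design.X[:, idx], y=design.y,
        columns=[design.columns[i] for i in idx],
        terms={t: [idx.index(i) for i in design.terms[t]] for t in keep_terms},
        group_outer=design.group_outer, group_inner=design.group_inner,
        outer_levels=design.outer_levels, inner_levels=design.inner_levels,
        spec=design.spec,
    )
    if fit.family == "gaussian":
        return LinearMixedModel(method=fit.method.lower()).fit(sub).fit_
    return GeneralizedLinearMixedModel(family=fit.family).fit(sub).fit_


def wald_type2(fit: MixedModelFit) -> pd.DataFrame:
    """Type-II Wald chi-square table.

    Each term is tested in a refit containing all other terms except the
    interactions involving the tested term (marginality principle); the
    chi-square is beta' V^-1 beta over the term's coefficients with df equal
    to the coefficient count.
    """
    design = fit.design
    terms = [t for t in design.terms if t != "Intercept"]
    rows = []
    for term in terms:
        drop = set(_interactions_containing(term, design.terms))
        keep = [t for t in design.terms if t not in drop]
        sub_fit = fit if not drop else _refit(design, keep, fit)
        cols = sub_fit.design.terms[term]
        beta = sub_fit.coefficients.to_numpy()[cols]
        v = sub_fit.cov_params[np.ix_(cols, cols)]
        rank = np.linalg.matrix_rank(v)
        if rank < len(cols):
            warnings.warn(f"singular covariance for term {term!r}; rank-adjusted df",
                          RuntimeWarning)
        chi2 = float(beta @ np.linalg.pinv(v) @ beta)
        df = int(rank)
        rows.append({"term": term, "chi2": chi2, "df": df,
                     "p": float(stats.chi2.sf(chi2, df))})
    table = pd.DataFrame(rows, columns=["term", "chi2", "df", "p"])
    fit.wald_table = table
    return table


@dataclass
class ReductionStep:
    dropped: str
    p_value: float
    remaining: list[str]


def reduce_model(design: DesignMatrices, family: str = "gaussian",
                 alpha: float = 0.05, protected: tuple[str, ...] = ("Intercept",),
                 method: str = "ml") -> tuple[MixedModelFit, list[ReductionStep]]:
    """Backward model reduction by type-II Wald tests.

    Iteratively drops the least-significant droppable term (p > alpha);
    interactions are dropped before the main effects they contain, and a
    main effect is droppable only once no retained interaction involves it.
    Returns the final fit and the audit trail.
    """
    current = list(design.terms)
    trail: list[ReductionStep] = []
    fit0 = (LinearMixedModel(method=method).fit(design).fit_
            if family == "gaussian"
            else GeneralizedLinearMixedModel(family=family).fit(design).fit_)
    fit = fit0
    while True:
        table = wald_type2(fit)
        droppable = []
        for _, row in table.iterrows():
            t = row["term"]
            if t in protected:
                continue
            if ":" not in t and any(
                i in fit.design.terms for i in _interactions_containing(t, design.terms)
            ):
                continue
            droppable.append((row["p"], t))
        droppable = [d for d in droppable if d[0] > alpha]
        if not droppable:
            break
        droppable.sort(key=lambda x: (-x[0], x[1]))
        p_val, victim = droppable[0]
        current = [t for t in fit.design.terms if t != victim]
        fit = _refit(fit.design, current, fit0)
        trail.append(ReductionStep(dropped=victim, p_value=float(p_val), remaining=current[1:]))
        if len(current) == 1:  # intercept-only
            break
    return fit, trail
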