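"""Shape statistics: allometry correction, PCA/CVA ordination, group
mean-shape permutation tests, and Goodall's F repeatability test.

All routines operate on flattened Procrustes shape matrices of shape
(n_specimens, 2k) — the tangent-space representation in which Euclidean
distance approximates Procrustes distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .procrustes import AlignedShapeSet, gpa


def _as_flat(shapes) -> np.ndarray:
    if isinstance(shapes, AlignedShapeSet):
        return shapes.flat()
    arr = np.asarray(shapes, float)
    if arr.ndim == 3:
        return arr.reshape(arr.shape[0], -1)
    return arr


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------

class AllometricRegression(BaseEstimator, TransformerMixin):
    """Multivariate regression of Procrustes coordinates on centroid size.

    Each of the 2k coordinates is regressed on CS by least squares; the
    pooled R-squared is the summed predicted sum of squares over the summed
    total sum of squares, and its significance is assessed by permuting CS
    against the shapes.  ``transform`` returns the size-free residuals used
    in all downstream shape analyses.

    Parameters
    ----------
    n_permutations : int
        Rounds for the permutation test of the pooled R-squared (0 disables).
    log_cs : bool
        Regress on log(CS) instead of CS.
    random_state : int or None
        Seed for the permutation test.

    Attributes
    ----------
    slope_vector_ : ndarray of shape (2k,)
        Regression coefficients of each coordinate on CS.
    intercepts_ : ndarray of shape (2k,)
    r_squared_ : float
        Pooled predicted-SS / total-SS fraction.
    permutation_p_ : float or None
    residuals_ : ndarray of shape (n, 2k)
    """

    def __init__(self, n_permutations: int = 10000, log_cs: bool = False,
                 random_state: int | None = None):
        self.n_permutations = n_permutations
        self.log_cs = log_cs
        self.random_state = random_state

    def fit(self, X, y=None, centroid_sizes=None):
        if centroid_sizes is None and isinstance(X, AlignedShapeSet):
            centroid_sizes = X.centroid_sizes
        flat = _as_flat(X)
        cs = np.asarray(centroid_sizes, float)
        if flat.shape[0] < 3:
            raise ValueError("allometric regression requires n >= 3")
        x = np.log(cs) if self.log_cs else cs
        if np.var(x) == 0:
            raise ValueError("centroid size is constant (degenerate predictor)")

        xc = x - x.mean()
        yc = flat - flat.mean(axis=0)
        sxx = float(xc @ xc)
        beta = (xc @ yc) / sxx
        self.slope_vector_ = beta
        self.intercepts_ = flat.mean(axis=0) - beta * x.mean()
        predicted = np.outer(xc, beta)
        ss_pred = float((predicted**2).sum())
        ss_tot = float((yc**2).sum())
        self.r_squared_ = ss_pred / ss_tot if ss_tot > 0 else 0.0
        self.residuals_ = yc - predicted
        self._x_mean = x.mean()

        if self.n_permutations:
            rng = np.random.default_rng(self.random_state)
            count = 0
            for _ in range(self.n_permutations):
                xp = rng.permutation(xc)
                bp = (xp @ yc) / float(xp @ xp)
                if float(xp @ xp) * float(bp @ bp) >= ss_pred - 1e-15:
                    count += 1
            self.permutation_p_ = (1 + count) / (self.n_permutations + 1)
        else:
            self.permutation_p_ = None
        return self

    def transform(self, X, centroid_sizes=None) -> np.ndarray:
        if centroid_sizes is None and isinstance(X, AlignedShapeSet):
            centroid_sizes = X.centroid_sizes
        flat = _as_flat(X)
        cs = np.asarray(centroid_sizes, float)
        x = np.log(cs) if self.log_cs else cs
        return flat - self.intercepts_ - np.outer(x, self.slope_vector_)


def allometric_regression(aligned: AlignedShapeSet, n_perm: int = 10000,
                          seed: int | None = None, log_cs: bool = False) -> AllometricRegression:
    """Fit :class:`AllometricRegression` on an aligned shape set."""
    return AllometricRegression(n_permutations=n_perm, log_cs=log_cs,
                                random_state=seed).fit(aligned)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class ShapeSpace:
    """Ordination result: component scores and variance shares."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    loadings: np.ndarray
    kind: str = "pca"
    group_labels: np.ndarray | None = None


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    # sign convention: largest-magnitude entry of each column is positive
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


class ShapePCA(BaseEstimator, TransformerMixin):
    """Principal component analysis of shape residuals (covariance matrix).

    Procrustes coordinates are commensurate, so the covariance (not
    correlation) matrix is decomposed.  Variance percentages are computed
    over all axes and sum to 100.
    """

    def fit(self, X, y=None):
        flat = _as_flat(X)
        if flat.shape[0] < 2:
            raise ValueError("PCA requires n >= 2")
        self.mean_ = flat.mean(axis=0)
        centered = flat - self.mean_
        cov = centered.T @ centered / (flat.shape[0] - 1)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = _fix_signs(eigvec[:, order])
        self.eigenvalues_ = eigval
        self.components_ = eigvec
        total = eigval.sum()
        self.pct_variance_ = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
        self.scores_ = centered @ eigvec
        return self

    def transform(self, X) -> np.ndarray:
        return (_as_flat(X) - self.mean_) @ self.components_

    def inverse_transform(self, scores) -> np.ndarray:
        return np.asarray(scores) @ self.components_.T + self.mean_

    def result(self) -> ShapeSpace:
        return ShapeSpace(self.scores_, self.eigenvalues_, self.pct_variance_,
                          self.components_, kind="pca")


def pca(residuals) -> ShapeSpace:
    """Functional wrapper over :class:`ShapePCA`."""
    return ShapePCA().fit(residuals).result()


class ShapeCVA(BaseEstimator, TransformerMixin):
    """Canonical variate analysis maximising between- over within-group variation.

    The generalized eigenproblem of the between-group vs pooled within-group
    covariance is solved in the subspace spanned by the within-group
    covariance's non-null eigenvectors (rank truncation at relative
    eigenvalue ``rank_tol``); at most min(g - 1, rank) axes are retained.
    """

    def __init__(self, rank_tol: float = 1e-10):
        self.rank_tol = rank_tol

    def fit(self, X, y):
        flat = _as_flat(X)
        labels = np.asarray(y)
        groups = np.unique(labels)
        if len(groups) < 2:
            raise ValueError("CVA requires at least two groups")
        n, p = flat.shape
        grand = flat.mean(axis=0)
        w = np.zeros((p, p))
        b = np.zeros((p, p))
        for g in groups:
            sub = flat[labels == g]
            if sub.shape[0] < 2:
                raise ValueError(f"group {g!r} has fewer than 2 members")
            gm = sub.mean(axis=0)
            d = sub - gm
            w += d.T @ d
            b += sub.shape[0] * np.outer(gm - grand, gm - grand)
        w /= n - len(groups)
        b /= len(groups) - 1

        # whiten by the within-covariance restricted to its non-null subspace
        wval, wvec = np.linalg.eigh(w)
        keep = wval > self.rank_tol * wval.max()
        basis = wvec[:, keep] / np.sqrt(wval[keep])
        b_star = basis.T @ b @ basis
        eigval, eigvec = np.linalg.eigh(b_star)
        order = np.argsort(eigval)[::-1]
        n_axes = min(len(groups) - 1, int(keep.sum()))
        eigval = np.clip(eigval[order][:n_axes], 0.0, None)
        axes = _fix_signs(basis @ eigvec[:, order][:, :n_axes])
        self.eigenvalues_ = eigval
        self.canonical_axes_ = axes
        total = eigval.sum()
        self.pct_variance_ = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
        self.mean_ = grand
        self.scores_ = (flat - grand) @ axes
        self.groups_ = groups
        self._labels = labels
        return self

    def transform(self, X) -> np.ndarray:
        return (_as_flat(X) - self.mean_) @ self.canonical_axes_

    def result(self) -> ShapeSpace:
        return ShapeSpace(self.scores_, self.eigenvalues_, self.pct_variance_,
                          self.canonical_axes_, kind="cva", group_labels=self._labels)


def cva(residuals, group_labels) -> ShapeSpace:
    """Functional wrapper over :class:`ShapeCVA`."""
    return ShapeCVA().fit(residuals, group_labels).result()


# ---------------------------------------------------------------------------
# Group mean-shape distances with permutation tests
# ---------------------------------------------------------------------------

@dataclass
class GroupDistanceTable:
    group_labels: list
    distances: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    alpha: float = 0.05
    n_pairs: int = 0
    bonferroni_alpha: float = field(default=0.05)

    def to_frame(self):
        """Long-format table: group_a, group_b, distance, p, significant_bonferroni."""
        import pandas as pd

        rows = []
        g = self.group_labels
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                rows.append({
                    "group_a": g[i], "group_b": g[j],
                    "distance": self.distances[i, j],
                    "p": self.p_values[i, j],
                    "significant_bonferroni": self.p_values[i, j] < self.bonferroni_alpha,
                })
        return pd.DataFrame(rows)


def _null_distances(pooled: np.ndarray, n1: int, n_perm: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Distances between pseudo-group means under reshuffling (sizes preserved)."""
    n = pooled.shape[0]
    total = pooled.sum(axis=0)
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
    sum_a = pooled[idx].sum(axis=1)
    mean_a = sum_a / n1
    mean_b = (total - sum_a) / (n - n1)
    return np.linalg.norm(mean_a - mean_b, axis=1)


def pairwise_group_distances(shapes, group_labels, n_perm: int = 10000,
                             seed: int | None = None,
                             alpha: float = 0.05) -> GroupDistanceTable:
    """Pairwise distances between group mean shapes with permutation tests.

    Distance is the Euclidean (tangent-space Procrustes) distance between the
    two group mean shape vectors.  For each pair, the null distribution is
    obtained by reshuffling that pair's specimens between the two groups with
    group sizes preserved; p = (1 + #{null >= observed}) / (n_perm + 1).  The
    Bonferroni-adjusted alpha (alpha / n_pairs) is reported alongside,
    mirroring an adjusted significance level rather than adjusted p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    flat = _as_flat(shapes)
    labels = np.asarray(group_labels)
    groups = list(dict.fromkeys(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    g = len(groups)
    rng = np.random.default_rng(seed)
    dist = np.zeros((g, g))
    pmat = np.ones((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            a = flat[labels == groups[i]]
            b = flat[labels == groups[j]]
            observed = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
            pooled = np.vstack([a, b])
            null = _null_distances(pooled, a.shape[0], n_perm, rng)
            p = (1 + int((null >= observed - 1e-15).sum())) / (n_perm + 1)
            dist[i, j] = dist[j, i] = observed
            pmat[i, j] = pmat[j, i] = p
    n_pairs = g * (g - 1) // 2
    return GroupDistanceTable(
        group_labels=groups, distances=dist, p_values=pmat,
        n_permutations=n_perm, alpha=alpha, n_pairs=n_pairs,
        bonferroni_alpha=alpha / n_pairs,
    )


# ---------------------------------------------------------------------------
# Goodall's F
# ---------------------------------------------------------------------------

@dataclass
class GoodallResult:
    f_value: float
    df_num: int
    df_den: int
    p_value: float
    n1: int
    n2: int


def goodall_f(group_a, group_b, already_aligned: bool = False) -> GoodallResult:
    """Goodall's F test comparing two groups' mean shapes.

    Used here as a repeatability test (two digitisation rounds of the same
    specimens should give F near 0, p near 1).  The statistic is

        F = [d^2 / (1/n1 + 1/n2)] / [SS_within / (n1 + n2 - 2)]

    with d the distance between the group mean shapes after joint Procrustes
    superimposition and SS_within the pooled within-group sum of squared
    deviations from the group means.  Degrees of freedom are q = 2k - 4 and
    q (n1 + n2 - 2), the shape-space dimension for 2-D landmarks.
    """
    a = [np.asarray(x, float) for x in group_a]
    b = [np.asarray(x, float) for x in group_b]
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("Goodall's F requires n >= 2 in each group")
    k = a[0].shape[0]
    if already_aligned:
        flat = np.stack([x.ravel() for x in a + b])
    else:
        flat = gpa(a + b).flat()
    ma = flat[:n1].mean(axis=0)
    mb = flat[n1:].mean(axis=0)
    d2 = float(((ma - mb) ** 2).sum())
    ssw = float(((flat[:n1] - ma) ** 2).sum() + ((flat[n1:] - mb) ** 2).sum())
    q = 2 * k - 4
    df_den = q * (n1 + n2 - 2)
    if ssw == 0.0:
        f = 0.0 if d2 == 0.0 else np.inf
    else:
        f = (d2 / (1 / n1 + 1 / n2)) / (ssw / (n1 + n2 - 2))
    p = float(stats.f.sf(f, q, df_den)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0
    return GoodallResult(f_value=f, df_num=q, df_den=df_den, p_value=p, n1=n1, n2=n2)
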