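"""Generalized Procrustes analysis (GPA) and Procrustes distances.

Partial Procrustes superimposition: each configuration is centred at the
origin, scaled to unit centroid size, and rotated onto the running consensus
by the optimal orthogonal rotation with determinant +1 (reflections are
disallowed by default because shells are chiral).  The consensus is
recomputed and the procedure iterated to convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .landmarks import LandmarkConfiguration, centroid_size


class ShapeMismatchError(ValueError):
    """Raised when two shapes have different landmark counts."""


@dataclass
class AlignedShapeSet:
    """Procrustes-aligned configurations with their consensus.

    ``aligned_coords`` has shape (n, k, 2); every configuration is centred at
    the origin with unit centroid size.  ``centroid_sizes`` retains the
    original sizes in mm.
    """

    specimen_ids: list[str]
    aligned_coords: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    tangent_projected: bool = False
    iterations_used: int = 0
    convergence_delta: float = np.nan
    converged: bool = True

    @property
    def n_specimens(self) -> int:
        return self.aligned_coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned_coords.shape[1]

    def flat(self) -> np.ndarray:
        """Coordinates flattened to an (n, 2k) matrix (x1, y1, x2, y2, ...)."""
        n = self.n_specimens
        return self.aligned_coords.reshape(n, -1)


def _center_and_scale(pts: np.ndarray) -> tuple[np.ndarray, float]:
    centered = pts - pts.mean(axis=0)
    cs = centroid_size(centered)
    return centered / cs, cs


def optimal_rotation(src: np.ndarray, dst: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Rotation matrix R minimising ||src @ R - dst||_F.

    With ``allow_reflection=False`` the solution is restricted to det(R) = +1.
    """
    u, _, vt = np.linalg.svd(src.T @ dst)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Iterative generalized Procrustes superimposition.

    Parameters
    ----------
    tol : float
        Convergence threshold on the root-mean-square change of the
        consensus between iterations.
    max_iter : int
        Maximum number of consensus updates; non-convergence sets a warning
        flag on the result rather than raising.
    allow_reflection : bool
        Permit improper rotations in the fits (off by default: shells are
        chiral).
    tangent_project : bool
        Project the aligned coordinates onto the tangent space at the
        consensus after convergence.

    Attributes
    ----------
    consensus_ : ndarray of shape (k, 2)
        Mean shape at convergence (unit centroid size).
    result_ : AlignedShapeSet
        Full alignment of the training configurations.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100,
                 allow_reflection: bool = False, tangent_project: bool = False):
        self.tol = tol
        self.max_iter = max_iter
        self.allow_reflection = allow_reflection
        self.tangent_project = tangent_project

    def _coerce(self, configs) -> tuple[list[str], np.ndarray]:
        ids, arrays = [], []
        for i, c in enumerate(configs):
            if isinstance(c, LandmarkConfiguration):
                ids.append(c.specimen_id)
                arrays.append(c.points)
            else:
                ids.append(str(i))
                arrays.append(np.asarray(c, float))
        k = arrays[0].shape[0]
        for arr, sid in zip(arrays, ids):
            if arr.shape[0] != k:
                raise ShapeMismatchError(
                    f"specimen {sid}: {arr.shape[0]} landmarks, expected {k}"
                )
        return ids, np.stack(arrays)

    def fit(self, X, y=None) -> "GeneralizedProcrustes":
        ids, pts = self._coerce(X)
        n = pts.shape[0]
        if n < 2:
            raise ValueError("GPA requires at least two configurations")
        scaled = np.empty_like(pts)
        sizes = np.empty(n)
        for i in range(n):
            scaled[i], sizes[i] = _center_and_scale(pts[i])

        consensus = scaled[0].copy()
        aligned = scaled.copy()
        delta = np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            for i in range(n):
                r = optimal_rotation(scaled[i], consensus, self.allow_reflection)
                aligned[i] = scaled[i] @ r
            new_consensus = aligned.mean(axis=0)
            # keep consensus at unit centroid size so tol is scale-free
            new_consensus /= centroid_size(new_consensus)
            delta = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
            consensus = new_consensus
            if delta < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"GPA did not converge in {self.max_iter} iterations (delta={delta:.3e})",
                RuntimeWarning,
            )
        # canonical orientation: rotate the solution onto the configuration
        # with the lexicographically smallest id, so the result does not
        # depend on input order
        anchor = ids.index(min(ids))
        r_canon = optimal_rotation(consensus, scaled[anchor], self.allow_reflection)
        consensus = consensus @ r_canon
        # final alignment pass onto the converged, canonically oriented consensus
        for i in range(n):
            r = optimal_rotation(scaled[i], consensus, self.allow_reflection)
            aligned[i] = scaled[i] @ r

        result = AlignedShapeSet(
            specimen_ids=ids,
            aligned_coords=aligned,
            consensus=aligned.mean(axis=0),
            centroid_sizes=sizes,
            iterations_used=it,
            convergence_delta=delta,
            converged=converged,
        )
        if self.tangent_project:
            result = tangent_project(result)
        self.consensus_ = result.consensus
        self.result_ = result
        return self

    def transform(self, X) -> np.ndarray:
        """Align new configurations onto the fitted consensus; returns (n, k, 2)."""
        _, pts = self._coerce(X)
        out = np.empty_like(pts, dtype=float)
        for i in range(pts.shape[0]):
            scaled, _ = _center_and_scale(pts[i])
            out[i] = scaled @ optimal_rotation(scaled, self.consensus_, self.allow_reflection)
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).result_.aligned_coords


def gpa(configs, tol: float = 1e-10, max_iter: int = 100,
        allow_reflection: bool = False) -> AlignedShapeSet:
    """Functional wrapper over :class:`GeneralizedProcrustes`."""
    est = GeneralizedProcrustes(tol=tol, max_iter=max_iter, allow_reflection=allow_reflection)
    return est.fit(configs).result_


def tangent_project(aligned: AlignedShapeSet) -> AlignedShapeSet:
    """Orthogonally project aligned shapes onto the tangent space at the consensus.

    The projection removes the component along the consensus direction and
    restores it, i.e. x -> c + (x - (x.c) c) with c the unit-norm consensus;
    it is idempotent and maps the consensus to itself.
    """
    c = aligned.consensus.ravel()
    c = c / np.linalg.norm(c)
    flat = aligned.flat()
    coef = flat @ c
    projected = flat - np.outer(coef - 1.0, c)
    coords = projected.reshape(aligned.aligned_coords.shape)
    return AlignedShapeSet(
        specimen_ids=list(aligned.specimen_ids),
        aligned_coords=coords,
        consensus=coords.mean(axis=0),
        centroid_sizes=aligned.centroid_sizes.copy(),
        tangent_projected=True,
        iterations_used=aligned.iterations_used,
        convergence_delta=aligned.convergence_delta,
        converged=aligned.converged,
    )


@dataclass
class ShapeDistance:
    value: float
    pair: tuple[str, str] = ("a", "b")


def procrustes_distance(shape_a, shape_b, allow_reflection: bool = False) -> float:
    """Procrustes distance between two configurations.

    Both shapes are centred and scaled to unit centroid size, shape_b is
    rotated optimally onto shape_a, and the root summed squared coordinate
    difference is returned.  Symmetric; zero iff the shapes are identical up
    to a similarity transform.
    """
    a = shape_a.points if isinstance(shape_a, LandmarkConfiguration) else np.asarray(shape_a, float)
    b = shape_b.points if isinstance(shape_b, LandmarkConfiguration) else np.asarray(shape_b, float)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"landmark counts differ: {a.shape[0]} vs {b.shape[0]}")
    a, _ = _center_and_scale(a)
    b, _ = _center_and_scale(b)
    r = optimal_rotation(b, a, allow_reflection)
    return float(np.sqrt(((b @ r - a) ** 2).sum()))


def export_aligned_csv(aligned: AlignedShapeSet, path) -> None:
    """Write aligned coordinates as CSV: specimen_id, lm1_x ... lmK_y, cs."""
    import pandas as pd

    k = aligned.n_landmarks
    cols = [f"lm{i + 1}_{ax}" for i in range(k) for ax in ("x", "y")]
    df = pd.DataFrame(aligned.flat(), columns=cols)
    df.insert(0, "specimen_id", aligned.specimen_ids)
    df["cs"] = aligned.centroid_sizes
    df.to_csv(path, index=False)
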