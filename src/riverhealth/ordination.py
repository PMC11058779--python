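"""Bray-Curtis dissimilarity and nonmetric multidimensional scaling.

The ordination is the analytical heart of the package: community tables
(entity relative abundances, or range-standardized biotic-integrity metric
values) are converted to Bray-Curtis dissimilarities and embedded in a low-
dimensional space by nonmetric multidimensional scaling (NMDS).  Site scores
along the first NMDS axis then serve as a continuous ecological-health
ordinate that can be regressed on chemical stressor gradients.

NMDS here is the classic Kruskal formulation, written out in full rather than
delegated: badness of fit is stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

where d_ij are configuration (Euclidean) distances and dhat_ij are disparity
values — the least-squares monotone (isotonic) regression of d on the rank
order of the input dissimilarities, fitted by pool-adjacent-violators (PAV).
The configuration is improved by steepest descent on stress with a
step-halving line search, restarted from several seeded random
configurations; the best start wins.  Ties in the dissimilarities are treated
weakly (primary approach): tied dissimilarities may take disparities in any
order, implemented by sub-sorting tied blocks by current configuration
distance before the isotonic fit.

Because an NMDS configuration is only defined up to rotation, reflection, and
scale, fitted coordinates are centered, rotated to principal axes, and given
a fixed sign convention so that repeated runs and downstream regressions are
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from ._utils import check_rng


# --- dissimilarity ----------------------------------------------------------

def bray_curtis(X, labels=None) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix of a site x feature table.

    d(i, j) = 1 - 2 * sum(min(x_i, x_j)) / sum(x_i + x_j), bounded in [0, 1]
    for non-negative features.  Accepts a DataFrame (labels from the index)
    or an array plus explicit labels.
    """
    if isinstance(X, pd.DataFrame):
        labels = list(X.index)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        labels = list(labels) if labels is not None else list(range(arr.shape[0]))
    if np.any(arr < 0):
        raise ValueError("Bray-Curtis requires non-negative features")
    row_sums = arr.sum(axis=1)
    zero = [labels[i] for i in np.flatnonzero(row_sums == 0)]
    if zero:
        raise ValueError(f"all-zero rows make Bray-Curtis undefined for sites: {zero}")
    d = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(d, index=labels, columns=labels)


def validate_distance_matrix(dm: pd.DataFrame) -> np.ndarray:
    d = dm.to_numpy(dtype=float) if isinstance(dm, pd.DataFrame) else np.asarray(dm, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    if np.any(d < 0):
        raise ValueError("distance matrix must be non-negative")
    return d


# --- isotonic regression ----------------------------------------------------

def pav_isotonic(y, weights=None) -> np.ndarray:
    """Least-squares non-decreasing fit by pool-adjacent-violators.

    Merges adjacent violating blocks into weighted block means until the
    sequence of means is non-decreasing.  Preserves the (weighted) total sum.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("pav_isotonic expects a non-empty 1-D array")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    # stack of blocks: (mean, weight, count)
    means: list[float] = []
    wts: list[float] = []
    cnts: list[int] = []
    for yi, wi in zip(y, w):
        means.append(float(yi))
        wts.append(float(wi))
        cnts.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, c2 = means.pop(), wts.pop(), cnts.pop()
            m1, w1, c1 = means.pop(), wts.pop(), cnts.pop()
            wt = w1 + w2
            means.append((m1 * w1 + m2 * w2) / wt)
            wts.append(wt)
            cnts.append(c1 + c2)
    out = np.empty_like(y)
    pos = 0
    for m, c in zip(means, cnts):
        out[pos : pos + c] = m
        pos += c
    return out


def stress1(d, dhat) -> float:
    """Kruskal stress-1 between configuration distances and disparities."""
    d = np.asarray(d, dtype=float)
    dhat = np.asarray(dhat, dtype=float)
    if d.shape != dhat.shape:
        raise ValueError("d and dhat must have identical shape")
    denom = float(np.sum(d * d))
    if denom == 0.0:
        raise ValueError("stress undefined: all configuration distances are zero")
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


# --- NMDS -------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Fitted NMDS configuration plus its convergence record."""

    coordinates: pd.DataFrame
    stress: float
    n_starts: int
    best_start: int
    n_iter: int
    converged: bool
    stress_trace: list[float] = field(default_factory=list)
    degenerate: bool = False


def _disparities(delta_flat: np.ndarray, d_flat: np.ndarray) -> np.ndarray:
    """Isotonic disparities of d against the dissimilarity order (weak ties)."""
    order = np.lexsort((d_flat, delta_flat))
    dhat = np.empty_like(d_flat)
    dhat[order] = pav_isotonic(d_flat[order])
    return dhat


def _stress_of(X: np.ndarray, delta_flat: np.ndarray):
    d_flat = pdist(X)
    # coincident points give zero distances; stress handles them, gradient guards
    dhat = _disparities(delta_flat, d_flat)
    return stress1(d_flat, dhat), d_flat, dhat


def _stress_gradient(
    X: np.ndarray, d_flat: np.ndarray, dhat: np.ndarray, stress: float
) -> np.ndarray:
    """dS/dX with disparities held fixed (Kruskal's descent direction)."""
    n, k = X.shape
    T = float(np.sum(d_flat * d_flat))
    U = float(np.sum((d_flat - dhat) ** 2))
    s = max(stress, 1e-12)
    # dS/dd_ij = (1/s) * ((d - dhat)/T - d * U / T^2)
    dS_dd = ((d_flat - dhat) / T - d_flat * U / T**2) / s
    safe_d = np.where(d_flat > 1e-12, d_flat, 1.0)
    coeff = squareform(dS_dd / safe_d)  # symmetric, zero diagonal
    # grad_i = sum_j coeff_ij * (x_i - x_j)
    grad = coeff.sum(axis=1, keepdims=True) * X - coeff @ X
    return grad


def nmds(
    dm,
    n_components: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    random_state=None,
    orient: bool = True,
    reference=None,
    init=None,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling of a dissimilarity matrix.

    Minimizes Kruskal stress-1 by alternating a PAV isotonic fit of the
    disparities with a steepest-descent configuration update under a
    step-halving line search; the best of ``n_starts`` seeded random starts
    is returned.  The stress trace within a start is non-increasing by
    construction.

    Parameters
    ----------
    dm : square DataFrame or array of dissimilarities.
    n_components : embedding dimension (2 gives the usual NMDS1/NMDS2 axes).
    n_starts, max_iter, tol : optimizer effort; ``tol`` is the relative
        stress improvement below which a start is declared converged.
    random_state : int or Generator; makes the fit reproducible.
    orient : center/rotate/sign-fix the winning configuration
        (see :func:`orient_axes`).
    reference : optional per-site covariate fixing axis signs.
    init : optional explicit starting configurations, shape
        (n_starts, n_sites, n_components); overrides the seeded random
        starts.  Because every optimizer step is permutation-equivariant,
        permuting sites and starts together permutes the fit identically.
    """
    labels = list(dm.index) if isinstance(dm, pd.DataFrame) else None
    d = validate_distance_matrix(dm)
    n = d.shape[0]
    if labels is None:
        labels = list(range(n))
    if n < n_components + 2:
        raise ValueError(f"need at least {n_components + 2} sites for a {n_components}-D NMDS")
    delta_flat = squareform(d, checks=False)
    if np.all(delta_flat == 0):
        raise ValueError("all dissimilarities are zero")
    rng = check_rng(random_state)
    scale = float(np.max(delta_flat))
    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.ndim == 2:
            init = init[None, :, :]
        if init.shape[1:] != (n, n_components):
            raise ValueError(
                f"init must have shape (n_starts, {n}, {n_components}), got {init.shape}"
            )
        n_starts = init.shape[0]

    best = None
    for start in range(n_starts):
        if init is not None:
            X = init[start].copy()
        else:
            X = rng.uniform(-0.5, 0.5, size=(n, n_components)) * scale
        stress, d_flat, dhat = _stress_of(X, delta_flat)
        trace = [stress]
        step = 0.2 * scale
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            grad = _stress_gradient(X, d_flat, dhat, stress)
            gnorm = float(np.linalg.norm(grad))
            if gnorm < 1e-14 or stress < 1e-12:
                converged = True
                break
            direction = grad / gnorm
            alpha = step
            improved = False
            for _ in range(30):
                Xn = X - alpha * direction
                s_new, d_new, dhat_new = _stress_of(Xn, delta_flat)
                if s_new < stress:
                    improved = True
                    break
                alpha *= 0.5
            if not improved:
                converged = True
                break
            rel = (stress - s_new) / max(stress, 1e-12)
            X, stress, d_flat, dhat = Xn, s_new, d_new, dhat_new
            trace.append(stress)
            step = min(alpha * 2.0, scale)
            if rel < tol:
                converged = True
                break
        cand = (stress, start, X, trace, converged, it)
        if best is None or cand[0] < best[0]:
            best = cand

    stress, start, X, trace, converged, it = best
    if not converged:
        warnings.warn("NMDS did not converge in any start; returning best configuration")
    degenerate = False
    if stress < 1e-6:
        # near-zero stress with near-duplicate points signals a degenerate fit
        d_final = pdist(X)
        if np.any(d_final < 1e-9 * max(scale, 1.0)):
            degenerate = True
    if orient:
        X = orient_axes(X, reference=reference)
    coords = pd.DataFrame(
        X, index=labels, columns=[f"NMDS{i + 1}" for i in range(n_components)]
    )
    return OrdinationResult(
        coordinates=coords,
        stress=stress,
        n_starts=n_starts,
        best_start=start,
        n_iter=it,
        converged=converged,
        stress_trace=trace,
        degenerate=degenerate,
    )


def orient_axes(coordinates, reference=None) -> np.ndarray:
    """Center, rotate to principal axes, and fix axis signs.

    Axis 1 carries the largest variance.  The sign of each axis is chosen so
    that its correlation with ``reference`` (a per-site covariate) is
    non-negative; without a reference, the element of largest magnitude on
    each axis is made positive.  Mirrored or rotated inputs therefore map to
    identical outputs.
    """
    X = np.asarray(coordinates, dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    # principal-axis rotation via SVD of the centered configuration
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if np.any(s < 1e-12 * max(s.max(initial=0.0), 1.0)):
        warnings.warn("zero-variance axis; skipping principal-axis rotation")
        Xr = X
    else:
        Xr = X @ Vt.T
    for j in range(Xr.shape[1]):
        col = Xr[:, j]
        if reference is not None:
            ref = np.asarray(reference, dtype=float)
            cov = float(np.dot(col - col.mean(), ref - ref.mean()))
            flip = cov < 0
            if cov == 0:
                flip = col[np.argmax(np.abs(col))] < 0
        else:
            flip = col[np.argmax(np.abs(col))] < 0
        if flip:
            Xr[:, j] = -col
    return Xr


def range_standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Scale each column to [0, 1] by its observed range.

    Used to make biotic-integrity metric values commensurate and non-negative
    before Bray-Curtis.  Constant columns map to 0.
    """
    arr = X.to_numpy(dtype=float)
    lo = np.nanmin(arr, axis=0)
    hi = np.nanmax(arr, axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return pd.DataFrame((arr - lo) / span, index=X.index, columns=X.columns)


class NMDS(BaseEstimator):
    """Estimator wrapper around :func:`nmds`.

    Parameters mirror the function; ``dissimilarity`` is ``"braycurtis"``
    (compute from a site x feature table) or ``"precomputed"``.

    Attributes
    ----------
    embedding_ : DataFrame of site scores (NMDS1, NMDS2, ...).
    stress_ : final Kruskal stress-1.
    result_ : full :class:`OrdinationResult`.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_starts: int = 20,
        max_iter: int = 300,
        tol: float = 1e-7,
        dissimilarity: str = "braycurtis",
        random_state=None,
    ):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.dissimilarity = dissimilarity
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.dissimilarity == "braycurtis":
            dm = bray_curtis(X)
            reference = (
                X.iloc[:, 0].to_numpy(dtype=float)
                if isinstance(X, pd.DataFrame)
                else np.asarray(X, float)[:, 0]
            )
        elif self.dissimilarity == "precomputed":
            dm = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
            reference = None
        else:
            raise ValueError(f"unknown dissimilarity {self.dissimilarity!r}")
        self.result_ = nmds(
            dm,
            n_components=self.n_components,
            n_starts=self.n_starts,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
            reference=reference,
        )
        self.embedding_ = self.result_.coordinates
        self.stress_ = self.result_.stress
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_
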