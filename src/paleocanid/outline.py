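"""Crown-outline geometric morphometrics.

This module implements the shape-analysis chain used to compare lower
first-molar (carnassial) crown outlines between canid groups:

1. arc-length resampling of a digitised closed outline into two curves of
   semilandmarks constrained by two homologous anchor landmarks,
2. sliding of the semilandmarks along their local tangents to remove the
   arbitrary-spacing artifact (minimising either thin-plate-spline bending
   energy against the Procrustes mean, or plain Procrustes distance),
3. generalized Procrustes analysis (GPA) producing unit-centroid-size,
   origin-centred shape coordinates with centroid size carried separately,
4. ordinary PCA and between-group PCA (bgPCA) of the shape coordinates,
   with a-posteriori projection of unknown specimens,
5. an allometry test regressing axis scores on log centroid size, and a
   descriptive group-assignment rule based on distances to group means.

The estimators follow scikit-learn conventions (``fit``/``transform``,
trailing-underscore fitted attributes) and operate on flattened ``(n, 2k)``
coordinate matrices; the module-level functions are thin wrappers that
accept the richer domain objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class Outline2D:
    """A closed 2D crown outline with two homologous anchor landmarks.

    Points are ordered along the curve and the outline is implicitly closed
    (the last point connects back to the first; the first point is *not*
    repeated).  ``anchors`` are indices into ``points``.
    """

    points: np.ndarray
    anchors: tuple[int, int]
    specimen_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("outline points must be an (m, 2) array")
        if len(self.points) < 4:
            raise ValueError("outline needs at least 4 points")
        i, j = self.anchors
        if i == j:
            raise ValueError("anchor landmarks must be distinct")
        m = len(self.points)
        if not (0 <= i < m and 0 <= j < m):
            raise ValueError("anchor indices out of range")

    def is_simple(self) -> bool:
        """True if the closed polygon does not self-intersect.

        Brute-force segment intersection test; outlines are a few hundred
        points so O(m^2) is acceptable.
        """
        p = self.points
        m = len(p)
        a = p
        b = np.roll(p, -1, axis=0)
        for s in range(m):
            # skip adjacent segments (share a vertex)
            others = [t for t in range(s + 2, m) if not (s == 0 and t == m - 1)]
            if not others:
                continue
            t = np.array(others)
            if _segments_intersect(a[s], b[s], a[t], b[t]).any():
                return False
        return True


def _segments_intersect(p1, p2, q1, q2):
    """Vectorised proper-intersection test of segment p1p2 vs segments q1q2."""
    def cross(o, a, b):
        return (a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1]) - (
            a[..., 1] - o[..., 1]
        ) * (b[..., 0] - o[..., 0])

    d1 = cross(q1, q2, p1[None, :])
    d2 = cross(q1, q2, p2[None, :])
    d3 = cross(p1[None, :], p2[None, :], q1)
    d4 = cross(p1[None, :], p2[None, :], q2)
    return (d1 * d2 < 0) & (d3 * d4 < 0)


@dataclass
class ShapeSet:
    """Procrustes-aligned configurations with pre-scaling centroid sizes."""

    coords: np.ndarray  # (n, k, 2), centred, unit centroid size
    centroid_sizes: np.ndarray  # (n,)
    specimen_ids: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    def flat(self) -> np.ndarray:
        return self.coords.reshape(self.n_specimens, -1)


# ---------------------------------------------------------------------------
# basic shape utilities
# ---------------------------------------------------------------------------

def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances of the points to their centroid."""
    p = np.asarray(points, dtype=float)
    c = p.mean(axis=0)
    return float(np.sqrt(((p - c) ** 2).sum()))


def signed_area(points: np.ndarray) -> float:
    """Signed polygon area (positive for counter-clockwise traversal)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def optimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation matrix R minimising ||src @ R - dst||_F (no reflection).

    Both configurations are assumed centred.
    """
    h = src.T @ dst
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _normalize(config: np.ndarray) -> tuple[np.ndarray, float]:
    """Centre a configuration and scale it to unit centroid size."""
    c = config - config.mean(axis=0)
    cs = np.sqrt((c**2).sum())
    if cs <= 0:
        raise ValueError("degenerate configuration: all points coincide")
    return c / cs, float(cs)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_outline(
    outline: Outline2D, counts: tuple[int, int] = (80, 60)
) -> np.ndarray:
    """Resample an outline into ``2 + counts[0] + counts[1]`` points.

    The output order is ``[anchor1, curve-1 semilandmarks, anchor2, curve-2
    semilandmarks]`` where curve 1 runs anchor1 -> anchor2 along the
    counter-clockwise traversal and curve 2 closes the loop.  Semilandmarks
    are equally spaced by arc length, exclusive of the anchors.

    Orientation is normalised: if the stored traversal from anchor 1 is
    clockwise the outline is mirrored across the x axis (right teeth are
    thereby mapped onto the left-form convention); rotation and position
    are left for the Procrustes step.
    """
    n1, n2 = counts
    if n1 < 2 or n2 < 2:
        raise ValueError("semilandmark counts must be >= 2")
    pts = np.asarray(outline.points, dtype=float)
    i1, i2 = outline.anchors
    if np.allclose(pts[i1], pts[i2]):
        raise ValueError("anchor landmarks coincide")

    # start traversal at anchor 1
    pts = np.roll(pts, -i1, axis=0)
    i2 = (i2 - i1) % len(pts)

    if signed_area(pts) < 0:  # clockwise: mirrored specimen
        pts = pts * np.array([1.0, -1.0])

    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])  # arc length at each vertex
    total = s[-1]
    s_a2 = s[i2]
    if s_a2 <= 0 or s_a2 >= total:
        raise ValueError("anchors do not split the outline into two arcs")

    def interp_at(targets: np.ndarray) -> np.ndarray:
        x = np.interp(targets, s, closed[:, 0])
        y = np.interp(targets, s, closed[:, 1])
        return np.column_stack([x, y])

    t1 = s_a2 * (np.arange(1, n1 + 1) / (n1 + 1))
    t2 = s_a2 + (total - s_a2) * (np.arange(1, n2 + 1) / (n2 + 1))
    out = np.vstack([pts[0], interp_at(t1), pts[i2], interp_at(t2)])
    return out


def anchor_indices(counts: tuple[int, int] = (80, 60)) -> tuple[int, int]:
    """Indices of the two anchors in a configuration built by resample_outline."""
    return 0, counts[0] + 1


# ---------------------------------------------------------------------------
# GPA estimator
# ---------------------------------------------------------------------------

class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Generalized Procrustes alignment of 2D landmark configurations.

    ``fit`` performs iterative GPA on the training sample: every
    configuration is centred, scaled to unit centroid size and rotated to
    the iteratively re-estimated mean shape until the mean stabilises.
    ``transform`` aligns configurations to the fitted mean by ordinary
    Procrustes superimposition (no re-estimation), which is the operation
    used for a-posteriori specimens.

    Parameters
    ----------
    tol : float
        Convergence threshold on the root-mean-square change of the mean
        shape between iterations.
    max_iter : int
        Maximum GPA iterations.

    Attributes
    ----------
    mean_shape_ : ndarray of shape (k, 2)
        Consensus configuration (centred, unit centroid size).
    aligned_ : ndarray of shape (n, k, 2)
        Training configurations after GPA.
    centroid_sizes_ : ndarray of shape (n,)
        Pre-scaling centroid sizes of the training configurations.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    # X may be (n, k, 2) or flattened (n, 2k)
    @staticmethod
    def _as_configs(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] % 2:
                raise ValueError("flattened configurations need an even width")
            X = X.reshape(X.shape[0], -1, 2)
        if X.ndim != 3 or X.shape[2] != 2:
            raise ValueError("expected (n, k, 2) or (n, 2k) input")
        return X

    def fit(self, X, y=None):
        configs = self._as_configs(X)
        n = configs.shape[0]
        if n < 2:
            raise ValueError("GPA needs at least two configurations")
        normed = []
        sizes = []
        for c in configs:
            z, cs = _normalize(c)
            normed.append(z)
            sizes.append(cs)
        normed = np.array(normed)
        ref = normed[0]
        aligned = normed.copy()
        for _ in range(self.max_iter):
            for i in range(n):
                aligned[i] = normed[i] @ optimal_rotation(normed[i], ref)
            mean, _ = _normalize(aligned.mean(axis=0))
            if np.sqrt(((mean - ref) ** 2).mean()) < self.tol:
                ref = mean
                break
            ref = mean
        self.mean_shape_ = ref
        self.aligned_ = aligned
        self.centroid_sizes_ = np.array(sizes)
        self.n_points_ = configs.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Ordinary Procrustes alignment of new configurations to the mean."""
        check_is_fitted(self, "mean_shape_")
        configs = self._as_configs(X)
        if configs.shape[1] != self.n_points_:
            raise ValueError(
                f"point-count mismatch: got {configs.shape[1]}, "
                f"model has {self.n_points_}"
            )
        out = np.empty_like(configs)
        for i, c in enumerate(configs):
            z, _ = _normalize(c)
            out[i] = z @ optimal_rotation(z, self.mean_shape_)
        return out.reshape(configs.shape[0], -1)

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.aligned_.reshape(self.aligned_.shape[0], -1)

    def to_shape_set(self, ids=None, groups=None) -> ShapeSet:
        check_is_fitted(self, "aligned_")
        n = self.aligned_.shape[0]
        return ShapeSet(
            coords=self.aligned_.copy(),
            centroid_sizes=self.centroid_sizes_.copy(),
            specimen_ids=list(ids) if ids is not None else [str(i) for i in range(n)],
            groups=list(groups) if groups is not None else ["unknown"] * n,
        )


def gpa(configurations, ids=None, groups=None, tol: float = 1e-10) -> ShapeSet:
    """Functional wrapper around :class:`GeneralizedProcrustes`."""
    est = GeneralizedProcrustes(tol=tol).fit(np.asarray(configurations, dtype=float))
    return est.to_shape_set(ids=ids, groups=groups)


# ---------------------------------------------------------------------------
# semilandmark sliding
# ---------------------------------------------------------------------------

def bending_energy_matrix(reference: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Thin-plate-spline bending-energy matrix for a 2D reference configuration.

    Uses the 2D TPS kernel U(r) = r^2 log r.  The returned (k, k) matrix B
    is symmetric positive semi-definite; the bending energy of a
    displacement field d is d_x' B d_x + d_y' B d_y.
    """
    ref = np.asarray(reference, dtype=float)
    k = len(ref)
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kmat = 0.5 * d2 * np.log(d2)
    kmat[~np.isfinite(kmat)] = 0.0
    p = np.hstack([np.ones((k, 1)), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = kmat + ridge * np.eye(k)
    L[:k, k:] = p
    L[k:, :k] = p.T
    linv = np.linalg.inv(L)
    b = linv[:k, :k]
    return (b + b.T) / 2


def _tangents(config: np.ndarray) -> np.ndarray:
    """Unit tangent at every point of a closed, ordered configuration."""
    fwd = np.roll(config, -1, axis=0) - np.roll(config, 1, axis=0)
    norms = np.linalg.norm(fwd, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return fwd / norms


@dataclass
class SlideResult:
    configs: np.ndarray  # slid, GPA-aligned configurations (n, k, 2)
    centroid_sizes: np.ndarray
    mean_shape: np.ndarray
    objective_path: list[float]
    converged: bool


def slide_semilandmarks(
    configurations,
    anchor_idx: tuple[int, int],
    mode: str = "bending_energy",
    max_iter: int = 10,
    tol: float = 1e-8,
) -> SlideResult:
    """Slide semilandmarks along outline tangents against the Procrustes mean.

    Anchor landmarks stay fixed.  Each iteration (i) runs GPA, (ii) slides
    every non-anchor point along its local tangent to minimise the chosen
    objective against the current mean shape, then repeats.  The recorded
    total objective is guaranteed non-increasing: an iteration that would
    increase it is reverted and the procedure stops (returning
    ``converged=False`` only when the iteration budget is exhausted while
    still improving).
    """
    if mode not in ("bending_energy", "procrustes_distance"):
        raise ValueError(f"unknown sliding mode: {mode!r}")
    configs = GeneralizedProcrustes._as_configs(np.asarray(configurations, float))
    n, k, _ = configs.shape
    if n < 2:
        raise ValueError("sliding needs at least two configurations")
    slide_idx = np.array([i for i in range(k) if i not in anchor_idx])

    current = configs.copy()
    path: list[float] = []
    converged = True
    prev_state = None
    sizes = None

    for it in range(max_iter + 1):
        est = GeneralizedProcrustes().fit(current)
        aligned = est.aligned_
        mean = est.mean_shape_
        if sizes is None:
            sizes = est.centroid_sizes_

        if mode == "bending_energy":
            bmat = bending_energy_matrix(mean)
            obj = sum(
                float(
                    (a - mean)[:, 0] @ bmat @ (a - mean)[:, 0]
                    + (a - mean)[:, 1] @ bmat @ (a - mean)[:, 1]
                )
                for a in aligned
            )
        else:
            obj = float(((aligned - mean) ** 2).sum())

        if path and obj > path[-1] + 1e-15:
            # revert: keep the previous (better) state
            aligned, mean = prev_state
            break
        path.append(obj)
        prev_state = (aligned.copy(), mean.copy())
        if it == max_iter:
            converged = len(path) > 1 and abs(path[-1] - path[-2]) < tol
            if not converged:
                warnings.warn("semilandmark sliding did not converge")
            break
        if len(path) > 1 and path[-2] - path[-1] < tol:
            break

        # slide step on the aligned coordinates
        new = aligned.copy()
        for i in range(n):
            tang = _tangents(aligned[i])
            resid = mean - aligned[i]
            if mode == "procrustes_distance":
                amt = (resid[slide_idx] * tang[slide_idx]).sum(axis=1)
            else:
                amt = _bending_slide_amounts(
                    aligned[i], mean, bmat, tang, slide_idx
                )
            new[i, slide_idx] += amt[:, None] * tang[slide_idx]
        current = new

    return SlideResult(
        configs=aligned,
        centroid_sizes=np.asarray(sizes),
        mean_shape=mean,
        objective_path=path,
        converged=converged,
    )


def _bending_slide_amounts(config, mean, bmat, tangents, slide_idx):
    """Closed-form tangent-slide magnitudes minimising TPS bending energy."""
    k = len(config)
    m = len(slide_idx)
    z = (config - mean).T.reshape(-1)  # (2k,) x block then y block
    # T maps slide magnitudes to stacked displacements
    t = np.zeros((2 * k, m))
    t[slide_idx, np.arange(m)] = tangents[slide_idx, 0]
    t[k + slide_idx, np.arange(m)] = tangents[slide_idx, 1]
    w = np.zeros((2 * k, 2 * k))
    w[:k, :k] = bmat
    w[k:, k:] = bmat
    lhs = t.T @ w @ t + 1e-10 * np.eye(m)
    rhs = -(t.T @ w @ z)
    return np.linalg.solve(lhs, rhs)


def slide_to_reference(
    configurations,
    reference: np.ndarray,
    anchor_idx: tuple[int, int],
    mode: str = "bending_energy",
    passes: int = 3,
) -> np.ndarray:
    """One-sided sliding of configurations against a fixed reference shape.

    Used for a-posteriori specimens (and for expressing ground-truth
    shapes) in the coordinate system of an already-slid training sample:
    each configuration is OPA-aligned to the reference and its
    semilandmarks are slid along their tangents for a few passes, without
    touching the reference.  Returns aligned slid configurations
    ``(n, k, 2)``.
    """
    configs = GeneralizedProcrustes._as_configs(np.asarray(configurations, float))
    k = configs.shape[1]
    slide_idx = np.array([i for i in range(k) if i not in anchor_idx])
    bmat = bending_energy_matrix(reference) if mode == "bending_energy" else None
    out = np.empty_like(configs)
    for i, c in enumerate(configs):
        z, _ = _normalize(c)
        z = z @ optimal_rotation(z, reference)
        for _ in range(passes):
            tang = _tangents(z)
            if mode == "bending_energy":
                amt = _bending_slide_amounts(z, reference, bmat, tang, slide_idx)
            else:
                amt = ((reference - z)[slide_idx] * tang[slide_idx]).sum(axis=1)
            z[slide_idx] += amt[:, None] * tang[slide_idx]
            z, _ = _normalize(z)
            z = z @ optimal_rotation(z, reference)
        out[i] = z
    return out


# ---------------------------------------------------------------------------
# PCA / bgPCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    components: np.ndarray  # (p, 2k)
    scores: np.ndarray  # (n, p)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray  # (2k,)


def pca(shapes: ShapeSet) -> PCAResult:
    """Principal component analysis of Procrustes shape coordinates.

    Retains at most ``min(n - 1, 2k - 4)`` axes (the dimension of 2D shape
    space after removing translation, scale and rotation).
    """
    x = shapes.flat()
    n, p2 = x.shape
    if n < 3:
        raise ValueError("PCA needs at least three specimens")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    keep = min(n - 1, p2 - 4)
    var = s**2 / (n - 1)
    total = var.sum()
    keep = min(keep, (s > 1e-12 * s[0]).sum()) if s[0] > 0 else keep
    return PCAResult(
        components=vt[:keep],
        scores=(u * s)[:, :keep],
        explained_variance_ratio=var[:keep] / total if total > 0 else var[:keep],
        mean=mean,
    )


class BetweenGroupPCA(BaseEstimator, TransformerMixin):
    """Between-group PCA of shape coordinates.

    Axes are the principal components of the *group mean* shapes (groups
    weighted equally, regardless of sample size), so at most ``g - 1``
    between-group axes exist for ``g`` groups.  All individuals -- training
    specimens and a-posteriori unknowns alike -- are projected onto those
    axes; unknowns never influence the means.  Optionally, principal axes
    of the pooled within-group residuals (orthogonal to the between-group
    axes) can be appended and are flagged as residual axes.

    Parameters
    ----------
    n_residual_axes : int
        Number of residual (within-group) axes appended after the
        between-group axes.

    Attributes
    ----------
    classes_ : ndarray of group labels.
    group_means_ : (g, 2k) group mean shapes.
    grand_mean_ : (2k,) unweighted mean of the group means.
    components_ : (p, 2k) orthonormal axes, between-group axes first.
    axis_is_between_ : boolean flags per axis.
    scores_ : (n, p) training scores.
    """

    def __init__(self, n_residual_axes: int = 0):
        self.n_residual_axes = n_residual_axes

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 3:
            x = x.reshape(x.shape[0], -1)
        y = np.asarray(y)
        if len(y) != len(x):
            raise ValueError("X and group labels differ in length")
        classes, inv = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("bgPCA needs at least two groups")
        means = np.array([x[inv == g].mean(axis=0) for g in range(len(classes))])
        counts = np.bincount(inv)
        for cls, cnt in zip(classes, counts):
            if cnt < 2:
                warnings.warn(
                    f"group {cls!r} has a single member; its mean is that specimen"
                )
        grand = means.mean(axis=0)
        mc = means - grand
        u, s, vt = np.linalg.svd(mc, full_matrices=False)
        nb = int((s > 1e-12 * max(s[0], 1e-30)).sum())
        nb = min(nb, len(classes) - 1)
        comps = vt[:nb]
        between_var = (s[:nb] ** 2) / max(len(classes) - 1, 1)

        flags = [True] * nb
        if self.n_residual_axes > 0:
            resid = x - means[inv]
            resid = resid - resid @ comps.T @ comps
            _, sr, vr = np.linalg.svd(resid - resid.mean(0), full_matrices=False)
            nr = min(self.n_residual_axes, int((sr > 1e-12 * max(sr[0], 1e-30)).sum()))
            comps = np.vstack([comps, vr[:nr]])
            flags += [False] * nr

        self.classes_ = classes
        self.group_means_ = means
        self.grand_mean_ = grand
        self.components_ = comps
        self.axis_is_between_ = np.array(flags)
        self.between_group_variance_ = between_var
        self.scores_ = (x - grand) @ comps.T
        self._train_labels = y.copy()
        self.group_mean_scores_ = (means - grand) @ comps.T
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 3:
            x = x.reshape(x.shape[0], -1)
        if x.shape[1] != self.components_.shape[1]:
            raise ValueError("point-count mismatch with fitted model")
        return (x - self.grand_mean_) @ self.components_.T

    def predict(self, X) -> np.ndarray:
        """Label of the nearest group mean in between-group score space."""
        scores = self.transform(X)
        return np.array([self._nearest(s) for s in scores])

    def _nearest(self, score) -> str:
        b = self.axis_is_between_
        d = np.linalg.norm(self.group_mean_scores_[:, b] - score[b], axis=1)
        return self.classes_[int(np.argmin(d))]


def bgpca(shapes: ShapeSet, groups: Sequence[str] | None = None,
          n_residual_axes: int = 0) -> BetweenGroupPCA:
    g = list(groups) if groups is not None else shapes.groups
    return BetweenGroupPCA(n_residual_axes=n_residual_axes).fit(shapes.flat(), g)


def project_unknowns(
    model: BetweenGroupPCA,
    aligner: GeneralizedProcrustes,
    configurations,
) -> np.ndarray:
    """A-posteriori projection: align unknowns to the training mean, project.

    The bgPCA model is left untouched; group means are not re-estimated.
    """
    aligned = aligner.transform(configurations)
    return model.transform(aligned)


# ---------------------------------------------------------------------------
# allometry & assignment
# ---------------------------------------------------------------------------

@dataclass
class AllometryResult:
    slopes: np.ndarray
    intercepts: np.ndarray
    r_squared: np.ndarray
    p_values: np.ndarray

    def as_dict(self) -> dict:
        return {
            f"axis{i + 1}": {
                "slope": float(self.slopes[i]),
                "r_squared": float(self.r_squared[i]),
                "p_value": float(self.p_values[i]),
            }
            for i in range(len(self.slopes))
        }


def test_allometry(scores: np.ndarray, centroid_sizes: np.ndarray) -> AllometryResult:
    """Regress each axis score on log centroid size (per-axis OLS + F test)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1 and scores.shape[1] > 1 and len(centroid_sizes) > 1:
        scores = scores.T if scores.shape[1] == len(centroid_sizes) else scores
    cs = np.asarray(centroid_sizes, dtype=float)
    if scores.shape[0] != len(cs):
        scores = scores.T
    n = len(cs)
    if n < 4:
        raise ValueError("allometry test needs n >= 4")
    if np.ptp(cs) <= 0:
        raise ValueError("centroid size has zero variance")
    x = np.log(cs)
    slopes, inters, r2s, ps = [], [], [], []
    for j in range(scores.shape[1]):
        res = stats.linregress(x, scores[:, j])
        slopes.append(res.slope)
        inters.append(res.intercept)
        r2s.append(res.rvalue**2)
        ps.append(res.pvalue)
    return AllometryResult(
        slopes=np.array(slopes),
        intercepts=np.array(inters),
        r_squared=np.array(r2s),
        p_values=np.array(ps),
    )


def assign_group(model: BetweenGroupPCA, score: np.ndarray,
                 hull_quantile: float = 0.95) -> dict:
    """Descriptive assignment of a projected specimen to a group cloud.

    Returns the nearest group mean (between-group axes only), a typicality
    per group -- the fraction of that group's training specimens lying at
    least as far from their own mean as the query -- and an overlap flag
    set when the query falls inside more than one group's
    ``hull_quantile`` distance hull.
    """
    check_is_fitted(model, "components_")
    score = np.asarray(score, dtype=float).ravel()
    b = model.axis_is_between_
    sb = score[: len(b)][b]
    typ = {}
    inside = []
    for gi, cls in enumerate(model.classes_):
        mask = model._train_labels == cls
        train = model.scores_[mask][:, b]
        mean = model.group_mean_scores_[gi, b]
        dists = np.linalg.norm(train - mean, axis=1)
        d = np.linalg.norm(sb - mean)
        typ[str(cls)] = float((dists >= d).mean())
        if d <= np.quantile(dists, hull_quantile):
            inside.append(cls)
    dmeans = np.linalg.norm(model.group_mean_scores_[:, b] - sb, axis=1)
    return {
        "label": str(model.classes_[int(np.argmin(dmeans))]),
        "typicality": typ,
        "overlap": len(inside) > 1,
    }
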