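"""Voxel-based dental and skeletal tissue analyses.

Implements the quantitative microCT protocol used to discriminate dog from
wolf lower first molars and to screen metacarpal epiphyses for skeletal
maturity:

* multi-level threshold segmentation of grayscale volumes into
  background / dentine / enamel (semi-automatic: thresholds are reported
  and can be overridden),
* total-least-squares fitting of the cervix reference plane,
* extraction of a 3D crown slice between two cervix-parallel
  cross-sections -- the bottom of the occlusal fossa between the
  paraconid and protoconid, and the level at which the two cusps
  separate -- and the percent of crown dentine Vcdp/Vc within it,
* an occlusal wear screen based on the enamel above the upper
  cross-section,
* reconstruction of a specimen with a broken cervix by aligning its
  preserved cervix ring onto those of intact reference teeth,
* BV/TV of a proximal epiphysis above a separation plane, and a
  Mann-Whitney comparison of group values.

All volumes use ``(z, y, x)`` index order with the first axis along the
crown / proximodistal axis, isotropic voxels, and physical coordinates in
millimetres (index * voxel_mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage.filters import threshold_multiotsu
from skimage.measure import label as cc_label
from skimage.morphology import ball, closing as _closing

DENTAL_SEMANTICS = {0: "background", 1: "dentine", 2: "enamel"}
BONE_SEMANTICS = {0: "void", 1: "bone"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """3D integer label grid with isotropic voxel size (mm).

    ``semantics`` maps label value -> tissue name and must cover every
    label present in ``data``.
    """

    data: np.ndarray
    voxel_mm: float
    semantics: dict[int, str] = field(default_factory=lambda: dict(DENTAL_SEMANTICS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")
        present = set(np.unique(self.data).tolist())
        if not present <= set(self.semantics):
            raise ValueError(
                f"labels {sorted(present - set(self.semantics))} missing from semantics"
            )

    def label_of(self, tissue: str) -> int:
        for k, v in self.semantics.items():
            if v == tissue:
                return k
        raise KeyError(tissue)

    def mask(self, tissue: str) -> np.ndarray:
        return self.data == self.label_of(tissue)

    def coords_mm(self, mask: np.ndarray) -> np.ndarray:
        return np.argwhere(mask).astype(float) * self.voxel_mm


@dataclass
class GrayVolume:
    data: np.ndarray
    voxel_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("gray volume must be 3D")


@dataclass
class Plane:
    """Oriented plane in mm coordinates: points x with normal . x = offset.

    The positive side (normal . x > offset) is the occlusal / proximal side.
    """

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("plane normal cannot be zero")
        self.normal = n / nn
        self.offset = float(self.offset)

    def signed_distance(self, points_mm: np.ndarray) -> np.ndarray:
        return np.asarray(points_mm, dtype=float) @ self.normal - self.offset

    def distance_grid(self, shape: tuple[int, int, int], voxel_mm: float) -> np.ndarray:
        """Signed distance of every voxel centre, as a full grid."""
        nz, ny, nx = shape
        z = np.arange(nz) * voxel_mm * self.normal[0]
        y = np.arange(ny) * voxel_mm * self.normal[1]
        x = np.arange(nx) * voxel_mm * self.normal[2]
        return (
            z[:, None, None] + y[None, :, None] + x[None, None, :] - self.offset
        )

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane directions."""
        n = self.normal
        a = np.array([1.0, 0.0, 0.0])
        if abs(n @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2


@dataclass
class CrownSlice:
    """3D tooth slice between the two crown cross-sections."""

    level1: float  # fossa-floor level (mm, plane coordinate)
    level2: float  # cusp-separation level
    plane: Plane
    voxel_mm: float
    counts_in: dict[str, int]
    counts_out: dict[str, int]
    tooth_breadth_mm: float

    def volume_mm3(self, tissue: str) -> float:
        return self.counts_in.get(tissue, 0) * self.voxel_mm**3


@dataclass
class TissueProportions:
    vc_mm3: float  # dentine + enamel volume in the slice
    vcdp_mm3: float  # dentine volume in the slice
    percent: float  # Vcdp/Vc * 100
    tooth_breadth_mm: float


@dataclass
class BvTvResult:
    bv_mm3: float
    tv_mm3: float
    ratio: float
    maturity_call: str
    threshold: float


@dataclass
class WearReport:
    worn: bool
    min_occlusal_enamel_frac: float
    severity: float


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_tissues(
    gray: GrayVolume,
    n_classes: int = 3,
    thresholds: np.ndarray | None = None,
    semantics: dict[int, str] | None = None,
) -> tuple[LabelVolume, np.ndarray]:
    """Threshold-based tissue segmentation ("semi-automatic" contract).

    Default thresholds come from multi-level Otsu; callers may override
    them, which reproduces manual assistance.  Returns the label volume and
    the thresholds actually used.
    """
    data = np.asarray(gray.data, dtype=float)
    if thresholds is None:
        flat = data.ravel()
        if np.ptp(flat) == 0:
            raise ValueError("degenerate histogram: volume is constant (range = 0)")
        if np.unique(flat).size < n_classes:
            raise ValueError(
                "degenerate histogram: fewer distinct intensities than classes"
            )
        thresholds = threshold_multiotsu(data, classes=n_classes)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    labels = np.digitize(data, thresholds).astype(np.uint8)
    if semantics is None:
        semantics = dict(DENTAL_SEMANTICS) if n_classes == 3 else dict(BONE_SEMANTICS)
    return LabelVolume(labels, gray.voxel_mm, semantics), thresholds


# ---------------------------------------------------------------------------
# cervix plane
# ---------------------------------------------------------------------------

def _cervix_ring_mask(data: np.ndarray, bg_label: int = 0, dentine_label: int = 1,
                      enamel_label: int = 2) -> np.ndarray:
    """Boolean mask of the cervix ring on a dental label grid.

    The cervix is where the outer enamel margin meets the exposed dentine
    of the root: enamel surface voxels within two voxels (26-connectivity)
    of dentine surface voxels.
    """
    struct = np.ones((3, 3, 3), dtype=bool)
    bg_d = ndimage.binary_dilation(data == bg_label, structure=struct)
    e_surf = (data == enamel_label) & bg_d
    d_surf = (data == dentine_label) & bg_d
    return e_surf & ndimage.binary_dilation(d_surf, structure=struct, iterations=2)


def extract_cervix_points(labels: LabelVolume) -> np.ndarray:
    """Cervix ring: enamel surface voxels adjacent to surface dentine.

    The cervix is the line where enamel, dentine and background meet --
    i.e. where the outer enamel margin meets the exposed dentine of the
    root.  Returned as (m, 3) mm coordinates.
    """
    ring = _cervix_ring_mask(
        labels.data,
        labels.label_of("background"),
        labels.label_of("dentine"),
        labels.label_of("enamel"),
    )
    pts = labels.coords_mm(ring)
    if len(pts) == 0:
        raise ValueError("no cervix ring found (enamel never meets surface dentine)")
    return pts


def fit_cervix_plane(points_mm: np.ndarray, toward: np.ndarray | None = None) -> Plane:
    """Total-least-squares plane through a cervix point set.

    ``toward`` is a point on the occlusal side used to orient the normal;
    when omitted the normal orientation is arbitrary.
    """
    pts = np.asarray(points_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("plane fit needs at least 3 points in 3D")
    c = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - c, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise ValueError("points are collinear; plane is undetermined")
    n = vt[2]
    offset = float(n @ c)
    plane = Plane(n, offset)
    if toward is not None and plane.signed_distance(np.atleast_2d(toward))[0] < 0:
        plane = Plane(-plane.normal, -plane.offset)
    return plane


# ---------------------------------------------------------------------------
# crown slice
# ---------------------------------------------------------------------------

def _split_level(
    enamel: np.ndarray, dgrid: np.ndarray, step: float, min_component: int
) -> float:
    """Lowest cervix-parallel level above which the enamel cap has exactly
    two sizable 26-connected components."""
    dvals = dgrid[enamel]
    lo, hi = float(dvals.min()), float(dvals.max())
    levels = np.arange(lo, hi, step)
    seen_one = False
    for z in levels:
        mask = enamel & (dgrid > z)
        if not mask.any():
            break
        lab, ncc = cc_label(mask, connectivity=3, return_num=True)
        if ncc == 0:
            break
        sizes = np.bincount(lab.ravel())[1:]
        big = int((sizes >= min_component).sum())
        if big <= 1:
            seen_one = True
        elif big == 2 and seen_one:
            return float(z)
        elif big == 2 and not seen_one and z == levels[0]:
            # cap already split at the base: no merged region exists
            break
    raise ValueError(
        "no cusp-separation level found: the enamel cap never splits into "
        "two components (single-cusp tooth?)"
    )


def extract_crown_slice(
    labels: LabelVolume,
    cervix: Plane,
    min_component: int = 20,
) -> CrownSlice:
    """Extract the 3D crown slice between the two crown cross-sections.

    Cross-section 2 is the lowest cervix-parallel level at which the
    enamel cap splits into two connected components (the paraconid and
    protoconid separating); cross-section 1 passes through the lowest
    point of the occlusal valley between the two cusp apices, found on a
    cervix-parallel height map along the inter-apex segment.
    """
    step = labels.voxel_mm
    tooth = labels.data != labels.label_of("background")
    enamel = labels.mask("enamel")
    if not enamel.any():
        raise ValueError("no enamel present")
    dgrid = cervix.distance_grid(labels.data.shape, step)

    level2 = _split_level(enamel, dgrid, step, min_component)

    # apices: highest voxel of each of the two cusp components just above level2
    mask2 = enamel & (dgrid > level2 + 0.5 * step)
    lab = cc_label(mask2, connectivity=3)
    sizes = np.bincount(lab.ravel())
    comp_ids = np.argsort(sizes[1:])[::-1][:2] + 1
    if len(comp_ids) < 2:
        raise ValueError("could not isolate two cusp components above level 2")
    e1, e2 = cervix.basis()
    apex_uv = []
    for cid in comp_ids:
        vox = np.argwhere(lab == cid).astype(float) * step
        d = cervix.signed_distance(vox)
        apex = vox[int(np.argmax(d))]
        apex_uv.append((apex @ e1, apex @ e2))

    # cervix-parallel top-height map over the tooth, binned at voxel pitch
    vox = np.argwhere(tooth).astype(float) * step
    d = cervix.signed_distance(vox)
    u = vox @ e1
    v = vox @ e2
    iu = np.round(u / step).astype(int)
    iv = np.round(v / step).astype(int)
    off_u, off_v = iu.min(), iv.min()
    iu -= off_u
    iv -= off_v
    top = np.full((iu.max() + 1, iv.max() + 1), -np.inf)
    np.maximum.at(top, (iu, iv), d)

    u0 = np.round(np.array([a[0] for a in apex_uv]) / step).astype(int) - off_u
    v0 = np.round(np.array([a[1] for a in apex_uv]) / step).astype(int) - off_v
    u0 = np.clip(u0, 0, top.shape[0] - 1)
    v0 = np.clip(v0, 0, top.shape[1] - 1)

    nsamp = max(8, 4 * int(np.hypot(u0[1] - u0[0], v0[1] - v0[0])))
    ts = np.linspace(0.0, 1.0, nsamp)
    heights = []
    for t in ts[1:-1]:
        ui = int(round(u0[0] + t * (u0[1] - u0[0])))
        vi = int(round(v0[0] + t * (v0[1] - v0[0])))
        h = top[ui, vi]
        if not np.isfinite(h):  # fall back to a 3x3 neighbourhood
            patch = top[max(ui - 1, 0) : ui + 2, max(vi - 1, 0) : vi + 2]
            finite = patch[np.isfinite(patch)]
            if finite.size == 0:
                continue
            h = finite.max()
        heights.append(h)
    if not heights:
        raise ValueError("no occlusal valley found between the cusp apices")
    level1 = float(min(heights))
    if level2 - level1 < step:
        raise ValueError(
            f"cross-section 2 ({level2:.3f} mm) does not lie above "
            f"cross-section 1 ({level1:.3f} mm)"
        )

    in_slice = (dgrid > level1) & (dgrid < level2)
    counts_in: dict[str, int] = {}
    counts_out: dict[str, int] = {}
    for val, name in labels.semantics.items():
        if name == "background":
            continue
        m = labels.data == val
        counts_in[name] = int((m & in_slice).sum())
        counts_out[name] = int((m & ~in_slice).sum())

    breadth = float(min(np.ptp(u), np.ptp(v)) + step)
    return CrownSlice(
        level1=level1,
        level2=level2,
        plane=cervix,
        voxel_mm=step,
        counts_in=counts_in,
        counts_out=counts_out,
        tooth_breadth_mm=breadth,
    )


def dentine_percent(crown_slice: CrownSlice) -> TissueProportions:
    """Percent of crown dentine: (dentine / (dentine + enamel)) * 100."""
    v3 = crown_slice.voxel_mm**3
    vcdp = crown_slice.counts_in.get("dentine", 0) * v3
    vc = vcdp + crown_slice.counts_in.get("enamel", 0) * v3
    if vc <= 0:
        raise ValueError("empty crown slice: Vc = 0")
    return TissueProportions(
        vc_mm3=vc,
        vcdp_mm3=vcdp,
        percent=100.0 * vcdp / vc,
        tooth_breadth_mm=crown_slice.tooth_breadth_mm,
    )


# ---------------------------------------------------------------------------
# wear screen
# ---------------------------------------------------------------------------

def detect_wear(
    labels: LabelVolume,
    cervix: Plane,
    level2: float | None = None,
    thin_frac: float = 0.5,
    min_region: int = 4,
    min_component: int = 20,
) -> WearReport:
    """Screen the occlusal enamel above cross-section 2 for wear.

    A tooth is flagged worn when dentine is exposed on the occlusal
    surface above cross-section 2 (a contiguous patch of at least
    ``min_region`` surface columns), or when a contiguous patch of
    occlusal enamel is thinner than ``thin_frac`` times the median
    occlusal thickness.  Severity is ``1 - min_occlusal_enamel_frac``.
    """
    step = labels.voxel_mm
    tooth = labels.data != labels.label_of("background")
    enamel = labels.mask("enamel")
    dentine = labels.mask("dentine")
    dgrid = cervix.distance_grid(labels.data.shape, step)
    if not enamel.any():
        return WearReport(worn=True, min_occlusal_enamel_frac=0.0, severity=1.0)
    if level2 is None:
        try:
            level2 = _split_level(enamel, dgrid, step, min_component)
        except ValueError:
            # heavily worn teeth may have no split level; treat the upper
            # half of the enamel span as occlusal
            dv = dgrid[enamel]
            level2 = float(0.5 * (dv.min() + dv.max()))

    above = dgrid > level2
    occl_tooth = tooth & above
    if not occl_tooth.any():
        return WearReport(worn=True, min_occlusal_enamel_frac=0.0, severity=1.0)

    e1, e2 = cervix.basis()
    vox = np.argwhere(occl_tooth).astype(float) * step
    d = cervix.signed_distance(vox)
    u = np.round((vox @ e1) / step).astype(int)
    v = np.round((vox @ e2) / step).astype(int)
    u -= u.min()
    v -= v.min()
    shape = (u.max() + 1, v.max() + 1)
    top_d = np.full(shape, -np.inf)
    np.maximum.at(top_d, (u, v), d)
    # label of the topmost voxel per column
    lab_vals = labels.data[occl_tooth]
    top_is_enamel = np.zeros(shape, dtype=bool)
    is_top = d >= top_d[u, v] - 1e-9
    elab = labels.label_of("enamel")
    np.logical_or.at(top_is_enamel, (u[is_top], v[is_top]), lab_vals[is_top] == elab)
    has_col = np.isfinite(top_d)

    # per-column enamel thickness above level 2
    ecount = np.zeros(shape)
    evox = np.argwhere(enamel & above).astype(float) * step
    if len(evox):
        eu = np.round((evox @ e1) / step).astype(int)
        ev = np.round((evox @ e2) / step).astype(int)
        # same binning origin as the tooth columns
        tu = np.round((np.argwhere(occl_tooth).astype(float) * step @ e1) / step)
        off_u = int(tu.min())
        tvv = np.round((np.argwhere(occl_tooth).astype(float) * step @ e2) / step)
        off_v = int(tvv.min())
        eu -= off_u
        ev -= off_v
        ok = (eu >= 0) & (eu < shape[0]) & (ev >= 0) & (ev < shape[1])
        np.add.at(ecount, (eu[ok], ev[ok]), 1.0)

    exposed = has_col & ~top_is_enamel
    worn = False
    if exposed.any():
        lab2, ncc = cc_label(exposed, connectivity=2, return_num=True)
        sizes = np.bincount(lab2.ravel())[1:]
        if (sizes >= min_region).any():
            worn = True

    # thickness statistics are taken well above the separation level, on
    # interior columns: the cap's own edge (top barely above level 2) is
    # legitimately thin and must not trigger the screen
    span = float(top_d[has_col].max() - level2)
    high = has_col & (top_d >= level2 + 0.15 * span)
    interior = ndimage.binary_erosion(has_col) & high
    if interior.sum() < min_region:
        interior = high if high.sum() >= min_region else has_col
    thick = ecount[interior]
    nonzero = thick[thick > 0]
    if nonzero.size == 0:
        return WearReport(worn=True, min_occlusal_enamel_frac=0.0, severity=1.0)
    med = float(np.median(nonzero))
    min_frac = float(np.clip(thick.min() / med, 0.0, 1.0)) if med > 0 else 0.0
    thin = interior & (ecount < thin_frac * med)
    if thin.any():
        lab3 = cc_label(thin, connectivity=2)
        if (np.bincount(lab3.ravel())[1:] >= min_region).any():
            worn = True
    return WearReport(
        worn=worn, min_occlusal_enamel_frac=min_frac, severity=1.0 - min_frac
    )


# ---------------------------------------------------------------------------
# broken-cervix reconstruction
# ---------------------------------------------------------------------------

def _umeyama(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Least-squares similarity transform (R, s, t) with dst ~ s R src + t."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    cov = dc.T @ sc / len(src)
    u, s, vt = np.linalg.svd(cov)
    d = np.eye(3)
    if np.linalg.det(u @ vt) < 0:
        d[2, 2] = -1.0
    r = u @ d @ vt
    var_s = (sc**2).sum() / len(src)
    scale = float(np.trace(np.diag(s) @ d) / var_s)
    t = mu_d - scale * r @ mu_s
    return r, scale, t


def align_point_sets(
    src: np.ndarray,
    dst: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """ICP similarity alignment of ``src`` onto ``dst``.

    Correspondences are nearest neighbours re-estimated each iteration.
    Initialised at the centroid translation with unit scale; returns
    (R, s, t, rms) with rms the final mean point-to-nearest distance.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    tree = cKDTree(dst)
    r = np.eye(3)
    s = 1.0
    t = dst.mean(axis=0) - src.mean(axis=0)
    prev = np.inf
    for _ in range(max_iter):
        cur = s * src @ r.T + t
        dists, idx = tree.query(cur)
        rms = float(dists.mean())
        if prev - rms < tol:
            break
        prev = rms
        r, s, t = _umeyama(src, dst[idx])
    cur = s * src @ r.T + t
    dists, _ = tree.query(cur)
    return r, s, t, float(dists.mean())


def reconstruct_broken_cervix(
    target: LabelVolume,
    references: list[LabelVolume],
    min_points: int = 30,
    min_component: int = 20,
) -> list[TissueProportions]:
    """Dentine percent of a cervix-broken tooth via reference alignment.

    The preserved part of the target's cervix ring is aligned to each
    reference's complete ring by a least-squares similarity transform
    (ICP); the reference's fitted cervix plane is pulled back through the
    inverse transform, giving an unbiased reference orientation for the
    target, from which the crown slice and dentine percent are computed.
    One estimate per reference is returned.
    """
    pts_t = extract_cervix_points(target)
    if len(pts_t) < min_points:
        raise ValueError(
            f"preserved cervix has only {len(pts_t)} points (< {min_points})"
        )
    occl_t = target.coords_mm(target.mask("enamel")).mean(axis=0)
    results = []
    for ref in references:
        pts_r = extract_cervix_points(ref)
        if len(pts_r) < min_points:
            raise ValueError("reference cervix ring too small")
        occl_r = ref.coords_mm(ref.mask("enamel")).mean(axis=0)
        r, s, t, rms = align_point_sets(pts_t, pts_r)
        if rms > 10 * ref.voxel_mm:
            raise ValueError(
                f"cervix alignment failed (rms {rms:.3f} mm); disjoint cervix?"
            )
        plane_r = fit_cervix_plane(pts_r, toward=occl_r)
        # pull the reference plane back into target coordinates:
        # n.(sRx + t) = o  =>  (R'n).x = (o - n.t)/s
        n_t = r.T @ plane_r.normal
        o_t = (plane_r.offset - plane_r.normal @ t) / s
        plane_t = Plane(n_t, o_t)
        if plane_t.signed_distance(np.atleast_2d(occl_t))[0] < 0:
            plane_t = Plane(-plane_t.normal, -plane_t.offset)
        sl = extract_crown_slice(target, plane_t, min_component=min_component)
        results.append(dentine_percent(sl))
    return results


# ---------------------------------------------------------------------------
# BV/TV
# ---------------------------------------------------------------------------

def bv_tv(
    labels: LabelVolume,
    separation: Plane,
    closing_frac: float = 0.0,
    maturity_threshold: float = 0.65,
) -> BvTvResult:
    """Bone volume over total volume of the proximal epiphysis.

    TV is the volume inside the outer bone envelope -- the bone labels
    with all enclosed cavities filled, so that marrow voids are included
    -- restricted to the proximal (positive) side of the separation
    plane; BV is the bone voxels on that side.  For specimens whose
    internal voids open through the cortex, ``closing_frac`` > 0 first
    applies a morphological closing (ball radius = that fraction of the
    bone extent) to seal the openings; closing inflates the envelope of a
    convex bone by a sub-voxel crust, so it is off by default.  The
    maturity call compares BV/TV with ``maturity_threshold`` (porous,
    low-BV/TV epiphyses belong to skeletally immature individuals).
    """
    bone = labels.mask("bone")
    if not bone.any():
        raise ValueError("no bone voxels")
    dgrid = separation.distance_grid(labels.data.shape, labels.voxel_mm)
    prox = dgrid > 0
    if not (bone & prox).any():
        raise ValueError("empty proximal side of the separation plane")
    # envelope from the full bone so that the cut face does not open voids
    env = bone
    if closing_frac > 0:
        bb = np.argwhere(bone)
        extent = (bb.max(axis=0) - bb.min(axis=0)).max()
        r = max(1, int(round(closing_frac * extent)))
        env = _closing(bone, ball(r)).astype(bool)
    env = ndimage.binary_fill_holes(env)
    tv = int((env & prox).sum())
    bv = int((bone & prox).sum())
    if tv == 0:
        raise ValueError("empty envelope on the proximal side")
    ratio = bv / tv
    v3 = labels.voxel_mm**3
    call = "adult" if ratio >= maturity_threshold else "immature"
    return BvTvResult(
        bv_mm3=bv * v3,
        tv_mm3=tv * v3,
        ratio=float(ratio),
        maturity_call=call,
        threshold=maturity_threshold,
    )


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_groups(values_a, values_b) -> dict:
    """Two-sided Mann-Whitney U comparison of two groups.

    Uses the exact U distribution when the combined sample size is at most
    25 and no ties are present, and the tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 25 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(min(res.pvalue, 1.0)),
            "method": method}
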