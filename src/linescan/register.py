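"""Cross-session ROI registration and identity assignment.

Sessions imaging the same field of view on different days are aligned by
an affine transform estimated between their time-averaged images (coarse
integer translation by phase cross-correlation, then direct optimization
of the six affine parameters against a normalized-correlation objective).
ROIs are transformed into a common space and clustered by UPGMA with
distance 1/J (J = Jaccard index of the pixel supports; J = 0 and
same-session pairs get infinite distance). Merges that would place two
ROIs of one session in a cluster, or any pair with J below the 0.25
cutoff, are vetoed. Each final cluster receives a fresh shared ``id``,
identifying the same cell across sessions.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy import optimize
from skimage.registration import phase_cross_correlation

from .rois import Roi, RoiList


@dataclass
class Affine2D:
    """2x3 affine map from source (x, y) to target (x, y) coordinates."""

    matrix: np.ndarray  # shape (2, 3): [[a11, a12, tx], [a21, a22, ty]]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("affine transform is degenerate (det ~ 0)")

    @classmethod
    def identity(cls) -> "Affine2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "Affine2D":
        return cls(np.array([[1.0, 0.0, tx], [0.0, 1.0, ty]]))

    @classmethod
    def rotation(cls, degrees: float, center=(0.0, 0.0)) -> "Affine2D":
        th = np.deg2rad(degrees)
        c, s = np.cos(th), np.sin(th)
        cx, cy = center
        tx = cx - c * cx + s * cy
        ty = cy - s * cx - c * cy
        return cls(np.array([[c, -s, tx], [s, c, ty]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (x, y) points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "Affine2D":
        A = self.matrix[:, :2]
        t = self.matrix[:, 2]
        Ainv = np.linalg.inv(A)
        return Affine2D(np.column_stack([Ainv, -Ainv @ t]))

    def compose(self, other: "Affine2D") -> "Affine2D":
        """self o other (apply ``other`` first)."""
        A = self.matrix[:, :2] @ other.matrix[:, :2]
        t = self.matrix[:, :2] @ other.matrix[:, 2] + self.matrix[:, 2]
        return Affine2D(np.column_stack([A, t]))


# ----------------------------------------------------------------------
def _prep(img: np.ndarray) -> np.ndarray:
    """Smooth and standardize, keeping unobserved (NaN) pixels unobserved."""
    img = np.asarray(img, dtype=float)
    ok = np.isfinite(img)
    filled = np.where(ok, img, img[ok].mean())
    smooth = ndi.gaussian_filter(filled, 1.0)
    out = (smooth - smooth[ok].mean()) / (smooth[ok].std() + 1e-12)
    out[~ok] = np.nan
    return out


def _warp_into(target_shape, img: np.ndarray, t: Affine2D) -> np.ndarray:
    """Resample ``img`` (source) onto the target grid through ``t``
    (source -> target); unseen target pixels become NaN."""
    inv = t.inverse().matrix  # target (x, y) -> source (x, y)
    # scipy affine_transform works in (row, col) = (y, x) order
    mat = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    off = np.array([inv[1, 2], inv[0, 2]])
    return ndi.affine_transform(img, mat, offset=off,
                                output_shape=target_shape, order=1,
                                mode="constant", cval=np.nan)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized correlation over the jointly valid region."""
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 16:
        return -1.0
    x = a[ok] - a[ok].mean()
    y = b[ok] - b[ok].mean()
    denom = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    if denom == 0:
        return -1.0
    return float((x * y).sum() / denom)


def estimate_affine(image_a: np.ndarray, image_b: np.ndarray) -> Affine2D:
    """Affine transform mapping coordinates of ``image_b`` into
    ``image_a``'s frame, estimated from intensities alone.

    Coarse translation comes from phase cross-correlation; the full six
    parameters are then refined by maximizing the normalized correlation
    between ``image_a`` and ``image_b`` warped into its frame. If the
    refinement does not improve the criterion, the coarse translation
    (or the identity) is returned. Raises when the images share no
    content (correlation below 0.1).
    """
    a = _prep(image_a)
    b = _prep(image_b)
    if np.isnan(a).any() or np.isnan(b).any():
        shift = phase_cross_correlation(
            np.nan_to_num(a), np.nan_to_num(b),
            reference_mask=np.isfinite(a), moving_mask=np.isfinite(b))[0]
    else:
        shift = phase_cross_correlation(a, b, normalization=None)[0]
    t0 = Affine2D.translation(tx=float(shift[1]), ty=float(shift[0]))
    warped0 = _warp_into(a.shape, b, t0)
    base_score = max(_ncc(a, warped0),
                     _ncc(a, _warp_into(a.shape, b, Affine2D.identity())))
    if base_score < 0.1:
        raise ValueError(
            "images do not overlap (correlation below 0.1); cannot register")
    # correlation is evaluated over the FIXED support of the coarse
    # alignment; content a candidate warp pushes out of view counts as
    # zero signal there (dilution), so a transform cannot improve its
    # score by discarding the poorly matched part of the field
    support = np.isfinite(a) & np.isfinite(warped0)
    a_sup = a[support] - a[support].mean()

    def fixed_support_score(warped):
        w = np.where(np.isfinite(warped), warped, 0.0)[support]
        w = w - w.mean()
        denom = np.sqrt((a_sup ** 2).sum() * (w ** 2).sum())
        if denom == 0:
            return -1.0
        return float((a_sup * w).sum() / denom)

    def unpack(theta):
        a11, a12, a21, a22, tx, ty = theta
        return Affine2D(np.array([[a11, a12, tx], [a21, a22, ty]]))

    def cost(theta):
        try:
            t = unpack(theta)
        except ValueError:
            return 1.0
        return -fixed_support_score(_warp_into(a.shape, b, t))

    # stage 1: rigid (rotation about the image centre + translation),
    # which avoids the shear/scale local minima of the full problem
    cy, cx = (np.asarray(a.shape) - 1) / 2.0

    def rigid_theta(params):
        ang, tx, ty = params
        t = Affine2D.rotation(ang, center=(cx, cy))
        m = t.matrix.copy()
        m[0, 2] += tx
        m[1, 2] += ty
        return np.array([m[0, 0], m[0, 1], m[1, 0], m[1, 1],
                         m[0, 2], m[1, 2]])

    x0_rigid = np.array([0.0, t0.matrix[0, 2], t0.matrix[1, 2]])
    coarse_cost = cost(rigid_theta(x0_rigid))
    res1 = optimize.minimize(lambda p: cost(rigid_theta(p)), x0_rigid,
                             method="Powell",
                             options={"xtol": 1e-6, "ftol": 1e-10,
                                      "maxiter": 2000})
    x0 = rigid_theta(res1.x if res1.fun < coarse_cost else x0_rigid)
    # stage 2: full affine refinement
    res2 = optimize.minimize(cost, x0, method="Powell",
                             options={"xtol": 1e-6, "ftol": 1e-10,
                                      "maxiter": 4000})
    best = min([(coarse_cost, rigid_theta(x0_rigid)),
                (res1.fun, rigid_theta(res1.x)), (res2.fun, res2.x)],
               key=lambda c: c[0])
    return unpack(best[1])


def transform_rois(rois: RoiList, t: Affine2D, target_shape) -> RoiList:
    """Map ROIs through an affine into the target image space.

    Polygon vertices are transformed directly; mask ROIs are resampled by
    nearest neighbour. Identity metadata is preserved; geometry falling
    outside ``target_shape`` is clipped at rasterization.
    """
    target_shape = tuple(target_shape)
    out = []
    inv = t.inverse()
    for roi in rois:
        if roi.polygons is not None:
            polys = [t.apply(p) for p in roi.polygons]
            out.append(Roi(polygons=polys, id=roi.id, label=roi.label,
                           tags=set(roi.tags), im_shape=target_shape))
        else:
            rr, cc = np.meshgrid(np.arange(target_shape[0]),
                                 np.arange(target_shape[1]), indexing="ij")
            src = inv.apply(np.column_stack([cc.ravel(), rr.ravel()]))
            sc = np.rint(src[:, 0]).astype(int)
            sr = np.rint(src[:, 1]).astype(int)
            ok = ((sr >= 0) & (sr < roi.mask.shape[0])
                  & (sc >= 0) & (sc < roi.mask.shape[1]))
            support = roi.mask != 0 if roi.mask.dtype != bool else roi.mask
            new = np.zeros(target_shape, dtype=bool)
            new.ravel()[ok.nonzero()[0]] = support[sr[ok], sc[ok]]
            out.append(Roi(mask=new, id=roi.id, label=roi.label,
                           tags=set(roi.tags), im_shape=target_shape))
    return RoiList(out, name=rois.name)


def jaccard(a: Roi, b: Roi) -> float:
    """|A n B| / |A u B| of the pixel supports (0 when the union is empty)."""
    sa, sb = a.support(), b.support()
    union = np.logical_or(sa, sb).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(sa, sb).sum() / union)


@dataclass
class IdentityClusters:
    """Co-registration result: clusters of (session, roi_index) pairs."""

    clusters: list[list[tuple[int, int]]]
    ids: list[str]

    def id_of(self, session: int, roi_index: int) -> str | None:
        for cid, members in zip(self.ids, self.clusters):
            if (session, roi_index) in members:
                return cid
        return None


def cluster_identities(session_rois: list[RoiList],
                       min_jaccard: float = 0.25,
                       rng: np.random.Generator | None = None
                       ) -> IdentityClusters:
    """UPGMA clustering of ROIs (already in a common space) at 1/J distance.

    Average-linkage agglomeration over all ROIs of all sessions, with
    distance 1/J between ROIs (infinite for J = 0 and for pairs from the
    same session). A merge is vetoed when the merged cluster would contain
    a same-session pair or any pair with J < ``min_jaccard``; vetoed pairs
    are skipped and agglomeration continues. Every cluster (including
    singletons) receives a fresh shared id, which is also written onto the
    ``id`` attribute of the input ROIs.
    """
    items = [(s, i) for s, rl in enumerate(session_rois)
             for i in range(len(rl))]
    n = len(items)
    supports = [session_rois[s][i].support() for s, i in items]
    dist = np.full((n, n), np.inf)
    jac = np.zeros((n, n))
    for p in range(n):
        for q in range(p + 1, n):
            sa, sb = supports[p], supports[q]
            union = np.logical_or(sa, sb).sum()
            j = (np.logical_and(sa, sb).sum() / union) if union else 0.0
            jac[p, q] = jac[q, p] = j
            if items[p][0] != items[q][0] and j > 0:
                dist[p, q] = dist[q, p] = 1.0 / j

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    cdist: dict[tuple[int, int], float] = {}
    for p in range(n):
        for q in range(p + 1, n):
            cdist[(p, q)] = dist[p, q]
    next_id = n
    forbidden: set[tuple[int, int]] = set()
    while True:
        candidates = [(d, key) for key, d in cdist.items()
                      if np.isfinite(d) and key not in forbidden]
        if not candidates:
            break
        d, (p, q) = min(candidates, key=lambda c: (c[0], c[1]))
        members = clusters[p] + clusters[q]
        ok = True
        for ii in range(len(members)):
            for jj in range(ii + 1, len(members)):
                a, b = members[ii], members[jj]
                if (items[a][0] == items[b][0]
                        or jac[a, b] < min_jaccard):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            forbidden.add((p, q))
            continue
        # UPGMA distance update, weighted by cluster sizes
        new = next_id
        next_id += 1
        np_, nq = len(clusters[p]), len(clusters[q])
        for other in list(clusters):
            if other in (p, q):
                continue
            dp = cdist.get((min(p, other), max(p, other)), np.inf)
            dq = cdist.get((min(q, other), max(q, other)), np.inf)
            cdist[(min(new, other), max(new, other))] = (
                (np_ * dp + nq * dq) / (np_ + nq))
        clusters[new] = members
        for other in list(clusters):
            cdist.pop((min(p, other), max(p, other)), None)
            cdist.pop((min(q, other), max(q, other)), None)
        del clusters[p], clusters[q]
        forbidden = {k for k in forbidden if p not in k and q not in k}

    final = sorted(clusters.values(), key=lambda m: min(m))
    ids = []
    out_clusters = []
    for members in final:
        if rng is None:
            cid = str(uuid.uuid4())
        else:
            cid = str(uuid.UUID(int=int(rng.integers(0, 2 ** 63)), version=4))
        ids.append(cid)
        pairs = [items[m] for m in sorted(members)]
        out_clusters.append(pairs)
        for s, i in pairs:
            session_rois[s][i].id = cid
    return IdentityClusters(clusters=out_clusters, ids=ids)


def propagate_tags(clusters: IdentityClusters,
                   session_rois: list[RoiList],
                   source_session: int) -> None:
    """Union the tags of source-session ROIs into their cluster mates."""
    for members in clusters.clusters:
        source_tags = set()
        for s, i in members:
            if s == source_session:
                source_tags |= session_rois[s][i].tags
        if not source_tags:
            continue
        for s, i in members:
            session_rois[s][i].tags |= source_tags


def register_sessions(sessions, reference: int = 0,
                      min_jaccard: float = 0.25,
                      rng: np.random.Generator | None = None):
    """Full cross-session registration.

    ``sessions`` is a list of (time_average_image, RoiList) pairs. Each
    session's image is registered to the reference session's; the ROIs are
    transformed into the reference space and clustered; shared ids are
    written back onto the input ROIs (which stay in their own session
    space).

    Returns (IdentityClusters, transforms, transformed_roi_lists).
    """
    ref_img = sessions[reference][0]
    target_shape = np.asarray(ref_img).shape
    transforms = []
    transformed = []
    for s, (img, rl) in enumerate(sessions):
        t = (Affine2D.identity() if s == reference
             else estimate_affine(ref_img, img))
        transforms.append(t)
        transformed.append(transform_rois(rl, t, target_shape))
    clusters = cluster_identities(transformed, min_jaccard=min_jaccard,
                                  rng=rng)
    for s, (_, rl) in enumerate(sessions):
        for i, roi in enumerate(rl):
            roi.id = transformed[s][i].id
    return clusters, transforms, transformed
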