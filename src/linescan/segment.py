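"""Segmentation of the field of view by iterative normalized cuts.

Pixels are nodes of a sparse affinity graph; edges connect pixels within a
rectangular neighbourhood and weigh both signal similarity and proximity:

    w_ij = exp(k_c c_ij) * exp(-(dy^2/sigma_y^2 + dx^2/sigma_x^2))

with c_ij the correlation between the two pixels' intensity time series
(estimated after a rank-``num_pcs`` principal-component reconstruction of
the movie, which denoises the correlations). The graph is recursively
bipartitioned by the Shi-Malik normalized cut; regions larger than
``cut_max_size`` always split, regions smaller than ``cut_min_size`` never
do, and intermediate regions split only when the next cut's penalty stays
below ``cut_max_pen``.

The plain ``normcut`` variant returns the partitions as ROIs. The
``ca1pc`` variant targets hippocampal CA1 pyramidal-cell nuclei, which
appear as uniform dark ellipses: it first multiplies each affinity by
exp(-k_I * M_ij), where M_ij is the maximum of a contrast-enhanced
(CLAHE + unsharp mask) mean image along the segment joining the pixels —
discouraging edges that cross bright neuropil — and then post-processes
each partition (per-partition Otsu threshold keeping the dark class,
binary opening/closing, minimum size and circularity filters) into
nucleus-shaped ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from skimage import exposure, measure

from .rois import Roi, RoiList


@dataclass
class SegmentationParams:
    """Tunable parameters (defaults follow the CA1 pyramidal-cell setup).

    Distances and sizes are in pixels; ``max_dist`` and ``spatial_decay``
    are (row, col) pairs since laser-scanned pixels are often anisotropic.
    ``k_I`` defaults to 3/(max I* - min I*) of the processed mean image.
    """

    variant: str = "normcut"
    num_pcs: int = 50
    max_dist: tuple[int, int] = (3, 6)
    spatial_decay: tuple[float, float] = (3.0, 6.0)
    cut_max_pen: float = 0.10
    cut_min_size: int = 50
    cut_max_size: int = 150
    x_diameter: float = 14.0
    y_diameter: float = 7.0
    circularity_threshold: float = 0.5
    min_roi_size: int = 20
    min_cut_size: int = 40
    k_c: float = 9.0
    k_I: float | None = None

    def __post_init__(self):
        if self.cut_min_size > self.cut_max_size:
            raise ValueError("cut_min_size must not exceed cut_max_size")


@dataclass
class Partition:
    """One final region of the iterative partitioning."""

    pixels: np.ndarray  # flat pixel indices, row-major
    penalty: float      # Ncut penalty of the split that produced it


# ----------------------------------------------------------------------
# pixel correlations
def _neighbor_offsets(r_y: int, r_x: int):
    """Offsets (dy, dx) of the upper half of the rectangular neighbourhood
    (each unordered pixel pair appears once)."""
    out = []
    for dy in range(0, r_y + 1):
        for dx in range(-r_x, r_x + 1):
            if dy == 0 and dx <= 0:
                continue
            out.append((dy, dx))
    return out


def pixel_correlations(frames, num_pcs: int, neighborhood: tuple[int, int],
                       im_shape=None) -> sp.csr_matrix:
    """Sparse pixel-pair correlations within a rectangular neighbourhood.

    The movie (frames x pixels) is reconstructed at rank ``num_pcs`` from
    its principal components before Pearson correlation, which suppresses
    uncorrelated shot noise. Zero-variance pixels correlate 0 with
    everything; values are clipped to [-1, 1].

    Returns a symmetric CSR matrix over row-major pixel indices.
    """
    stack = np.asarray([np.asarray(f, dtype=float) for f in frames])
    if stack.ndim != 3:
        raise ValueError("frames must yield 2-D images")
    T, R, C = stack.shape
    if T < 2:
        raise ValueError("correlation estimation needs >= 2 frames")
    X = stack.reshape(T, R * C)
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isfinite(X), X, col_mean[None, :])
    X = np.where(np.isfinite(X), X, 0.0)
    Xc = X - X.mean(axis=0)
    k = min(num_pcs, T - 1, R * C)
    if k < min(T - 1, R * C):
        # temporal covariance eigendecomposition; reconstruct at rank k
        G = Xc @ Xc.T
        vals, vecs = np.linalg.eigh(G)
        U = vecs[:, ::-1][:, :k]
        Xr = U @ (U.T @ Xc)
        Xr = Xr - Xr.mean(axis=0)
    else:
        Xr = Xc
    norm = np.sqrt((Xr ** 2).sum(axis=0))
    Z = np.divide(Xr, norm, out=np.zeros_like(Xr), where=norm > 0)
    Zg = Z.reshape(T, R, C)

    rows, cols, vals = [], [], []
    idx = np.arange(R * C).reshape(R, C)
    for dy, dx in _neighbor_offsets(*neighborhood):
        r_sl = slice(0, R - dy)
        r_sl2 = slice(dy, R)
        c_sl = slice(max(0, -dx), min(C, C - dx))
        c_sl2 = slice(max(0, dx), min(C, C + dx))
        a = Zg[:, r_sl, c_sl]
        b = Zg[:, r_sl2, c_sl2]
        cc = np.clip((a * b).sum(axis=0), -1.0, 1.0)
        p = idx[r_sl, c_sl].ravel()
        q = idx[r_sl2, c_sl2].ravel()
        rows.append(p)
        cols.append(q)
        vals.append(cc.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    m = sp.coo_matrix((np.concatenate([vals, vals]),
                       (np.concatenate([rows, cols]),
                        np.concatenate([cols, rows]))),
                      shape=(R * C, R * C))
    return m.tocsr()


# ----------------------------------------------------------------------
# affinities
def affinity_normcut(corr: sp.spmatrix, im_shape: tuple[int, int],
                     params: SegmentationParams) -> sp.csr_matrix:
    """Affinity graph of the plain normalized-cut variant.

    Every pixel pair within the ``max_dist`` rectangle gets weight
    exp(k_c c_ij) * exp(-(dy^2/sy^2 + dx^2/sx^2)); pairs beyond it get 0.
    ``corr`` supplies c_ij (absent entries count as 0).
    """
    R, C = im_shape
    corr = corr.tocsr()
    sy, sx = params.spatial_decay
    idx = np.arange(R * C).reshape(R, C)
    rows, cols, vals = [], [], []
    for dy, dx in _neighbor_offsets(*params.max_dist):
        spatial = np.exp(-(dy ** 2 / sy ** 2 + dx ** 2 / sx ** 2))
        r_sl = slice(0, R - dy)
        r_sl2 = slice(dy, R)
        c_sl = slice(max(0, -dx), min(C, C - dx))
        c_sl2 = slice(max(0, dx), min(C, C + dx))
        p = idx[r_sl, c_sl].ravel()
        q = idx[r_sl2, c_sl2].ravel()
        cvals = np.asarray(corr[p, q]).ravel()
        w = np.exp(params.k_c * cvals) * spatial
        rows.append(p)
        cols.append(q)
        vals.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    m = sp.coo_matrix((np.concatenate([vals, vals]),
                       (np.concatenate([rows, cols]),
                        np.concatenate([cols, rows]))),
                      shape=(R * C, R * C))
    return m.tocsr()


def ca1pc_process_image(avg_image: np.ndarray, x_diameter: float,
                        y_diameter: float) -> np.ndarray:
    """Contrast-enhance a mean image for nucleus segmentation.

    CLAHE with tiles of about twice the cell diameter corrects slow
    intensity inhomogeneities; the unsharp mask (image minus a
    cell-diameter-scale Gaussian blur, shifted to be non-negative) makes
    dark nuclei stand out from the bright neuropil. A constant image is
    returned unchanged (equalization is undefined there).
    """
    img = np.asarray(avg_image, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("avg_image must be finite")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return img.copy()
    norm = (img - lo) / (hi - lo)
    ky = min(img.shape[0], max(2, int(round(2 * y_diameter))))
    kx = min(img.shape[1], max(2, int(round(2 * x_diameter))))
    eq = exposure.equalize_adapthist(norm, kernel_size=(ky, kx),
                                     clip_limit=0.02)
    blur = ndi.gaussian_filter(eq, sigma=(y_diameter / 2, x_diameter / 2))
    out = eq - blur
    return out - out.min()


def affinity_ca1pc(w: sp.spmatrix, i_star: np.ndarray,
                   k_i: float | None = None) -> sp.csr_matrix:
    """Attenuate affinities by the brightest point between the pixels.

    Each weight is multiplied by exp(-k_I M_ij) with M_ij the maximum of
    the processed image ``i_star`` along the segment between the two pixel
    centers, sampled at steps of at most half a pixel with nearest-pixel
    lookup. ``k_i`` defaults to 3 / (max i_star - min i_star).
    """
    R, C = i_star.shape
    if k_i is None:
        rng = i_star.max() - i_star.min()
        k_i = 3.0 / rng if rng > 0 else 0.0
    coo = w.tocoo()
    pr, pc = np.divmod(coo.row, C)
    qr, qc = np.divmod(coo.col, C)
    dr = qr - pr
    dc = qc - pc
    data = coo.data.copy()
    for off in set(zip(dr.tolist(), dc.tolist())):
        sel = (dr == off[0]) & (dc == off[1])
        length = max(abs(off[0]), abs(off[1]))
        n_steps = int(np.ceil(2 * length)) + 1
        svals = np.linspace(0.0, 1.0, max(n_steps, 2))
        m = np.full(sel.sum(), -np.inf)
        base_r, base_c = pr[sel], pc[sel]
        for s in svals:
            rr = np.clip(np.rint(base_r + s * off[0]).astype(int), 0, R - 1)
            cc = np.clip(np.rint(base_c + s * off[1]).astype(int), 0, C - 1)
            m = np.maximum(m, i_star[rr, cc])
        data[sel] *= np.exp(-k_i * m)
    return sp.coo_matrix((data, (coo.row, coo.col)), shape=w.shape).tocsr()


# ----------------------------------------------------------------------
# normalized cuts
def ncut_penalty(w: sp.spmatrix, a, b) -> float:
    """Normalized-cut penalty of splitting region V = A u B.

    cut(A,B)/assoc(A,V) + cut(A,B)/assoc(B,V); defined as 2 (the maximum)
    when either side has zero association.
    """
    w = w.tocsr()
    a = np.asarray(a)
    b = np.asarray(b)
    cut = w[a][:, b].sum()
    assoc_a = w[a].sum()
    assoc_b = w[b].sum()
    if assoc_a <= 0 or assoc_b <= 0:
        return 2.0
    return float(cut / assoc_a + cut / assoc_b)


_NUM_THRESHOLDS = 32


def spectral_split(w: sp.spmatrix):
    """Best bipartition of a weighted pixel graph by the Shi-Malik method.

    Solves (D - W) x = lambda D x for the second-smallest eigenvector,
    thresholds it at 32 evenly spaced quantiles, and returns the candidate
    (A, B, penalty) with the smallest normalized-cut penalty. Disconnected
    graphs split along connected components with penalty 0. Deterministic
    given its input.
    """
    n = w.shape[0]
    if n < 2:
        raise ValueError("cannot split a region of fewer than 2 nodes")
    ncomp, labels = connected_components(w, directed=False)
    if ncomp > 1:
        a = np.flatnonzero(labels == labels[0])
        b = np.flatnonzero(labels != labels[0])
        return a, b, 0.0
    d = np.asarray(w.sum(axis=1)).ravel()
    d = np.maximum(d, 1e-300)
    dinv = 1.0 / np.sqrt(d)
    A = sp.diags(dinv) @ w @ sp.diags(dinv)
    k_extra = 2 if n > 3 else 1
    if n <= 600:
        _, vecs = np.linalg.eigh(A.toarray())
        xs = [dinv * vecs[:, -1 - k] for k in range(1, k_extra + 1)]
    else:
        # smallest nontrivial eigenvectors of L = I - A via shift-invert
        L = (sp.eye(n) - A).tocsc()
        v0 = np.ones(n) / np.sqrt(n)
        vals, vecs = eigsh(L, k=1 + k_extra, sigma=-1e-3, which="LM", v0=v0)
        order = np.argsort(vals)
        xs = [dinv * vecs[:, order[k]] for k in range(1, 1 + k_extra)]
    best = None
    # candidate splits: threshold sweeps of the 2nd (and 3rd) smallest
    # generalized eigenvectors — the Fiedler sweep alone can miss good
    # cuts on irregular graphs
    for x in xs:
        if n <= 2 * _NUM_THRESHOLDS:
            thresholds = np.unique(x)[:-1]
        else:
            qs = (np.arange(_NUM_THRESHOLDS) + 0.5) / _NUM_THRESHOLDS
            thresholds = np.quantile(x, qs)
        cand = None
        for t in thresholds:
            mask = x <= t
            na = int(mask.sum())
            if na == 0 or na == n:
                continue
            a = np.flatnonzero(mask)
            b = np.flatnonzero(~mask)
            pen = ncut_penalty(w, a, b)
            if cand is None or pen < cand[2]:
                cand = (a, b, pen)
        if cand is None:  # degenerate (constant) eigenvector
            continue
        if n <= 200:
            cand = _refine_split(w, *cand)
        if best is None or cand[2] < best[2]:
            best = cand
    if best is None:
        a = np.array([0])
        b = np.arange(1, n)
        best = (a, b, ncut_penalty(w, a, b))
    return best


def _refine_split(w, a, b, pen):
    """Greedy local refinement of a bipartition (Kernighan-Lin style).

    Single-node moves across the cut while the penalty drops; on small
    graphs also cross-side pair swaps. Deterministic; closes the gap the
    one-dimensional eigenvector sweep leaves on irregular graphs.
    """
    n = w.shape[0]
    side = np.zeros(n, dtype=bool)
    side[b] = True

    def penalty():
        return ncut_penalty(w, np.flatnonzero(~side), np.flatnonzero(side))

    for _ in range(2 * n):
        improved = None
        for i in range(n):
            if side.sum() == (1 if side[i] else n - 1):
                continue  # would empty one side
            side[i] = ~side[i]
            pen_new = penalty()
            if pen_new < (improved[1] if improved else pen) - 1e-15:
                improved = (("move", i), pen_new)
            side[i] = ~side[i]
        if improved is None and n <= 40:
            for i in np.flatnonzero(~side):
                for j in np.flatnonzero(side):
                    side[i], side[j] = True, False
                    pen_new = penalty()
                    if pen_new < (improved[1] if improved else pen) - 1e-15:
                        improved = (("swap", i, j), pen_new)
                    side[i], side[j] = False, True
        if improved is None:
            break
        action = improved[0]
        if action[0] == "move":
            side[action[1]] = ~side[action[1]]
        else:
            side[action[1]], side[action[2]] = True, False
        pen = improved[1]
    return np.flatnonzero(~side), np.flatnonzero(side), pen


def iterative_partition(w: sp.spmatrix,
                        params: SegmentationParams) -> list[Partition]:
    """Recursive normalized-cut partitioning of the whole pixel graph.

    A region splits iff it exceeds ``cut_max_size``, or its size is within
    [cut_min_size, cut_max_size] and the best next split's penalty is
    below ``cut_max_pen``. Final regions are returned as disjoint
    partitions covering the image.
    """
    w = w.tocsr()
    n = w.shape[0]
    max_splits = 10 * max(1, n // max(1, params.cut_min_size))
    splits = 0
    done: list[Partition] = []
    stack = [(np.arange(n), np.nan)]
    while stack:
        pixels, pen = stack.pop()
        size = len(pixels)
        if size < 2 or size < params.cut_min_size:
            done.append(Partition(pixels, pen))
            continue
        force = size > params.cut_max_size
        sub = w[pixels][:, pixels]
        a, b, split_pen = spectral_split(sub)
        if force or split_pen < params.cut_max_pen:
            splits += 1
            if splits > max_splits:
                raise RuntimeError("iterative partitioning did not converge")
            stack.append((pixels[a], split_pen))
            stack.append((pixels[b], split_pen))
        else:
            done.append(Partition(pixels, pen))
    return done


# ----------------------------------------------------------------------
# ca1pc post-processing
def otsu_threshold(values) -> float:
    """Threshold maximizing between-class variance of a 256-bin histogram."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or values.min() == values.max():
        raise ValueError("Otsu threshold needs >= 2 distinct values")
    hist, edges = np.histogram(values, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    weight = hist.astype(float)
    total = weight.sum()
    w0 = np.cumsum(weight)[:-1]
    w1 = total - w0
    sum0 = np.cumsum(weight * centers)[:-1]
    sum_total = (weight * centers).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = sum0 / w0
        mu1 = (sum_total - sum0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # threshold = right edge of the last bin of the dark class
    return float(edges[int(np.argmax(between)) + 1])


def _ellipse_footprint(ry: int, rx: int) -> np.ndarray:
    yy, xx = np.mgrid[-ry:ry + 1, -rx:rx + 1]
    return (yy / max(ry, 1e-9)) ** 2 + (xx / max(rx, 1e-9)) ** 2 <= 1.0


def _circularity(mask: np.ndarray) -> float:
    """4 pi A / P^2 with P the marching-squares contour length."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    perim = sum(np.sqrt(((np.diff(c, axis=0)) ** 2).sum(axis=1)).sum()
                for c in contours)
    if perim == 0:
        return 0.0
    area = float(mask.sum())
    return 4 * np.pi * area / perim ** 2


def ca1pc_postprocess(partitions: list[Partition], i_star: np.ndarray,
                      params: SegmentationParams) -> RoiList:
    """Turn partitions into nucleus ROIs (dark class, cleaned, filtered).

    Per partition: Otsu threshold of the processed image restricted to the
    partition, keep the darker class; binary opening then closing with an
    elliptical footprint of quarter-cell-diameter radii; keep connected
    components with area >= ``min_roi_size`` and circularity >=
    ``circularity_threshold``. Partitions smaller than ``min_cut_size``
    or with constant intensity are skipped.
    """
    R, C = i_star.shape
    # elliptical footprint with full axes of a quarter cell diameter
    # (semi-axes diameter/8); larger elements erase whole nuclei
    ry = max(1, int(round(params.y_diameter / 8)))
    rx = max(1, int(round(params.x_diameter / 8)))
    footprint = _ellipse_footprint(ry, rx)
    rois = []
    for part in partitions:
        if len(part.pixels) < params.min_cut_size:
            continue
        region = np.zeros(R * C, dtype=bool)
        region[part.pixels] = True
        region = region.reshape(R, C)
        vals = i_star[region]
        if vals.min() == vals.max():
            continue
        thr = otsu_threshold(vals)
        dark = region & (i_star < thr)
        cleaned = ndi.binary_opening(dark, structure=footprint)
        cleaned = ndi.binary_closing(cleaned, structure=footprint)
        cleaned &= region
        labels, n = ndi.label(cleaned, structure=np.ones((3, 3), dtype=int))
        for lab in range(1, n + 1):
            comp = labels == lab
            area = int(comp.sum())
            if area < params.min_roi_size:
                continue
            if _circularity(comp) < params.circularity_threshold:
                continue
            rois.append(Roi(mask=comp, im_shape=(R, C)))
    return RoiList(rois)


# ----------------------------------------------------------------------
# evaluation and the top-level entry point
def evaluate_segmentation(found: RoiList, truth: RoiList,
                          min_jaccard: float = 0.25):
    """Compare found against true ROIs by greedy Jaccard matching.

    Pairs are matched one-to-one in order of descending Jaccard index,
    accepting only pairs with J >= ``min_jaccard``. Returns
    (false_negative_rate, false_positive_rate, matching) where matching is
    a list of (truth_index, found_index, jaccard).
    """
    if len(truth) == 0:
        raise ValueError("false negative rate undefined for empty truth")
    t_supports = [r.support() for r in truth]
    f_supports = [r.support() for r in found]
    pairs = []
    for i, ts in enumerate(t_supports):
        for j, fs in enumerate(f_supports):
            inter = np.logical_and(ts, fs).sum()
            if inter == 0:
                continue
            union = np.logical_or(ts, fs).sum()
            j_idx = inter / union
            if j_idx >= min_jaccard:
                pairs.append((j_idx, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_t, used_f, matching = set(), set(), []
    for j_idx, i, j in pairs:
        if i in used_t or j in used_f:
            continue
        used_t.add(i)
        used_f.add(j)
        matching.append((i, j, float(j_idx)))
    fn = (len(truth) - len(matching)) / len(truth)
    fp = (len(found) - len(matching)) / len(found) if len(found) else 0.0
    return fn, fp, matching


def segment(dataset, variant: str = "normcut", label: str = "auto",
            channel=0, params: SegmentationParams | None = None,
            **kwargs) -> RoiList:
    """Segment a dataset's field of view into an ROI list.

    Keyword arguments populate :class:`SegmentationParams`. The resulting
    RoiList is stored on the dataset under ``label`` and persisted.
    """
    if params is None:
        params = SegmentationParams(variant=variant, **kwargs)
    j = dataset.channel_index(channel)
    frames = [f for cycle in dataset.cycles for f in cycle[j]]
    im_shape = dataset.frame_shape
    # NaN-free copy for correlation/affinity computation
    corr = pixel_correlations(frames, params.num_pcs, params.max_dist)
    w = affinity_normcut(corr, im_shape, params)
    if variant == "ca1pc":
        avg = dataset.time_average(j)
        avg = np.where(np.isfinite(avg), avg, np.nanmin(avg))
        i_star = ca1pc_process_image(avg, params.x_diameter,
                                     params.y_diameter)
        w = affinity_ca1pc(w, i_star, params.k_I)
        partitions = iterative_partition(w, params)
        roi_list = ca1pc_postprocess(partitions, i_star, params)
    elif variant == "normcut":
        partitions = iterative_partition(w, params)
        rois = []
        for part in partitions:
            mask = np.zeros(im_shape[0] * im_shape[1], dtype=bool)
            mask[part.pixels] = True
            rois.append(Roi(mask=mask.reshape(im_shape), im_shape=im_shape))
        roi_list = RoiList(rois)
    else:
        raise ValueError(f"unknown segmentation variant {variant!r}")
    for i, roi in enumerate(roi_list):
        roi.label = f"{label}_{i:03d}"
    roi_list.name = label
    dataset.add_roi_list(roi_list, name=label)
    return roi_list
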