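"""Regions of interest: weighted-pixel or polygon regions with identity.

An :class:`Roi` is either a list of polygons (vertices in continuous
(x=col, y=row) coordinates, pixel centers at integer positions) or a weight
mask over the image. Binary geometry — polygons and boolean masks — carries
the normalized weighting w_ip = 1/N_i over its N_i covered pixels, the
convention used by signal extraction; real-valued masks (e.g. component
weights) are kept verbatim.

Identity metadata: ``label`` names an ROI within one session, ``id`` tracks
the same structure across sessions (set by registration), ``tags`` is a free
set of annotation strings.
"""

from __future__ import annotations

from collections.abc import Iterator, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union


class Roi:
    """A single region of interest.

    Parameters
    ----------
    polygons : sequence of vertex lists, optional
        Each vertex list has >= 3 (x, y) pairs. Mutually exclusive with
        ``mask``.
    mask : 2-D array, optional
        Boolean masks select pixels (weights become 1/N); float masks are
        arbitrary per-pixel weights used as-is.
    im_shape : (rows, cols)
        Shape of the image the ROI lives in. Required for rasterization of
        polygon ROIs; inferred from ``mask`` when a mask is given.
    """

    def __init__(self, polygons=None, mask=None, id: str | None = None,
                 label: str | None = None, tags=(), im_shape=None):
        if (polygons is None) == (mask is None):
            raise ValueError("provide exactly one of polygons or mask")
        if polygons is not None:
            self.polygons = [np.asarray(p, dtype=float) for p in polygons]
            for p in self.polygons:
                if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                    raise ValueError("each polygon needs >= 3 (x, y) vertices")
            self.mask = None
        else:
            mask = np.asarray(mask)
            if mask.ndim != 2:
                raise ValueError("mask must be 2-D")
            self.polygons = None
            self.mask = mask
            if im_shape is None:
                im_shape = mask.shape
            elif tuple(im_shape) != mask.shape:
                raise ValueError("im_shape disagrees with mask shape")
        self.id = id
        self.label = label
        self.tags = set(tags)
        self.im_shape = tuple(im_shape) if im_shape is not None else None

    # ------------------------------------------------------------------
    @property
    def is_binary(self) -> bool:
        """True when weights follow the {0, 1/N} convention."""
        return self.polygons is not None or self.mask.dtype == bool

    def rasterize(self) -> np.ndarray:
        """Weight mask of shape ``im_shape``.

        Polygon ROIs: a pixel is covered when its center lies strictly
        inside the union of the polygons; covered pixels weigh 1/N with N
        the total covered count across all polygons. Boolean masks are
        normalized the same way; float masks are returned as stored.
        """
        if self.mask is not None:
            if self.mask.dtype == bool:
                n = int(self.mask.sum())
                out = np.zeros(self.mask.shape, dtype=float)
                if n:
                    out[self.mask] = 1.0 / n
                return out
            return np.asarray(self.mask, dtype=float)
        if self.im_shape is None:
            raise ValueError("polygon ROI needs im_shape to rasterize")
        rows, cols = self.im_shape
        covered = np.zeros((rows, cols), dtype=bool)
        geom = unary_union([Polygon(p) for p in self.polygons])
        minx, miny, maxx, maxy = geom.bounds
        c0 = max(0, int(np.ceil(minx)))
        c1 = min(cols - 1, int(np.floor(maxx)))
        r0 = max(0, int(np.ceil(miny)))
        r1 = min(rows - 1, int(np.floor(maxy)))
        if c0 <= c1 and r0 <= r1:
            cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
            inside = shapely.contains_xy(geom, cc.ravel(), rr.ravel())
            covered[rr.ravel()[inside], cc.ravel()[inside]] = True
        n = int(covered.sum())
        out = np.zeros((rows, cols), dtype=float)
        if n:
            out[covered] = 1.0 / n
        return out

    def support(self) -> np.ndarray:
        """Boolean mask of pixels with nonzero weight."""
        return self.rasterize() != 0

    @property
    def size(self) -> int:
        return int(self.support().sum())

    def copy(self) -> "Roi":
        if self.polygons is not None:
            return Roi(polygons=[p.copy() for p in self.polygons],
                       id=self.id, label=self.label, tags=set(self.tags),
                       im_shape=self.im_shape)
        return Roi(mask=self.mask.copy(), id=self.id, label=self.label,
                   tags=set(self.tags), im_shape=self.im_shape)

    # ------------------------------------------------------------------
    def _todict(self) -> dict:
        d = {"id": self.id, "label": self.label,
             "tags": sorted(self.tags), "im_shape": list(self.im_shape or ())}
        if self.polygons is not None:
            d["polygons"] = [p.tolist() for p in self.polygons]
        else:
            mask = self.mask
            d["mask_dtype"] = "bool" if mask.dtype == bool else "float"
            if mask.dtype == bool:
                rr, cc = np.nonzero(mask)
                d["mask_pixels"] = [rr.tolist(), cc.tolist()]
            else:
                rr, cc = np.nonzero(mask)
                d["mask_pixels"] = [rr.tolist(), cc.tolist(),
                                    mask[rr, cc].tolist()]
        return d

    @staticmethod
    def _fromdict(d: dict) -> "Roi":
        im_shape = tuple(d["im_shape"]) or None
        common = dict(id=d["id"], label=d["label"], tags=set(d["tags"]),
                      im_shape=im_shape)
        if "polygons" in d:
            return Roi(polygons=d["polygons"], **common)
        px = d["mask_pixels"]
        if d["mask_dtype"] == "bool":
            mask = np.zeros(im_shape, dtype=bool)
            mask[px[0], px[1]] = True
        else:
            mask = np.zeros(im_shape, dtype=float)
            mask[px[0], px[1]] = px[2]
        return Roi(mask=mask, **common)

    def __repr__(self) -> str:
        geom = (f"{len(self.polygons)} polygon(s)" if self.polygons is not None
                else f"{self.mask.dtype} mask")
        return f"Roi(label={self.label!r}, id={self.id!r}, {geom})"


class RoiList:
    """Ordered, named collection of :class:`Roi`.

    Labels must be unique among the ROIs that have one.
    """

    def __init__(self, rois: Sequence[Roi] = (), name: str | None = None):
        self.rois = list(rois)
        self.name = name
        labels = [r.label for r in self.rois if r.label is not None]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate ROI labels within one list")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self) -> Iterator[Roi]:
        return iter(self.rois)

    def __getitem__(self, i):
        return self.rois[i]

    def append(self, roi: Roi) -> None:
        self.rois.append(roi)

    def _todict(self) -> dict:
        return {"name": self.name, "rois": [r._todict() for r in self.rois]}

    @staticmethod
    def _fromdict(d: dict) -> "RoiList":
        return RoiList([Roi._fromdict(r) for r in d["rois"]], name=d["name"])

    def __repr__(self) -> str:
        return f"RoiList(name={self.name!r}, n={len(self)})"


def merge_rois(a: Roi, b: Roi) -> Roi:
    """Merge two ROIs of the same image.

    Overlapping polygons fuse into one polygon; disjoint polygons are kept
    side by side in a multi-polygon ROI. If either side is a mask ROI the
    merge happens in mask space (union of supports). Tags are united; the
    label comes from ``a``.
    """
    if a.im_shape != b.im_shape:
        raise ValueError("ROIs live in different image shapes")
    tags = a.tags | b.tags
    if a.polygons is not None and b.polygons is not None:
        geom = unary_union([Polygon(p) for p in a.polygons]
                           + [Polygon(p) for p in b.polygons])
        if isinstance(geom, Polygon):
            geoms = [geom]
        elif isinstance(geom, MultiPolygon):
            geoms = list(geom.geoms)
        else:  # GeometryCollection from degenerate input
            geoms = [g for g in geom.geoms if isinstance(g, Polygon)]
        polys = [np.asarray(g.exterior.coords)[:-1] for g in geoms]
        return Roi(polygons=polys, label=a.label, tags=tags,
                   im_shape=a.im_shape)
    union = a.support() | b.support()
    return Roi(mask=union, label=a.label, tags=tags, im_shape=a.im_shape)
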