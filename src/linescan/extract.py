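"""ROI fluorescence extraction, exact under per-frame missing pixels.

The signal of ROI i at frame t is a weighted sum of mean-normalized pixel
intensities, s_it = sum_p w_ip f_pt / f_p (w_ip = 1/N_i inside a binary
ROI). After line-by-line motion correction not every pixel location is
imaged in every frame; the extraction then solves the underlying linear
model — (f_pt - f_p)/f_p = sum_i a_pi (s_it - s*_i) with a_pi the entries
of pinv(W) and s*_i = sum_p w_ip — by least squares over the observed
pixel set P_t:

    s_it = sum_{p in P_t} w_ipt (f_pt - f_p)/f_p + s*_i,

where the w_ipt are the entries of pinv(A restricted to the rows P_t).
The restricted pseudoinverse is computed once per distinct observation
pattern and cached (line-wise motion produces few patterns). ROIs with no
observed pixel in a frame get NaN there.

Two cheaper exact special cases are dispatched automatically: full
observation (the plain weighted sum) and non-overlapping ROIs (a per-ROI
closed form with no pseudoinverse).
"""

from __future__ import annotations

import datetime
import os
from dataclasses import dataclass

import numpy as np

from .dataset import Dataset, SignalsRecord
from .rois import RoiList

_PINV_RTOL = 1e-10  # relative cutoff on singular values


@dataclass
class WeightMatrix:
    """ROI x pixel weights restricted to the pixels any ROI touches."""

    w: np.ndarray               # (num_rois, num_active)
    pixel_index: np.ndarray     # flat row-major indices of active pixels
    im_shape: tuple[int, int]
    is_binary: bool

    @property
    def num_rois(self) -> int:
        return self.w.shape[0]

    @property
    def roi_pixel_counts(self) -> np.ndarray:
        return (self.w != 0).sum(axis=1)

    @property
    def overlap_pixels(self) -> list[tuple[int, int]]:
        """Pixels carried by two or more ROIs, as (row, col) pairs."""
        shared = (self.w != 0).sum(axis=0) >= 2
        flat = self.pixel_index[shared]
        return [tuple(divmod(int(p), self.im_shape[1])) for p in flat]

    @property
    def has_overlap(self) -> bool:
        return bool(((self.w != 0).sum(axis=0) >= 2).any())


def build_weights(roi_list: RoiList, im_shape=None) -> WeightMatrix:
    """Stack rasterized ROI weights into a :class:`WeightMatrix`."""
    masks = []
    binary = True
    for roi in roi_list:
        if im_shape is not None and roi.im_shape is None:
            roi.im_shape = tuple(im_shape)
        masks.append(roi.rasterize().ravel())
        binary = binary and roi.is_binary
    full = np.asarray(masks)
    if im_shape is None:
        im_shape = roi_list[0].im_shape
    active = np.flatnonzero((full != 0).any(axis=0))
    return WeightMatrix(w=full[:, active], pixel_index=active,
                        im_shape=tuple(im_shape), is_binary=binary)


def remove_overlaps(wm: WeightMatrix) -> WeightMatrix:
    """Drop pixels shared by several ROIs and renormalize the weights.

    Only defined for binary (1/N) weights. An ROI emptied by the removal
    keeps zero support; extraction then reports NaN for it everywhere.
    """
    if not wm.is_binary:
        raise ValueError("overlap removal is defined for binary ROIs only")
    support = wm.w != 0
    shared = support.sum(axis=0) >= 2
    support = support & ~shared
    counts = support.sum(axis=1)
    w = np.zeros_like(wm.w)
    for i in range(wm.num_rois):
        if counts[i]:
            w[i, support[i]] = 1.0 / counts[i]
    return WeightMatrix(w=w, pixel_index=wm.pixel_index,
                        im_shape=wm.im_shape, is_binary=True)


@dataclass
class ExtractionInputs:
    """Frame intensities restricted to the active pixels.

    ``frames``: (num_frames, num_active) with NaN marking unobserved
    pixels; ``pixel_means``: per-pixel time-average f_p over observed
    frames (supplied externally when the mean should pool several cycles).
    """

    frames: np.ndarray
    pixel_means: np.ndarray

    @classmethod
    def from_stack(cls, stack: np.ndarray, wm: WeightMatrix,
                   pixel_means: np.ndarray | None = None):
        T = stack.shape[0]
        flat = stack.reshape(T, -1)[:, wm.pixel_index]
        if pixel_means is None:
            with np.errstate(invalid="ignore"):
                pixel_means = np.nanmean(flat, axis=0)
        else:
            pixel_means = np.asarray(pixel_means).ravel()[wm.pixel_index]
        return cls(frames=flat, pixel_means=pixel_means)


def _check_means(wm: WeightMatrix, f_p: np.ndarray) -> None:
    bad = ((wm.w != 0).any(axis=0)
           & (~np.isfinite(f_p) | (f_p <= 0)))
    if bad.any():
        p = wm.pixel_index[np.argmax(bad)]
        r, c = divmod(int(p), wm.im_shape[1])
        raise ValueError(
            f"pixel ({r}, {c}) has non-positive mean intensity under a "
            "nonzero ROI weight; normalized extraction is undefined")


def extract_simple(wm: WeightMatrix, inputs: ExtractionInputs) -> np.ndarray:
    """Full-observation weighted sum: s_it = sum_p w_ip f_pt / f_p."""
    if not np.isfinite(inputs.frames).all():
        raise ValueError("extract_simple requires fully observed frames")
    _check_means(wm, inputs.pixel_means)
    return wm.w @ (inputs.frames / inputs.pixel_means).T


def extract_missing(wm: WeightMatrix, inputs: ExtractionInputs) -> np.ndarray:
    """Least-squares extraction under arbitrary observation patterns."""
    _check_means(wm, inputs.pixel_means)
    f = inputs.frames
    rel = (f - inputs.pixel_means) / inputs.pixel_means
    s_star = wm.w.sum(axis=1)
    A = np.linalg.pinv(wm.w, rcond=_PINV_RTOL)  # (pixels, rois) = a_pi
    support = wm.w != 0
    T = f.shape[0]
    out = np.empty((wm.num_rois, T))
    cache: dict[bytes, np.ndarray] = {}
    observed = np.isfinite(f)
    for t in range(T):
        obs = observed[t]
        if not obs.any():
            out[:, t] = np.nan
            continue
        key = obs.tobytes()
        wt = cache.get(key)
        if wt is None:
            wt = np.linalg.pinv(A[obs, :], rcond=_PINV_RTOL)
            cache[key] = wt
        out[:, t] = wt @ rel[t, obs] + s_star
        empty = ~(support & obs).any(axis=1)
        out[empty, t] = np.nan
    return out


def extract_nonoverlapping(wm: WeightMatrix,
                           inputs: ExtractionInputs) -> np.ndarray:
    """Closed-form extraction for ROIs that share no pixel."""
    if wm.has_overlap:
        raise ValueError("ROIs overlap; use extract_missing instead")
    _check_means(wm, inputs.pixel_means)
    f = inputs.frames
    rel = (f - inputs.pixel_means) / inputs.pixel_means
    obs = np.isfinite(f)
    rel0 = np.where(obs, rel, 0.0)
    w2_total = (wm.w ** 2).sum(axis=1)                 # per ROI
    w2_obs = obs @ (wm.w ** 2).T                       # (T, rois)
    wsum = rel0 @ wm.w.T                               # (T, rois)
    s_star = wm.w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (w2_total / w2_obs) * wsum + s_star
    out[w2_obs == 0] = np.nan
    return out.T


def extract_binary(wm: WeightMatrix, inputs: ExtractionInputs) -> np.ndarray:
    """Binary-mask special case: s_it = (1/N_it) sum_{p in P_it} f_pt/f_p."""
    if not wm.is_binary:
        raise ValueError("binary extraction requires binary weights")
    _check_means(wm, inputs.pixel_means)
    support = wm.w != 0
    obs = np.isfinite(inputs.frames)
    norm = np.where(obs, inputs.frames / inputs.pixel_means, 0.0)
    n_it = obs @ support.T.astype(float)               # (T, rois)
    sums = norm @ support.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / n_it
    out[n_it == 0] = np.nan
    return out.T


def extract(dataset: Dataset, rois=None, channel=0,
            label: str | None = None,
            exclude_overlaps: bool = False) -> SignalsRecord:
    """Extract per-ROI signals from a dataset channel and persist them.

    ``rois`` is an RoiList or the name of one stored on the dataset
    (defaults to the only stored list). The most specific exact formula is
    dispatched: plain weighted sum under full observation, the
    non-overlapping closed form when no pixel is shared, the pseudoinverse
    least-squares estimator otherwise. A verification overlay (PDF) is
    written into the dataset bundle.
    """
    j = dataset.channel_index(channel)
    if rois is None:
        if len(dataset.roi_lists) != 1:
            raise KeyError("specify rois: dataset has zero or several lists")
        roi_list = next(iter(dataset.roi_lists.values()))
    elif isinstance(rois, str):
        try:
            roi_list = dataset.roi_lists[rois]
        except KeyError:
            raise KeyError(f"no ROI list named {rois!r}") from None
    else:
        roi_list = rois
    wm = build_weights(roi_list, dataset.frame_shape)
    overlap_pixels = wm.overlap_pixels
    if exclude_overlaps:
        wm = remove_overlaps(wm)
    mean_image = dataset.time_average(j)
    f_p_full = mean_image.ravel()

    signals = []
    for cycle in dataset.cycles:
        stack = cycle[j].to_array()
        inputs = ExtractionInputs.from_stack(stack, wm,
                                             pixel_means=f_p_full)
        if np.isfinite(inputs.frames).all():
            sig = extract_simple(wm, inputs)
        elif not wm.has_overlap:
            sig = extract_nonoverlapping(wm, inputs)
        else:
            sig = extract_missing(wm, inputs)
        signals.append(sig)

    record = SignalsRecord(
        raw_signals=signals,
        mean_image=mean_image,
        overlap_pixels=overlap_pixels,
        roi_list_name=roi_list.name or "rois",
        channel=dataset.channel_names[j],
        timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
        roi_ids=[r.id for r in roi_list],
        roi_labels=[r.label for r in roi_list],
        roi_tags=[set(r.tags) for r in roi_list])
    name = label or roi_list.name or "signals"
    dataset.signal_records[name] = record
    dataset.save()
    _write_verification_pdf(dataset, record, wm, name)
    return record


def _write_verification_pdf(dataset: Dataset, record: SignalsRecord,
                            wm: WeightMatrix, name: str) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    img = np.where(np.isfinite(record.mean_image), record.mean_image, 0.0)
    ax.imshow(img, cmap="gray", interpolation="nearest")
    support = np.zeros(wm.im_shape, dtype=float).ravel()
    for i in range(wm.num_rois):
        support[wm.pixel_index[wm.w[i] != 0]] = i + 1
    ax.contour(support.reshape(wm.im_shape) > 0, levels=[0.5],
               colors="red", linewidths=0.5)
    if record.overlap_pixels:
        ov = np.array(record.overlap_pixels)
        ax.plot(ov[:, 1], ov[:, 0], ".", color="yellow", markersize=2)
    ax.set_title(f"extraction overlay: {name}")
    ax.axis("off")
    out = os.path.join(dataset.save_path, "signals")
    os.makedirs(out, exist_ok=True)
    fig.savefig(os.path.join(out, f"{name}_verification.pdf"))
    plt.close(fig)
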