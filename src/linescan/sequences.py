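"""Frame sequences: re-iterable sources of 2-D image frames.

A :class:`FrameSequence` is the unit of raw data in this package: an object
that can be traversed any number of times, each traversal yielding the same
ordered frames as 2-D float arrays. Pixels that were not observed (e.g. rows
lost to motion correction) are marked NaN; ``numpy.isfinite`` of a frame is
its observation mask.

Concrete sources: in-memory stacks (:class:`ArraySequence`), multi-page TIFF
files (:class:`TiffSequence`), and HDF5 datasets (:class:`Hdf5Sequence`).
"""

from __future__ import annotations

import os
from collections.abc import Iterator

import h5py
import numpy as np
import tifffile


class FrameSequence:
    """Abstract re-iterable sequence of equally shaped 2-D frames."""

    @property
    def shape(self) -> tuple[int, int, int]:
        """(num_frames, num_rows, num_cols)."""
        raise NotImplementedError

    @property
    def num_frames(self) -> int:
        return self.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.shape[1:]

    def __len__(self) -> int:
        return self.num_frames

    def __iter__(self) -> Iterator[np.ndarray]:
        raise NotImplementedError

    def _todict(self) -> dict:
        """JSON-serializable description used by the dataset manifest."""
        raise NotImplementedError

    def to_array(self) -> np.ndarray:
        """Materialize as a (T, R, C) float array with NaN for unobserved."""
        out = np.empty(self.shape, dtype=float)
        for t, frame in enumerate(self):
            out[t] = frame
        return out

    @staticmethod
    def create(source, **kwargs) -> "FrameSequence":
        """Coerce ``source`` into a FrameSequence.

        Arrays (or anything array-like of dim 3) become
        :class:`ArraySequence`; paths ending in .tif/.tiff become
        :class:`TiffSequence`; paths ending in .h5/.hdf5 become
        :class:`Hdf5Sequence`.
        """
        if isinstance(source, FrameSequence):
            return source
        if isinstance(source, (str, os.PathLike)):
            path = os.fspath(source)
            lower = path.lower()
            if lower.endswith((".tif", ".tiff")):
                return TiffSequence(path)
            if lower.endswith((".h5", ".hdf5")):
                return Hdf5Sequence(path, **kwargs)
            raise ValueError(f"cannot infer sequence type from path {path!r}")
        return ArraySequence(np.asarray(source))

    @staticmethod
    def _fromdict(d: dict) -> "FrameSequence":
        kind = d["__type__"]
        if kind == "hdf5":
            return Hdf5Sequence(d["path"], dataset=d["dataset"],
                                layout=d["layout"],
                                mask_dataset=d.get("mask_dataset"))
        if kind == "tiff":
            return TiffSequence(d["path"])
        raise ValueError(f"unknown sequence type {kind!r}")


class ArraySequence(FrameSequence):
    """FrameSequence view of an in-memory (T, R, C) stack.

    NaN entries mark unobserved pixels. The stack is converted to float only
    lazily, per yielded frame, so integer sources are kept intact.
    """

    def __init__(self, array: np.ndarray):
        array = np.asarray(array)
        if array.ndim != 3:
            raise ValueError(
                f"expected a (frames, rows, cols) stack, got ndim={array.ndim}")
        self._array = array

    @property
    def shape(self) -> tuple[int, int, int]:
        return self._array.shape

    def __iter__(self) -> Iterator[np.ndarray]:
        for frame in self._array:
            yield np.asarray(frame, dtype=float)

    @property
    def raw(self) -> np.ndarray:
        return self._array

    def _todict(self) -> dict:
        raise TypeError("in-memory sequences are persisted as HDF5 bundles")


class TiffSequence(FrameSequence):
    """FrameSequence backed by a grayscale multi-page TIFF file."""

    def __init__(self, path: str):
        self.path = os.fspath(path)
        with tifffile.TiffFile(self.path) as tif:
            n = len(tif.pages)
            first = tif.pages[0].shape
        if len(first) != 2:
            raise ValueError(f"{self.path}: pages are not 2-D grayscale")
        self._shape = (n, first[0], first[1])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self._shape

    def __iter__(self) -> Iterator[np.ndarray]:
        with tifffile.TiffFile(self.path) as tif:
            for page in tif.pages:
                yield np.asarray(page.asarray(), dtype=float)

    def _todict(self) -> dict:
        return {"__type__": "tiff", "path": os.path.abspath(self.path)}


class Hdf5Sequence(FrameSequence):
    """FrameSequence backed by an HDF5 dataset.

    Parameters
    ----------
    path : str
        HDF5 file path.
    dataset : str
        Name of the node holding the frame data.
    layout : str
        Axis-order string over characters 't' (time), 'y' (row), 'x'
        (column); default "tyx". One channel per node.
    mask_dataset : str, optional
        Name of a boolean node of the same (t, y, x) extent; False marks
        unobserved pixels, which are yielded as NaN.
    """

    def __init__(self, path: str, dataset: str = "data", layout: str = "tyx",
                 mask_dataset: str | None = None):
        if sorted(layout) != ["t", "x", "y"]:
            raise ValueError(f"layout must permute 'tyx', got {layout!r}")
        self.path = os.fspath(path)
        self.dataset = dataset
        self.layout = layout
        self.mask_dataset = mask_dataset
        self._perm = [layout.index(ax) for ax in "tyx"]
        with h5py.File(self.path, "r") as f:
            raw_shape = f[self.dataset].shape
        if len(raw_shape) != len(layout):
            raise ValueError(
                f"{self.path}:{dataset} has ndim {len(raw_shape)}, "
                f"layout {layout!r} expects {len(layout)}")
        self._shape = tuple(raw_shape[p] for p in self._perm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self._shape

    def __iter__(self) -> Iterator[np.ndarray]:
        t_axis = self.layout.index("t")
        with h5py.File(self.path, "r") as f:
            data = f[self.dataset]
            mask = f[self.mask_dataset] if self.mask_dataset else None
            for t in range(self._shape[0]):
                idx = [slice(None)] * 3
                idx[t_axis] = t
                frame = np.asarray(data[tuple(idx)], dtype=float)
                if self.layout.replace("t", "") == "xy":
                    frame = frame.T
                if mask is not None:
                    m = np.asarray(mask[tuple(idx)], dtype=bool)
                    if self.layout.replace("t", "") == "xy":
                        m = m.T
                    frame = frame.copy()
                    frame[~m] = np.nan
                yield frame

    def _todict(self) -> dict:
        return {"__type__": "hdf5", "path": os.path.abspath(self.path),
                "dataset": self.dataset, "layout": self.layout,
                "mask_dataset": self.mask_dataset}
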