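"""The imaging dataset: cycles x channels of frames plus derived products.

A :class:`Dataset` bundles the frame sequences of one imaging session —
organized as an ordered list of *cycles* (continuous acquisition epochs),
each holding one :class:`~linescan.sequences.FrameSequence` per optical
*channel* — together with everything derived from them: per-line motion
displacements, named ROI lists, and named extracted-signal records.

Datasets persist as a directory bundle (conventional suffix ``.ls``):

    <path>.ls/
      manifest.json                  channel names, shapes, references
      frames/cycle{i}_chan{j}.h5     /data plus boolean /observed mask
      displacements.h5               per-cycle (frames, rows, 2) int arrays
      rois/<name>.json
      signals/<name>.h5 (+ .json)

``load(save(d))`` reproduces frames, metadata, ROI lists and signal records.
"""

from __future__ import annotations

import csv
import json
import os
import shutil
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile

from .rois import RoiList
from .sequences import ArraySequence, FrameSequence, Hdf5Sequence

BUNDLE_SUFFIX = ".ls"


@dataclass
class SignalsRecord:
    """Extraction output: per-ROI time series plus provenance.

    ``raw_signals`` is one (num_rois, num_frames) float array per cycle,
    with NaN where no pixel of an ROI was imaged in a frame.
    """

    raw_signals: list[np.ndarray]
    mean_image: np.ndarray
    overlap_pixels: list[tuple[int, int]]
    roi_list_name: str
    channel: str
    timestamp: str
    roi_ids: list = field(default_factory=list)
    roi_labels: list = field(default_factory=list)
    roi_tags: list = field(default_factory=list)


def _resolve_channel(channel_names: list[str], channel) -> int:
    if isinstance(channel, (int, np.integer)):
        if not 0 <= channel < len(channel_names):
            raise KeyError(f"channel index {channel} out of range")
        return int(channel)
    try:
        return channel_names.index(channel)
    except ValueError:
        raise KeyError(f"unknown channel {channel!r}") from None


class Dataset:
    """Multi-cycle, multi-channel imaging dataset with persistence.

    Parameters
    ----------
    iterables : list of lists
        ``iterables[i][j]`` is the frame source of cycle ``i``, channel
        ``j`` — a FrameSequence, a 3-D array, or a TIFF/HDF5 path.
    save_path : str
        Directory the bundle is written to (suffix ``.ls`` appended when
        absent). The dataset is saved immediately on creation.
    channel_names : list of str, optional
        Defaults to "0", "1", ...
    """

    def __init__(self, iterables, save_path, channel_names=None,
                 displacements=None, _defer_save=False):
        if not iterables or not iterables[0]:
            raise ValueError("iterables must be a non-empty list of lists")
        self.cycles: list[list[FrameSequence]] = [
            [FrameSequence.create(src) for src in cycle] for cycle in iterables]
        n_chan = len(self.cycles[0])
        frame_shape = self.cycles[0][0].frame_shape
        for i, cycle in enumerate(self.cycles):
            if len(cycle) != n_chan:
                raise ValueError(f"cycle {i} has {len(cycle)} channels, "
                                 f"expected {n_chan}")
            n_frames = cycle[0].num_frames
            for j, seq in enumerate(cycle):
                if seq.frame_shape != frame_shape:
                    raise ValueError(
                        f"cycle {i} channel {j}: frame shape "
                        f"{seq.frame_shape} != {frame_shape}")
                if seq.num_frames != n_frames:
                    raise ValueError(
                        f"cycle {i} channel {j}: {seq.num_frames} frames, "
                        f"other channels of the cycle have {n_frames}")
        if channel_names is None:
            channel_names = [str(j) for j in range(n_chan)]
        if len(channel_names) != n_chan:
            raise ValueError("one channel name per channel required")
        if len(set(channel_names)) != n_chan:
            raise ValueError("channel names must be unique")
        self.channel_names = list(channel_names)
        self.displacements = displacements  # per cycle: (F, R, 2) int array
        self.roi_lists: dict[str, RoiList] = {}
        self.signal_records: dict[str, SignalsRecord] = {}
        self.save_path = self._canonical_path(save_path)
        if not _defer_save:
            self.save()

    # ------------------------------------------------------------------
    @staticmethod
    def _canonical_path(path) -> str:
        path = os.fspath(path)
        if not path.endswith(BUNDLE_SUFFIX):
            path += BUNDLE_SUFFIX
        return path

    @property
    def num_cycles(self) -> int:
        return len(self.cycles)

    @property
    def num_channels(self) -> int:
        return len(self.channel_names)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.cycles[0][0].frame_shape

    def channel_index(self, channel) -> int:
        return _resolve_channel(self.channel_names, channel)

    # ------------------------------------------------------------------
    # persistence
    def save(self) -> None:
        path = self.save_path
        os.makedirs(path, exist_ok=True)
        frames_dir = os.path.join(path, "frames")
        os.makedirs(frames_dir, exist_ok=True)
        refs = []
        for i, cycle in enumerate(self.cycles):
            cycle_refs = []
            for j, seq in enumerate(cycle):
                fname = os.path.join(frames_dir, f"cycle{i:02d}_chan{j:02d}.h5")
                already_here = (isinstance(seq, Hdf5Sequence)
                                and os.path.abspath(seq.path)
                                == os.path.abspath(fname))
                if not already_here:
                    _write_frames_h5(fname, seq)
                    seq = Hdf5Sequence(fname, dataset="data", layout="tyx",
                                       mask_dataset="observed")
                    self.cycles[i][j] = seq
                cycle_refs.append({"file": os.path.basename(fname)})
            refs.append(cycle_refs)
        if self.displacements is not None:
            with h5py.File(os.path.join(path, "displacements.h5"), "w") as f:
                for i, disp in enumerate(self.displacements):
                    f.create_dataset(f"cycle{i:02d}",
                                     data=np.asarray(disp, dtype=np.int32))
        rois_dir = os.path.join(path, "rois")
        if self.roi_lists:
            os.makedirs(rois_dir, exist_ok=True)
        for name, rl in self.roi_lists.items():
            with open(os.path.join(rois_dir, f"{name}.json"), "w") as f:
                json.dump(rl._todict(), f, sort_keys=True)
        sig_dir = os.path.join(path, "signals")
        if self.signal_records:
            os.makedirs(sig_dir, exist_ok=True)
        for name, rec in self.signal_records.items():
            _write_signals(os.path.join(sig_dir, name), rec)
        manifest = {
            "channel_names": self.channel_names,
            "frame_shape": list(self.frame_shape),
            "num_cycles": self.num_cycles,
            "frames": refs,
            "has_displacements": self.displacements is not None,
            "roi_lists": sorted(self.roi_lists),
            "signal_records": sorted(self.signal_records),
        }
        with open(os.path.join(path, "manifest.json"), "w") as f:
            json.dump(manifest, f, sort_keys=True, indent=1)

    @classmethod
    def load(cls, path) -> "Dataset":
        path = cls._canonical_path(path)
        manifest_path = os.path.join(path, "manifest.json")
        if not os.path.isfile(manifest_path):
            raise FileNotFoundError(f"no dataset bundle at {path}")
        with open(manifest_path) as f:
            manifest = json.load(f)
        iterables = []
        for i, cycle_refs in enumerate(manifest["frames"]):
            cycle = []
            for ref in cycle_refs:
                fname = os.path.join(path, "frames", ref["file"])
                cycle.append(Hdf5Sequence(fname, dataset="data", layout="tyx",
                                          mask_dataset="observed"))
            iterables.append(cycle)
        displacements = None
        if manifest["has_displacements"]:
            with h5py.File(os.path.join(path, "displacements.h5"), "r") as f:
                displacements = [np.asarray(f[f"cycle{i:02d}"])
                                 for i in range(manifest["num_cycles"])]
        ds = cls(iterables, path, channel_names=manifest["channel_names"],
                 displacements=displacements, _defer_save=True)
        for name in manifest["roi_lists"]:
            with open(os.path.join(path, "rois", f"{name}.json")) as f:
                ds.roi_lists[name] = RoiList._fromdict(json.load(f))
        for name in manifest["signal_records"]:
            ds.signal_records[name] = _read_signals(
                os.path.join(path, "signals", name))
        return ds

    def add_roi_list(self, roi_list: RoiList, name: str | None = None) -> None:
        name = name or roi_list.name or "rois"
        roi_list.name = name
        self.roi_lists[name] = roi_list
        self.save()

    # ------------------------------------------------------------------
    # derived images
    def time_average(self, channel) -> np.ndarray:
        """Pixelwise mean over all frames of all cycles, ignoring
        unobserved (NaN) pixels; never-observed pixels stay NaN."""
        j = self.channel_index(channel)
        total = np.zeros(self.frame_shape, dtype=float)
        count = np.zeros(self.frame_shape, dtype=float)
        for cycle in self.cycles:
            for frame in cycle[j]:
                obs = np.isfinite(frame)
                total[obs] += frame[obs]
                count[obs] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = total / count
        avg[count == 0] = np.nan
        return avg

    def time_averages(self) -> list[np.ndarray]:
        return [self.time_average(j) for j in range(self.num_channels)]

    # ------------------------------------------------------------------
    # exports
    def export_frames(self, filenames, fmt: str = "TIFF16",
                      scale_values: bool = False,
                      fill_gaps: bool = False) -> None:
        """Write frames to TIFF16 or HDF5 files, one file per cycle/channel.

        ``filenames`` mirrors the cycles x channels layout. With
        ``fill_gaps``, an unobserved pixel is replaced by its value in the
        nearest frame (of the same cycle) in which it was observed, ties
        broken toward the earlier frame; pixels observed nowhere become 0.
        With ``scale_values``, the dataset-wide maximum maps to the output
        format's integer maximum (65535).
        """
        fmt = fmt.upper()
        if fmt not in ("TIFF16", "HDF5"):
            raise ValueError(f"unsupported format {fmt!r}")
        if (len(filenames) != self.num_cycles
                or any(len(row) != self.num_channels for row in filenames)):
            raise ValueError("filenames must mirror cycles x channels")
        stacks = {}
        global_max = 0.0
        for i, cycle in enumerate(self.cycles):
            for j in range(self.num_channels):
                stack = cycle[j].to_array()
                if fill_gaps:
                    stack = fill_unobserved(stack)
                m = np.nanmax(stack) if np.isfinite(stack).any() else 0.0
                global_max = max(global_max, float(m))
                stacks[(i, j)] = stack
        scale = 1.0
        if scale_values and global_max > 0:
            scale = 65535.0 / global_max
        for (i, j), stack in stacks.items():
            out = stack * scale
            out = np.where(np.isfinite(out), out, 0.0)
            fname = filenames[i][j]
            if fmt == "TIFF16":
                tifffile.imwrite(fname,
                                 np.round(out).astype(np.uint16))
            else:
                with h5py.File(fname, "w") as f:
                    if scale_values:
                        f.create_dataset(
                            "data", data=np.round(out).astype(np.uint16))
                    else:
                        f.create_dataset("data", data=out)
                    f.create_dataset("observed", data=np.isfinite(stack))
                    f["data"].attrs["layout"] = "tyx"

    def export_averages(self, filenames, fmt: str = "TIFF16",
                        scale_values: bool = False) -> None:
        """Write the per-channel time averages, one file per channel."""
        if len(filenames) != self.num_channels:
            raise ValueError("one filename per channel required")
        avgs = self.time_averages()
        peak = max((float(np.nanmax(a)) for a in avgs
                    if np.isfinite(a).any()), default=0.0)
        scale = 65535.0 / peak if scale_values and peak > 0 else 1.0
        for fname, avg in zip(filenames, avgs):
            out = np.where(np.isfinite(avg), avg * scale, 0.0)
            if fmt.upper() == "TIFF16":
                tifffile.imwrite(fname, np.round(out).astype(np.uint16))
            elif fmt.upper() == "HDF5":
                with h5py.File(fname, "w") as f:
                    f.create_dataset("data", data=out)
            else:
                raise ValueError(f"unsupported format {fmt!r}")

    def export_signals(self, path, record_name: str | None = None) -> None:
        """Write one signals record as CSV.

        Layout: three header rows (id, label, tags — tags ';'-joined,
        sorted) with two leading spacer cells, then one row per frame time:
        cycle index, frame index, one signal column per ROI. NaN becomes an
        empty field.
        """
        rec = self._get_record(record_name)
        with open(path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["id", ""] + [x if x is not None else ""
                                          for x in rec.roi_ids])
            writer.writerow(["label", ""] + [x if x is not None else ""
                                             for x in rec.roi_labels])
            writer.writerow(["tags", ""] + [";".join(sorted(t))
                                            for t in rec.roi_tags])
            for i, sig in enumerate(rec.raw_signals):
                for t in range(sig.shape[1]):
                    row = [i, t] + ["" if not np.isfinite(v) else repr(float(v))
                                    for v in sig[:, t]]
                    writer.writerow(row)

    def _get_record(self, record_name: str | None) -> SignalsRecord:
        if record_name is None:
            if len(self.signal_records) != 1:
                raise KeyError("record_name required (zero or several records)")
            return next(iter(self.signal_records.values()))
        try:
            return self.signal_records[record_name]
        except KeyError:
            raise KeyError(f"no signals record named {record_name!r}") from None

    # convenience hooks implemented in sibling modules -------------------
    def segment(self, variant: str = "normcut", label: str = "auto", **kwargs):
        from .segment import segment as _segment
        return _segment(self, variant=variant, label=label, **kwargs)

    def extract(self, rois=None, channel=0, label: str | None = None,
                exclude_overlaps: bool = False):
        from .extract import extract as _extract
        return _extract(self, rois=rois, channel=channel, label=label,
                        exclude_overlaps=exclude_overlaps)

    def signals(self, record_name: str | None = None) -> SignalsRecord:
        return self._get_record(record_name)

    def delete(self) -> None:
        shutil.rmtree(self.save_path, ignore_errors=True)

    def __repr__(self) -> str:
        return (f"Dataset({self.num_cycles} cycle(s), "
                f"{self.num_channels} channel(s), "
                f"frame_shape={self.frame_shape}, path={self.save_path!r})")


def fill_unobserved(stack: np.ndarray) -> np.ndarray:
    """Replace NaN pixels by the nearest-in-time observed value.

    Search alternates backward/forward around each frame, preferring the
    earlier frame on distance ties; pixels observed in no frame become 0.
    """
    stack = np.array(stack, dtype=float)
    T = stack.shape[0]
    observed = np.isfinite(stack)
    out = stack.copy()
    for t in range(T):
        missing = ~observed[t]
        if not missing.any():
            continue
        for d in range(1, T):
            if not missing.any():
                break
            for t2 in (t - d, t + d):
                if 0 <= t2 < T:
                    take = missing & observed[t2]
                    if take.any():
                        out[t][take] = stack[t2][take]
                        missing &= ~take
        out[t][missing] = 0.0
    return out


def _write_frames_h5(fname: str, seq: FrameSequence) -> None:
    T, R, C = seq.shape
    raw = None
    if isinstance(seq, ArraySequence):
        raw = seq.raw
    with h5py.File(fname, "w") as f:
        if raw is not None and raw.dtype.kind in "iub":
            f.create_dataset("data", data=raw)
            f.create_dataset("observed", data=np.ones(raw.shape, dtype=bool))
        else:
            data = f.create_dataset("data", shape=(T, R, C), dtype="f8")
            mask = f.create_dataset("observed", shape=(T, R, C), dtype=bool)
            for t, frame in enumerate(seq):
                obs = np.isfinite(frame)
                data[t] = np.where(obs, frame, 0.0)
                mask[t] = obs
        f["data"].attrs["layout"] = "tyx"


def _write_signals(base: str, rec: SignalsRecord) -> None:
    with h5py.File(base + ".h5", "w") as f:
        for i, sig in enumerate(rec.raw_signals):
            f.create_dataset(f"cycle{i:02d}", data=sig)
        f.create_dataset("mean_image",
                         data=np.asarray(rec.mean_image, dtype=float))
    meta = {
        "overlap_pixels": [list(map(int, p)) for p in rec.overlap_pixels],
        "roi_list_name": rec.roi_list_name,
        "channel": rec.channel,
        "timestamp": rec.timestamp,
        "roi_ids": rec.roi_ids,
        "roi_labels": rec.roi_labels,
        "roi_tags": [sorted(t) for t in rec.roi_tags],
        "num_cycles": len(rec.raw_signals),
    }
    with open(base + ".json", "w") as f:
        json.dump(meta, f, sort_keys=True)


def _read_signals(base: str) -> SignalsRecord:
    with open(base + ".json") as f:
        meta = json.load(f)
    with h5py.File(base + ".h5", "r") as f:
        raw = [np.asarray(f[f"cycle{i:02d}"])
               for i in range(meta["num_cycles"])]
        mean_image = np.asarray(f["mean_image"])
    return SignalsRecord(
        raw_signals=raw, mean_image=mean_image,
        overlap_pixels=[tuple(p) for p in meta["overlap_pixels"]],
        roi_list_name=meta["roi_list_name"], channel=meta["channel"],
        timestamp=meta["timestamp"], roi_ids=meta["roi_ids"],
        roi_labels=meta["roi_labels"],
        roi_tags=[set(t) for t in meta["roi_tags"]])
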