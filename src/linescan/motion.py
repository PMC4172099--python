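"""Line-by-line motion correction with a hidden Markov model.

During laser-scanning microscopy each image row is acquired at a different
time, so brain motion displaces individual rows, not whole frames. The
correction models the unknown per-row displacement as the hidden state of
an HMM:

* states: integer 2-D displacements (dy, dx) with |dy| <= max_dy,
  |dx| <= max_dx, enumerated row-major over (dy, dx);
* transitions: one step of a bounded random walk — moves restricted to the
  nearest neighbours {-1, 0, +1}^2, with probabilities from an isotropic
  discretized Gaussian of std ``movement_sigma`` normalized over the nine
  moves (moves leaving the displacement bounds are forbidden and their
  probability mass dropped);
* emissions: Poisson photon statistics. Intensities divided by the detector
  ``gain`` are treated as photon counts k with mean given by the
  gain-scaled time-averaged reference image at the displaced position;
  log p = k log lam - lam - log Gamma(k+1), summed over the pixels of the
  row that overlap the reference (pixels falling off the reference
  contribute zero — they are marginalized out).

Decoding uses the Viterbi algorithm restricted to a beam: only the N
highest-scoring states are retained per line step (ties at the boundary
broken by ascending state index), reducing the cost from O(S T) to O(N T)
for T = num_frames * num_rows line steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import gammaln

from .dataset import Dataset
from .sequences import ArraySequence, FrameSequence

_LAMBDA_FLOOR = 1e-6  # photons; keeps log(lam) finite on dark reference pixels


@dataclass
class HmmParams:
    """Parameters of the HMM motion-correction procedure.

    ``gain`` (intensity units per photon) and ``movement_sigma`` (pixels of
    displacement random walk per line step) are estimated from the data
    when left ``None``. ``trim_criterion`` selects the output extent:
    "minimal" (default; region inside the field of view in every frame),
    "maximal" (bounding box of everything ever imaged), or a fraction f in
    (0, 1] (largest rectangle imaged in at least f of the frames).
    """

    num_states_retained: int = 50
    max_displacement: tuple[int, int] = (10, 10)
    correction_channels: list | None = None
    trim_criterion: object = "minimal"
    gain: float | None = None
    movement_sigma: float | None = None
    max_iterations: int = 3

    def __post_init__(self):
        if self.num_states_retained < 1:
            raise ValueError("num_states_retained must be >= 1")
        if min(self.max_displacement) < 0:
            raise ValueError("max_displacement must be non-negative")
        if isinstance(self.trim_criterion, (int, float)):
            if not 0 < self.trim_criterion <= 1:
                raise ValueError("trim fraction must lie in (0, 1]")
        elif self.trim_criterion not in ("minimal", "maximal"):
            raise ValueError(f"bad trim_criterion {self.trim_criterion!r}")


class HiddenStateSpace:
    """Displacement states, transition model, and initial distribution."""

    def __init__(self, max_displacement: tuple[int, int],
                 movement_sigma: float):
        self.max_dy, self.max_dx = int(max_displacement[0]), int(
            max_displacement[1])
        self.movement_sigma = float(movement_sigma)
        self.grid_shape = (2 * self.max_dy + 1, 2 * self.max_dx + 1)
        dys, dxs = np.meshgrid(
            np.arange(-self.max_dy, self.max_dy + 1),
            np.arange(-self.max_dx, self.max_dx + 1), indexing="ij")
        self.states = np.column_stack((dys.ravel(), dxs.ravel()))
        self.num_states = len(self.states)
        # transition log-probabilities over the 9 nearest-neighbour moves
        moves = np.array([(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1)])
        s2 = max(self.movement_sigma, 1e-6) ** 2
        w = np.exp(-(moves[:, 0] ** 2 + moves[:, 1] ** 2) / (2 * s2))
        self.moves = moves
        # initial distribution: discretized Gaussian centred on (0, 0);
        # far states may underflow to probability 0 (-inf log-prob)
        w0 = np.exp(-(self.states[:, 0] ** 2 + self.states[:, 1] ** 2)
                    / (2 * s2))
        with np.errstate(divide="ignore"):
            self.move_logp = np.log(w / w.sum())
            self.initial_logp = np.log(w0 / w0.sum())

    def state_index(self, dy: int, dx: int) -> int:
        return (dy + self.max_dy) * self.grid_shape[1] + (dx + self.max_dx)


# ----------------------------------------------------------------------
# parameter estimation
def estimate_gain(frames) -> float:
    """Photons-per-intensity gain from Poisson mean-variance scaling.

    For Poisson counts scaled by a gain g, the temporal variance of a
    static pixel equals g times its temporal mean; g is estimated as the
    median of the per-pixel variance/mean ratios (robust to pixels whose
    variance is inflated by motion or signal).
    """
    stack = _as_stack(frames)
    if stack.shape[0] < 2:
        raise ValueError("gain estimation needs at least 2 frames")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        var = np.nanvar(stack, axis=0, ddof=1)
    ok = np.isfinite(mean) & np.isfinite(var) & (mean > 0)
    if not ok.any() or not (var[ok] > 0).any():
        raise ValueError("cannot estimate gain from a constant movie")
    g = float(np.median(var[ok] / mean[ok]))
    if g <= 0:
        raise ValueError("cannot estimate gain from a constant movie")
    return g


def estimate_movement_sigma(frames, max_displacement) -> float:
    """Per-line random-walk std from frame-to-frame correlation shifts.

    The std of consecutive whole-frame shifts, pooled over both axes,
    divided by sqrt(num_rows) (a frame-to-frame displacement accumulates
    over num_rows line steps).
    """
    stack = _as_stack(frames)
    num_rows = stack.shape[1]
    shifts = _coarse_shifts(stack, max_displacement)
    steps = np.diff(shifts, axis=0)
    sigma = float(np.sqrt(np.mean(steps.astype(float) ** 2)))
    return max(sigma / np.sqrt(num_rows), 0.01)


def _as_stack(frames) -> np.ndarray:
    if isinstance(frames, FrameSequence):
        return frames.to_array()
    return np.asarray(frames, dtype=float)


def _coarse_shifts(stack: np.ndarray, max_displacement) -> np.ndarray:
    """Integer whole-frame shifts (dy, dx) vs the stack mean, by FFT
    cross-correlation restricted to the displacement bounds."""
    my, mx = int(max_displacement[0]), int(max_displacement[1])
    clean = np.where(np.isfinite(stack), stack, 0.0)
    ref = clean.mean(axis=0)
    ref = ref - ref.mean()
    R, C = ref.shape
    shape = (R + 2 * my, C + 2 * mx)
    fref = np.fft.rfft2(ref, shape)
    shifts = np.zeros((stack.shape[0], 2), dtype=int)
    for t, frame in enumerate(clean):
        fr = frame - frame.mean()
        corr = np.fft.irfft2(np.fft.rfft2(fr, shape).conj() * fref, shape)
        # corr[u, v] = sum_rc fr[r, c] * ref[r+u, c+v] (circular over shape)
        window = np.empty((2 * my + 1, 2 * mx + 1))
        for i, u in enumerate(range(-my, my + 1)):
            for j, v in enumerate(range(-mx, mx + 1)):
                window[i, j] = corr[u % shape[0], v % shape[1]]
        i, j = np.unravel_index(np.argmax(window), window.shape)
        shifts[t] = (i - my, j - mx)
    return shifts


# ----------------------------------------------------------------------
# emission model
def line_log_likelihood(line, row_index, state, reference, gain) -> float:
    """Poisson log-likelihood of one image row under a displacement state.

    ``reference`` is the expected-photon image; pixel ``c`` of the row maps
    to reference position (row_index + dy, c + dx). Pixels mapping outside
    the reference, or onto undefined (NaN) reference pixels, contribute 0.
    """
    line = np.asarray(line, dtype=float)
    if not np.isfinite(line).all():
        raise ValueError("non-finite intensities in input line")
    dy, dx = int(state[0]), int(state[1])
    reference = np.asarray(reference, dtype=float)
    r = row_index + dy
    if not 0 <= r < reference.shape[0]:
        return 0.0
    k = line / gain
    cols = np.arange(line.size) + dx
    ok = (cols >= 0) & (cols < reference.shape[1])
    lam = reference[r, cols[ok]]
    valid = np.isfinite(lam)
    lam = np.maximum(lam[valid], _LAMBDA_FLOOR)
    kk = k[ok][valid]
    return float(np.sum(kk * np.log(lam) - lam - gammaln(kk + 1)))


class _EmissionTables:
    """Vectorized per-line emission tables against a canvas reference.

    The canvas is the reference image padded by (max_dy, max_dx) on each
    side, so frame pixel (r, c) under state (dy, dx) reads canvas position
    (r + dy + max_dy, c + dx + max_dx). Undefined canvas pixels contribute
    zero to the log-likelihood.
    """

    def __init__(self, canvas: np.ndarray, gain: float,
                 max_displacement: tuple[int, int]):
        self.my, self.mx = max_displacement
        valid = np.isfinite(canvas)
        lam = np.where(valid, np.maximum(canvas, _LAMBDA_FLOOR), 0.0)
        self.loglam = np.where(valid, np.log(np.maximum(lam, _LAMBDA_FLOOR)),
                               0.0)
        self.lam = lam
        self.valid = valid.astype(float)
        self.gain = gain
        # pixels shifted onto undefined reference positions are scored
        # under the mean reference rate (marginal over position); scoring
        # them 0 would reward states that push lines off the reference
        self.lam_bar = max(float(lam[valid].mean()) if valid.any() else 1.0,
                           _LAMBDA_FLOOR)
        self.log_lam_bar = np.log(self.lam_bar)
        # cumulative sums along columns for O(1) sliding window sums
        self._cum_lam = np.cumsum(self.lam, axis=1)
        self._cum_valid = np.cumsum(self.valid, axis=1)

    def line_table(self, line: np.ndarray, row: int) -> np.ndarray:
        """(2*max_dy+1, 2*max_dx+1) table of log-likelihoods for one row."""
        C = line.size
        k = line / self.gain
        lg = gammaln(k + 1)
        slab = slice(row, row + 2 * self.my + 1)
        winL = sliding_window_view(self.loglam[slab], C, axis=1)
        winV = sliding_window_view(self.valid[slab], C, axis=1)

        def slide(cum):
            cs = cum[slab]
            return cs[:, C - 1:] - np.pad(cs[:, :-C], ((0, 0), (1, 0)))

        lam_sum = slide(self._cum_lam)
        v_count = slide(self._cum_valid)
        k_valid = winV @ k
        # valid pixels: k log(lam) - lam - lgamma(k+1)
        # invalid pixels: k log(lam_bar) - lam_bar - lgamma(k+1)
        return (winL @ k - lam_sum
                + self.log_lam_bar * (k.sum() - k_valid)
                - self.lam_bar * (C - v_count)
                - lg.sum())


# ----------------------------------------------------------------------
# decoding
def viterbi_beam(frames, params: HmmParams, reference: np.ndarray,
                 state_space: HiddenStateSpace | None = None) -> np.ndarray:
    """Beam-restricted Viterbi decoding of per-line displacements.

    Parameters
    ----------
    frames : FrameSequence or list of FrameSequence
        The correction channel(s) of one cycle; log-likelihoods of several
        channels are summed.
    reference : 2-D array
        Expected-photon canvas, already padded by ``max_displacement``.

    Returns
    -------
    (num_frames, num_rows, 2) integer array of (dy, dx) per acquired line.
    """
    if params.num_states_retained < 1:
        raise ValueError("num_states_retained must be >= 1")
    if isinstance(frames, FrameSequence):
        frames = [frames]
    if state_space is None:
        state_space = HiddenStateSpace(params.max_displacement,
                                       params.movement_sigma or 0.1)
    gy, gx = state_space.grid_shape
    stacks = [_as_stack(seq) for seq in frames]
    T_frames, R, C = stacks[0].shape
    tables = [_EmissionTables(reference, params.gain,
                              (state_space.max_dy, state_space.max_dx))
              for _ in stacks]

    def emissions(t):
        f, r = divmod(t, R)
        out = np.zeros((gy, gx))
        for stack, tab in zip(stacks, tables):
            line = stack[f, r]
            if not np.isfinite(line).all():
                raise ValueError("non-finite intensities in input line")
            out += tab.line_table(line, r)
        return out

    path = _decode(emissions, T_frames * R, state_space,
                   params.num_states_retained)
    return state_space.states[path].reshape(T_frames, R, 2)


def decode_sequence(emission_tables: list[np.ndarray],
                    state_space: HiddenStateSpace,
                    num_retained: int) -> np.ndarray:
    """Decode an explicit list of emission tables (one per line step).

    Returns the (T, 2) state sequence. This is the same decoder
    ``viterbi_beam`` uses, exposed for oracle comparisons on small HMMs.
    """
    path = _decode(lambda t: emission_tables[t], len(emission_tables),
                   state_space, num_retained)
    return state_space.states[path]


def _decode(emissions, num_steps: int, space: HiddenStateSpace,
            num_retained: int) -> np.ndarray:
    gy, gx = space.grid_shape
    score = space.initial_logp.reshape(gy, gx) + emissions(0)
    score = _prune(score, num_retained)
    backptr = np.empty((num_steps, gy, gx), dtype=np.int8)
    backptr[0] = -1
    neg = -np.inf
    for t in range(1, num_steps):
        best = np.full((gy, gx), neg)
        bp = np.zeros((gy, gx), dtype=np.int8)
        for m, (a, b) in enumerate(space.moves):
            lp = space.move_logp[m]
            # candidate[y, x] = score[y - a, x - b] + lp
            ys = slice(max(a, 0), gy + min(a, 0))
            ysrc = slice(max(-a, 0), gy + min(-a, 0))
            xs = slice(max(b, 0), gx + min(b, 0))
            xsrc = slice(max(-b, 0), gx + min(-b, 0))
            cand = score[ysrc, xsrc] + lp
            upd = cand > best[ys, xs]
            best[ys, xs][upd] = cand[upd]
            bp[ys, xs][upd] = m
        score = _prune(best + emissions(t), num_retained)
        backptr[t] = bp
    # backtrace; np.argmax returns the first (lowest-index) maximizer
    path = np.empty(num_steps, dtype=np.int64)
    s = int(np.argmax(score))
    path[-1] = s
    for t in range(num_steps - 1, 0, -1):
        a, b = space.moves[backptr[t].ravel()[s]]
        y, x = divmod(s, gx)
        s = (y - a) * gx + (x - b)
        path[t - 1] = s
    return path


def _prune(score: np.ndarray, n: int) -> np.ndarray:
    """Keep the n best entries of the score grid; ties at the cutoff are
    resolved toward ascending state index (stable sort)."""
    flat = score.ravel()
    if n >= flat.size:
        return score
    order = np.argsort(-flat, kind="stable")
    out = np.full(flat.size, -np.inf)
    keep = order[:n]
    out[keep] = flat[keep]
    return out.reshape(score.shape)


# ----------------------------------------------------------------------
# geometry of the corrected output
def output_extent(displacements, frame_shape, trim_criterion="minimal"):
    """Choose the output rectangle after motion correction.

    Line (frame f, row r) with displacement (dy, dx) images scene rows
    r + dy, columns dx .. dx + num_cols. "maximal" returns the bounding box
    of every location ever imaged; "minimal" the largest rectangle of
    locations imaged in every frame; a fraction f the largest rectangle of
    locations imaged in at least f of the frames.

    Returns ``(row_offset, col_offset, rows, cols)`` in scene coordinates
    (offsets relative to the un-displaced frame origin, possibly negative).
    """
    if isinstance(displacements, np.ndarray):
        displacements = [displacements]
    R, C = frame_shape
    all_disp = np.concatenate([np.asarray(d).reshape(-1, 2)
                               for d in displacements])
    my = int(np.abs(all_disp[:, 0]).max(initial=0))
    mx = int(np.abs(all_disp[:, 1]).max(initial=0))
    count = np.zeros((R + 2 * my, C + 2 * mx), dtype=np.int32)
    total_frames = 0
    for disp in displacements:
        disp = np.asarray(disp)
        total_frames += disp.shape[0]
        for f in range(disp.shape[0]):
            frame_mask = np.zeros_like(count, dtype=bool)
            for r in range(R):
                dy, dx = disp[f, r]
                frame_mask[r + dy + my, dx + mx: dx + mx + C] = True
            count += frame_mask
    if trim_criterion == "maximal":
        rows_any = np.flatnonzero(count.any(axis=1))
        cols_any = np.flatnonzero(count.any(axis=0))
        return (int(rows_any[0]) - my, int(cols_any[0]) - mx,
                int(rows_any[-1] - rows_any[0] + 1),
                int(cols_any[-1] - cols_any[0] + 1))
    if trim_criterion == "minimal":
        needed = total_frames
    else:
        needed = int(np.ceil(float(trim_criterion) * total_frames - 1e-9))
    mask = count >= needed
    rect = _largest_rectangle(mask)
    if rect is None:
        raise ValueError(
            "no location satisfies the trim criterion; pass a fraction "
            "smaller than 1 as trim_criterion")
    r0, c0, h, w = rect
    return (r0 - my, c0 - mx, h, w)


def _largest_rectangle(mask: np.ndarray):
    """Largest all-True axis-aligned rectangle (histogram algorithm).

    Ties by area resolve to the smallest top row, then leftmost column.
    Returns (row0, col0, height, width) or None for an all-False mask.
    """
    if not mask.any():
        return None
    nrows, ncols = mask.shape
    heights = np.zeros(ncols, dtype=int)
    best = (0, None)
    for r in range(nrows):
        heights = np.where(mask[r], heights + 1, 0)
        stack = []  # (start_col, height)
        for c in range(ncols + 1):
            h = heights[c] if c < ncols else 0
            start = c
            while stack and stack[-1][1] >= h:
                sc, sh = stack.pop()
                area = sh * (c - sc)
                if area > best[0]:
                    best = (area, (r - sh + 1, sc, sh, c - sc))
                start = sc
            if h > 0:
                stack.append((start, h))
    return best[1]


# ----------------------------------------------------------------------
# full correction pipeline
def correct(dataset_or_iterables, save_path=None, params: HmmParams = None,
            channel_names=None, **kwargs) -> Dataset:
    """Run HMM motion correction and return the corrected dataset.

    Accepts either an existing :class:`Dataset` or raw cycles x channels
    iterables plus ``save_path``. Keyword arguments populate
    :class:`HmmParams`. The displacement estimates from the correction
    channels are applied identically to all channels; the decoded
    per-line displacement field is persisted with the corrected dataset.
    """
    if params is None:
        params = HmmParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either params or keyword arguments, not both")
    if isinstance(dataset_or_iterables, Dataset):
        src = dataset_or_iterables
        if save_path is None:
            save_path = src.save_path.removesuffix(".ls") + "_mc"
        stacks = [[seq.to_array() for seq in cycle] for cycle in src.cycles]
        names = src.channel_names
    else:
        if save_path is None:
            raise ValueError("save_path required when passing raw iterables")
        src = None
        stacks = [[FrameSequence.create(s).to_array() for s in cycle]
                  for cycle in dataset_or_iterables]
        names = channel_names or [str(j) for j in range(len(stacks[0]))]

    corr_idx = _correction_indices(params.correction_channels, names)
    my, mx = params.max_displacement
    R, C = stacks[0][0].shape[1:]

    # combined correction-channel stack, concatenated over cycles
    corr_stacks = [np.sum([cyc[j] for j in corr_idx], axis=0)
                   for cyc in stacks]
    concat = np.concatenate(corr_stacks, axis=0)

    gain = params.gain if params.gain is not None else estimate_gain(concat)
    sigma = (params.movement_sigma if params.movement_sigma is not None
             else estimate_movement_sigma(concat, params.max_displacement))
    space = HiddenStateSpace(params.max_displacement, sigma)
    run_params = HmmParams(
        num_states_retained=params.num_states_retained,
        max_displacement=params.max_displacement,
        correction_channels=params.correction_channels,
        trim_criterion=params.trim_criterion, gain=gain,
        movement_sigma=sigma, max_iterations=params.max_iterations)

    # initial reference: coarse whole-frame alignment of the photon-scaled
    # correction channels, averaged on the padded canvas; the shifts are
    # median-centred so the reference keeps the input frame origin (the
    # alignment is otherwise only defined up to a global offset)
    shifts = _coarse_shifts(concat, params.max_displacement)
    shifts = shifts - np.round(shifts.mean(axis=0)).astype(int)
    shifts[:, 0] = np.clip(shifts[:, 0], -my, my)
    shifts[:, 1] = np.clip(shifts[:, 1], -mx, mx)
    canvas = _build_canvas_frames(concat / gain, shifts, my, mx)

    displacements = None
    for _ in range(max(1, params.max_iterations)):
        new_disp = []
        for cyc in corr_stacks:
            d = viterbi_beam(ArraySequence(cyc), run_params, canvas, space)
            new_disp.append(d)
        new_disp = _recenter(new_disp, my, mx)
        if displacements is not None:
            prev = np.concatenate([d.reshape(-1, 2) for d in displacements])
            cur = np.concatenate([d.reshape(-1, 2) for d in new_disp])
            frac_changed = np.mean(np.abs(prev - cur).max(axis=1) >= 1)
            displacements = new_disp
            if frac_changed < 0.01:
                break
        else:
            displacements = new_disp
        canvas = _build_canvas_lines(
            np.concatenate(corr_stacks, axis=0) / gain,
            np.concatenate(displacements, axis=0), my, mx)

    extent = output_extent(displacements, (R, C), run_params.trim_criterion)
    corrected = [
        [_resample(stacks[i][j], displacements[i], extent)
         for j in range(len(names))]
        for i in range(len(stacks))]
    ds = Dataset(corrected, save_path, channel_names=names,
                 displacements=[np.asarray(d, dtype=np.int32)
                                for d in displacements])
    return ds


def _recenter(displacements: list[np.ndarray], my: int, mx: int):
    """Shift a decoded field so its mean displacement is near (0, 0).

    The displacement origin is a gauge freedom (the reference is only
    defined up to a translation); anchoring the rounded mean at zero keeps
    the output aligned with the input frame coordinates (brain motion is
    stationary around rest). The shift is clamped so no displacement
    leaves the [-max, max] bounds.
    """
    flat = np.concatenate([d.reshape(-1, 2) for d in displacements])
    shift = np.round(flat.mean(axis=0)).astype(int)
    for ax, bound in ((0, my), (1, mx)):
        lo = flat[:, ax].max() - bound
        hi = flat[:, ax].min() + bound
        shift[ax] = min(max(shift[ax], lo), hi)
    if np.all(shift == 0):
        return displacements
    return [d - shift[None, None, :] for d in displacements]


def _correction_indices(correction_channels, names) -> list[int]:
    if correction_channels is None:
        return list(range(len(names)))
    return [_channel_to_index(ch, names) for ch in correction_channels]


def _channel_to_index(ch, names) -> int:
    if isinstance(ch, (int, np.integer)):
        return int(ch)
    return names.index(ch)


def _build_canvas_frames(photon_stack, shifts, my, mx) -> np.ndarray:
    """Mean photon canvas from whole-frame integer shifts."""
    T, R, C = photon_stack.shape
    total = np.zeros((R + 2 * my, C + 2 * mx))
    count = np.zeros_like(total)
    for t in range(T):
        dy, dx = shifts[t]
        frame = photon_stack[t]
        obs = np.isfinite(frame)
        sl = (slice(dy + my, dy + my + R), slice(dx + mx, dx + mx + C))
        total[sl][obs] += frame[obs]
        count[sl][obs] += 1
    with np.errstate(invalid="ignore"):
        canvas = total / count
    canvas[count == 0] = np.nan
    return canvas


def _build_canvas_lines(photon_stack, displacements, my, mx) -> np.ndarray:
    """Mean photon canvas from per-line displacements."""
    T, R, C = photon_stack.shape
    total = np.zeros((R + 2 * my, C + 2 * mx))
    count = np.zeros_like(total)
    for t in range(T):
        for r in range(R):
            dy, dx = displacements[t, r]
            line = photon_stack[t, r]
            obs = np.isfinite(line)
            sl = (r + dy + my, slice(dx + mx, dx + mx + C))
            total[sl][obs] += line[obs]
            count[sl][obs] += 1
    with np.errstate(invalid="ignore"):
        canvas = total / count
    canvas[count == 0] = np.nan
    return canvas


def _resample(stack, displacements, extent) -> np.ndarray:
    """Place each line at its displaced scene position inside the extent.

    Scene locations hit by several lines of one frame are averaged;
    locations not imaged in a frame are NaN.
    """
    r0, c0, H, W = extent
    T, R, C = stack.shape
    out = np.full((T, H, W), np.nan)
    for t in range(T):
        total = np.zeros((H, W))
        count = np.zeros((H, W))
        for r in range(R):
            dy, dx = displacements[t, r]
            row = r + dy - r0
            if not 0 <= row < H:
                continue
            cstart = dx - c0
            src0 = max(0, -cstart)
            src1 = min(C, W - cstart)
            if src0 >= src1:
                continue
            line = stack[t, r, src0:src1]
            obs = np.isfinite(line)
            seg_t = total[row, cstart + src0: cstart + src1]
            seg_c = count[row, cstart + src0: cstart + src1]
            seg_t[obs] += line[obs]
            seg_c[obs] += 1
        with np.errstate(invalid="ignore"):
            frame = total / count
        frame[count == 0] = np.nan
        out[t] = frame
    return out


# public alias mirroring the common entry-point name
hmm = correct
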