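"""Synthetic movies with known ground truth.

Generates laser-scanning movies that emulate the statistics the analysis
assumes: a static scene (bright neuropil with elliptical cells, either
bright somata or dark nuclei), per-cell fluorescence transients (seeded
Poisson event trains convolved with a single-exponential decay kernel),
per-line rigid displacements (bounded Gaussian random walk, per-frame
jitter, or a square wave), Poisson photon shot noise, and a detector gain.
Ground truth — cell masks, the displacement of every acquired line, and
the per-cell time courses — is returned alongside, so motion correction,
segmentation, extraction and registration can all be scored exactly.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import Dataset
from .register import Affine2D
from .rois import Roi, RoiList


@dataclass
class CellSpec:
    """One elliptical cell: center (row, col), semi-axes (ry, rx) in
    pixels, and polarity ("bright" soma or "dark" nucleus)."""

    center: tuple[float, float]
    axes: tuple[float, float] = (3.5, 7.0)
    polarity: str = "bright"
    contrast: float = 0.6  # fractional intensity change inside the cell


@dataclass
class SceneSpec:
    """Parameters of a synthetic movie.

    Defaults describe a high-signal two-photon recording: baseline 50
    expected photons per pixel per frame, detector gain 2 intensity units
    per photon, calcium-like transients at 0.02 events/frame decaying over
    10 frames, and no motion. Cell diameters default to the 7 x 14 px
    (y x x) pyramidal-nucleus geometry the segmentation defaults target.
    """

    im_shape: tuple[int, int] = (48, 96)
    cells: list[CellSpec] = field(default_factory=list)
    baseline: float = 50.0          # expected photons / pixel / frame
    event_rate: float = 0.02        # transient events per frame per cell
    amplitude: float = 1.0          # peak transient, fraction of baseline
    decay_tau: float = 10.0         # transient decay constant, frames
    gain: float = 2.0               # intensity units per photon
    motion: str = "none"            # "none" | "randomwalk" | "jitter" | "squarewave"
    movement_sigma: float = 0.3     # random-walk std, px per line step
    max_displacement: tuple[int, int] = (4, 4)
    squarewave_dx: int = 2          # amplitude of the square-wave motion
    squarewave_period: int = 20     # frames per half cycle
    texture_amp: float = 0.15       # static background modulation depth
    texture_scale: float = 2.0      # background granularity, px (neuropil
                                    # speckle is much finer than a nucleus)
    num_frames: int = 200
    seed: int = 0


def make_cells(n: int, im_shape, axes=(3.5, 7.0), polarity: str = "bright",
               contrast: float = 0.6, margin: int = 10,
               rng: np.random.Generator | None = None,
               jitter: float = 2.0) -> list[CellSpec]:
    """Place ``n`` cells on a jittered grid, keeping them inside bounds
    and apart from one another."""
    rng = rng or np.random.default_rng(0)
    R, C = im_shape
    ncols = int(np.ceil(np.sqrt(n * C / R)))
    nrows = int(np.ceil(n / ncols))
    ys = np.linspace(margin, R - margin, nrows)
    xs = np.linspace(margin, C - margin, ncols)
    cells = []
    for y in ys:
        for x in xs:
            if len(cells) >= n:
                break
            cy = float(np.clip(y + rng.uniform(-jitter, jitter),
                               axes[0] + 1, R - axes[0] - 2))
            cx = float(np.clip(x + rng.uniform(-jitter, jitter),
                               axes[1] + 1, C - axes[1] - 2))
            cells.append(CellSpec(center=(cy, cx), axes=axes,
                                  polarity=polarity, contrast=contrast))
    return cells


def nuclei_scene(seed: int, im_shape=(48, 96), num_cells: int = 24,
                 num_frames: int = 150) -> SceneSpec:
    """Standard pyramidal-nucleus evaluation scene.

    A densely packed field of dark elliptical nuclei (7 x 14 px diameter,
    60% darker than the surrounding neuropil, packed as in the CA1
    pyramidal layer), fine-grained background speckle, and calcium-like
    transients — the fixture the ca1pc segmentation defaults are
    evaluated on.
    """
    cells = make_cells(num_cells, im_shape, axes=(3.5, 7.0),
                       polarity="dark", contrast=0.6, margin=6,
                       rng=np.random.default_rng(seed))
    return SceneSpec(im_shape=im_shape, cells=cells, motion="none",
                     num_frames=num_frames, event_rate=0.05, amplitude=1.0,
                     seed=seed)


def motion_scene(seed: int, motion: str = "randomwalk",
                 im_shape=(128, 64), num_frames: int = 500,
                 max_displacement=(4, 4)) -> SceneSpec:
    """Standard motion-correction evaluation scene: bright somata over
    speckled neuropil at ~25 expected photons/pixel, with the requested
    motion model (random walk of 0.3 px/line by default)."""
    cells = make_cells(10, im_shape, axes=(3.5, 7.0), polarity="bright",
                       rng=np.random.default_rng(seed))
    return SceneSpec(im_shape=im_shape, cells=cells, motion=motion,
                     movement_sigma=0.3, num_frames=num_frames,
                     max_displacement=max_displacement, baseline=25.0,
                     seed=seed)


def _ellipse_mask(im_shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0:im_shape[0], 0:im_shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + \
        ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _texture(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth static multiplicative background pattern (padded scene)."""
    import scipy.ndimage as ndi

    my, mx = spec.max_displacement
    shape = (spec.im_shape[0] + 2 * my, spec.im_shape[1] + 2 * mx)
    noise = rng.standard_normal(shape)
    smooth = ndi.gaussian_filter(noise, spec.texture_scale)
    smooth /= max(np.abs(smooth).max(), 1e-12)
    return 1.0 + spec.texture_amp * smooth


def render_scene(spec: SceneSpec, rng: np.random.Generator | None = None):
    """Static expected-photon scene (padded by max_displacement) plus the
    per-cell footprints (unpadded, scene coordinates)."""
    rng = rng or np.random.default_rng(spec.seed)
    my, mx = spec.max_displacement
    scene = spec.baseline * _texture(spec, rng)
    footprints = []
    for cell in spec.cells:
        fp = _ellipse_mask(spec.im_shape, cell.center, cell.axes)
        footprints.append(fp)
        padded = np.pad(fp, ((my, my), (mx, mx)))
        if cell.polarity == "dark":
            scene[padded] *= (1.0 - cell.contrast)
        else:
            scene[padded] *= (1.0 + cell.contrast)
    return scene, footprints


def transient_traces(spec: SceneSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """(num_cells, num_frames) multiplicative activity traces >= 1."""
    T = spec.num_frames
    kernel = np.exp(-np.arange(int(6 * spec.decay_tau) + 1) / spec.decay_tau)
    traces = np.ones((len(spec.cells), T))
    for i in range(len(spec.cells)):
        events = rng.random(T) < spec.event_rate
        amps = events * spec.amplitude * rng.uniform(0.5, 1.5, T)
        traces[i] += np.convolve(amps, kernel)[:T]
    return traces


def sample_displacements(spec: SceneSpec,
                         rng: np.random.Generator) -> np.ndarray:
    """(num_frames, num_rows, 2) integer (dy, dx) per acquired line."""
    T, R = spec.num_frames, spec.im_shape[0]
    my, mx = spec.max_displacement
    if spec.motion == "none":
        return np.zeros((T, R, 2), dtype=int)
    if spec.motion == "squarewave":
        disp = np.zeros((T, R, 2), dtype=int)
        phase = (np.arange(T) // spec.squarewave_period) % 2
        disp[:, :, 1] = np.where(phase == 0, spec.squarewave_dx,
                                 -spec.squarewave_dx)[:, None]
        return disp
    if spec.motion == "jitter":
        # per-frame rigid displacement: slow mean-reverting drift around
        # the resting position, constant within each frame
        pos = _ou_walk(T, sigma=0.8, theta=0.1, rng=rng)
        pos[:, 0] = np.clip(pos[:, 0], -my, my)
        pos[:, 1] = np.clip(pos[:, 1], -mx, mx)
        pos = np.rint(pos).astype(int)
        return np.repeat(pos[:, None, :], R, axis=1)
    if spec.motion == "randomwalk":
        # per-line random walk with weak mean reversion: tissue drifts
        # with std ``movement_sigma`` per line step but returns to its
        # resting position rather than wandering without bound
        n = T * R
        pos = _ou_walk(n, sigma=spec.movement_sigma, theta=0.01, rng=rng)
        pos[:, 0] = np.clip(pos[:, 0], -my, my)
        pos[:, 1] = np.clip(pos[:, 1], -mx, mx)
        return np.rint(pos).astype(int).reshape(T, R, 2)
    raise ValueError(f"unknown motion model {spec.motion!r}")


def _ou_walk(n: int, sigma: float, theta: float,
             rng: np.random.Generator) -> np.ndarray:
    """Discrete Ornstein-Uhlenbeck path: x_{t+1} = (1-theta) x_t + eta."""
    steps = rng.normal(0.0, sigma, size=(n, 2))
    pos = np.empty((n, 2))
    x = np.zeros(2)
    for t in range(n):
        x = (1.0 - theta) * x + steps[t]
        pos[t] = x
    return pos


def generate_movie(spec: SceneSpec, save_path=None):
    """Render a movie and return ``(dataset_or_stack, truth)``.

    ``truth`` holds "rois" (binary cell masks), "displacements"
    ((T, R, 2) per-line ground truth), "signals" ((cells, T) activity
    traces), and "scene" (the padded expected-photon image). When
    ``save_path`` is None the raw (T, R, C) intensity stack is returned in
    place of a persisted :class:`Dataset`.
    """
    rng = np.random.default_rng(spec.seed)
    scene, footprints = render_scene(spec, rng)
    traces = transient_traces(spec, rng)
    disp = sample_displacements(spec, rng)
    my, mx = spec.max_displacement
    R, C = spec.im_shape
    T = spec.num_frames
    stack = np.empty((T, R, C))
    pad_fp = [np.pad(fp, ((my, my), (mx, mx))) for fp in footprints]
    for t in range(T):
        scene_t = scene.copy()
        for i, fp in enumerate(pad_fp):
            if traces[i, t] != 1.0:
                scene_t[fp] *= traces[i, t]
        for r in range(R):
            dy, dx = disp[t, r]
            stack[t, r] = scene_t[r + dy + my, dx + mx: dx + mx + C]
        stack[t] = spec.gain * rng.poisson(stack[t])
    truth = {
        "rois": RoiList([Roi(mask=fp, label=f"cell_{i:02d}",
                             im_shape=(R, C))
                         for i, fp in enumerate(footprints)], name="truth"),
        "displacements": disp,
        "signals": traces,
        "scene": scene,
    }
    if save_path is None:
        return stack, truth
    return Dataset([[stack]], save_path), truth


def two_session_fixture(spec: SceneSpec, transform: Affine2D,
                        dropout: float = 0.0, save_paths=None):
    """Two sessions of the same field with a known affine misalignment.

    The second session's cells are the first's mapped through
    ``transform`` (cells landing outside the frame are dropped), minus a
    seeded random ``dropout`` fraction, re-rendered with fresh noise.
    Returns ``(movie_a, movie_b, truth)`` where each movie is the
    ``generate_movie`` output for its session and ``truth`` has "pairs"
    (list of (index_in_a, index_in_b)) and "transform".
    """
    rng = np.random.default_rng(spec.seed + 1)
    R, C = spec.im_shape
    keep = rng.random(len(spec.cells)) >= dropout
    cells_b = []
    pairs = []
    for i, cell in enumerate(spec.cells):
        if not keep[i]:
            continue
        cy, cx = cell.center
        # transform maps session-b coordinates into session-a space, so
        # cell positions in b are the inverse image of those in a
        x, y = transform.inverse().apply(np.array([[cx, cy]]))[0]
        if not (cell.axes[0] < y < R - cell.axes[0] - 1
                and cell.axes[1] < x < C - cell.axes[1] - 1):
            continue
        pairs.append((i, len(cells_b)))
        cells_b.append(replace(cell, center=(float(y), float(x))))
    spec_b = replace(spec, cells=cells_b, seed=spec.seed + 1000)
    path_a, path_b = save_paths if save_paths else (None, None)
    movie_a = generate_movie(spec, path_a)
    movie_b = generate_movie(spec_b, path_b)
    return movie_a, movie_b, {"pairs": pairs, "transform": transform}
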