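# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
evaluations do and do not establish.

## Dataset model and persistence

A dataset is an ordered list of *cycles* (continuous acquisition epochs),
each holding one frame sequence per optical *channel*. Frame sources
(in-memory stacks, multi-page TIFF, HDF5) are re-iterable: traversal never
exhausts them, and every frame is a 2-D array of a fixed shape. Pixels not
imaged in a frame (a consequence of line-by-line motion correction) are
carried as NaN in memory; on disk the bundle stores the data array plus an
explicit boolean `observed` mask, so integer movies round-trip losslessly.
The bundle is a plain directory (`.ls` suffix) with a JSON manifest, HDF5
frame stores, JSON ROI lists, and HDF5+JSON signal records — everything
inspectable with standard tools.

Time averages are means over observed samples only; a pixel observed in no
frame stays NaN. Frame export can optionally fill unobserved pixels from
the nearest frame in which they were observed (earlier frame wins ties)
and rescale the dataset maximum to the full 16-bit range.

## Motion correction

### Model

One rigid integer displacement (dy, dx) per scanned line, bounded by
`max_displacement`. This assumes negligible motion within the ~1 ms of a
single line — the same assumption that justifies a per-line (rather than
per-pixel) displacement.

* **Transitions.** One step of a nearest-neighbour random walk per line:
  moves in {-1, 0, +1}^2 with probabilities from an isotropic discretized
  Gaussian of std `movement_sigma` (pixels/line step) normalized over the
  nine moves. Moves that would leave the displacement bounds are forbidden
  and their probability mass dropped — *not* redistributed, so the stay
  probability is identical at every state and boundary states enjoy no
  artificial advantage. The frame boundary (last line of frame t to first
  line of frame t+1) uses the same one-step model; flyback time is
  ignored.
* **Initial distribution.** A discretized Gaussian centred on (0, 0) with
  the same std, so a completely uninformative movie decodes to the resting
  position.
* **Emissions.** Poisson photon statistics: intensities divided by the
  detector gain are treated as photon counts k with mean lam given by the
  gain-scaled time-averaged reference at the displaced position;
  log p = k log(lam) - lam - log Gamma(k+1), summed over the pixels of the
  row. Pixels whose displaced position has no defined reference value are
  scored under the mean reference rate (a marginal over position). Scoring
  them zero instead — i.e. silently dropping them — systematically rewards
  states that push edge rows off the reference, because every overlapping
  pixel contributes a negative log-pmf; this appeared in testing as large
  spurious vertical displacements in the top and bottom rows.

### Parameter estimation

* **Gain** (intensity units per photon): for Poisson counts scaled by g,
  temporal variance = g x temporal mean per static pixel; g is the median
  of per-pixel variance/mean ratios, robust to pixels inflated by motion
  or transients. A constant movie raises an error.
* **movement_sigma**: std of consecutive whole-frame cross-correlation
  shifts divided by sqrt(num_rows), floored at 0.01 px/line.

### Decoding and reference refinement

Beam-restricted Viterbi: at each of T = frames x rows line steps only the
`num_states_retained` highest-scoring states survive (ties at the cutoff
broken toward ascending state index, row-major over (dy, dx)). With the
beam open to all states this is exact Viterbi; the tests verify exact path
equality against an independent full dynamic program, and that the exact
decode's joint log-probability dominates any narrower beam's. Note that
the decoded log-probability is *not* in general monotone in the beam width
(a wider beam can prune the greedy path early); the guarantee worth
testing — and tested — is domination by the exact decode.

The reference starts as the mean of coarsely aligned frames (whole-frame
integer shifts by FFT cross-correlation), is rebuilt from the decoded
per-line placements, and re-decoded up to `max_iterations` (default 3)
times, stopping early when fewer than 1% of lines change by >= 1 px.

**Gauge freedom.** The data determine displacements only up to a global
translation (shifting the reference and all displacements together changes
nothing). The decoded field is therefore anchored by subtracting its
rounded *mean* displacement (clamped to stay within bounds). The mean, not
the median, because motion is modelled as stationary around rest and the
median of a bimodal field (e.g. square-wave motion between +2 and -2)
interpolates to a spurious offset. Accuracy evaluations against synthetic
ground truth are likewise performed modulo one global integer offset;
zero-motion movies are still required to decode to exactly zero.

### Output geometry

After correction the field of view moves against a static scene. The
output rectangle is chosen by `trim_criterion`: "minimal" (default) is the
largest rectangle imaged in *every* frame; "maximal" is the bounding box
of everything *ever* imaged; a fraction f keeps the largest rectangle
imaged in at least f of the frames. Large sustained motion can make the
"minimal" region empty, in which case the error message suggests a
fraction. Scene locations hit by several lines of one frame are averaged;
locations missed by a frame are NaN in that frame.

## Segmentation

Affinities: `w_ij = exp(k_c c_ij) exp(-(dy^2/s_y^2 + dx^2/s_x^2))` for
|dy| <= r_y, |dx| <= r_x, zero beyond. The per-axis decay and rectangular
cutoff generalize the isotropic form because scanned pixels are usually
anisotropic. Correlations c_ij are Pearson correlations of the pixel time
series after reconstructing the frames x pixels matrix at rank `num_pcs`
from its principal components — the reconstruction denoises shot noise so
that within-cell correlations stand out; zero-variance pixels correlate 0.

Defaults (`SegmentationParams`) follow the CA1 pyramidal-cell setting:
num_pcs=50, max_dist=(3, 6), spatial_decay=(3, 6), cut_max_pen=0.10,
cut_min_size=50, cut_max_size=150, x_diameter=14, y_diameter=7,
circularity_threshold=0.5, min_roi_size=20, min_cut_size=40, k_c=9, and
k_I defaulting to 3/(max I* - min I*).

**Spectral split.** The generalized eigenproblem (D - W)x = lambda D x is
solved on the normalized Laplacian (dense below 600 nodes; shift-invert
Lanczos above). Candidate bipartitions come from threshold sweeps of the
second- *and* third-smallest eigenvectors (the Fiedler sweep alone can
miss good cuts on irregular graphs): all split points for small regions,
32 evenly spaced quantiles for large ones. On regions up to 200 nodes the
best candidate is polished by deterministic greedy node moves (plus pair
swaps up to 40 nodes). Disconnected regions split along connected
components with penalty 0. Everything is deterministic given the input.

**Termination.** A region splits iff it exceeds cut_max_size, or its size
is in [cut_min_size, cut_max_size] and the best split's penalty is below
cut_max_pen. `min_cut_size` acts as a pre-filter in the ca1pc
post-processing: smaller partitions are skipped entirely.

**ca1pc post-processing.** The mean image is CLAHE-equalized (tiles of
about twice the cell diameter, clip limit 0.02) and unsharp-masked
(subtract a Gaussian blur at half the cell diameter, shift to
non-negative). Per partition: Otsu threshold of the processed values, keep
the dark class (nuclei are dark); binary opening then closing with an
elliptical footprint whose semi-axes are max(1, round(diameter/8)) —
quarter-cell *full* axes; larger elements erase whole nuclei; keep
components with area >= min_roi_size and circularity 4*pi*A/P^2 >=
circularity_threshold, with P the marching-squares contour length (digital
contours can push the circularity of small disks slightly above 1).

**Otsu.** Implemented from the 256-bin histogram definition (cumulative
between-class variance). The maximizing threshold is not unique when empty
bins separate the classes; comparisons against the exhaustive scan are
therefore made on the class assignment and the achieved variance.

## Signal extraction

Weights: w_ip = 1/N_i inside binary/polygon ROIs, arbitrary for
real-valued masks; `s*_i = sum_p w_ip` (1 for normalized binary ROIs) is
the additive constant of the linear model. Pixel means f_p are computed
over observed frames only (the same rule as the time average), pooling all
cycles. A zero or undefined mean under a nonzero weight is an error naming
the pixel.

Three exact routes, dispatched automatically:

1. full observation — the plain weighted sum;
2. disjoint ROIs — the per-ROI closed form (no pseudoinverse);
3. general — A = pinv(W) once, then per distinct observation pattern the
   restricted pseudoinverse pinv(A[P_t]) is computed and cached (line-wise
   motion produces few distinct patterns; the cache is exact, verified by
   per-frame recomputation). Pseudoinverses use SVD with relative
   singular-value cutoff 1e-10; rank-deficient restrictions silently use
   the minimum-norm solution.

ROIs with no observed pixel in a frame get NaN there. Optional overlap
exclusion removes pixels shared by >= 2 ROIs and renormalizes the 1/N
weights; an ROI emptied by removal keeps zero support and extracts NaN.
The signals record stores the raw signals per cycle, the mean image, the
overlap pixels, the ROI list and channel used, and a timestamp; a PDF
overlay of ROIs on the mean image is written for visual verification.

## Cross-session registration

Affine estimation is intensity-based: phase cross-correlation gives a
coarse integer shift; a rigid stage (rotation about the image centre +
translation) and then a full six-parameter stage are optimized by Powell's
method. The objective is the normalized correlation between the reference
image and the warped moving image evaluated over a *fixed* support region
(the coarse alignment's overlap), with pixels a candidate warp pushes out
of view counted as zero signal. Evaluating over a transform-dependent
region instead lets the optimizer "win" by discarding the poorly matched
part of the field — a failure mode observed with independent background
textures. If no stage improves on the coarse shift, the coarse shift is
returned; images whose best correlation stays below 0.1 raise an error.

Identity clustering: UPGMA (average linkage) over all ROIs of all sessions
at distance 1/J, with infinite distance for J = 0 and for same-session
pairs. A merge is vetoed — skipped, not terminal — when the merged cluster
would contain a same-session pair or any pair with J < 0.25. Every final
cluster, singletons included, receives a fresh UUID-style id shared by its
members and written onto the ROIs; tags can then be propagated from a
chosen session to all cluster mates (set union, never removal).

## Synthetic data

`linescan.synth` renders what the models assume: a static scene (baseline
photon rate, multiplicative speckle texture, elliptical cells that are
either bright somata or dark nuclei), per-cell transients (seeded
Poisson event trains convolved with a single-exponential kernel,
multiplicative on the cell footprint), per-line displacements, Poisson
photon draws, and a detector gain. Deterministic given the seed.

Motion models are mean-reverting (discrete Ornstein–Uhlenbeck) rather than
free random walks — tissue returns toward rest, and a free walk's origin
drifts, making absolute ground truth unidentifiable. The background
speckle is fine-grained (2 px correlation scale): neuropil granularity is
much smaller than a nucleus, and a nucleus-scale texture would be an
unrealistically adversarial fixture for nucleus detection.

Two standard evaluation scenes are fixed once:

* `nuclei_scene`: 48 x 96 px, 150 frames, 24 dark 7 x 14 px nuclei at 60%
  contrast packed as in the CA1 pyramidal layer, baseline 50 photons/px,
  gain 2, events at 0.05/frame decaying over 10 frames. End-to-end ca1pc
  segmentation on 20 such scenes shows mean false-negative rates around
  1% and false-positive rates around 25% at the J >= 0.25 matching rule
  (the acceptance script recomputes the exact numbers). Residual false
  positives are speckle patches in cell-free margins.
* `motion_scene`: 128 x 64 px, 500 frames, bright somata at 25 expected
  photons/px, per-line OU walk with sigma 0.3 px/line, bounds +-4 px.
  Around 93% of line displacements are recovered within 1 px (modulo the
  global-offset gauge); zero-motion controls decode to exactly zero.

**What passing these tests does and does not show.** The generator draws
from the same observation model the correction assumes (Poisson, rigid
per-line shifts, static scene), so the motion results certify correctness
of the estimator, not robustness to model violations (slow drift of the
scene, within-line motion, non-Poisson noise). Likewise the nuclei scenes
have ideal elliptical cells; real tissue adds out-of-focus structure,
vessels, and overlapping somata, for which published false-positive rates
on in-vivo data are the more relevant guide. The extraction identities,
by contrast, are exact algebra and hold for any data.

## Numerical choices and limitations

* Reference photon rates are floored at 1e-6 before logs.
* Beam pruning and all tie-breaks are deterministic (stable sorts,
  first-maximum argmax), so repeated runs are bit-identical.
* Pixel-center-in-polygon rasterization with vertices in continuous
  (x, y); integer-shift translation equivariance away from borders is
  property-tested.
* ImageJ ROI I/O supports polygon, freehand, rectangle and oval records;
  16-bit integer vertex storage means exported polygons must have
  near-integer vertices to round-trip exactly.
* No sub-pixel or within-line displacements, no non-rigid warping, no 3-D
  volumes, no spike inference or neuropil subtraction.
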