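# linescan

Analysis of laser-scanning fluorescence imaging time series (two-photon
calcium imaging and similar): correction of within-frame motion artifacts,
automated segmentation of the field of view into regions of interest
(ROIs), extraction of per-ROI fluorescence signals that stays exact when
parts of a frame were never imaged, and registration of ROIs across
imaging sessions recorded days apart.

It is written for experimenters who image awake animals with raster-scanning
microscopes. Because each image row is acquired at a different instant,
animal motion displaces individual rows, not whole frames — frame-alignment
tools cannot fix this, and the downstream signal of a small structure
(dendrite, bouton) is easily corrupted.

## The methods in brief

**Motion correction.** The unknown displacement of each scanned line is the
hidden state of a hidden Markov model: states are integer displacements
(dy, dx) within a user bound; transitions allow one-pixel moves per line
step (a random walk with std `movement_sigma`); emissions are Poisson photon
statistics of the observed row against a time-averaged reference, using the
detector gain to convert intensities to photon counts,

    log p(row | dy, dx) = sum_p [ k_p log lam_p - lam_p - log Gamma(k_p + 1) ],

with `k_p = intensity/gain` and `lam_p` the gain-scaled reference at the
displaced position. Decoding uses the Viterbi algorithm restricted to the
N most probable states per step (`num_states_retained`), giving O(NT) cost
over T = frames x rows line steps.

**Segmentation.** Pixels form a sparse affinity graph,
`w_ij = exp(k_c c_ij) exp(-(dy^2/s_y^2 + dx^2/s_x^2))` within a rectangular
neighbourhood, where `c_ij` is the correlation of the pixels' time series
after a rank-`num_pcs` principal-component reconstruction. The graph is
recursively bipartitioned by normalized cuts (Shi–Malik). The `ca1pc`
variant, aimed at dark pyramidal-cell nuclei in hippocampal CA1,
additionally multiplies each weight by `exp(-k_I max I*)` along the segment
between the pixels (`I*` a CLAHE + unsharp-mask enhanced mean image) and
post-processes each partition: per-partition Otsu threshold keeping the
dark class, binary opening/closing, then minimum-size and circularity
(4*pi*A/P^2) filters.

**Extraction.** The signal of ROI i at frame t is
`s_it = sum_p w_ip f_pt / f_p` (weights 1/N_i inside a binary ROI, f_p the
pixel's time average). When only a subset P_t of pixels was imaged, the
package computes the least-squares estimate
`s_it = sum_{p in P_t} w_ipt (f_pt - f_p)/f_p + sum_p w_ip`, where the
`w_ipt` come from the pseudoinverse of pinv(W) restricted to the observed
rows; disjoint and fully observed cases use exact closed forms. Frames in
which an ROI is entirely unobserved yield NaN.

**Registration.** Affine transforms between session mean images are
estimated by phase correlation plus direct optimization of a normalized
correlation objective; ROIs are transformed into a common space and
clustered by UPGMA with distance 1/J (Jaccard index), never merging two
ROIs of one session or any pair with J < 0.25. Each cluster receives a
shared `id`.

A seeded synthetic-movie generator (`linescan.synth`) renders all of the
above with known ground truth, so every pipeline is testable without data
downloads.

## Worked example

```python
import linescan as ls

# a 48x96, 150-frame movie of 24 dark cell nuclei with known truth
spec = ls.nuclei_scene(seed=1)
stack, truth = ls.generate_movie(spec)

ds = ls.Dataset([[stack]], "/tmp/example.ls", channel_names=["GCaMP"])
rois = ds.segment(variant="ca1pc", label="auto")
fn, fp, matches = ls.evaluate_segmentation(rois, truth["rois"], 0.25)
print(f"found {len(rois)} ROIs; FN {fn:.2f}, FP {fp:.2f}")

rec = ds.extract(rois="auto", channel="GCaMP")
sig = rec.raw_signals[0]
print(f"signals: {sig.shape[0]} ROIs x {sig.shape[1]} frames")
```

Output:

```
found 31 ROIs; FN 0.00, FP 0.23
signals: 31 ROIs x 150 frames
```

All 24 true nuclei were found (FN 0.00) along with 7 spurious detections
(FP 0.23); extraction returns one normalized fluorescence trace per ROI
(values near 1 at baseline, rising with calcium transients).

Motion correction of a movie with line-by-line displacements:

```python
spec = ls.motion_scene(seed=1)           # 128x64 px, 500 frames,
stack, truth = ls.generate_movie(spec)   # 0.3 px/line random walk
ds = ls.correct([[stack]], "/tmp/mc.ls", max_displacement=(4, 4),
                num_states_retained=50, trim_criterion=0.5)
d = ds.displacements[0]                  # (500, 128, 2) per-line (dy, dx)
```

The same workflow is available from the shell: `linescan synth movie`,
`linescan mc run`, `linescan segment`, `linescan extract`,
`linescan register`, and `linescan dataset export-*`.

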