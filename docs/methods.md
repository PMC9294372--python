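# Methods

`trialcal` analyses trial-based fluorescence (calcium) imaging movies fast
enough for closed-loop use: each stage operates on one trial's worth of data
with simple, deterministic statistics, so active neurons can be identified
and their dF/F exported between trials. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not establish.

## Translation registration

**Model.** Brain motion within a session is treated as per-frame rigid
translation by an integer number of pixels. Each frame `a` is aligned to a
fixed template `t` (by default the first frame) by minimising the
overlap-normalised sum of squared differences

    D(x, y) = 1 / ((h-|x|)(w-|y|)) * Σ_{i,j} (t[i,j] - a[i+x, j+y])²

over integer offsets `(x, y)` with `|x|, |y| ≤ Ms`. Both images are
standardized (mean 0, unit population SD) first, which makes the objective
insensitive to global brightness and gain changes between frames.

**Fast evaluation.** Only the central crop of the frame (margins of width
`Ms` removed) is matched against the full template. The overlap area is then
the constant `A' = (h-2Ms)(w-2Ms)` and

    A'·D(x, y) = Σ t²  (over the template window)  +  Σ a'²  -  2 Σ a'·t

where `Σ a'²` is offset-independent, the sliding-window sum of `t²` is
computed once with an integral image, and the cross-correlation term for all
offsets at once with FFTs. The argmin is therefore exactly the argmin of the
brute-force objective — the FFT accelerates, it does not approximate. A
widely circulated description of this decomposition writes the
window-sum-as-convolution step with the roles of frame and template swapped;
the implementation follows the mathematically consistent form above (the
sliding window runs over the template; the cropped frame's sum is the
constant), and the tests pin the equivalence to brute force.

**Parameters.** `max_shift` (Ms) defaults to 1/5 of the smaller frame
dimension. Too small and real shifts exceed the search window; too large and
the crop gets small enough for spurious matches (below 4×4 it is refused).
`coarse_to_fine` first estimates on a block-averaged image, then refines by
exhaustive local search at full resolution within ±(factor+1) pixels; on all
test fixtures this equals the exhaustive result.

**Numerical choices.** Because FFT arithmetic perturbs scores at the 1e-12
level, scores within 1e-9 (relative) of the minimum are treated as exact
ties and resolved deterministically: smallest `|x|+|y|`, then row-major
`(x, y)`. Constant (zero-variance) frames or crops abort with a clear error
rather than silently returning (0, 0). Sub-pixel registration is
deliberately not implemented: the objective is defined over integer offsets
and registered movies are produced by pure re-indexing with no
interpolation. Rotation within a session is out of scope (see cross-session
alignment for between-session rotation).

## Trial segmentation, algorithm #1 (cumulative dF/F + entropy threshold)

Per-pixel dF/F is computed against the baseline-period mean `s̄`
(`s̃ = (s - s̄)/s̄`; pixels with `s̄` below 1e-6 of the dynamic range are
zeroed and counted). The response-period sum of `s̃` is floored at zero and
multiplied by the per-pixel *temporal* SD of `s̃` over the response period —
the SD factor is read as temporal because it is the only reading that
produces a 2-D scale image; it boosts transient pixels over flat drifts of
equal sum. The resulting cumulative image is auto-thresholded by Renyi
entropy, the binary image is Gaussian-smoothed (σ = 1 px) and re-binarised
at 0.5 to merge fragmented cell footprints, 8-connected components are
labelled, and components smaller than `area_threshold` (16 px) or with peak
cumulative score below `intensity_threshold` are dropped.

**Renyi thresholding.** The standard three-order procedure: optimal
background/foreground splits are found for Renyi orders ρ = 0.5, ρ → 1
(Shannon/maximum-entropy limit) and ρ = 2 on a 256-bin histogram of the
linearly rescaled image, and the three sorted candidate bins are combined
with the published cumulative-probability β-weighting. The implementation
is unit-tested bin-for-bin against a from-scratch exhaustive evaluation of
the entropy criterion, and the returned threshold (mapped back to original
intensity units) is invariant to affine intensity rescaling up to binning
granularity. Histogram-edge splits that would leave one side with ~1e-16
residual mass are excluded.

**Units of `intensity_threshold`.** The threshold applies in original
cumulative-dF/F units (not rescaled histogram units). Its conventional
default of 10 presumes strong, sustained transients (tens of summed dF/F);
for the synthetic world below (amplitude 0.5, τ = 10 frames, peak cumulative
scores ≈ 1.9) the planted-recovery tests set it to 1.0, between the noise
floor (< 0.5) and the planted response score. It is a user-facing threshold
by design and must be scaled to the data's response magnitude.

## Trial segmentation, algorithm #2 (binary sensitivity + run amplification)

Each pixel is binarised at `s̄ + 3d`, where `s̄` and `d` are the mean and
population SD over the baseline frames only (configurable to all frames;
zero-SD pixels use `s̄ + ε`). Real transients stay above this threshold for
consecutive frames; noise alternates. The recurrence

    L_1 = χ_1,    L_t = α · χ_t · (L_{t-1} + β)        (β = 1/α by default)

amplifies runs geometrically: a run of n ones reaches `(αⁿ-1)/(α-1)`, and
the temporal sum of a contiguous run strictly dominates any scattering of
the same number of ones. The summed index is smoothed with a normalised
Gaussian kernel (σ = 1 px) truncated to a cell-sized window (9×9 default for
σ≈3 px cells) and thresholded at `T = α·F + k`, where `F` is the indicator
dynamic time in frames — how many consecutive supra-threshold frames
constitute a real event. `T = α·F + k` is the literal default ("linear"
mode); because the amplified index itself grows geometrically, a "geometric"
mode `T = α^F + k` is provided behind a flag. α defaults to 2 (no
conventional default exists; 2 makes the closed form `2ⁿ-1` and is the value
used in all worked examples). Connected components of the thresholded image
are filtered by area only and ranked by peak pixel dF/F.

Both algorithms are deterministic and translation-equivariant for content
away from the border smoothing zone (boundary truncation of the Gaussian
kernels breaks exact equivariance within ~4 px of the frame edge).

## Session mask integration

ROIs identified trial-by-trial are merged into one session mask with a
capture-all rule: every trial ROI survives, repeated detections of the same
cell are united. Two ROIs from different trials match when their pixel
overlap is ≥ `overlap_fraction` (default 0.3) of the smaller ROI; matching
is transitive (union-find), and the merged shape is the pixel union. The
fraction rule and its 0.3 default are this package's choice — the
capture-all union strategy itself does not specify a matching rule — and a
plain binary-OR mode (`--merge-mode or`) is provided as the simplest
reading, with the caveat that adjacent distinct cells can fuse. Merged
output is sorted by centroid, so the result is independent of trial order.
ROI pixel records are authoritative; when unmerged ROIs overlap, the label
image shows the smaller ROI on top (larger ROIs painted first).

## Cross-session alignment

Sessions are represented by time-averaged images; the first session is the
reference frame. Because the imaging plane preserves collinearity, an affine
map corrects translation, rotation and unidirectional distortion between
sessions. No similarity metric is canonical here; the package maximises the
negative masked mean-squared error between standardized images (equivalent
to maximising correlation for standardized inputs), over a 3-level pyramid
(block-mean factors 4, 2, 1):

1. **Rigid stage.** Rotation candidates θ ∈ {-6°, …, +6°} in 2° steps are
   each given an FFT translation initialisation (reusing the registration
   engine on the de-rotated target), the best candidate is refined by
   Nelder-Mead in (θ, t_row, t_col) at each pyramid level.
2. **Affine stage.** All six matrix entries are relaxed from the rigid
   solution by Nelder-Mead at the finer levels. If refinement fails to
   improve the similarity the rigid matrix is returned (so affine is never
   worse than rigid).

The procedure is deterministic (fixed grid, fixed simplex options, no RNG).
Transforms map target coordinates to reference coordinates; intensity images
are warped bilinearly, label masks with nearest-neighbour sampling (labels
are categorical). ROIs pushed outside the reference frame are cropped or
dropped with a log entry. In practice rotations well beyond 5° are recovered
on synthetic blob fields; the documented ~5° practical limit for real data
reflects loss of margin content, which no estimator can restore. The
interactive inspect-and-confirm step of a microscope-side workflow is
replaced by the alignment report (overlay + MSE diagnostics) and an explicit
`--transform-override` accepting a saved 2×3 matrix.

## Trace extraction

Per ROI, `F(t)` is the mean intensity over the ROI's pixels, `F0` the mean
of `F(t)` over the baseline frames of the trial (the printed form of this
double average is read as the mean over ROI pixels and baseline frames), and
`F_activity = (F - F0)/F0`. F0 is per-trial by default, matching the
trial-based design; a session-constant F0 is available by flag. An ROI is
active when its peak `F_activity` exceeds the mean of its own baseline-period
`F_activity` by `n_sd` baseline SDs. The default is 5 SD; a 3-SD variant is
in circulation for cross-session response plots, and both are exposed via
`n_sd`. Fixed dF/F floors and minimum-size filters are available as
alternative criteria. Export orders active ROIs first by descending peak
dF/F, ties broken by centroid.

dF/F is exactly invariant to a power-of-two gain (pure exponent shift) and
invariant to machine precision for any other positive gain; adding an offset
`b` changes traces by the closed form `dF/F · F0/(F0+b)` — both are pinned
by tests.

## Synthetic ground truth (the stated world)

**Shift simulator.** Heartbeat-like motion: per axis, frame `i` (from 1)
gets the positive half-wave of a sinusoid of amplitude `M` at
`heartbeat_rate` Hz (default 1 Hz; phase `2π·rate·i/fps`), zero on the
negative half-wave, plus uniform jitter from `[-Mr, Mr]`, rounded to integer
pixels. The printed form of this phase is ambiguous ("sin(2πFi)"); the 1-s
period heartbeat reading is used and generalised by the rate parameter.
Shifts are rounded to integers *before* movie construction so that
registration accuracy is not confounded by interpolation. The accuracy
metric `diff(t, e) = Σ (tᵢ-eᵢ)²` per axis is implemented exactly as printed
(no square root); an RMS variant is a flag away. Defaults: 300 frames at
15 fps, amplitudes 10 px, jitter 3 px, on a 256×256 blob field with
`Ms = 51` downstream — under these conditions recovery is exact,
`diff = (0, 0)`.

**Planted-cell movies.** One 4-s trial at 15 fps (60 frames, first 15 = 1 s
baseline) on a 128×128 field; 8 Gaussian cells (σ = 3 px, resting peak 100
above a background of 100) placed by rejection sampling so 2σ disks never
overlap (centre distance ≥ 4σ); all cells responsive by default with a dF/F
transient of amplitude 0.5 — instantaneous rise at stimulus onset,
exponential decay with τ = 10 frames — and i.i.d. Gaussian read noise of
SD 10. That noise level puts the pixel-level baseline dF/F SD at ≈ 0.1, i.e.
the planted transient sits at 5× the noise floor, the regime the recovery
guarantees are stated for. The transient's spatial profile is the cell's own
Gaussian, scaled so the ROI-mean dF/F peaks *exactly* at the requested
amplitude in the noise-free movie (tested to ±0.01). Ground truth returned:
label mask (2σ disks), centres, responsive flags, per-cell dF/F traces.

**What a green test does not establish.** The generator omits neuropil
contamination, overlapping/demixing-requiring cells, photobleaching, slow
drift, shot-noise scaling with intensity, and z-motion. Recovery numbers on
this world are upper bounds for real movies. Cells at the minimum allowed
separation (4σ) can fuse into one component under algorithm #2 when the
transient is strong (the detectable footprint exceeds 2σ); the aggregate
≥ 90% recovery criterion absorbs this, and it is the expected behaviour of
a connected-components segmenter, not a defect.

## Degenerate inputs, logging, conventions

Zero-variance frames, constant histograms, zero baselines and zero-SD pixels
each have an explicit policy (error or ε-fallback with a logged count) —
nothing silently returns a default. All commands log their effective
parameters including defaults. All arrays are (row, col) 0-based; JSON
exports are 0-based `[row, col]` (MATLAB-side consumers must convert —
the classic porting hazard). Label TIFFs are 16-bit, switching to 32-bit
with a warning above 65535 ROIs.

## Known limitations

Integer-only within-session registration; no non-rigid or piecewise warps;
no spike deconvolution, neuropil correction or demixing; cross-session
alignment assumes a planar FOV (no z-drift correction); large inter-session
rotations lose margin data irrecoverably; processing-speed claims of
GPU-based implementations of this pipeline family are out of scope.
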