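# Methods

This note documents the model behind `flagelliq`, the choices made where
the design was genuinely open, and what the synthetic benchmarks do and do
not establish about real data.

## Image model and assumptions

The pipeline assumes a single cell per stack, imaged so that the flagellum
is *brighter than the background* (dark-field or epifluorescence; DIC and
phase contrast are out of scope). Intensities are processed as real numbers
at their native scale — no rescaling — because the sub-pixel machinery fits
continuous Gaussians to raw intensity profiles. Coordinates are 0-based
with pixel centres at integers; `x` is the column and `y` the row. Angles
are measured from the image x-axis toward positive y (row-down) and
reported in degrees; one convention is used everywhere.

Two background corrections are offered. Min-projection subtraction removes
any strictly static background and suits tethered cells; per-frame
rolling-ball subtraction (ball radius in px, default 10) suits swimming
cells under uneven illumination. The rolling ball is the geometric ball
variant with no pre-smoothing and no light-background mode; different
rolling-ball dialects differ by a few percent of the local background
curvature, which is irrelevant after thresholding. Both corrections clip
negatives to zero and never increase a pixel.

## Rough reconstruction

Per frame: Gaussian blur (σ = `gauss_sigma`, optionally restricted to the
user ROI so a bright head can be blurred without washing out the thin
flagellum) → global histogram threshold → optional re-blur of the binary
mask with the same σ, re-binarized at 0.5 (the symmetric choice for a 0/1
mask) → skeletonization by iterative thinning.

*Thresholds.* Li, Triangle and Otsu are computed on a 256-bin histogram
spanning the frame's min–max — the 8-bit histogram semantics these
algorithms were published on. Li minimizes the cross-entropy criterion by
an exact scan over all bins (the criterion is flat across empty bins, so
any minimiser is equivalent); Triangle uses the peak-to-far-end geometric
construction with the longer-tail side mirrored right; Otsu maximizes
between-class variance. Foreground is strictly above the threshold value,
and a ROI mask clears foreground outside it.

*Skeleton to path.* The skeleton is reduced to one curve by keeping the
largest 8-connected component and extracting the longest
endpoint-to-endpoint geodesic (Dijkstra with Euclidean step weights); side
branches — typically spurs off the head blob — are discarded. A closed-loop
skeleton is rejected.

*Ordering.* The point list is ordered to minimize the summed consecutive
distance. For n ≤ 12 an exact Held–Karp dynamic program guarantees the
optimum (nearest-neighbour chaining alone is not exact for arbitrary point
clouds, which the oracle tests cover); above that, nearest-neighbour chains
from candidate endpoints are compared against the incoming order and the
shortest kept — skeleton paths arrive essentially ordered, so this is a
verification pass, not a solver.

*Orientation.* Dark-field images are brightest at the head, so mean
intensities in radius-8-px disks around the two ends decide the direction;
equal means keep the current order. Optional start-point policies prepend
the intensity-weighted head centre of mass (useful when a stable Θ
reference matters) and/or replace every frame's first point by the
across-frames mean. Finally `upscaling_fold − 1` equidistant points are
interpolated into each gap (default fold 3), preserving endpoints and total
length exactly.

## Sub-pixel refinement

Tangents use the chord from point `i−k` to `i+k`,
`k = max_vector_length_points // 2`, clamped (one-sided) at the ends;
normals are tangents rotated +90°. The intensity profile along each normal
is sampled at 1-px steps out to `normal_radius_um` (converted to px),
bilinearly interpolated, optionally smoothed with a 3-tap moving average,
and fitted with a four-parameter Gaussian (baseline, height a, centre c,
width d). The baseline term is essential: dark-field profiles sit on a
nonzero background. The fit is a batched Levenberg–Marquardt iteration
(damped normal equations, analytic Jacobian, iteration cap 1000,
initialisation: baseline = min, a = max−min, c = offset of the maximum,
d = half the normal radius); it matches `scipy.optimize.curve_fit` to
1e-3 on the same profiles and runs two orders of magnitude faster, which is
what makes whole-movie analysis interactive. `r² = 1 − SS_res/SS_tot`.
A fit is accepted iff `r² > 0.8`, `a > 0`, `d < 2R` and `|c| < R` (R the
normal radius in px); accepted points shift by `c·n̂`, rejected points stay.

*Head handling.* Points within the 8-px head disk of the first point can be
exempted from correction and deletion (`exclude_head_from_correction`) —
head blobs are poorly described by a single Gaussian cross-section. The
8-px constant is the same head scale used for orientation. With the
exemption enabled the head points retain skeleton accuracy (~0.5 px),
which is visible in the Θ series; analyses that need a quiet Θ baseline
should disable the exemption or enable the head-COM start point.

*Outlier rule.* An interior point is dropped when its distance to the
previous point strictly exceeds its distance to the next; all violations
of one sweep are marked simultaneously (no cascade). On pixelated paths
this also prunes the alternating straight/diagonal steps, thinning the list
to roughly isotropic spacing — harmless, since arc lengths are recomputed.

*Median-projection smoothing.* For each point, up to
`smoothing_neighbor_count` neighbours on each side (excluding the point)
are paired in all combinations; the point is projected onto every pair's
line and replaced by the projection whose displacement is nearest the
median displacement. Lower median for even counts, lowest pair index on
ties, replacements computed from the original list — all for determinism.
The same scheme smooths the width signal d(s) in one dimension
(inter-/extrapolation along arc length), with neighbours restricted to
`z_smoothing_arc_distance_um`; a zero limit disables width smoothing.

*Pass order.* Fit/centre → outlier removal → xy smoothing → arc lengths →
outlier removal → new tangents → refit **and re-centre** → optional removal
of criteria-failing points → width smoothing. Re-centring in the second
pass uses the recalculated fits; it is what guarantees the second pass
never degrades the first pass's accuracy (smoothing alone introduces a
small chord bias on curved segments).

## Kinematics

Θ is the angle of the head-midpiece vector v (first point → trace point at
`reference_vector_arc_length_um`, interpolated on the polyline), unwrapped
over time by ±360° steps so spectra are meaningful. The head frame
translates the head to the origin and rotates v onto +x. Curvature at s
compares the tangents at `s ± Q/2` (Q = `curvature_reference_distance_um`)
and divides the signed angle by the actual arc separation; near the ends
the support is clamped, i.e. a smaller distance is used. The curvature
angle compares T(s) with T(s−Q), shortening the support below s = Q (the
proximal region is reported rather than masked; masking is a one-line
filter on arc length for users who prefer it). Values between trace points
are linearly interpolated along the polyline. The rolling signal samples a
9-px-thick line through the head, normal to v (the orientation the paper
leaves open; normal-to-axis maximizes sensitivity to the elliptical head
profile), averages across the thickness and takes the maximum along the
line.

## Kymographs and spectra

Kymographs bin each frame's parameter values by arc length (default bin
width = one pixel size, the native resolution) and average within bins;
bins a frame's trace does not reach stay masked. Because the refined point
spacing (~0.5–0.8 µm after outlier pruning) can exceed the bin width, each
frame is first evaluated on the bin-centre grid by linear interpolation
within its own arc span — the same interpolation rule used for all
between-point values — so rows are gap-free wherever the trace reaches.

Spectra use a plain rectangular-window DFT of the mean-subtracted series,
one-sided amplitudes scaled 2/W, DC excluded. Up to 10% missing frames are
linearly interpolated; more is an error naming the frames. The primary
frequency is the highest local maximum; the secondary is the second-highest
local maximum at a non-adjacent bin, so leakage shoulders of the primary
cannot masquerade as a second peak; amplitude ties go to the lower
frequency. The spectrum COM is the amplitude-weighted mean frequency over
all non-DC bins. Windows shorter than the movie slide at stride 1.
Arc-length rows at or below `fft_skip_initial_um` are skipped.

## Synthetic renderer

The renderer draws what the pipeline assumes: a constant background, an
elliptical Gaussian head blob (optionally intensity-modulated at a rolling
frequency), and a flagellum built by max-blending Gaussian cross-sections
of width σ(s) along an analytic centerline sampled every 0.25 px
(max-blending avoids self-interference brightening at tight bends). The
centerline is a travelling wave in a body frame,
`y(s,t) = A(s)·sin(2π(f·t − s/λ) + φ)` plus optional harmonic terms gated
to an arc-length range; the body frame can rotate rigidly (multi-component
Θ oscillation) and translate. An out-of-plane oscillation maps to width
via `σ_eff = √(σ(s)² + z(t)²)` — even in z, so one z-cycle gives two width
maxima, reproducing the focal-plane-crossing frequency-doubling artefact.
Noise (Gaussian and/or Poisson) is applied last from a seeded generator;
identical parameters and seed give bit-identical movies.

Ground-truth scoring measures point-to-curve distances against the true
centerline extended straight through the head and ~2σ past the tip,
because the detected trace legitimately starts inside the head blob and
ends inside the tube's luminous end cap; arc length is compared over the
matched extent between the projections of the two trace endpoints.

What the renderer does **not** emulate: hydrodynamics (waveforms are
kinematic prescriptions), out-of-focus blur beyond the width proxy,
motility-chamber debris, photobleaching, camera fixed-pattern noise, or
multiple cells. Passing the synthetic suite therefore demonstrates the
correctness and numerical accuracy of the algorithms under the stated
image model, not robustness to every real-world artefact; the threshold
and ROI machinery exist precisely because real movies are messier.

## Default parameters

Two presets mirror the two acquisition regimes the pipeline targets:
tethered mouse cells (200 fps, 16×, 0.6875 µm/px: Li threshold, σ = 3 px,
normal radius 5 µm, head exempt from correction, reference vector 10 µm,
FFT window 200) and freely swimming human cells (500 fps, 20×,
0.55 µm/px: Triangle threshold, σ = 2 px, repeat-blur enabled, normal
radius 6 µm, reference vector 6.4 µm, FFT window 500). Shared defaults:
upscaling fold 3, tangent support 14–20 points, smoothing neighbourhood 15,
width-smoothing arc limit 9.6 µm, curvature reference 10 µm, rolling-line
half-length 10 px with fixed 9-px thickness.

Synthetic defaults follow the same regimes: mouse-like 100 µm flagellum
beating at 11 Hz, human-like 55 µm flagellum rolling at 9 Hz with three
beat cycles per roll (27 Hz), tube σ 2 px, head/flagellum intensity
contrast ≈ 2:1, Nyquist-checked frequencies. Test problem sizes — 200-frame
movies at 192×256 px or smaller, 20-frame movies for tracking-error
statistics — were chosen as the smallest sizes at which frequency bins are
integer Hz and error statistics stabilise.

## Numerical choices and tie-breaks

* 256-bin histograms spanning min–max; thresholds compare strictly above.
* Held–Karp exact ordering for n ≤ 12; above, best of nearest-neighbour
  chains and the incoming order.
* Lower median for even counts; lowest-index pair on median ties; equal
  head/tip disk means keep the current order.
* Gaussian fit width reported positive; degenerate (constant or
  too-short) profiles are rejected rather than fitted.
* Duplicate consecutive points are merged before arc-length accumulation.
* The Θ series is unwrapped before any FFT.

## Known limitations

* The z proxy is uncalibrated and sign-blind (above/below focus are
  indistinguishable); its frequency content is trustworthy, its magnitude
  is relative.
* Accuracy inside the head region is skeleton-limited when the head is
  exempted from correction (~0.5 px) — by design, since head blobs violate
  the Gaussian cross-section model.
* Tangent support is point-count-based, so per-point curvature values
  carry a small dependence on local point density; aggregate statistics
  and frequency content are stable (the equivariance tests quantify this).
* One cell per stack; crop multi-cell recordings first.
* The curvature angle's proximal values (s < Q) use a shortened support
  and should be interpreted accordingly.
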