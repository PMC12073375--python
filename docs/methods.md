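# Methods

This note records the models, estimators, numerical conventions and design
choices behind `fibermesh`, and what its validation does and does not show.

## Image model and calibration

Input micrographs are single-channel 8/16-bit TIFF or PNG (RGB containers
are reduced by channel mean), normalized to [0, 1]. The pixel scale
`s` (µm/px) is supplied either directly or as `label_µm / bar_px` from an
embedded scale bar the user measures; automatic bar detection is out of
scope because bar styles vary by vendor and a manual reading is
unambiguous. All reported lengths scale as `s` and areas as `s²`
(scale equivariance is asserted in the tests).

## Segmentation

Fibers are bright on dark. Default threshold is Otsu's; a fixed threshold
is available for exact reproducibility. Cleanup removes foreground
components below `min_object_px` (default 16 px — a speck filter well below
any plausible fiber fragment at the 0.05 µm/px study scale) and optionally
applies a morphological closing (default radius 0: the synthetic noise
model does not produce holes; real micrographs with charging artifacts may
need 1–2 px). Cleanup is idempotent.

Skeletonization uses topology-preserving thinning (scikit-image). Spur
branches shorter than `prune_px` (default 5 px) that terminate at a
junction are deleted — these are thinning artifacts at fiber edges; free
ends of open paths are never shortened. A residual one-pixel stub at the
spur base is also removed when its neighbours remain mutually connected
without it. The result satisfies the 1-px-width invariant (no full 2×2
block).

## Centerline length

Adjacent skeleton pixels (8-connectivity) form steps counted once each:

- `chain` (default): 1 px axial, √2 px diagonal. Diagonal steps that merely
  shortcut an axial corner (both endpoints sharing an on-skeleton axial
  neighbour) are skipped, so an L-path of 10+10 axial steps measures 20 px.
  This convention is exact on axial and 45° digital lines but overestimates
  oblique lines — +8.2% worst case at 22.5°, ≈ +5% averaged over uniform
  orientations, which is exactly what we measure on random-angle synthetic
  meshes.
- `corrected`: Vossepoel–Smeulders weights (0.948 axial, 1.340 diagonal),
  the minimum-bias linear estimator of digital line length; recovers
  synthetic ground-truth length within ~1.5%. Use this when absolute
  length accuracy matters.
- `pixel_count`: every skeleton pixel counts 1 px — a compatibility
  convention matching workflows that report raw pixel totals.

The default stays `chain` because it is the convention the rest of the
per-step arithmetic (surface integration) is defined on, and because
between-sample comparisons cancel its orientation bias to first order.

## Local diameter

`d = 2 · EDT · s` at each skeleton pixel, where EDT is the Euclidean
distance transform of the mask. A half-pixel boundary correction
(`radius_correction_px`) is available but defaults to 0: a calibration
experiment on rendered single strokes (widths 4–16 px, random orientations
and sub-pixel offsets) shows the raw reading is already unbiased to
≈ +0.1 px once orientations are averaged; the textbook pixel-center
overshoot materializes only for axis-aligned, integer-offset strokes.

Excluded from diameter statistics (but not from the per-step surface
integral, which wants local coverage): pixels within 2 px (Chebyshev) of a
skeleton junction, where crossing fibers inflate the EDT; border-adjacent
pixels; and pixels whose EDT disk reaches the frame, where the transform is
truncated. Statistics are computed over included measurement points — n
therefore counts points, not fibers; `subsample_per_fiber` provides the
one-value-per-fiber convention (median per label) when a label image
exists, matching protocols that count ≥100 distinct fibers. SD is the
population SD and the median uses linear interpolation; both conventions
are stated because they matter at the reported precision.

## Pores

Pores are 8-connected components of the mask complement. (Foreground also
uses 8-connectivity; at these coverages the paired-connectivity subtleties
of digital topology are immaterial and one convention for both is
simplest.) Equivalent diameter is that of the equal-area circle. Default
classes: 0–0.2, 0.2–0.4, 0.4–0.6, 0.6–0.8, 0.8–1.0, >1.0 µm. "Void volume"
per class is a void-*area* fraction — a 2-D proxy from a single projection;
no 3-D porosity is claimed. Border-touching pores have unknown true extent
and are excluded from the distribution but counted, with their area
tracked, so pore accounting tiles the image exactly in px².

## Surface area

Cylinder model: `A* = π d` per unit length. Two integration rules:

- `mean_diameter` (default): `total_area = L · π · mean(d_included)` — the
  classic two-factor estimate, robust when the diameter distribution is
  well sampled.
- `per_pixel`: `Σ_steps π · d̄(step) · step_length`, with `d̄` the mean of
  the two endpoint samples. This is a genuinely local integral and comes
  with an independent cross-check: for non-overlapping fibers the projected
  mask area is `Σ d·L`, so `per_pixel total ≈ π × mask area` — two
  estimators of the same quantity from different image features, asserted
  to agree within 15% on synthetic meshes.

`normalized = total_area / (H·W·s²)` is dimensionless; between-sample
comparison reports the ratio of normalized values and requires equal
calibrations (a deliberate guard against accidentally mixing
magnifications).

## Absorption and molar-mass models

`AC(%) = (W_h − W_d)/W_d × 100`; negative values (mass loss) are returned
and flagged, not rejected. Equilibrium in a soak series is the first time
point from which every subsequent consecutive relative AC change stays
below `tol` (default 2% — configurable; protocols rarely state their
numerical criterion) through the series end; a series whose last step still
moves ≥ tol reports "not reached". Blotting and weighing error are outside
the model.

Molar-mass averages are the moment ratios Mn, Mw, Mz with PDI = Mw/Mn;
the power-mean inequality (Mn ≤ Mw ≤ Mz, equality iff monodisperse) is
asserted as a property test. Input is a number-abundance table or raw
per-molecule masses. For a lognormal mass distribution PDI = exp(σ²)
exactly, which the tests use as a closed-form oracle.

## Synthetic mesh generator

The generator emulates what the estimators actually consume: bright
constant-width strokes (capsule of radius d/2 around a polyline) on a dark
background, diameters from a constant or lognormal law (defaults: median
0.48 µm, sigma_log 0.586 → mean ≈ 0.57 µm at 0.05 µm/px, matching the
electrospun bacterial-cellulose meshes this package targets), additive
Gaussian noise (SD 0.05) applied only after all ground-truth masks are
frozen, and optional quadratic-Bézier curvature. Two placement modes:
border-to-border chords (long through-going fibers; overlap allowed, union
mask, totals count each fiber fully — the projection convention) and finite
segments with rejection-sampled disjoint placement (thickest first, minimum
2 px separation), the geometry quantitative validation needs because
crossings bias every mask-based estimator. Fiber length statistics are not
calibrated to any measured mesh — only the diameter law is; length defaults
(0.2–0.4 of the image side) are a plausible scale chosen once.

Diameter sampling is iid by default; `stratified` draws one value per
equal-probability stratum (then shuffles). Marginals and the expected mean
are unchanged, but the Monte Carlo variance of the sample mean collapses —
the right design when checking an estimator against population parameters,
where finite-sample noise would otherwise dominate the comparison (a
10%-band check at n = a few hundred iid lognormal draws fails a few percent
of the time on sampling noise alone).

What the generator does **not** model: SEM contrast physics (charging,
secondary-electron edge brightening), partial-volume gray edges, 3-D fiber
stacking and out-of-focus layers, beads and diameter variation along a
fiber. Passing tests therefore demonstrate correctness of the measurement
chain on ideal cylindrical geometry, not robustness to every real-world
imaging artifact; on real micrographs the dominant additional error source
is segmentation, which is why the threshold and cleanup provenance is
persisted with every run.

## Validation scale and determinism

Synthetic validation runs use 512–2048 px meshes with 20–400 fibers and
coverages 0.10–0.20 (well under the 0.25 ceiling above which disjoint
placement becomes infeasible and mask-based estimators degrade). The
headline recovery (scripts/acceptance.py) uses 400 fibers at 2048² px —
enough measurement points (~55 000) that the residual deviation from the
population mean is estimator bias (~+1%), not noise. Everything random is
driven by a single integer seed through numpy's SeedSequence; equal
(spec, seed) reproduces images and ground truth bit-for-bit, and repeated
pipeline runs write byte-identical metric files.

## Known limitations

- Crossing fibers are not tracked as individuals; junction exclusion keeps
  crossings out of diameter statistics but a heavily overlapped mesh
  under-samples its thickest regions.
- The chain length metric's +5% mean orientation bias is inherent to the
  {1, √2} convention; use `corrected` for absolute lengths.
- Pore metrics are 2-D projections; they are comparative, not volumetric.
- Sub-pixel centerline or contour fitting is not attempted; at d ≈ 10 px
  the pixel-level EDT is within ~1% on average, but meshes imaged at
  d < 4 px would need super-resolution treatment the package does not
  provide.
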