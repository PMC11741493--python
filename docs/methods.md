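# Methods

This note documents the models, conventions and design choices behind
`contrastsweep`, in the package's own terms.

## Signal model

Contrast synthesis uses the saturation-recovery spin-echo equation

    S(x) = gain · B1(x) · PD(x) · (1 − e^(−TR/T1(x))) · e^(−TE/T2(x))

with T1, T2 in milliseconds and PD in arbitrary units. Voxels with PD = 0
or T1 = 0 are background and map to 0; T2 = 0 with TE > 0 also gives 0.
This is the canonical approximation used when discussing synthetic
contrast weighting; commercial synthesis engines add proprietary
sequence-specific corrections (slice profile, echo-train weighting) that
are not modelled and unknowable from the outside. What the model does
preserve — and what the sweep methodology probes — is the TR/TE contrast
behaviour: S is non-decreasing in TR, non-increasing in TE, and linear in
gain and PD (all property-tested).

The inversion-recovery variant replaces the recovery term with
`1 − 2e^(−TI/T1) + e^(−TR/T1)` and returns the magnitude signal, so the
null point at TI = T1·ln 2 is reproduced. It is an optional extension; the
sweep itself only uses the spin-echo model.

B1 transmit inhomogeneity is modelled as a purely multiplicative bias field
(no flip-angle dependence). This is sufficient to reproduce the
lateral-asymmetry failure mode that coil-placement inhomogeneity causes in
practice, which is the phenomenon worth emulating in a QA harness.

Timing validation: TE < TR (and TI < TR) is enforced when an image is
actually synthesized, not when a grid is enumerated. The default grid
contains TE ≥ TR combinations only inside the excluded mixed region, so
they are never synthesized; enumerating them (e.g. with
`include_mixed=True` for accounting) is allowed, synthesizing them is an
error naming the point.

Maps whose fitted T2 exceeds T1 voxelwise are physically implausible but
only warned about: noisy relaxometry fits do produce such voxels and
rejecting them would make real data unusable.

## The digital phantom

The phantom exists so the entire pipeline is testable with no data
download. It is a head-sized ellipsoid of muscle-like tissue containing
four gland-like ellipsoids (bilateral parotid-like and submandibular-like
pairs, mirror-symmetric about the mid-sagittal plane) and an anterior
fat-like region. Geometry is specified in millimetres relative to the
volume centre, so the same anatomy renders at any shape/spacing.

Tissue values are literature-plausible 3 T defaults — parotid-like
T1 ≈ 1100 / T2 ≈ 120 ms, submandibular-like 1300/100, muscle-like 1400/40,
fat-like 400/130 — chosen once for contrast *ordering*, which is all the
methodology needs; they are phantom defaults, not subject measurements.
Gaussian noise (default s.d. 20 ms T1, 4 ms T2, 0.02 a.u. PD) is added
inside the head only, so background stays exactly zero.

Default spacing is 0.5 × 0.5 mm in-plane with a 5 mm slice axis (4 mm
slices + 1 mm gap — centre-to-centre distance is what surface metrics
need). The test suite and the acceptance script use a 64 × 64 × 16 grid at
1.5 × 1.5 × 5 mm: the same anatomy at a resolution where a full 216-point
sweep takes seconds rather than minutes. This scaling changes voxel counts,
not the phenomena being tested.

Simulated raters emulate contouring disagreement, the quantity STAPLE
models: each rater's mask is the truth's signed-distance field thresholded
at an independently drawn signed offset ~ N(0, perturbation) plus a smooth
zero-mean jitter field of the same scale (≈3 mm correlation length,
clipped at ±2 s.d. so local boundary error is bounded). The largest
connected component is kept, preserving topology. Perturbation 0
reproduces the truth exactly; an offset draw below the structure's depth
empties the mask and is a hard error.

What the phantom does **not** model: anatomically realistic shapes and
neighbouring-tissue interfaces, partial-volume voxels, acquisition noise
correlated with contrast, motion, or inter-subject variability. Passing
tests on the phantom demonstrate that the *machinery* (synthesis, fusion,
metrics, aggregation) is correct and that the sweep detects
contrast-dependent segmenter degradation; they say nothing quantitative
about any clinical model's robustness.

## STAPLE consensus

Standard binary STAPLE EM: the E-step computes the voxelwise posterior
foreground probability from the current rater sensitivities p_j and
specificities q_j; the M-step re-estimates (p_j, q_j) from the posterior.
Numerical conventions:

- initialization p_j = q_j = 0.99999 (the common reference convention;
  avoids the symmetric saddle),
- prior π = mean rater foreground fraction (scalar) unless overridden,
- convergence when |Δ(mean p + mean q)| < 1e−7 (default), max 100
  iterations; the incomplete-data log-likelihood trace is exposed and
  asserted non-decreasing in tests,
- consensus = (W ≥ 0.5), ties to foreground,
- computation restricted to the bounding box of the rater-mask union
  dilated by 5 voxels; outside voxels are background with W = 0. The
  specificity estimate depends on how much empty background is included,
  so the crop rule is fixed and part of the method definition.

A caveat worth knowing: with a large background, noisy raters and a flat
prior, the EM can converge to an asymmetric mode (e.g. "truth = union of
votes"). This is a genuine property of the model, not a bug; the
majority-vote equivalence with symmetric raters therefore holds in
balanced-foreground settings, which is how it is tested. The
implementation cross-checks against SimpleITK's STAPLE filter on a toy
stack where both see identical data.

## Metrics

DSC = 2|A∩B| / (|A|+|B|); both-empty is defined as 1.0, exactly-one-empty
as 0.0.

HD95 uses the **pooled symmetric** convention: surface voxels are mask
voxels with ≥1 face-adjacent (6-connected) background neighbour, with the
volume border counting as background; distances are Euclidean millimetres
between surface-voxel centres under anisotropic spacing (no sub-voxel mesh
extraction); the two directed nearest-distance multisets are pooled and
the 95th percentile taken with linear interpolation. This is exactly
symmetric and single-valued; the directed-max variant (max of the two
directed percentiles) is available behind a flag. The implementation uses
a Euclidean distance transform of each surface's complement, which is
exact for voxel-centre distances and is verified against an O(n²)
all-pairs oracle to 1e−9 mm.

Empty predictions give DSC 0 and an *undefined* HD95, carried as a typed
error that the sweep layer converts into a failure sentinel (NaN +
`hd95_defined=False`) — total segmentation failures are an expected
outcome of a contrast sweep and must not abort it or vanish from the grid.
Undefined HD95 values are excluded from HD95 statistics and counted
separately; in exceedance calculations they count as *not* exceeding.

## Sweep, regions, aggregation

Contrast regions follow the conventional synthetic-MR partition: T1W
(TR < 1000, TE ≤ 40 ms), T2W (TR ≥ 1000, TE > 40), PDW (TR ≥ 1000,
TE ≤ 40), MIXED (TR < 1000, TE > 40, excluded by default). The default
grid — TR {100..1000 step 100, 1500..5000 step 500}, TE {5..40 step 5,
60..200 step 20} — yields 216 used points, 72 per region.

Aggregation reports mean, median, min and max per structure × region (mean
and median styles are both useful; both are always computed). Relative
offsets ΔTR, ΔTE are reported against the anchor acquisition TR = 1535 ms,
TE = 212 ms — the *equivalent* TE convention is used for the anchor, since
that is the contrast-equivalent description of a fast-spin-echo training
acquisition.

IOV exceedance is "performs at least as well as human interobserver
variability": DSC ≥ cutoff, HD95 defined and ≤ cutoff, both inclusive.
Default cutoffs are published interobserver levels for the four salivary
glands (DSC 0.83 / 0.84 / 0.75 / 0.78 and HD95 4.9 / 5.1 / 3.1 / 3.1 mm
for left/right parotid and left/right submandibular). The denominator is
always the evaluated grid (216 points by default), overall and per region.

## Reference segmenter

The plug-in contract is any deterministic callable
`(image, spacing) → integer label volume` of the input shape. Conformance
is smoke-checked on an 8 × 8 × 4 volume at registration.

Preprocessing follows the standard deep-learning normalization chain: clip
to the [0.25, 99.75] intensity percentiles, z-score with the population
standard deviation (a deterministic choice), then linearly map the
post-clip min/max to [−1, 1]; a constant image maps to zeros. Scaling
bounds are computed post-clip, so the clipped outlier lands exactly on the
output maximum.

The reference segmenter thresholds the preprocessed image to a
per-structure window calibrated at the anchor acquisition ([P5, P95] of
in-mask intensities, widened by half a window width per side), intersects
a spatial prior ball (true centroid, maximal extent + 20 %), and keeps the
largest connected component. The widening constant makes performance decay
smoothly with contrast drift instead of collapsing one grid point from the
anchor. The segmenter's dependence on absolute post-normalization contrast
is deliberate: it makes the sweep exhibit the phenomenon the method
exists to measure (near-perfect at the anchor contrast, degraded in the
PD-weighted region where gland/background contrast is most dissimilar).
It is a test harness, not a model of any trained network.

## Reproducibility

All randomness flows from one global seed through named `SeedSequence`
substreams (phantom, raters, B1, per-sweep seeds in the acceptance
script). CSV output uses a fixed float format, so identical configurations
reproduce byte-identical files; every run writes a provenance record
(config echo, seed, package version).

## Known limitations

- The synthesis model omits sequence-specific corrections; absolute
  synthetic intensities need not match any vendor's output, only the
  TR/TE contrast structure.
- STAPLE results depend on the documented prior/crop conventions; other
  implementations may differ by a boundary voxel layer.
- HD95 is computed on voxel surfaces; mesh-based toolkits will differ by
  up to about half a voxel diagonal.
- The phantom's simplicity means quantitative results (DSC levels,
  exceedance percentages) characterize the harness, not clinical
  performance; only the method's machinery and qualitative sensitivity
  structure transfer.
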