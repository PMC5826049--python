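# Methods

This note documents the models, estimators and design choices behind
embryodyn, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Centrosome fluctuation analysis

Centrosome motion in the syncytial cortex superposes slow collective
drift (minute scale: cortical flows, stage drift, nuclear-array
rearrangement) on fast second-scale fluctuations that report on the
mechanics of the aster network. The analysis separates the two by time
scale:

- **Drift** is a centred moving average of each trajectory. The window is
  60 s by default ("minute scale"), converted to an odd sample count
  w = round(window/dt) + 1. At trajectory ends the window is truncated
  symmetrically so it stays centred; samples with truncated windows are
  flagged and excluded from the fluctuation average, which removes end
  bias at the cost of w − 1 samples per track.
- **Fluctuation parameter.** Residuals u(t) = r(t) − drift(t); the
  per-step statistic is |u(t+τ) − u(t)|² / (4τ) with lag τ = 1 frame by
  default (the finest scale the 1 Hz acquisition resolves), and D_i is
  its time average. The divisor 4τ is the 2-D mean-squared-displacement
  convention, so D_i is an apparent diffusion constant in µm²/s.
- **Averaging order**: time average per centrosome first, then ensemble
  statistics over centrosomes, so every centrosome contributes one D_i
  regardless of track length. Centrosomes from different embryos of a
  condition are pooled; embryo-nested analysis is possible by running
  per-embryo inputs separately.

Known estimator bias: subtracting a moving average of width w removes a
1/w share of the step variance, E[D̂] = D(1 − 1/w) for free Brownian
motion (≈ 1.6% at w = 61). This is far below the statistical spread at
realistic ensemble sizes and is left uncorrected; disabling drift
subtraction (window = None) gives the unbiased estimator when no drift is
present.

Conditions are compared by the fold change of mean D and a two-sided
pooled-variance Student's t-test. Degenerate inputs (two identical
constant samples) return p = 1 by convention.

### Simulated regimes

The generator provides the two mechanistic regimes the analysis is meant
to distinguish:

- **Free**: Brownian steps of variance 2·D·dt per axis plus optional
  constant drift velocity — a centrosome whose asters are uncoupled from
  the network (motor-depleted), or, at low D, a passive ATP-depleted
  cortex.
- **Tethered**: an Ornstein–Uhlenbeck process about a fixed anchor with
  relaxation time τ (default 20 s) and stationary variance D·τ per axis —
  a centrosome elastically crosslinked into the aster network. The exact
  discretisation x′ = a + (x−a)e^{−dt/τ} + σ_st√(1−e^{−2dt/τ})·ξ is used,
  so there is no Euler step-size bias at any dt, and particles start from
  a stationary draw. At lag dt the tether's *apparent* diffusion is
  D·τ(1−e^{−dt/τ})/dt, which the pipeline's condition presets use to set
  the depleted condition at 3× and the ATP-depleted condition at 1/5 of
  the control's apparent D.

The magnitude of the wild-type D in the embryo is not published in units
we could adopt, so the default true_D = 0.01 µm²/s is a free parameter
chosen to give realistic sub-pixel per-second displacements at a 0.2 µm
pixel size; all recovery tests are relative to the generator's ground
truth, not to the embryo.

## Nuclear-array topology and irregularity

Interphase nuclei form a near-hexagonal monolayer. Topology is read from
a Delaunay triangulation of the nuclear centroids:

- **Neighbor definition**: Delaunay adjacency, with edges longer than 2×
  the median Delaunay edge length pruned. Pruning removes the spurious
  hull-spanning edges a triangulation of a bounded field produces; the
  factor is configurable and the unpruned graph is available
  (prune_factor=None), which is also the configuration validated against
  a brute-force empty-circumcircle oracle.
- **Boundary exclusion**: a nucleus enters the statistics only if its
  Voronoi cell is bounded and lies entirely within the convex hull of the
  observed centroids (optionally shrunk by a margin). Nuclei at the field
  edge have unobserved neighborhoods and would otherwise bias the counts
  downward. The hull rather than the image rectangle is used so that the
  interior/boundary classification — and with it every reported
  statistic — is invariant under rigid rotation of the field of view;
  with an axis-aligned rectangle that invariance is unattainable.
- **Statistics**: neighbor-count proportions over interior nuclei in the
  bins {<5, 5, 6, 7, >7}; irregularity σ/µ = sd/mean over the unique edge
  lengths incident to at least one interior nucleus, pooled per embryo.
  Pooling edges (rather than averaging per-nucleus values) is the
  simplest reading of "variation of distances to neighboring nuclei" and
  is configurable in principle; both choices agree at 0 for a perfect
  lattice.
- **Comparisons** treat the embryo as the statistical unit (one
  proportion per bin and one σ/µ per embryo; two-sided pooled-variance
  t-test), matching the small-N design of injection experiments.

The generator emulates an embryo field as a triangular lattice (spacing
5 µm, the order of internuclear distances at syncytial blastoderm
stages) with isotropic Gaussian jitter and two kinds of packing defect,
each at rate defect_rate/2: site deletion (a missing or fused nucleus)
and displacement by half a spacing (a mispositioned nucleus). Deletion
lowers neighbor counts around the hole while displacement creates both
under- and over-coordinated nuclei, reproducing the spread of the bins
below 5 and above 7. The default condition presets — control jitter
0.25× spacing; depleted 0.40× spacing with defect rate 0.15 — were chosen
so the control reproduces the roughly 50/33/13% split of 6/5/7-neighbor
nuclei reported for buffer-injected embryos, and the depleted condition
a visibly degraded but still lattice-like field.

## Depletion kinetics

Total fluorescence per frame is summed after subtracting a per-frame
background estimated as the mode of the intensity histogram (robust to a
bright minority foreground; a fixed value or ROI mean can be supplied).
The series is normalized to the mean of pre-injection frames when the
time vector contains t < 0, else to the first frame. Saturated frames
are flagged via the log, never silently dropped.

The decay model is I(t) = I∞ + (I₀ − I∞)e^{−kt}, fitted by nonlinear
least squares with initialization from the series extrema and a
log-linear regression for k. The plateau term accommodates persistent
cleaved fluorophore; a pure-exponential mode (plateau pinned at 0) is
available and is the better-conditioned choice when the data are known to
decay to background — with a free plateau, half-life estimates on
hour-scale, 2%-noise series scatter by roughly ±7%, versus ±2% for the
pinned model. Fits with k ≤ 0, negligible amplitude, or failed
convergence are returned flagged with an undefined half-life rather than
raising.

Axis profiles project band pixels orthogonally onto a user-specified
body-axis segment (default band 10 µm, 100 bins); stripe depletion is the
mean intensity inside stripe intervals over the mean outside, per stripe
and pooled.

## Detection, linking, segmentation

Spot detection is scale-normalized Laplacian-of-Gaussian filtering with
local-maximum extraction above a relative threshold (0.3 of the maximum
response), quadratic sub-pixel interpolation of the response peak, and
merging of detections closer than the PSF width (brighter wins).
Convention: 0-based pixels, x = column, y = row, origin at the top-left
pixel centre; positions convert to µm only at the linking boundary.

Linking is greedy globally-nearest-pair assignment frame to frame:
candidate pairs within max_displacement (5 px default) are assigned in
order of increasing distance; tracks absent for at most max_gap frames
(2 default) may resume their id. Greedy assignment is deterministic and
essentially optimal when inter-particle spacing is large relative to the
per-frame step, which holds for centrosomes in the cortex; it is a
declared, replaceable choice and is validated by ground-truth identity
recovery on simulations rather than by equivalence to any particular
published tracker.

Nuclear segmentation: Gaussian smoothing → Otsu threshold → connected
components → small-object removal → watershed on the distance transform
to split touching nuclei → intensity-weighted centroids.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the estimators rely
on: Brownian/OU trajectory statistics on the acquisition grid, Gaussian
PSF spots at controlled SNR on a 16-bit range, lattice disorder and
packing defects, monoexponential decay, striped profiles, and per-embryo
binomial phenotype counts. One root seed drives everything through
per-purpose, per-particle derived streams, so outputs are bit-identical
given the seed and adding particles does not reshuffle existing ones.

It does not emulate: mitotic waves or cell-cycle remodeling of the array,
spatially correlated drift fields, anisotropic or depth-dependent PSFs,
photobleaching other than the plateau term, nuclear shape (only
centroids), or 3-D motion. Passing tests therefore demonstrate estimator
correctness under the stated models, not robustness to every real-data
pathology; the ingestion paths (TIFF/CSV) accept real recordings where
those effects are present.

## Problem sizes and numerical choices

Simulation-based tests use 100–300 particles over 220 s at 1 Hz, 3
embryos per condition with 9×9–20×20 nuclear lattices, and 60-point decay
series — ensemble sizes at which the recovery tolerances (10–15%
relative) sit several standard errors above the estimator noise floor.
Quartiles use linear interpolation of order statistics. Delaunay/Voronoi
degeneracies (collinear input) raise informative errors; cocircular
point sets are not in general position and their triangulation is
implementation-defined, which the oracle tests avoid by using continuous
random coordinates. Rendering clips to the 16-bit range, so noise floors
should stay well above 0 to avoid clipping bias.
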