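# Methods

## The model

A VPN type is a population of cells whose dendrites tile a 2D retinotopic
sheet (the lobula) and whose axons converge in one optic glomerulus. The
central object is the connectivity matrix `W[i, j]`: synapses from VPN cell
`i` onto postsynaptic partner `j`. The pipeline tests and quantifies one
hypothesis: `W[·, j]` is not uniform across cells but follows a spatial
gradient of the cells' dendritic positions, so each partner reads a weighted
region of visual space.

Four linked analyses operationalize this:

1. **Clustering.** Cells are points in partner space (columns standardized
   to unit variance after dropping partners with fewer than 50 total
   synapses — about one synapse per cell, the assumed EM reconstruction
   error floor — and within-type connections). PCA compresses to at most 10
   components; k-means with k from the scree elbow groups cells by output
   profile. The elbow is the k maximizing the discrete second difference of
   the within-cluster sum of squares, with a linear-curve fallback to k = 1;
   an automatic stand-in for what is usually a visual judgement, so the
   selected k should be treated as indicative, not definitive.
2. **Gradient geometry.** Each cell's dendritic endpoint centroid is
   projected onto a cut-plane; each partner gets a synapse-weighted input
   centroid (component-wise weighted median, lower median on ties — the
   median is used because count distributions are skewed and a single
   high-weight cell should not drag the centroid). The most anticorrelated
   partner pairs define perpendicular bisectors between their centroids; the
   axial median of those lines is the optimal unbiased separator, and
   partner positions are compared by signed projection onto its
   perpendicular. The anticorrelation threshold is not fixed a priori: it is
   chosen over the grid of observed negative pair correlations to maximize
   the absolute rank correlation between pairwise centroid distance and
   connectivity correlation.
3. **Glomerulus organization.** If axon terminals preserve the dendritic
   order, partners with anticorrelated inputs must occupy different
   glomerular subvolumes. Per pair, a linear soft-margin SVM (C = 1)
   estimates the separating plane between the two partners' postsynaptic
   site clouds; the median plane over pairs (normals flipped to one
   hemisphere, component-wise median, renormalized; median of signed
   offsets) gives the population separator. Projected site distributions
   are compared by the two-sample KS statistic (exact method when both
   classes have ≤ 25 sites, asymptotic otherwise) and the distance between
   projected medians.

   *Cross-fitting.* The plane is estimated on a deterministic half of each
   cloud and all statistics are computed on the held-out half. Fitting and
   testing on the same sites lets the separator chase noise: in simulation
   the same-data variant rejected a true null in ~13% of runs at α = 0.05,
   while the cross-fitted statistic is calibrated. This is a deliberate
   deviation from the naive procedure.
4. **Receptive-field readout.** All dendritic endpoints are jointly fit
   with a least-squares quadratic surface in the frame whose z-axis is the
   cloud's minor principal axis. A cell's projected dendritic polygon
   (convex hull in surface-intrinsic coordinates) becomes a circular
   Gaussian of unit height; σ is the radius of the equal-area circle
   (a `width_mode="cutoff"` switch reads the same radius as a 2σ cutoff
   instead). Two anchor surface points with known eye coordinates (eye
   centre; a dorsal point on the central meridian) fix a similarity
   transform into (azimuth, elevation) degrees — an affine approximation to
   a proper eye map, adequate over the central field but increasingly wrong
   toward the eye margin. A partner's predicted looming response is the sum
   over cells of synapse count times the fraction of the cell's σ-disc
   covered by the stimulus at its maximum size (30°); coverage is computed
   on the tangent plane at the RF centre (azimuth differences scaled by
   cos(elevation); spherical excess < 2% for ≤ 30° stimuli). Tuning curves
   recentre the stimulus across azimuth and normalize to the maximum.

Supporting metrics: the looming laws θ(t) = 2 tan⁻¹(l/(v|t|)) (contact at
t = 0, θ → 180°) and θ(t) = vₐ·t; circular statistics of takeoff direction
(R̄ = |Σ e^{iθⱼ}|/n and the Hodges–Ajne test); Δ[T2 leg angle] (angle
between the vertical through the T2-tarsi midpoint and the segment to the
centre of mass, forward lean positive, order-2 Butterworth low-pass at
50 Hz on 600 Hz tracking); spike detection by rise-slope threshold (first
difference over 1-ms steps, threshold = across-trial mean of the baseline
maximum slope, multiplier configurable, 2-ms refractory); and the
integrated potential (trapezoidal area of the baseline-subtracted trace
over the 150-ms response window, in ms·mV).

## The synthetic generator

The generator emulates the statistical structure the analyses consume, not
EM anatomy. Study conditions (defaults):

- 60 cells on a jittered grid over a 10 × 10-unit lobula sheet; dendritic
  arbors are isotropic Gaussian endpoint clouds (σ = 0.75, 30 endpoints).
- Partner specs `(direction, slope, baseline)`: expected count =
  baseline + slope · g, with g the min-shifted scalar projection of the
  cell position on the gradient direction (so baseline is the minimum
  expected count and expectations are non-negative by construction). The
  default antiparallel pair uses slope 5 synapses/unit and baseline 20,
  spanning counts 20–70 — the dynamic range of single-cell VPN→DN synapse
  numbers seen in EM (roughly 1–75).
- Counts are Poisson draws around expectation (`count_noise="none"` rounds
  the expectation instead). Negative binomial overdispersion is not
  modelled.
- The glomerulus is an elongated box; in topographic mode each cell's axon
  terminal position along the box axis is a monotone (affine + 5% jitter)
  image of its lobula gradient coordinate, and each synapse site is a
  Gaussian perturbation (σ = 1 unit) of the presynaptic cell's terminal —
  which localizes each partner's postsynaptic cloud where its high-weight
  cells terminate. In non-topographic mode terminals are position-
  independent and sites are uniform in the box, giving an exact iid null
  for the KS contrast. Partner dendrite clouds sit at the glomerular pole
  matching the partner's gradient (box centre for uniform partners).
- All randomness flows from one integer seed through `numpy.random.
  SeedSequence.spawn`, so sub-streams (positions, counts, glomerulus,
  sites) are independently reproducible.

What passing tests on this generator do **not** show: real arbors are
branched and anisotropic, real gradients need not be linear or monotone,
synapse counts are often overdispersed relative to Poisson, glomeruli have
curved neuropil boundaries, and cut-planes are chosen manually on real
data. The generator demonstrates that the estimators recover planted
structure at realistic noise levels — not that any particular biological
VPN type has that structure.

## Numerical choices

- Standardization includes mean-centering (PCA follows); k-means uses
  k-means++ with 25 restarts and a fixed random state.
- Spearman ρ is Pearson on mid-ranks (constant vectors give NaN, reported
  as missing, never coerced to 0).
- The axial median of line orientations is the observed orientation
  minimizing summed axial distance (period 180°); anchor points combine by
  component-wise median.
- SVM planes are fit on at most 1,000 subsampled sites per class
  (deterministic subsample); projections always use every site.
- Disc-coverage fractions use closed-form circle-intersection areas, with
  pairwise inclusion–exclusion for disjoint stimulus arrays and a
  10⁴-point sunflower-spiral quadrature when array discs overlap
  (deterministic; cross-checked against Monte Carlo to ±0.01).
- Hodges–Ajne: the boundary is scanned just past each data direction
  (half-open half-planes); the exact p = (n − 2m)·C(n, m)/2^{n−1} applies
  for m < n/3, larger m reports p = 1. At n = 20 the attained level at
  α = 0.05 is 0.0304 — the test suite asserts this exact level and checks
  the empirical rejection rate against it within binomial error, because a
  2,000-replicate estimate alone cannot resolve a level that close to the
  acceptance band edge.
- Track gaps strictly shorter than 5 frames are linearly interpolated;
  longer gaps stay missing; smoothing is a NaN-aware centered moving
  average.
- Spike times are reported at the end of the 1-ms rise step that crosses
  threshold (within 1 ms of the true rise onset at the defaults).

## Problem sizes

Simulation-backed checks run at the study conditions above: 50 seeds for
gradient and clustering recovery, 20 + 100 seeds for the topographic vs
shuffled glomerulus contrast, 5 seeds for tuning curves, 2,000 replicates
for test calibration. These sizes put Monte-Carlo error comfortably inside
the asserted margins while keeping the default suite in tens of seconds.

## Known limitations

- The eye mapping is a 2-anchor similarity transform, not a geodesic eye
  model; RF positions far from the anchors inherit its distortion.
- The scree-elbow rules for the PC count and k are deterministic stand-ins
  for visual judgement and need not match a human call on real data.
- The topography index summarizes order along a single principal axis of
  the glomerulus; genuinely 2D topographies would need two axes.
- Δ[T2 leg angle] uses a vertical reference axis read off the tracked
  geometry; the convention is configurable but a body-axis reference would
  change absolute values (not signs).
- With the spike threshold multiplier at 1.0 (threshold = baseline maximum
  slope), pure-noise excursions in a 150-ms response window exceed the
  threshold in roughly `n_response/(n_response + n_baseline)` of trials;
  averaging or a multiplier > 1 suppresses these single-trial false
  positives.
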