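# Methods

`periplaque` quantifies the spatial relationship between amyloid-β plaques
and pre-synaptic boutons in 2D fluorescence images, and validates every
stage against a forward simulator with complete ground truth.  This note
documents the models, the parameters that matter, and the design decisions
taken where the problem left genuine freedom.

## The measurement problem

In amyloidosis models, dense-core plaques (stained with X34) are surrounded
by axons whose pre-synaptic boutons carry an HA-tagged synaptophysin
reporter.  The scientific questions are spatial: is bouton density reduced
inside and immediately around plaques; does that local loss propagate to
whole-axon bouton density; are inter-bouton spacings disturbed for axons
passing near plaques; how often does a plaque harbour a dystrophic (swollen)
axon segment; and does pre/post-synaptic apposition (HA–Homer1
colocalization) change.  All quantities are computed per subject (mouse) or
per axon, matching the statistical units of the corresponding designs.

## Scene model (simulator)

Scenes are 2D — the data this emulates are single confocal planes of
thin sections; there is no 3D rendering.

**Plaques.** Radial-perturbation polygons: a circle of lognormal radius
(median 4 µm, σ_log 0.25 at the reference conditions) perturbed by
low-order Fourier modes (orders 2–6, amplitude ∝ irregularity / order).
Irregularity 0 yields a regular 64-gon, so analytic disk results hold to
polygonization error.  Plaques are placed by rejection sampling without
mutual overlap; failure to place after bounded retries raises an error
naming the constraint.

**Axons.** Each axon is a persistent random walk entering from a field
edge: per arc step `ds` the heading receives a normal increment of standard
deviation `axon_curvature · sqrt(ds)` (a Wiener process in heading, so the
curvature parameter has units rad/√µm).  Default 0.08 rad/√µm gives gently
curving axons with a persistence length of hundreds of µm.

**Boutons.** A gamma renewal process along arc length: gaps have mean
`mean_inter_bouton_um` (5 µm) and coefficient of variation `spacing_cv`
(0.5).  The process is started ten mean gaps before the axon origin so the
point process is stationary on the axon ("equilibrium renewal" by burn-in);
the expected count is L/mean for any CV.  A per-axon rate multiplier
(lognormal, unit mean, CV `axon_rate_cv` = 0.35) models the large
between-axon variability of bouton density that real per-axon data show.
The unit-mean parameterization leaves the expected scene-wide count
unchanged.  Without this heterogeneity, per-axon densities are so uniform
that even the ~2 % whole-axon dilution caused by localized depletion
becomes statistically detectable at realistic axon counts — a regime real
data do not exhibit.

**Depletion.** Piecewise-constant removal: boutons strictly inside a plaque
are removed with probability `depletion_prob_inside`, boutons within
`depletion_radius_um` (5 µm) of the boundary with `depletion_prob_ring`
(both 0.8 at reference conditions), boutons beyond never.  This is the
simplest model producing loss confined to the plaque and its first
annulus; smooth kernels were considered and rejected because recovering a
sharp spatial scale is exactly what the annulus analysis is asked to do.

**Dystrophies.** For every (plaque, axon) pair in contact (axon passing
within the depletion radius), a Bernoulli draw with probability 0.11 places
one 3-µm swelling at the axon's closest point to that plaque.  The default
probability is calibrated so that ≈30 % of plaques carry at least one
swelling under the reference geometry — the regime the dystrophy scoring is
meant to operate in.

**Optics and noise.** Objects render as isotropic Gaussians: an object of
physical diameter d has σ_obj = d/(2√2), convolved with a Gaussian PSF
(σ 0.3 µm) giving σ_eff = √(σ_obj² + σ_PSF²).  Plaques render as filled
polygons blurred by the PSF; the axon channel renders the polylines with
line-spread blur.  Noise: Poisson shot noise (`Poisson(I·s)/s`) plus
Gaussian read noise, clipped to the bit-depth range.  Default amplitudes
(bouton 100 over background 20, read noise 2) give spot SNR ≈ 9.  Geometry
and noise use separate random sub-streams of one master seed, so redrawing
noise leaves the scene fixed.

What the simulator does **not** model: 3D structure and out-of-focus light,
uneven illumination, photobleaching, autofluorescence structure, glial or
vascular channels, plaque-core/halo substructure, and true biological
variation beyond the two variability knobs (gap CV, axon rate CV).  Passing
the recovery tests therefore demonstrates correctness of the measurement
pipeline under the stated imaging model, not performance on any particular
real dataset.

## Detection

Puncta: multi-scale Laplacian-of-Gaussian blob detection (6 log-spaced
scales spanning 0.25–1.4 µm), threshold expressed relative to the image's
robust noise scale (1.4826·MAD), followed by two suppression passes —
duplicates (keep the higher peak when centroids are closer than one blob
sigma) and containment (drop a coarse blob whose support already holds a
distinctly finer kept blob; the coarse maximum is the scale-space echo of a
resolved pair).  skimage's internal overlap pruning is disabled because it
makes the opposite choice (it would keep the coarse blob).  Centroids are
refined to sub-pixel precision by background-subtracted intensity centroids
in a ±2σ window; apparent diameter is reported as 2√2·σ of the best scale.
Each detection also carries a *fill factor* — flux within 2.5σ divided by
peak·2πσ², ≈1 for a solid Gaussian — used to reject loose clusters.

Dystrophies are the detections with apparent diameter ≥ 2.5 µm and fill
factor ≥ 0.6.  The diameter threshold sits between the apparent size of a
bouton (≈1.3 µm), of an unresolved bouton pair (≈2.0 µm), and of a 3-µm
swelling (≈2.8 µm); 2.5 µm rejects pair artifacts while keeping swellings.

Plaques: Otsu threshold on the X34 channel (fixed-threshold mode available
for reproducibility), morphological closing (0.5 µm radius), hole filling,
connected components, minimum-area filter (10 µm²), boundary polygon from
the 0.5 iso-contour.

Axon assignment: each punctum snaps to the axon with minimal perpendicular
distance if within `snap_radius_um` (1 µm); the arc position of the
orthogonal projection is recorded; ties break to the lower axon id and
ambiguous cases (second axon also in range) are counted and logged.

Coordinate convention everywhere: pixel (i, j) has its centre at
((j+0.5)·µm/px, (i+0.5)·µm/px), origin at the image top-left; all analysis
is in µm.

## Spatial statistics

**Distance field.** Signed Euclidean distance from the union plaque mask
(negative inside), computed by EDT with anisotropic pixel sampling.  With
no plaques the field is +∞.

**Annulus profile.** Bins: plaque interior plus rings with edges
[0, 5, 15, 25, 35] µm (configurable).  The inner 0–5 µm edge is the
scientifically meaningful scale; the intermediate edges are a reasonable
partition of the 5–35 µm range with the outermost ring serving as the
far-field reference.  Density = bouton count / bin area (∩ ROI);
percentages normalize each bin's density by the sum over bins, so they sum
to 100.  Zero-area bins are excluded from the normalization and flagged;
bins touching the field border are flagged clipped.

Two implementations exist with one output schema: a raster path (bin
membership and areas from the distance-field image — the natural path when
the input *is* an image with an ROI mask), and an exact vector path
(ring areas from buffered plaque polygons clipped to the field; bouton
distances from exact polygon geometry).  Counts and areas must share one
geometric definition: mixing exact counts with raster areas (or sampling a
coarse raster across the sharp depletion edge) injects a systematic
per-bin density bias that a blocked ANOVA across subjects happily detects.
Cohort-level simulation studies therefore use the exact path; the raster
path is used for image data, at the image's own resolution.

**Per-axon metrics.**  Closest approach = minimum of the signed distance
field along the densely resampled polyline (≤ pixel pitch); axons entering
a plaque get negative values; binned with the ring edges, interior folded
into "0–5 µm"; axons beyond the last edge are excluded from
plaque-conditioned analyses.  NND-3 = mean geodesic (arc-length) distance
from each bouton to its three nearest same-axon boutons, averaged over
boutons; axons with fewer than four boutons are excluded; a straight-line
(Euclidean) mode is provided since either reading of "distance along the
same axon" is defensible.  Linear density = 100·n/L per axon; per subject,
total boutons / total annotated length, with subjects excluded below
1,000 µm of summed annotated length.

**Colocalization.** Greedy one-to-one nearest-pair matching of pre- to
post-synaptic centroids within 0.5 µm; fraction = matched / all pre × 100.
Greedy matching (not optimal assignment) is deliberate: it is simple,
order-independent (pairs are processed by ascending distance), and at
realistic densities differs negligibly from the optimal matching.

**Dystrophy scoring.** A plaque is DN-positive if any detected swelling
lies inside it or within 5 µm (= the first ring width) of its boundary;
the summary is the DN-positive percentage over plaques.

## Statistics

* Repeated-measures one-way ANOVA: randomized-complete-block sums of
  squares (subject = block), df = (k−1, (k−1)(n−1)), no sphericity
  correction — the standard reading of the figure-legend convention; a
  Greenhouse–Geisser option is not applied by default.  When the treatment
  SS is numerically zero, F = 0 and p = 1 by convention.
* One-way ANOVA across independent groups; two-way ANOVA with interaction,
  type-II sums of squares (statsmodels OLS backend).
* Unpaired two-sided pooled-variance t test; mean ± SEM reported.
* Dunnett post hoc (every bin/group vs the pre-declared reference, the
  25–35 µm ring): two-sided adjusted p-values from the multivariate-t
  representation with correlation ρ_ij = λ_i λ_j (λ = √(n_i/(n_i+n_ref));
  ½ for the balanced block design), integrating the common normal factor by
  96-node Gauss–Hermite and the studentizing chi factor by 128-node
  Gauss–Legendre quadrature.  This is deterministic (no Monte Carlo) and
  agrees with `scipy.stats.dunnett` to that implementation's own
  quasi-Monte-Carlo accuracy (~10⁻⁴).

The type-I behaviour of the full profile→RM-ANOVA chain is itself a
validation target: percentage profiles are compositional and mildly
heteroscedastic across bins (small interior areas ⇒ noisier percentages),
which makes the uncorrected RM-F slightly anticonservative at n = 3.  At
the reference conditions the measured rejection rate under the
no-depletion null is ≈7–11 % at α = 0.05 (runs of 200 cohorts); markedly
sparser bouton fields push it higher.

## Reference experiment sizes

The canonical experiments (`periplaque.experiments`) use: 20 fields of
1024×1024 px at 0.2 µm/px for detector fidelity; 200 three-subject cohorts
for null calibration; 50 cohorts for the depletion headline; 50 single
fields for radius recovery; one ~1,100-bouton field for colocalization;
4×50 plaques for dystrophy scoring.  Cohort fields are 800×800 µm with 250
axons, of which 150 are treated as the annotated subset for per-axon
statistics — the annulus analysis sees all boutons in the field, the
per-axon analysis only the annotated axons, mirroring the two workflows.
Cohort-level closest-approach maps use a 1 µm/px distance field (bin-edge
misassignment ≤ one pixel, immaterial for 10-µm-wide bins); analytic
geometry checks run at 0.2 µm/px.

## Known limitations

* 2D only; axial structure and section thickness are not modelled.
* The detector's diameter estimate is quantized to the LoG scale grid;
  size-based dystrophy classification inherits that quantization.
* Sub-resolution bouton pairs (closer than ≈1 µm at the default optics)
  merge into one detection; at reference densities this caps recall near
  0.95.  This is an optics limit, not a detector parameter choice.
* The RM-ANOVA is reported without sphericity correction by design (see
  above); for strongly heteroscedastic profiles its α is optimistic.
* Greedy colocalization is not an optimal bipartite matching (differences
  are negligible below ~0.1 pairs/µm²).
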