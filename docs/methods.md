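# Methods

This note documents the models implemented in `colonyflow`, their
assumptions, the parameter defaults and why they were chosen, and the
numerical decisions that affect results. Units are SI internally; the API
boundary accepts the laboratory units usual in microfluidics (µm, mm/s,
µl/min, cm²/s).

## Transport of planktonic swimmers

Swarmer cells in a rectangular channel (length *L* = 1 cm along the flow,
width *w* ∈ {250, 500} µm, height *h* ∈ {25, 50, 90} µm) are modelled as
point particles advected along *x* and diffusing across the depth *z* with
an effective diffusivity *D*. Swimming is treated as unbiased run-and-
tumble motion, i.e. pure diffusion at long times, with the standard
enteric-bacterium value *D* = 4 × 10⁻⁶ cm² s⁻¹ as default
(`D_SWIM`); nonmotile cells get a Stokes–Einstein-order passive value
*D* = 2 × 10⁻⁹ cm² s⁻¹ (`D_PASSIVE`, a ~1-µm particle in water at 30 °C).
There is no chemotaxis, no hydrodynamic wall interaction, no run-tumble
microstructure and no lateral (*y*) dynamics in the transport simulator —
the channel is ≥ 2.8× wider than tall and sidewalls are ignored.

The competition between advection and vertical exploration is captured by
the timescales τ_a = L/v and τ_D = h²/D and their ratio, the Péclet
number Pe = h²v/(DL). At v = 0 we report τ_a = ∞ and Pe = 0 rather than
raising, so quiescent limits are representable.

**Reactive floor.** The timescale argument alone fixes no attachment
scale, so the floor is a partially absorbing (Robin) boundary with
reactivity κ (m/s). The regime matters: a perfectly absorbing floor would
give p_att ∼ Pe^(−1/2…−1/3) (capture limited by transport into the
depletion layer), whereas the empirically observed inverse-Pe scaling
requires reaction-limited capture, κh/D ≪ 1, where the depth profile
stays well mixed and

p_att = 1 − exp(−κL/(vh)), with κL/(vh) = (κh/D)·Pe⁻¹.

The default dimensionless reactivity is κh/D = 0.01, two orders inside the
reaction-limited regime (flagged below κh/D = 0.1). κ absorbs everything
the model does not resolve — pili/holdfast kinetics, near-wall
hydrodynamics, and the fact that assay inocula are swarmer/stalked
mixtures which biases measured probabilities low but leaves the scaling
exponent untouched.

**Discretisation.** Euler–Maruyama steps: x ← x + u(z)·dt (plug profile
u = v by default, since mean velocity is used throughout; plane-Poiseuille
u = 6v(z/h)(1−z/h) available for sensitivity analysis), z ← z +
√(2D·dt)·N(0,1). The ceiling reflects. On each floor contact the particle
sticks with the Erban–Chapman probability P = κ√(π·dt/D), which renders
the continuum absorption rate dt-invariant (verified by a
halved-dt test); P > 0.5 triggers a coarse-timestep warning. The default
dt satisfies both √(2D·dt) ≤ h/50 and v·dt ≤ L/100; simulated time is
capped at 10·τ_a under flow (particles still airborne then are counted as
exited, i.e. right-censored). Statuses are terminal.

**Estimators.** Two capture estimators are provided. The *analog*
estimator performs Bernoulli absorption, yielding discrete attachment
events with positions/times (needed for dispersal kernels and confidence
intervals; Wilson 95% CI). The *weighted* estimator uses implicit capture
(survival biasing): each particle carries a weight multiplied by (1−P) at
every contact, and the absorbed weight estimates the same probability with
far lower variance. This matters at the high-Pe end of the scaling
experiment, where the expected number of analog attachments per 2 × 10⁴
particles falls below one and log-transformed analog estimates are
dominated by Poisson noise; the scaling exponent is therefore fitted on
weighted estimates, while analog runs are used to verify agreement with
the closed form to within three binomial standard errors at every Pe.

**Scaling fit.** Ordinary least squares of log₁₀(p_att) on log₁₀(Pe);
the slope is the power-law exponent (α log x = log xᵅ). Nonpositive
probabilities cannot be placed on log axes; the pipeline drops such
points before fitting (with the weighted estimator this does not occur at
the default problem sizes).

## Agent-based surface colonization

Stalked cells are immotile points on the channel floor carrying a lineage
color (two constitutive labels, 1:1 at seeding) and a founder id. Division
is a renewal process per cell: intervals are Normal(T_div, CV·T_div)
truncated at 0.2·T_div, with T_div = 5400 s (a typical *C. crescentus*
doubling in rich medium at 30 °C; the in-channel value is not directly
measured) and CV = 0.15. Founders draw their first interval from the same
distribution at t = 0. Attached cells never detach; there is no nutrient
field, no EPS mechanics, no 3-D growth.

At each division the daughter either:

* **attaches locally** (probability `p_near`): proposed one cell length
  (2 µm) downstream of the mother with 0.3 µm isotropic jitter, then
  snapped to the nearest free site of an occupancy lattice. The lattice is
  anisotropic, matched to the cell outline — axial spacing equal to the
  cell length (2.03 µm for a 1.29 µm² footprint at aspect ratio 2.5),
  lateral spacing footprint/length (0.64 µm) — so each site holds one
  cell, site area equals the mean cell footprint, and microcolonies grow
  as compact monolayer patches whose area tracks cell count. (A pure
  offset-plus-jitter rule without occupancy was tried first and rejected:
  cells pile onto a line of sites, producing one-cell-wide streaks whose
  rendered area is nearly independent of cell count, unlike real
  microcolonies.) The daughter inherits color and founder id.

* **enters the bulk** (probability 1 − `p_near`): its fate is drawn from
  an exponential waiting-time kernel with rate
  1/(h/κ + h²/(3D)) — the reaction resistance in series with the mean
  vertical first-passage resistance (h²/3D is the reflecting-top mean
  first-passage time from a uniform start). The cell lands v·t downstream
  (washed out if past the outlet) with lateral Gaussian spread √(2Dt),
  reflected at the sidewalls, and founds a *new* colony (fresh founder
  id, inherited color). For motile cells at the default reactivity the
  rate reduces to κ/h within 0.3%, so the implied attachment probability
  1 − exp(−κ(L−x)/(vh)) is consistent with the Brownian-dynamics
  simulator (cross-validated in the tests). For nonmotile cells the
  diffusion resistance dominates, suppressing reattachment — which is
  precisely the flagellum-less phenotype: with κ (adhesion) held fixed,
  loss of swimming removes the transport to the wall.

`p_near` is the probability that a daughter attaches immediately after
division; experimental work reports it similar between wild type and
flagellum-less mutants (hence one value for both modes) but gives no
number. It is a calibration knob with documented bounds 0.3–0.6. The
library default is 0.4. A maturation delay before a reattached swarmer
divides is not modelled (absorbed into T_div).

An event ledger (divisions, local attachments, reattachments, washouts)
satisfies local + reattached + washed = divisions at all times. A
population cap (default 5 × 10⁵ cells) truncates runaway runs with a
warning.

## Synthetic imaging

Populations are rendered into two single-channel 16-bit rasters (one per
fluorophore, mirroring separate acquisitions) at 0.1791 µm/px — the pixel
size back-derived from the empirical equivalence 1.29 µm² ≈ 40.2 px of the
mean cell footprint; this inference (the acquisition's true
magnification-to-pixel mapping is not independently known) makes the 15-px and 200-px
thresholds physically meaningful on synthetic data. Each cell is a filled
ellipse (aspect 2.5 → 2.0 × 0.8 µm) oriented along the flow; the image is
Gaussian-blurred (default 0.15 µm, the Gaussian-PSF scale of a 0.9-NA
objective), then a linear background gradient and additive Gaussian noise
are applied (Poisson statistics, photobleaching, drift and stitching are
not modelled). Ground-truth label masks are the pre-blur, pre-noise
labels, so they are invariant to the noise seed; rasterised single-cell
area is 40 ± 3 px over subpixel positions (mean 40.3).

Named deterministic fixtures (`blank`, `single_cell`, `two_squares_gap6`,
`two_squares_gap20`, `checkerboard_mixed`, `segregated_halves`,
`near_saturated`) provide exactly known ground truth for every branch of
the quantification pipeline.

## Quantification

* **Segmentation.** Per channel, local-mean adaptive threshold: T =
  µ_local + (1 − s)(F − µ_local), where µ_local is a 251-px moving
  average, F a robust foreground plateau (75th percentile of pixels more
  than 5 robust σ above µ_local), and the sensitivity s is a
  piecewise-linear function of the normalised median intensity (defaults
  0.50 rising to 0.65; s = 0.5 is the half-max contour, which best
  recovers the pre-blur outline). A configurable background-percentile
  floor implements percentage background removal. The exact calibrations
  such pipelines use in practice are instrument-specific and unpublished;
  these mappings are declared approximations. Images with no resolvable
  foreground, or constant intensity, yield an empty result (the latter
  with a warning), mirroring the exclusion of aberrantly segmented
  images. Components are 8-connected; objects under 15 px (one upright
  cell) are removed; border objects are retained.
* **Coverage** is the pixel fraction of the OR-merge of the two channel
  masks. Images above 80% coverage are excluded from colony and mixing
  statistics (clusters are unresolvable there).
* **Colony areas.** On the OR-merge: remove objects < 200 px (≈ 5 cells),
  close with a disk of radius 5 px (masks are padded first so border
  objects close identically), label, convert to µm², report the median.
  Filtering before closing is the default order; the reverse order
  is available behind a flag. Closing bridges gaps < 10 px, verified
  against an independent morphology implementation.
* **Cross-lineage mixing.** Channels are closed separately; for every
  colony centroid the Euclidean distance to the nearest opposite-color
  centroid is pooled over both directions (mean/SD, µm). No minimum-area
  filter is applied by default (only the closing); a filter is available
  through `min_colony_px`. Empty channels give an explicitly *undefined*
  statistic, distinct from zero. A table-based route
  (`mixing_from_tables`) computes the same statistic from ground-truth
  colony centroids.
* **Attachment kinetics.** In a uniformly sampled timelapse, an event is
  the first frame of each maximal run of ≥ 3 detections whose centroid
  moves ≤ 3 px/frame (greedy nearest matching; both the run length and
  the "same location" tolerance are configurable — the tolerance is a
  design choice, not a measured quantity). The rate r is the OLS slope of the
  cumulative event count; p_att = r/(Q·C), with the areal flux J = Q·C/A
  reported when geometry is supplied, and r/(Q·C) > 1 rejected as
  inconsistent.

## Replica study conditions

The end-to-end replica (`ReplicaConfig`) runs colonization at 2 vs
27 mm/s for 24 simulated hours in a 1 cm × 500 µm × 25 µm channel, 300
founders, 10 seeds per condition, renders a 500-µm window of the full
channel width centred 9 mm downstream, quantifies it, and separately fits
the Pe scaling in the 500 × 90 µm attachment-assay geometry (Pe ∈ {3, 10,
30, 100, 300}, 2 × 10⁴ particles each, weighted estimator).

Two of these conditions deserve justification:

* **Channel height 25 µm.** Experimental channels span heights of
  25–90 µm, and the pairing of height with flow condition is
  unconstrained. 2 mm/s is a diffusion-dominated "weak flow" condition
  only in the shallow channel (Pe = 0.31 at h = 25 µm vs 2.0 at 90 µm),
  so the shallow geometry is the one in which the weak/strong contrast at
  2 vs 27 mm/s is physically meaningful. Chosen once and fixed.
* **p_near = 0.5.** With the library default 0.4 the weak-flow median
  microcolony area sits at ≈ 50 µm², at the boundary of the small-colony
  regime rather than inside it; within the documented 0.3–0.6 bounds the
  replica uses 0.5, which places the weak-flow condition clearly in the
  mixed/small-colony phase (median ≈ 20–30 µm²) while strong flow remains
  in the large-colony phase (median ≫ 100 µm²). The founder count (300)
  was chosen once so that 24-h populations (~2 × 10⁵ cells) stay under
  the population cap.

Problem sizes throughout (particle counts, founder numbers, seed counts,
window size) are the package's default study conditions; they can be
scaled up freely through the config.

## What the synthetic data does and does not show

The generator emulates the geometry, transport physics, division
statistics, two-label seeding and optics of the experimental system, so
passing tests demonstrate internal consistency: the simulator reproduces
the closed-form attachment probability, the pipeline recovers known
ground truth, and the emergent colonization regimes (coverage and colony
area vs flow, mixing vs flow, motile vs nonmotile) move in the
experimentally observed directions. It does *not* emulate real cell-shape
mechanics, adhesion maturation, EPS, uneven illumination or camera
non-Gaussianity, and κ, p_near and T_div are calibration parameters, not
measurements — so quantitative agreement with any particular
experimental number (e.g. absolute coverage curves or mixing SDs) is
outside what these tests establish.

## Known limitations

* The transport model is 2-D (x, z); lateral structure enters only
  through the colonization kernel's Gaussian spread.
* Reaction-limited capture is assumed; the analytic form refuses to
  evaluate outside κh/D < 0.1 rather than silently extrapolating.
* Overcrowding is handled by nearest-free-site search up to 40 µm; at
  pathological local saturation a cell is placed untracked.
* The analog capture estimator is noisy at Pe ≳ 100 with 2 × 10⁴
  particles (expected events ≲ 2); use the weighted estimator or more
  particles there.
* Timelapse event detection uses greedy nearest matching, adequate for
  the sparse attachment fields it targets, not for dense crossing tracks.
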