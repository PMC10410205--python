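# Methods

`sealspacing` analyses the fine-scale spatial arrangement of seals resting
("hauled out") in colonies, starting from georeferenced polygon outlines of
individual animals. This note documents the models and procedures the
package implements, the choices made where the design was genuinely open,
and what the synthetic test data can and cannot show.

## Input model

One annotation is one animal: a simple polygon in a projected metric CRS
(e.g. Amersfoort / RD New, EPSG:28992). Annotations are grouped into
haul-out sites; each site carries a species label (`grey`, `harbour`, or
`mixed` when its members disagree) and an analysis window. Mixed-species
sites and pupping-season sites are excluded from species comparisons:
mixed sites confound the species contrast, and mother–pup pairs lie
unusually close together, biasing nearest-neighbour statistics downward.

Input is GeoJSON; a missing CRS or a geographic (degree-unit) CRS is a hard
error because every downstream quantity is a planar Euclidean distance in
metres. Reprojection is deliberately out of scope — callers must supply
projected coordinates.

**Analysis window.** Where no explicit window is supplied, the per-site
window is the convex hull of all annotation polygons buffered by 10 m. This
is bounded, contains every animal, and is reproducible from the annotations
alone. The buffer matters for the shuffle null (below): it is the space into
which perturbed animals may move. 10 m is of the order of the largest radius
used in the density analysis, so perturbed animals can leave the occupied
area slightly but not colonise arbitrary empty space.

## Nearest-neighbour distances (NND)

For each animal, the NND is the minimum *edge-to-edge* distance between its
outline and any other outline on the same site; touching or overlapping
animals are at distance 0. Edge-to-edge (rather than centre-to-centre)
distance is the behaviourally relevant gap between bodies and is insensitive
to body size differences between species. The statistic is directed: every
animal contributes one value, treating each animal's position as its own
spatial decision, so mutual nearest neighbours are deliberately counted
twice. NNDs are never computed across sites.

Quantile summaries use linear interpolation between order statistics
(quantile type 7), pinned so that summaries reproduce bit-for-bit.

## Neighbourhood density

For each focal animal, the number of other animals whose centre points
(area centroids) fall within circles of radius 1, 3, 5 and 10 m of the
focal centroid. A distance exactly equal to the radius counts as inside
(ties are measure-zero on real data; the rule is pinned for determinism).
No edge correction is applied: counts near the colony boundary are biased
low, but the bias acts on both species alike in a comparison. Summaries
report the mean with a normal-approximation 95% CI and, separately, the
2.5%/97.5% distributional quantiles, since either reading of a "95% CI"
may be wanted in a density table.

## The spatial-perturbation ("shuffle") null model

The question: do animals avoid very small gaps, beyond what their colony's
coarse density explains? The null model erases fine-scale spacing while
preserving coarse structure:

1. **Bandwidth.** An isotropic Gaussian kernel bandwidth σ is chosen per
   site by minimising a leave-one-out mean-square-error cross-validation
   criterion for the kernel intensity estimate
   λ̂_σ(u) = Σ_j φ_σ(u − x_j):

   M(σ) = ∫ λ̂_σ(u)² du − 2 Σ_i λ̂_σ^{(−i)}(x_i),

   where the squared integral reduces by the Gaussian convolution identity
   to a pairwise Gaussian sum at bandwidth σ√2. The search runs over
   [0.1 m, diameter(window)/2] (log-spaced grid, then golden-section
   refinement) and is fully deterministic. On clustered patterns the
   criterion has a sharp interior minimum near the cluster scale; on
   spatially homogeneous patterns it favours heavy smoothing and can run to
   the upper bound, which is the correct answer for a flat intensity.
   Per-site bandwidths are averaged within species by default and the
   common value applied to every site of that species, so a single busy
   site does not dominate its own null; per-site and manual-override
   policies are available in configuration.

2. **Perturbation.** Each polygon's centroid is displaced by an isotropic
   Gaussian of standard deviation σ per axis ("jitter" mode, the default),
   rejection-resampled until the new centroid lies inside the window.
   Orientation is preserved. Because the displacement scale equals the
   kernel bandwidth, the perturbed pattern has (in expectation) the
   original pattern's kernel-smoothed intensity: coarse density is kept,
   sub-σ structure — including any short-range avoidance — is destroyed.
   An alternative "intensity" mode draws fresh centres from the fitted
   colony-wide surface by rejection sampling; it preserves the same coarse
   surface but discards each animal's identity-specific location, and is
   provided for sensitivity analysis.

3. **Overlap resolution.** Animals rarely lie on top of one another, so
   the null configuration must be overlap-free (overlap = interior
   intersection of area > 1e-9 m²; boundary contact is allowed). Polygons
   are finalized one at a time in a seeded random order, each tested
   against already-finalized polygons only, which makes termination
   behaviour order-explicit and reproducible. An overlapping polygon is
   first rotated about its centroid in +1° increments through 359°; if no
   rotation frees it, the rotation is discarded and the polygon is stepped
   10 cm at a time along a random unit direction until free (up to a
   configurable step cap, default 1000). If a step would carry the
   centroid outside the window, a fresh direction is drawn (from the same
   seeded stream) and stepping continues; the step budget keeps accruing,
   so termination is still guaranteed or reported as an error naming the
   polygon and seed. The per-polygon resolution log records whether the
   polygon initially overlapped and how many degrees/metres were needed,
   which proves that orientations change only where the resolver required
   it. Alternative resolution strategies can be plugged in behind the same
   interface.

4. **Comparison.** NNDs of the placed polygons are compared with the
   observed NNDs via the proportion below 25 cm (see inference). The
   25 cm threshold exceeds the typical annotation imprecision of 7.5–10 cm
   imagery, so a deficit below it cannot be an artefact of sloppy outlines.

All randomness flows from a single seed; per-site substreams are derived
from (seed, CRC32(site id)), so adding or removing a site never perturbs
another site's draws, and a fixed seed reproduces every output bit for bit.

**Properties and limitations of the null.** The perturbation operator is
*diffusive*: applied repeatedly to a clustered pattern it spreads the
clusters (variance grows by σ² per pass), so the operator has no
stationary clustered distribution. Consequently the "no spurious signal"
calibration — shuffling a pattern that was itself produced by one jitter
pass must not change the small-NND proportion — holds on spatially uniform
patterns (where the operator is near-stationary) and is tested there; on
strongly clustered patterns a second pass slightly *raises* typical NNDs,
which makes the test of an observed small-NND deficit conservative rather
than anticonservative. The overlap-resolution step adds a weak effective
inhibition at body scale to the null itself; this too is conservative for
detecting avoidance at distances beyond body contact.

## Inference

Three comparisons, all pooling sites within species (site-level random
effects are a documented non-goal):

- **Median (and 25%-quantile) NND difference** — quantile regression of
  NND on a species indicator (0.5 or 0.25 quantile). The coefficient is
  the between-species quantile difference; the t statistic is the
  asymptotic kernel-based (Greene) value, flagged in the result metadata
  since several inference methods exist for quantile regression. The point
  estimate, not the t value, is the scientifically meaningful surface.
- **Density difference per radius** — negative-binomial GLM (log link,
  NB2, dispersion estimated by maximum likelihood) of neighbour count on
  species. Valid under over- or under-dispersion; the coefficient is a log
  rate ratio. A species with all-zero counts at some radius leaves the
  rate ratio undefined; the pipeline logs and skips that radius instead of
  aborting the whole report.
- **Observed vs shuffled proximity** — binomial GLM (logit link) on the
  aggregated counts of NNDs < 25 cm ("successes") and ≥ 25 cm
  ("failures"), with condition (observed/shuffled) as the factor. An NND
  exactly equal to the threshold counts as a failure (pinned). On a 2×2
  table this GLM equals the closed-form log odds ratio. When a cell is
  zero — exactly what a strong avoidance pattern produces in the observed
  condition — Wald inference from the GLM degenerates, so the
  Haldane–Anscombe 0.5-cell correction with the closed-form Wald test is
  used instead and flagged in the metadata; this is conservative.
  The pipeline compares against a single shuffled configuration by
  default (`shuffle_replicates: 1`); more replicates pool the shuffled
  NNDs for a tighter null.

## Synthetic colonies

The generator emulates what the analysis needs from real data: per-site
clustered, heterogeneous patterns of oriented body-ellipse polygons with
controllable abundance and a controllable hard-core (minimum edge-to-edge)
gap. Cluster parents are uniform in the window; animals are Gaussian
offspring of a random parent (a Thomas-like process); `cluster_sd = inf`
yields a uniform pattern. Bodies are 24-vertex ellipses — NND is
edge-to-edge, so only the convex footprint matters at the tested scales.
Placement is dart-throwing (sequential rejection) against the hard-core
constraint: simpler than an equilibrium Gibbs sampler, and the tests need
only the hard-core guarantee, not a specific process law.

The default grey-like (2.0 × 0.6 m body, 0.10 m gap, tighter clusters) and
harbour-like (1.5 × 0.5 m body, 0.40 m gap, looser clusters) profiles are
placeholders: plausible orders of magnitude, *not* measured seal biology.
They are configured once so that the constructed species contrast has a
known sign (grey-like denser, smaller NNDs). Every numeric claim in the
tests derives from this configured truth. What passing tests therefore
show: the pipeline recovers spacing contrasts and planted hard-core
avoidance from data with the assumed structure. What they do not show:
anything about real seals, tides, topography, or mother–pup pairing, none
of which the generator emulates.

## Numerical choices and problem sizes

- Overlap tolerance 1e-9 m²; congruence checks at 1e-9 relative; the
  kernel intensity is renormalised by window quadrature (200² midpoint
  grid) to integrate to n, skipped when σ is below twice the cell size
  (boundary leakage is then negligible and the quadrature could not
  resolve the kernels anyway).
- Bandwidth search floor 0.1 m — below annotation precision, nothing
  physical lives there.
- Degenerate inputs are errors, not silent fixes: single-animal sites have
  no NND; identical centre points have no bandwidth; fewer than 10 centres
  refuse cross-validation and ask for an explicit bandwidth.
- The test suite and the acceptance script run synthetic studies of 2×200
  grey-like + 5×120 harbour-like animals (and smaller), with 10–20 seed
  replicates for stochastic checks — sizes chosen to exercise every code
  path at comfortable interactive runtimes while keeping Monte-Carlo noise
  well inside the asserted tolerances.

## Known limitations

- No site-level random effects; sites are pooled within species.
- No edge correction in the density analysis.
- The shuffle null is a one-pass perturbation, not an equilibrium sampler
  of a point-process model; see the diffusivity note above.
- GeoJSON only; ESRI shapefiles must be converted upstream.
- No automated detection or image handling: the pipeline starts at
  polygons.
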