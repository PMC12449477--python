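# Methods

## The analysis model

`tmezone` analyses targeted-panel in situ transcriptomics of tumour tissue
as a geometry-first problem.  The primitive observation is a cell: a
centroid (x, y in µm, image convention with y downward), an area (µm²),
and a sparse vector of transcript counts over a fixed gene panel.  All
downstream statistics are built from three derived objects:

1. **Positivity calls.**  A cell is positive for a gene when its count is
   at least τ (default 2) and negative when the count is exactly 0.  The
   definition is deliberately asymmetric: a count of 1 under τ = 2 fails
   both the positive and the negative test and is excluded from both sets.
   This keeps both stated rules literal; the alternative (treating 1 as
   negative) would silently change every negative-marker conjunction.
   Cell types are assigned by an ordered first-match rule list; conflicts
   between rules are resolved by priority order, since no pathologist
   review is available to an automated pipeline.  Cross-group marker z
   scores use the population (not sample) standard deviation across the
   group means: with a handful of groups the z score is a descriptive
   rescaling for bubble charts, not an inferential statistic.

2. **Gene density.**  Counts per µm² of cell area; regions pool counts and
   areas before dividing, so a region's density is the density of its
   pooled tissue, not a mean of per-cell ratios.

3. **The signed distance field.**  Cells are pooled onto a regular grid
   (spacing s = 10 µm).  Grid cells satisfying the tumour marker rule
   (every positive marker's pooled count ≥ 1, negative marker = 0) form a
   raw mask; a 3×3 median filter followed by a 3×3 mean blur re-binarized
   at ≥ 0.5 (replication padding) removes speckle.  The grid-cell
   positivity threshold is 1, not the per-cell τ = 2, because grid cells
   pool several cells; the flag `min_count` exposes the choice.  The outer
   boundary of one 8-connected component is traced by Moore border
   following ("first" = earliest component in raster order, matching a
   border-following hierarchy; "largest" selects the maximal-area
   component and is origin-invariant — preferred when a tissue has several
   nests, since the first-contour rule discards all but one).  Distances
   are multi-source shortest paths over the full grid graph (8-neighbour;
   orthogonal edges weigh s, diagonal s·√2), computed with a single
   Dijkstra sweep from all contour cells; the sign is negative for
   mask-true cells off the contour.  Bands are half-open intervals of the
   signed distance, lower edge inclusive, so 20 µm falls in "mid"
   (peri < 20 ≤ mid < 70 ≤ distal < 120).  4-connectivity is available but
   makes the Euclidean edge weights trivial.

Band profiles (density per band) are clustered with UPGMC — centroid
linkage on Euclidean distances, where a merged cluster's centroid is the
unweighted mean of all member observations — and exported as Newick with
branch lengths equal to merge-height differences.

## Contrast statistics

Two-group contrasts use Welch's unequal-variance t with the
Welch–Satterthwaite degrees of freedom, two-sided (sidedness is a
convention choice; two-sided is the conservative default).  Multiplicity is
corrected with Benjamini–Hochberg step-up over exactly the genes tested in
one call — one contrast, one family; families are never pooled across
contrasts.  Effect size is classic Cohen's d with the pooled
Bessel-corrected SD, even though the test allows unequal variances: "d"
without qualification is the pooled form.  Degenerate genes are handled
explicitly rather than producing infinities: both groups constant and
equal → t = 0, p = 1, d = 0 (flag `zero_var_equal`); constant but unequal →
t, p, d undefined (flag `zero_var_unequal`) and excluded from the BH
family.  Hot/cold labels come from the basis-gene count rule (≥ 2 hot,
≤ 1 cold, default CD274); a boolean exclusion mask drops poorly segmented
cells before the contrast.

## Spot-level enrichment

After removing genes with < 10 total counts and cells with < 10 counts and
rescaling every cell to the *pre-filter* median cell total (the
normalization target is otherwise arbitrary; the pre-filter median keeps
the target independent of the filter thresholds), the field's bounding box
is tiled into k × k spots (default 125 × 125 = 15,625) and member-cell
expression summed per spot.  The top-5% DEG rule is read per gene across
spots: gene g is a DEG in the spots where its expression reaches its own
nearest-rank 95th percentile and is strictly positive.  This is the only
reading that yields spot-specific DEG sets; the per-spot-across-genes
alternative would give every spot the same size-5% set of its own loudest
genes.  Nearest-rank (ceiling) quantiles are used because they are
unambiguous on ties and reproducible across platforms.  A gene constant
and positive across all spots saturates the ≥-cutoff rule (DEG everywhere)
and is flagged, not suppressed.  Enrichment per spot and term is the
one-sided hypergeometric upper tail on the panel background, BH-adjusted
across terms within the spot (each spot's DEG set is one query); maps
carry −log10 of both the adjusted and raw p (floored at 1e-300), and map
versus expression-map agreement is plain Pearson correlation over spots.

## The synthetic-tissue generator

The generator emulates the statistical structure the analyses assume, and
emits the exact file bundle the readers consume plus a `truth.json`:

- **Geometry.**  Circular tumour nests (default: one nest, radius 250 µm,
  centred in a 1.2 × 1.2 mm field).  Tumour cells are uniform inside
  nests; all other types are complete spatial randomness over the field —
  the simplest null compatible with the band analyses.  Truth distances to
  the nest boundary are computed from the circle analytically, so the
  truth is independent of the grid pipeline under test.
- **Expression.**  Per-type Poisson rates; strong markers at 3–6 counts
  per cell (the scale where a count ≥ 2 call is reliable, and a realistic
  magnitude for strong targeted-panel markers), plus a uniform background
  rate of 0.01 per gene modelling ambient/off-target signal.  Cell areas
  are lognormal(ln 80 µm², σ = 0.4) clipped at 10 µm².
- **Chemokine gradient.**  Immune cells within d_peri = 20 µm of a nest
  boundary express the designated chemokines (CXCL9, CXCL13) at
  peri_fold = 3 times the baseline rate.  Real peritumoural chemokine
  gradients are only known qualitatively; f = 3 and d_peri = 20 µm are
  free parameters of the emulation, not estimates, and the recovery tests
  check the pipeline against the generator's own truth, not against any
  real tissue.
- **Hot/cold mosaic.**  The field is tiled with 100 µm patches, each hot
  with probability 0.5; tumour cells inherit the patch state.  Hot cells
  get CD274 λ = 3.0 (so a count ≥ 2 call is usually positive), cold cells
  λ = 0.1, with an opposing MKI67 shift (0.5 vs 2.5) emulating the
  proliferative cold phenotype.
- **Coupling.**  A designated gene pair can share a latent per-cell
  Poisson intensity: N ~ Poisson(λ/ρ) with both genes independent
  Binomial(N, ρ) thinnings.  The count correlation is then exactly ρ
  (Cov = ρ²·Var(N) = ρλ; Var = λ), so no numerical calibration is needed;
  the construction and ρ are recorded in the truth record.
  `coupled_spot_maps` applies the same construction directly at spot level
  for correlation-recovery checks.

What the generator does *not* emulate: optical noise, segmentation error,
transcript-level spot positions, irregular (non-circular) tumour
boundaries, cell-shape anisotropy, or realistic co-expression structure
beyond the designated coupled pair.  Tests passing on synthetic tissue
therefore demonstrate correctness of the computations under the stated
model, not robustness to real-tissue artefacts.

## Verification design and problem sizes

Every statistic has an independent oracle in the test suite: Welch t and
Cohen's d against direct formula evaluation, BH against step-up
enumeration, Pearson against the covariance definition, the hypergeometric
tail against an exact combinatorial sum, the distance field against a
networkx multi-source Dijkstra on an explicit edge list (100 random blob
masks up to 30×30), and UPGMC against a naive greedy centroid-merge trace.
The production paths use scipy/statsmodels; the oracles never do.

Calibration checks simulate 10,000 independent genes under the generator's
null (equal Poisson rate λ = 5, fresh lognormal areas per gene, 100 cells
per group) and require the Welch rejection rate at α = 0.05 to fall in the
95% binomial interval.  Independence per simulated gene matters: with one
shared area vector the per-gene tests are strongly dependent and the
binomial interval does not apply.  The hypergeometric calibration uses a
term of 51 genes and DEG draws of 40 on the 302-gene background: discrete
tests reject with probability equal to the largest attainable p below α,
which at these sizes is 0.049997 ≈ α (derived from the exact distribution;
at most other sizes the exact test is conservative by construction, which
is a property of discrete p-values, not a miscalibration).

Geometric recovery uses two instance classes.  The band-recovery check
runs the default ~20,000-cell tissue and requires the peri/distal
chemokine density ratio through the full grid→mask→contour→Dijkstra→band
chain to be within 15% of the generated fold of 3.  The circle-agreement
check compares grid distances with the analytic circle distance within
s·√2 on a compact instance (320 µm field, 100 µm nest, 2100 cells with a
densely sampled nest and sparse stroma), pooled over seeds 1–5: on an
ideal disk mask the agreement is 100% (max error ≈ 10 µm, from the octile
metric and discretization), so the instance is chosen dense enough that
mask sampling noise does not dominate; a sparse nest produces occasional
boundary dents whose distance shadows are sampling artefacts of the mask,
not errors of the distance computation.

## Known limitations

- The octile (8-neighbour) path metric overestimates Euclidean distance by
  up to 8.2% at angles near 22.5°; distances far from the surface carry
  that bias.  The bands of interest (≤ 150 µm) keep it below ~1.2 grid
  cells.
- The first-contour rule ties the analysis to one tumour component;
  multi-nest tissues should use the `largest` option or run per nest.
- Region-level hot/cold state is assigned by majority vote of member-cell
  labels; thin regions with mixed labels are sensitive to the 50% cut.
- `filter_and_normalize` runs in float32 (scanpy); totals match the target
  to ~1e-6 relative.
- The generator's mosaic patches are axis-aligned squares; spatial
  autocorrelation of hot/cold labels is therefore anisotropic at the patch
  scale.
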