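# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of the package, in the order the pipeline runs them.

## Synthetic study system

The generator produces data with exactly the statistical structure the
downstream analysis assumes, so every stage can be validated against known
truth.

* **Phylogeny** — pure-birth (Yule) tree. Starting from two lineages, with
  k lineages the next speciation waits Exp(k·λ) and a uniformly chosen
  lineage splits; a final waiting period is drawn at n lineages. The
  expected root-to-tip depth is therefore Σ_{k=2..n} 1/(kλ) (≈ 3.50 for
  n = 50, λ = 1), which the test suite checks by Monte Carlo.
* **Body size** — Brownian motion along the tree: independent Gaussian
  increments with variance σ²·(branch length). Defaults: root 76 mm,
  σ² = 8 mm² per unit length — a medium-sized lizard clade whose realized
  tip SVLs span roughly 60–90 mm at the default tree depth. Because SVL is
  a positive trait, the table validator rejects non-positive values; at the
  default root and rate the diffusion never approaches zero.
* **Ranges** — one circular range per species (radius 100 km by default),
  discretized as a 64-vertex polygon (area error < 0.5%). Placement uses a
  local equirectangular projection at the domain center; geodesy only
  matters downstream, where sympatry uses true great-circle distances.
  Ranges sit on a regular lattice with guaranteed clearance; species named
  in a co-occurrence pair are placed as a unit, with the second disc offset
  east by the separation whose circle–circle lens area equals the requested
  overlap fraction (inverted numerically with Brent's method). Packing that
  cannot satisfy the disjointness contract raises an explicit error rather
  than silently overlapping.
* **Co-occurrence designs** — `divergent` pairs the smallest third of
  species with the largest third; `assorted` pairs adjacent size ranks;
  `size_structured` overlays both patterns (half the large species overlap
  each other, the rest overlap small species), which is the configuration
  the signed divergence statistic is designed to detect: small species
  divergent, large species a mix of divergent and convergent.
* **Occurrences** — uniform rejection sampling inside each polygon
  (boundary-inclusive), a fixed count per species. No sampling bias,
  observation error, or duplicate records are emulated.
* **Rasters** — elevation is 1000 m plus a relief amplitude times a
  unit-variance smoothed Gaussian field (relief 0 gives a flat grid);
  biomes are quantile bands of an independent smooth field, so exactly
  `n_biomes` labels are present. Both are written in the ESRI ASCII grid
  dialect.
* **Reproducibility** — one root seed; every stage derives a child seed
  from the stage name by SHA-256, so stages are individually reproducible
  and all outputs are byte-identical across reruns.

What passing tests on this system do **not** show: robustness to spatial
sampling bias, coordinate error, range maps that disagree with occurrences,
non-circular ranges, or non-Brownian trait evolution. The generator is a
clean-room version of the analysis' assumptions, not of field data.

## Cleaning and summaries

Point-in-polygon is boundary-inclusive (`shapely.covers`): only points
clearly outside a species' range are removed. Records for species without a
polygon are reported as "unfilterable" and dropped from the retained table.
The operation is idempotent and conserves counts
(retained + removed + unfilterable = input, per species). Species centroids
are plain arithmetic means of longitude and latitude — correct for a
single-hemisphere study domain, wrong across the antimeridian, and
documented as such. Duplicate occurrence rows are retained by default.

## Bioregions

* **Adaptive grid** — 4° cells anchored at integer multiples of 4° from
  (−180°, −90°); a cell with more than 100 points splits into quadrants
  while its side exceeds 2°; after a split, any quadrant left as a leaf
  with fewer than 10 points pulls the whole parent back into a single leaf
  (so a split succeeds only when all four quadrants are adequately
  occupied). Empty cells are dropped. A re-merged leaf can legitimately
  hold more than 100 points.
* **Network** — weighted bipartite species×cell graph, edge weight = that
  species' occurrence count in the cell; total edge weight equals the
  number of retained occurrences by construction.
* **Clustering** — seeded asynchronous two-mode label propagation: cells
  start with unique labels, species unlabeled; each sweep updates species
  then cells to the weighted-majority neighbor label (ties broken by the
  lowest label) in an order shuffled by the seed, iterated to a fixed point
  (capped at 200 sweeps). The algorithm sits behind a single function so a
  map-equation optimizer can be substituted; what downstream stages need is
  only a partition of cells by shared species composition. Disconnected
  components can never merge, and planted two-block networks are recovered
  exactly in the test suite.
* **Summaries** — cell area is the spherical quadrilateral
  R²·Δλ·(sin φ₂ − sin φ₁) with R = 6371.0088 km; region centroid latitude
  is the area-weighted mean of cell-center latitudes and northing is that
  latitude times the great-circle degree length (111.195 km/deg); raster
  cells are attributed to regions by cell-center containment; elevation SD
  is the population SD of member raster values; biome count is the number
  of distinct labels. Missing rasters yield null fields, not zeros.
* **Correlates** — Spearman and Pearson correlations of richness against
  area, centroid northing, and elevation SD (both reported side by side),
  and an OLS of richness on biome count with F(1, n−2) and R². Zero-variance
  covariates are flagged undefined rather than scored.

## Sympatry

Distances are haversine on the mean-radius sphere (6371.0088 km); the
ellipsoidal error is far below the 5-km threshold granularity. The directed
rule calls *a* sympatric with *b* when at least `min_points` (default 10) of
*a*'s points lie within `threshold_km` (default 5, inclusive) of at least
one *b* point; each focal point counts at most once per partner species,
however many partner points are near. The default is directional, with an
optional logical-OR symmetrization. The production path proposes candidate
pairs with a 3-D k-d tree on unit-sphere coordinates using a slightly
inflated chord radius and then confirms every candidate with the same
haversine formula as the brute-force path, so indexed counts are exactly
equal to the O(n²) computation (verified over 100 random instances).

## Size classes and divergent sympatry

Three size classes come from Fisher–Jenks optimal 1-D classification — the
dynamic program minimizing total within-class sum of squared deviations
(O(k·n²); verified against exhaustive search) — replacing by-eye histogram
breaks with a deterministic optimum; explicit breaks can be supplied
instead. Boundary values go to the lower class.

For a focal species with n sympatric congeners, O is the vector of congener
counts per class and E = n × (genus-wide class proportions), with the genus
pool excluding the focal by default (a flag includes it). χ² sums over
classes with E > 0; the sign is −1 when the focal's own class is
over-represented among its congeners, +1 otherwise. Species with zero
sympatric congeners are flagged undefined and excluded from downstream
tests rather than scored 0.

The sign-category test partitions a class's species into
divergent / near-neutral / convergent by signed score against a neutral
band (default 0, which empties the middle category unless scores are
exactly zero; a positive band must be chosen explicitly and is echoed in
the report) and tests the counts against uniform expectation with the
standard Pearson statistic, df = 2. The per-bioregion composition test
compares a region's size-class counts to genus-wide frequencies with
df = (classes with E > 0) − 1; single-species regions are flagged untested.

## Comparative methods

All trait models are Gaussian GLS computations on the tree covariance C
(shared root-to-MRCA path lengths), with the root mean and σ² concentrated
out analytically:

* **BM** — exact closed form, no iteration. All-equal traits give σ̂² = 0
  and a degenerate (infinite-density) likelihood, flagged as such.
* **OU** — requires an ultrametric tree (checked, not silently accepted);
  V_ij = σ²/(2α)·e^{−2α(T−t_ij)}·(1 − e^{−2α t_ij}), computed with `expm1`
  so the α → 0 limit is numerically continuous; bounded 1-D search over α
  from five deterministic starts (L-BFGS-B), with the α = 0 boundary
  evaluated explicitly so OU can never report worse than BM.
* **EB** — rate decays as σ²·e^{rt}, giving C_ij → (e^{r t_ij} − 1)/r;
  same search strategy over r in ±10/T. Non-convergence is reported
  honestly via the `converged` flag.
* **Pagel's λ** — off-diagonal scaling of C, profiled over λ ∈ [0, 1] with
  both endpoints checked, so logL(λ̂) ≥ max(logL(0), logL(1)) − 1e−6.
* **Ancestral states** — conditional expectations (and variances) of
  internal nodes given tips under the fitted BM model; the root estimate
  equals the GLS root by construction.
* **PGLS** — intercept-only (there is no predictor: the residuals are
  phylogenetically detrended body sizes); the GLS mean equals the BM root,
  and C⁻¹-weighted residuals sum to zero.
* **MPD/SES** — mean pairwise patristic distance per assemblage; the null
  shuffles tip labels across the pool of species present in at least one
  assemblage (999 draws by default); SES = (obs − null mean)/null SD, with
  negative values indicating clustering; the p-quantile uses the
  (r+1)/(n+1) rank convention, avoiding 0/1 endpoints. An assemblage equal
  to the whole pool has zero null variance and is flagged degenerate, not
  scored 0.

## Pipeline and problem sizes

The pipeline runs load → bioregions → sympatry → size divergence →
comparative → dispersion from one strictly validated YAML config, writes
every table as CSV, and records a manifest with the config echo, per-stage
seeds, and SHA-256 digests of every output; identical configs reproduce
byte-identical files. Species-name mismatches among occurrences, tree, and
traits are reconciled up front; comparative and dispersion stages run on
the shared intersection with exclusions recorded in the manifest.

The shipped analysis and acceptance runs use a 40-species / 8,000-point
system, a 200-tip tree for estimator-recovery checks (200 trait replicates),
199-draw nulls inside the ~1,000-replicate calibration loops (the
calibration property does not depend on the null count; the pipeline default
stays 999), and 100 random instances for each oracle-equivalence check.
These sizes were chosen as the smallest at which the sampling intervals are
informative.

## Known limitations

* Label propagation is a deterministic, seeded stand-in for map-equation
  bioregionalization; region counts are not comparable across algorithms.
* The divergence statistic conditions on the realized sympatry matrix; no
  null-model randomization of the matrix itself is provided.
* The PGLS-residual vs divergence correlation is noisy at a few dozen
  defined species; its sign matches the planted structure only in
  expectation, and single-seed runs can fluctuate.
* Arithmetic-mean centroids and the directional sympatry rule behave as
  documented, not as geodetic or symmetrized alternatives; both are
  flag-selectable where a choice exists.
* On a lattice range layout without clade-structured geography, MPD SES
  hovers near zero — detecting clustering requires geographically
  structured clades, which the planted-clade tests construct explicitly.
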