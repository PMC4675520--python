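# Methods

This note documents the models and procedures `divscape` implements,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## Population-genetic statistics

Genotypes are codominant diploid SSR calls: an unordered pair of
positive integer allele labels per individual and locus, with 0,0
encoding a missing pair (a pair with exactly one missing allele is
treated as wholly missing on read, with a warning). Missing pairs are
excluded locus-wise from both numerator and denominator of every
statistic.

* **Allele frequencies** count allele copies over 2 × the scored
  individuals at a locus.
* **Expected heterozygosity** is plain Nei gene diversity,
  He = 1 − Σp²a, without the 2n/(2n−1) small-sample correction: all
  cell-level statistics are computed on fixed-size subsamples (3
  trees), where the correction is a constant factor absorbed by the
  subsequent min–max standardization.
* **Fis** = 1 − Ho/He; undefined (signalled) for monomorphic loci.
* **Mantel test**: Pearson correlation of the off-diagonal upper
  triangles, null built by jointly permuting rows and columns of one
  matrix; one-sided p = (1 + #{r⋆ ≥ r}) / (perms + 1). When n! does not
  exceed the requested permutation count the full permutation group is
  enumerated and the p-value is exact. Genetic distance between
  individuals is allele-sharing distance (1 − shared copies / 2,
  averaged over commonly scored loci) — parameter-free and standard for
  SSR data at the individual level; geographic distance is great-circle
  (haversine) in km, appropriate for samples spanning tens of degrees.

### Locally common alleles

An allele is *locally common* when its within-cell frequency exceeds
`lca_freq` (default 0.05) in at least one occupied cell but in fewer
than `lca_area` (default 0.25) of all occupied cells. The
"distribution area" denominator is the set of occupied cells of the
analysis grid — the only discretization of the range the pipeline owns
— and is recorded in the catalog for auditability. LCA richness of a
subsample is the mean, over loci, of the number of distinct catalogued
LCA alleles observed.

## Diversity mapping

The grid is geographic lon/lat, default 10 arc-minutes, row-major from
the north-west corner, values addressed at cell centers. Each tree is
replicated into every cell whose center lies within 1° (half of the 2°
neighborhood diameter) of the tree, measured in **flat degree space**:
the diameter is specified in degrees and the intended study regions
straddle the equator, where the distortion against great-circle
distance is small. Cell-center membership (rather than any polygon
overlap) is the simplest testable convention.

Replication leaves cells with unequal sample sizes, so each cell
statistic is the mean over `replicates` (default 1,000) bootstrap
subsamples of exactly `sample_size` (default 3) distinct trees; cells
below the minimum become nodata. A cell with exactly the minimum has
one possible subsample and is computed exactly. Per-cell RNG streams
are derived from (seed, row, column), so results are independent of
evaluation order and stable under parallel or partial evaluation.
Replicates on which a statistic fails are skipped; a cell with a
majority of failures becomes nodata.

Per-cell **allelic richness** is the mean number of distinct alleles
per scored locus in the subsample (not the total over loci): robust to
differing locus counts when merging datasets, and the scale choice is
absorbed by standardization anyway. Note that the mean-over-subsamples
richness is *not* monotone under adding individuals to a cell — an
added low-diversity tree (e.g. a homozygote for a common allele) lowers
the subsample mean — although richness of the full set is monotone;
tests assert the latter.

Trait diversity is the unweighted mean coefficient of variation
(sample sd / mean) over traits with at least two non-missing values;
zero-mean traits are excluded. Collections are compared with a
two-sided variance-ratio F test first (homoscedasticity gate) and a
pooled-variance t test second, mirroring the usual reporting order.

Rasters are standardized linearly to [0, 1]; a constant raster maps to
all zeros so a dataset with no spatial contrast cannot dominate the
subsequent cell-wise max-merge (both nodata → nodata; one valued → that
value; both → maximum).

## Niche analysis

PCA is fitted on the centered, unit-scaled environmental values at
*all* presence points (both varieties share one space); constant
variables and failed extractions are dropped. The wild niche is the
convex hull of the wild scores dilated outward — true polygon
offsetting with rounded joins, since "3% of the largest hull axis"
defines a distance, not a scaling — by `hull_buffer` × the maximum
pairwise vertex distance. Boundary points count as inside.

Occurrence densities are 2-D histograms on a fixed lattice
(`density_resolution` = 100 per axis) smoothed with a Gaussian kernel,
bandwidth by Silverman's rule per axis computed on the pooled points so
both densities share one kernel, then renormalized. Schoener's
D = 1 − ½Σ|z₁ − z₂| (equivalently 1 − total variation distance).

The **equivalency test** pools the two point sets and re-splits at the
original sizes; equivalency is rejected for *low* observed overlap, so
p = (1 + #{D⋆ ≤ D}) / (perms + 1). Identical point sets give D = 1 and
p = 1 (no null split can undercut complete overlap). The **similarity
test** relocates one set's point cloud to random centers drawn from its
environmental background, preserving its shape, and rejects for *high*
observed overlap.

## Suitability modelling

Component models implement one interface (a score in [0, 1] over
locations given an environment stack), making the ensemble machinery
model-agnostic; further members can be plugged in as callables.

* **Envelope** (BIOCLIM-style): per variable, 2·min(F(x), 1 − F(x))
  with F the mid-rank empirical CDF of presence values (1 at the
  median, 0 outside the presence range); overall score is the minimum
  over variables.
* **Logistic regression** on linear + quadratic terms of standardized
  variables, fitted by Newton/IRLS to gradient norm < 1e−8 within 100
  iterations; on separation or non-convergence an L2 (ridge 1e−4)
  penalized fit is substituted and logged.
* **Geographic null**: 1 / (1 + d), d the great-circle distance in km
  to the nearest training presence — the benchmark every environmental
  model must beat.

Background points are sampled uniformly without replacement from valid
grid cells, by default 10 × the presences, capped at 10,000 and at the
number of available cells.

**Evaluation.** Presences and background are partitioned into k = 5
folds, twice (identical partitions for every model). Each round fits on
4/5 and evaluates on the held-out fifth after **spatial sorting bias
removal**: each test presence (distance d_p to the nearest training
presence) is greedily matched, in increasing d_p order, to an unused
test absence with |d_a − d_p|/d_p ≤ 0.33 (the conventional pairwise
distance-sampling tolerance; configurable); unmatched presences are
dropped, and a warning marks rounds with < 20% matched. AUC on the
matched sets is the Mann–Whitney pair statistic (ties count ½). The ten
resulting cAUCs per model are compared with the null's by a one-sided
Mann–Whitney test; models with p < `alpha` (0.05) are retained. On
spatially unbiased data this protocol calibrates the null's mean cAUC
to ≈ 0.5 — the property the acceptance benchmark checks.

**Ensemble search** enumerates all 2^m − 1 subsets of retained models
(guarded at m ≤ 12); each subset predicts the weighted mean of member
scores with each member's *global* mean cAUC as its weight
(renormalized within the subset — weights are not re-estimated per
subset), and each subset is evaluated by the same cAUC protocol with
the same partitions. Ties prefer the smaller subset, then lexicographic
member order. The winning ensemble is thresholded at **maximum training
sensitivity + specificity** (candidates are midpoints between
consecutive sorted unique scores; a point is suitable when score ≥
threshold; ties take the lowest threshold), projected to alternative
climate stacks with below-threshold cells set to nodata, and scenario
maps are averaged cell-wise with nodata contributing 0 (a cell suitable
in only some scenarios is down-weighted); future-scenario summaries are
additionally restricted to means above the calibration threshold.

## Prioritization

Each input layer's cutoff is the 75th percentile (linear interpolation)
of its valid cell values — the empirical distribution, not a kernel
density of cell values, which would require an arbitrary bandwidth and
converges to the same quartile. Priority cells are strictly above the
cutoff in *every* layer. Genetic (allelic richness) and phenotypic
(trait CV) priority runs are separate analyses.

## The synthetic world

The generator produces the structure the analysis assumes, with
defaults matching the motivating study system: ~55 wild + ~166
cultivated presence points of which 55 wild + 80 cultivated are
genotyped, 9 SSR loci with 4–12 alleles each, 10–15 correlated fruit
traits, a 20°×20° equatorial region at 10′ with 4 bioclim-like layers,
3 circular refugia (radius 1.5°), and 2 alternative climate stacks.

* **Environment**: standardized low-frequency gradients (linear +
  low-order cosine terms) plus white noise; pairwise |r| < 0.95
  enforced by regeneration. Alternative climates add smooth
  linear-shift fields. Layers are built in degree space on the same
  grid the mapping uses, so no resampling/projection step exists.
* **Presences**: wild points ∝ sigmoid(w·z) × Gaussian refugium
  proximity; cultivated points use an optimum shifted by `niche_shift`
  standard deviations of the suitability index and a refugium pull
  relaxed by exponent 1/(1 + shift), so their niche broadens beyond the
  wild envelope; `niche_shift = 0` makes both draws identical.
* **Genotypes**: per locus, local allele frequencies are a softmax of
  per-allele Gaussian-process fields (squared-exponential, length scale
  `ibd_scale` = 5°), giving isolation by distance; a frequency floor
  keeps every allele drawable so observed per-locus counts stay in the
  requested range. Refugia carry *private* alleles (frequency 0.35
  inside, 0 outside; per-locus-per-refugium probability 0.6) and an
  evenness boost (local frequencies mixed halfway toward uniform) —
  the implanted high-diversity signal. Calls are local Hardy–Weinberg
  draws; 2% of pairs are masked missing. This is a spatially
  autocorrelated allele-frequency field, *not* a coalescent simulation:
  it has no genealogy, no linkage, and no drift dynamics, so passing
  tests demonstrate that the mapping statistics recover implanted
  spatial structure, not that they would behave identically on data
  with realistic coalescent variance.
* **Traits**: value = mean × (1 + cv_region × z) with z sharing one
  latent factor across traits (loading 0.5), so realized per-region CVs
  match the request and traits are positively correlated.

Hotspot-recovery tests operationalize "hotspots at refugium locations"
as enrichment: the fraction of top-decile cells within a capture zone
(refugium radius + neighborhood radius + one cell) must exceed the base
rate of valid cells there, with the additional requirement for the LCA
statistic — whose signal exists only where private alleles do — that
the peak cell itself lies in the capture zone. Full containment of the
top decile is geometrically unattainable because 2° neighborhoods smear
every statistic about 1° beyond the implanted regions.

## Problem sizes and determinism

Unit and end-to-end tests run on reduced sizes chosen to keep the suite
fast while preserving every code path: a 10°×10° world at 30′, 120
presence points, 60 bootstrap replicates, 29–49 permutations. The
calibration benchmark (null-model cAUC) uses the full 200 presences /
2,000 background protocol over 10 seeds. All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`; two
pipeline runs with one seed produce byte-identical artifacts (the run
log is timestamp-free for this reason).

## Known limitations

* Neighborhood membership uses cell centers in flat degree space; at
  high latitudes the 2° circle distorts (a config switch would be the
  extension point).
* The ensemble ships with two environmental component models; tree
  ensembles, GAMs, or maximum-entropy models can be plugged in through
  the model interface but are not bundled.
* The similarity test's background shift relocates the whole point
  cloud rigidly; availability-weighted density correction beyond this
  is not implemented.
* Scenario averaging treats below-threshold cells as zero
  contribution; the alternative (averaging over suitable scenarios
  only) is a documented config choice, not the default.
* GeoTIFF is not emitted; rasters are ESRI ASCII grids (readable by
  GDAL/QGIS and by `divscape.raster.read_ascii_grid`).
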