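# divscape

Spatial analysis of crop genetic resources: where is a species' genetic
and phenotypic diversity concentrated, where was — and will be — its
habitat suitable, and where do the two overlap enough to prioritize
on-farm conservation?

`divscape` implements, as one reusable pipeline, the analysis chain
used in studies of crop domestication geography (the motivating system
is a Neotropical palm with wild and cultivated varieties, genotyped at
a handful of SSR loci and scored for fruit traits):

1. **Population genetics** (`divscape.popgen`) — per-locus allele
   frequencies, expected/observed heterozygosity (He = 1 − Σp²a, Ho),
   the fixation index Fis = 1 − Ho/He, a permutation Mantel test for
   isolation by distance, and a **locally common allele (LCA)**
   classifier: an allele is locally common when its frequency exceeds
   5% in at least one occupied grid cell but in fewer than 25% of all
   occupied cells — a fingerprint of historically isolated populations
   (glacial refugia).
2. **Diversity mapping** (`divscape.divmap`) — every tree is replicated
   into all 10′ grid cells whose centers fall inside a 2°-diameter
   circle around it; cell statistics (allelic richness, Ho, LCA
   richness, trait coefficient of variation) are rarefied by averaging
   over 1,000 bootstrap subsamples of exactly 3 trees, cells with fewer
   trees are discarded; rasters are min–max standardized to [0, 1] and
   datasets merged cell-wise by maximum.
3. **Niche analysis** (`divscape.niche`) — presences are projected onto
   the first two PCs of the environmental predictors; the wild niche is
   the convex hull of wild points dilated by 3% of its largest axis;
   cultivated points are partitioned against that hull; overlap between
   two occurrence densities on a smoothed 100×100 PC-space lattice is
   Schoener's **D** = 1 − ½Σ|z₁ − z₂| ∈ [0, 1], with permutation
   equivalency and similarity tests.
4. **Suitability modelling** (`divscape.sdm`) — component models
   (BIOCLIM-style percentile envelope, quadratic logistic regression)
   are evaluated against an inverse-distance **geographic null model**
   by 5-fold × 2-repeat cross-validation in which spatial sorting bias
   is removed from each test partition by pairwise distance matching;
   the resulting **calibrated AUC (cAUC)** of the null is ≈ 0.5 by
   construction. Models that beat the null (one-sided Mann–Whitney,
   p < 0.05) enter an exhaustive ensemble search (cAUC-weighted model
   averaging); the winner is thresholded at maximum training
   sensitivity + specificity and projected to alternative climates,
   whose threshold-limited maps are averaged.
5. **Prioritization** (`divscape.prioritize`) — priority cells are the
   intersection of the top quartiles of current suitability, future
   suitability, and a diversity layer.

A first-class synthetic-data generator (`divscape.synth`) produces
landscapes, presence points, SSR genotypes (with isolation by distance
and refugium-private alleles) and correlated fruit traits with the
statistical structure the pipeline assumes, so everything is testable
end to end without external data. Rasters travel as ESRI ASCII grids,
tables as CSV.

## Worked example

Run the whole pipeline on a compact synthetic world (10°×10° at 30′,
120 presence points, 90 genotyped trees):

```bash
cat > config.toml <<'TOML'
seed = 3
resolution_arcmin = 30.0
replicates = 60
extent = [-75.0, -65.0, -5.0, 5.0]
n_wild = 40
n_cult = 80
n_cult_genotyped = 50
n_traits = 8
niche_permutations = 29
TOML
divscape all --config config.toml --out run
cat run/run.log
```

which prints (abridged):

```
simulate: 120 presence points (40 wild, 80 cultivated)
simulate: genotyped 90 individuals at 9 loci; traits for 50 cultivated individuals
popgen: 9 loci summarized; Mantel r=0.198 p=0.0010
divmap: 230 occupied cells
divmap: CV collections F=0.826 (p=0.521), t=-0.582 (p=0.562)
niche: PCA explains 81.6%; 72/80 cultivated points inside the wild niche hull
niche: Schoener's D=0.717, p_equivalency=0.067, p_similarity=0.033
sdm:
model                    mean cAUC
envelope                     0.628 (retained)
null                         0.511 (benchmark)
regression                   0.654 (retained)
best ensemble: regression
max sens+spec threshold: 0.2821
prioritize: 1 genetic-priority cells
```

Reading the numbers: the Mantel test (r = 0.198, p = 0.001) confirms the
isolation by distance the generator implanted; the two trait collections
are homoscedastic (F ≈ 0.83), so their CV rasters may be standardized and
max-merged; Schoener's D of 0.72 says the cultivated niche still largely
overlaps the wild one; the geographic null's mean cAUC of 0.51 shows the
spatial-sorting-bias correction is doing its job, and both environmental
models beat it; the priority mask is the (small) region jointly in the
top quartile of present suitability, future suitability and allelic
richness. Artifacts land in `run/` (`*.asc` rasters, `locus_summaries.csv`,
`evaluation.csv`, `priority_*.asc`, …).

The same analysis is available programmatically; the suitability stage
follows the model/results idiom:

```python
from divscape.sdm import EnsembleSDM
results = EnsembleSDM(presences, background, env).fit(seed=3)
print(results.summary())
current_map = results.project()                 # threshold-limited raster
future_map = results.project(alt_climate)      # alternative climate stack
```

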