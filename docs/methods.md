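# Methods

This note documents the models, the numerical choices and the design
decisions behind `sedna`, and what the synthetic-data tests do and do not
demonstrate about real surveys.

## Filtering cascade

Six steps run in a fixed order on each marker's ASV-by-sample count table;
each logs removed ASVs, removed reads, thresholds and the reads-per-sample
summary (mean ± SE over true samples) into the audit.

1. **Single-sample ASVs.** An ASV with nonzero counts in fewer than two
   columns is removed. Blank columns count toward the occurrence tally by
   default (`include_blanks=True`): a read in a blank is still evidence the
   sequence exists. The switch is exposed because the opposite reading is
   defensible.
2. **Blank-sum contamination filter.** For each ASV take its maximum count
   over extraction and PCR blanks; the sum of these maxima is the *blank
   sum*. An ASV is removed from all samples when its blank maximum is
   **strictly greater** than `blank_fraction` (default 0.001) of the blank
   sum. Positive controls are never treated as blanks — they contain real
   target DNA. A zero blank sum makes the step a logged no-op; a table with
   no blank columns is an error rather than a silent skip.
3. **Global low-abundance filter.** An ASV is removed when its total reads
   over true samples are **strictly less** than `global_fraction` of the
   true-sample grand total. The default is 1e-5 (0.001%), i.e. a 100-read
   cutoff in a 10-million-read library. Blanks are excluded from both the
   numerator and the denominator: negative controls are not samples.
4. **Taxonomy completeness.** Keep an ASV only if at least one of
   family/genus/species *and* at least one of phylum/class/order is
   assigned. Missing ranks are explicit empty strings.
5. **Clustering and merging.** Greedy centroid clustering in decreasing
   total-abundance order (ties by ASV id): each ASV joins the first
   centroid it matches at ≥ `cluster_identity` (default 0.97), else founds
   a cluster. Identity is matches / alignment length under a global
   alignment (match +1, mismatch −1, gap open −2, extend −0.5). Reads are
   summed only for ASVs sharing both the cluster and an identical
   seven-rank taxonomy tuple (unassigned ranks compare as equal empty
   strings); the OTU id is the centroid's id for the centroid's taxonomy
   group and the most abundant member's id otherwise. Total reads are
   conserved exactly.
6. **Low-read samples.** True samples whose total is strictly below
   `sample_read_floor_fraction` (default 0.5) of the lower quartile of
   per-sample totals are dropped. The lower quartile uses linear
   interpolation between order statistics (numpy's default), the common
   convention of R's `quantile` type 7; the choice is fixed and documented
   because reasonable alternatives move the cutoff.

After the cascade the blank columns are retired (they exist to inform step
2). The cascade is **not idempotent in general**: residual blank leakage
shrinks the blank sum on a second pass and can trigger further removals;
with clean blanks a second pass removes nothing, and the test suite checks
exactly that property.

## Rarefaction and marker fusion

Each marker's OTU table is rarefied to a common depth — by default the
lower quartile of its per-sample totals — by a multivariate hypergeometric
draw (subsampling without replacement). Each sample gets an independent
RNG stream derived from the master seed and a hash of the sample id, so
results do not depend on column order. Because the lower-quartile depth
exceeds roughly a quarter of the sample totals by construction, samples
below the depth keep all their reads (`shallow="keep"`, the behaviour of
vegan's `rrarefy`); the strict mode that rejects them is the default for
direct library use.

Counts become percents per sample, and the two markers are fused by
averaging percents over the intersection of samples that survived both
markers' filters. OTUs are aligned across markers by the full taxonomy
tuple — the only key the markers share; within-marker collisions (same
taxonomy, different centroid) are summed first. An OTU undetected by one
marker contributes 0 to the mean (default `mean_with_zero`: the markers
are treated as replicate observations of the community, so 10% in one
marker and absence in the other fuses to 5%); `mean_detected` averages
over detecting markers only. Both modes are exposed because either reading
of "mean per cent" is defensible; the default keeps per-sample fused
percents summing to 100. OTUs flagged neither marine nor estuarine are
then removed; OTUs without a flag are retained with a warning, mirroring a
habitat lookup that only removes positively categorised species.

## Environmental design

- **Decadal SST trend**: OLS slope of annual mean SST on year × 10, for
  series like 1980–2016. The contract is annual means in, °C/decade out.
- **Grid extraction**: a minimal ESRI-style ASCII grid (header + matrix,
  row 0 north); the containing cell's value, else the nearest non-missing
  cell by haversine distance (mean Earth radius 6371 km), ties to the
  smallest (row, col).
- **VIF pruning**: iteratively compute VIF_k = 1/(1 − R²_k) by regressing
  each covariate on the rest; while any exceeds the threshold (default 4),
  remove the least-preferred offender, one per round. The default
  preference order keeps bottom temperature over ice cover, primary
  productivity over nitrate, and SST change over distance to land —
  covariates previously related to Arctic marine fauna.
- **Centring/scaling**: mean 0, sample SD 1 (n − 1 denominator; the
  convention is stated because it changes nothing downstream but must be
  fixed for reproducibility). The stored scaling is invertible.

## Community inference

Per-taxon fits use a vectorised Fisher-scoring (IRLS) engine for the
binomial/cloglog GLM: all taxa share the design, so one loop updates an
(n × m) block with per-taxon step-halving. Convergence is max |score| <
1e-8 or 200 iterations; η is clipped to [−30, 3.5] and quasi-separated
fits (|β| > 15) are flagged and excluded from per-taxon inference. The
engine agrees with statsmodels' GLM and with direct BFGS likelihood
maximisation to < 1e-6 (tested), but is ~100× faster across taxa, which
the resampling needs.

Terms are tested sequentially: the null for term k contains terms 1..k−1,
so the ANOVA table's residual df decrement by one per row. The community
statistic is `sqrt(z' R(λ)⁻¹ z)` with `z` the per-taxon signed Wald (or
score) statistics and `R(λ)` the shrunk among-taxon correlation of
null-model Pearson residuals (Pearson, not randomised-quantile, so the
observed statistic is deterministic and invariant to row order). λ is the
analytic Schäfer–Strimmer intensity, clipped to [0, 1]; at λ = 1 the
squared statistic is the plain sum of per-taxon statistics. Taxa with
prevalence 0 or 1 are excluded up front with a logged count.

The null distribution uses PIT residual resampling: randomized
probability-integral residuals `u ~ U(F(y−), F(y))` under the null fit are
uniform marginally; rows of the uniform matrix are permuted jointly across
taxa (preserving among-taxon dependence) and pseudo-responses are
reconstructed through the null fitted probabilities at the receiving rows
(Freedman–Lane in spirit). Each resample refits null and full models and
recomputes its own shrunk correlation. P-values are add-one, so they live
in [1/(B+1), 1]. Per-taxon multiplicity uses Westfall–Young step-down
maxT on the same resamples, with monotonicity enforced by a running
maximum. The Wald statistic is the default and the score statistic a flag,
because the two families answer the same question and the source workflows
in this area use both interchangeably.

Calibration, measured by the test suite at 70 samples × 40 taxa with
B = 199 over 200 null datasets: community type-I error ≈ 0.035 at nominal
0.05 (inside [0.02, 0.09]) with uniform null p-values, and step-down
familywise error ≈ 0.055, inside two binomial SE of 0.05. These problem
sizes were chosen to match the scale of a single-cruise sediment survey
while keeping the suite runnable on a laptop.

Coefficient-based taxon clusters use average-linkage hierarchical
clustering on Euclidean distances between full-model coefficient vectors;
the indicator report lists taxa with step-down adjusted p below 0.10 for
at least one term, with coefficient signs, significance flags at 0.05 and
taxonomy truncated to genus.

## Ordination and surfaces

Bray–Curtis dissimilarities on presence/absence (the default; identical
to Sørensen) or on log-transformed percents. The log transform is
`log10(1 + x/c)` with c = half the smallest nonzero percent: equivalent to
`log10(x + c)` up to an additive constant per matrix, but non-negative
with zeros mapping to zero, which Bray–Curtis requires.

NMDS minimises Kruskal stress-1 via SMACOF (nonmetric, isotonic
disparities) with a classical-scaling warm start plus 20 random restarts
by default; the best configuration by stress-1 is centred, rotated to
principal axes and sign-fixed for determinism. Convergence is a relative
stress change below 1e-6 or 500 iterations.

Environmental surfaces are a penalised thin-plate-style smooth: radial
basis φ(r) = r² log r at min(n−1, 10) deterministic farthest-point knots
plus an unpenalised linear part, ridge penalty on the bending-energy norm
of the radial coefficients, and the penalty weight chosen by GCV over a
40-point log-spaced grid (1e-8..1e4 on standardised coordinates). Reported
are effective df (trace of the hat matrix), an approximate F and deviance
explained = 1 − RSS/TSS. This is a deliberately transparent analogue of
cross-validatory thin-plate GAM smoothing: on an exactly linear response
it explains ≥ 99.9% of deviance, on pure noise at n = 100 the GCV guard
keeps deviance explained below 0.15, and on planted curved surfaces it
agrees with an independent CV-tuned kernel-ridge smoother within 0.1
(all tested).

The distance-decay diagnostic correlates pairwise community similarity
(1 − Bray–Curtis) with haversine distance and assesses it by a seeded
Mantel-type permutation (two-sided, add-one). It is implemented in-package
for byte-reproducibility; scikit-bio's `mantel` serves as the independent
cross-check in the tests.

## Synthetic data generator

The generator emulates the post-denoising artefacts of a two-marker
sediment survey, with one seeded RNG stream (bit-identical output per
config): correlated environmental covariates (multivariate normal;
default five covariates at pairwise r = 0.3); taxon presence from the
cloglog model with per-taxon intercepts drawn from a base-prevalence range
(0.15–0.6) and a planted effect matrix (default: ~20% of taxa respond to
bottom temperature at |β| = 1.3, a handful to SST change and primary
productivity); counts given presence negative-binomial (dispersion 5)
around a lognormal per-taxon abundance profile normalised so expected
per-sample totals equal `reads_mean` (default 30,000); per-taxon marker
detectability (p = 0.85 per marker, at least one marker forced) to give
the fusion step single-marker OTUs; contaminants with Poisson blank
counts (mean 5,000) scattered lightly through true samples; true-taxon
leakage into blanks at `blank_leak_rate` (default 5e-4) to exercise the
blank-filter boundary; singleton ASVs; ASVs failing the taxonomy rule both
ways; and near-identical ASV pairs (2% substitutions, no indels) that must
co-cluster at 97%. Sequences are random DNA of marker-appropriate length
(~115 and ~140 nt). `n_cluster_pairs` and `n_nonmarine` extend the
config so the clustering and habitat-flag stages have planted structure.

What the generator does *not* emulate — PCR chemistry, chimeras, tag-jump
mechanisms, sequencing error profiles, spatially autocorrelated
communities, phylogenetic signal in taxonomy — bounds what green tests
mean: they demonstrate the algorithms implement their definitions and are
calibrated under the stated model, not that the model captures every
failure mode of real libraries.

## Degenerate inputs and tie-breaks

Empty tables, missing taxonomy entries, empty sequences, all-zero sample
columns, zero-variance covariates, single-class responses and asymmetric
dissimilarity matrices are rejected with named errors. Ties: clustering
order by (−abundance, id); OTU group ids by (−abundance, id); nearest-cell
by (distance rounded to 1e-9 km, row, col); VIF removal by preference
rank then later column. NMDS axis signs are fixed by the largest-|loading|
coordinate.

## Known limitations

- The blank-sum filter assumes blanks share the library's contamination
  profile; it cannot see contaminants absent from blanks.
- The sequential (type-I) ANOVA makes term order matter; the pipeline
  reports the order it was given and does not reorder.
- The surface smoother is a fixed-knot ridge analogue of thin-plate GAMs,
  not a full REML/GCV spline: effective df is comparable but not
  identical to mgcv's.
- Percent fusion assumes the two markers survey the same community with
  independent biases; a taxon invisible to one marker is diluted 2× under
  the default fusion mode.
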