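# Methods

This note documents the models, estimators and numerical conventions
implemented in `gcniche`, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Synthetic germinal centers

**Geometry.** The GC is a disc of radius `gc_radius` (default 250 μm, a
~500 μm follicle). The dark zone is the half-plane `x < x_cut`, with
`x_cut` solved from the circular-segment area equation so the DZ covers
`dz_fraction` (default 0.5) of the disc. Richer geometries are not
modeled; the half-plane cut matches the two-compartment appearance of GC
sections and makes the true interface (a chord) available as a geometric
oracle.

**Point patterns.** B cells are uniform over the disc (default 1500,
≈0.008 cells/μm²). T cells are a homogeneous Poisson process of intensity
`t_intensity` (default 0.002/μm², a few hundred cells per GC) thinned
independently inside the DZ with retention probability `dz_t_retention`
(default 0.2). Independent thinning was chosen over pairwise-interaction
(Gibbs) processes because its expectations are analytic — the expected DZ
T-cell count is `retention·λ·A_DZ`, which the tests verify by Monte
Carlo — while still producing the repulsion phenotype. γδT-like cells use
a DZ intensity multiplier (default 3, DZ-enriched) simulated by thinning
from the dominating intensity. `with_aid_labels()` relabels DZ B cells as
`AID`, the marker phenotype that imaging maps actually observe; T-cell
exclusion analyses compare T against AID, not against all B cells (T cells
sit next to LZ B cells regardless of exclusion, so the all-B contrast
carries almost no signal).

**Nuclei.** Each nucleus is a disc (radius 3.5 μm at 0.15 μm/px ⇒ 23 px)
of euchromatin carrying non-overlapping heterochromatin foci placed by
dart-throwing (focus radius defaults to nucleus_radius/6; the thrower
shrinks the focus radius when packing jams and sizes the last focus to the
remaining area, so the realized HC fraction tracks the request within
rasterization error, |Δ| ≤ 0.02 at this radius). Foci are
`hc_intensity_ratio` (default 3) times brighter than euchromatin, and the
**integrated intensity per nucleus is conserved**: the euchromatin level is
`base_mean / (1 + f·(ratio−1))`. This conservation is the mechanism that
links compaction to the observable features — more heterochromatin dims
the euchromatin floor (lower minimum intensity) and widens the intensity
spread (higher p80/p20 and HC/EC ratios). Per-nucleus heterochromatin
fractions are jittered (`f_hc_sd`, default 0.05) and brightness gets
lognormal jitter (`brightness_sd`, default 0.05) so features are noisy
proxies rather than deterministic class labels; additive Gaussian noise
(`noise_sd`, default 0.01 on the [0,1] intensity scale) stands in for
detector noise. Defaults `f_hc` 0.35 (DZ) vs 0.15 (LZ) give a clearly
separable classification problem (CV accuracy ≈ 0.97); the generator makes
no attempt to match any particular reported accuracy, only the direction
and testability of the effect. Not modeled: optical point-spread
functions, 3-D tissue, nucleus shape variation beyond the disc, graded
chromatin density.

**Expression.** Paired-ROI values are
`x = μ_g + b_i ± logfc/2·[g planted] + ε`, with the pair offset `b_i`
shared by both members (so within-pair differences have variance
`2·gene_sd²` regardless of `pair_effect_sd`). Defaults mirror a matched
design of 10 DZ/LZ pairs over ~1800 genes with 150 planted effects of
|log2FC| = 1, half up, half down. Cohorts draw a latent per-sample DZ
activity `a ~ N(0,1)` loading on the signature genes, and a latent T-cell
fraction `logistic(cohort_beta·a + η)` (default β = −2, η sd 0.5) loading
on a dedicated 30-gene T-cell block — so the DZ-score/T-fraction
anti-correlation is planted with a recorded truth. Sequencing-level
artifacts (counts, library size, dropout, batch) are not simulated; all
values are already on a log2-like scale. Passing tests therefore
demonstrate estimator correctness and calibration under the assumed model,
not robustness to the technical noise of real assays.

**Randomness.** Every generator draws from a named sub-stream derived from
its config seed (`SeedSequence([seed, crc32(name)])`), so stages can be
re-run independently and all outputs are bit-identical under a fixed seed.

## Chrometric features

A fixed 14-feature inventory (the registry order of `FEATURE_NAMES`):
min/max/mean/sd of intensity, histogram entropy (32 bins), p20/p50/p80,
p80/p20 ratio, HC/EC ratio, area, perimeter, eccentricity, solidity.
Conventions: percentiles are linear interpolation on sorted pixel values
(used identically in features, tests and oracles); the HC/EC ratio
thresholds each nucleus at its own `mean + k_sd·sd` (population sd,
default k = 1), returning 0 when nothing exceeds threshold — a per-nucleus
adaptive rule that is invariant to inter-image illumination scaling;
images may be min–max normalized per image before extraction (the pipeline
default; ratio features are unaffected). Labels under 10 pixels are
flagged and left unmeasured. Pixel coordinates are 0-based, x right /
y down; physical units enter only through `pixel_size`. Segmentation is
threshold (Otsu/mean/fixed) + small-object removal, with an optional
distance-transform watershed for touching nuclei; no learned segmentation.

## DZ/LZ classifier

Random forest, 500 trees, unlimited depth, √p features per split, fixed
seed (hyperparameters exposed in `ModelConfig`; features are z-scored for
importance comparability although forests do not need it). Evaluation:
balanced subsample (equal class counts, without replacement), 10-fold
stratified CV, per-fold row-normalized confusion matrices averaged after
normalization (each row of the average sums to 1), NIR = max class prior.
The signed-rank test of fold accuracies against the NIR drops zero
differences, uses midranks for ties, and computes the exact sign-flip null
by dynamic programming for up to 25 folds (all 10 folds above the NIR
gives exactly p = 1/1024); beyond that a tie-corrected normal
approximation is used.

A calibration caveat measured on the synthetic fixtures: a single 10-fold
CV on label-null data has an irreducible spread of about ±0.025 around 0.5
that does not shrink with the number of nuclei (fold estimates share
training data and are positively correlated). Null-calibration statements
therefore average the CV accuracy over several independently generated
datasets (six in the test suite) rather than reading a single run.

A related instability worth knowing: with this feature table, impurity
importances split the compaction signal among several strongly correlated
readouts (min_intensity, p20, p50, p80/p20 ratio, HC/EC ratio). The HC/EC
ratio — in these synthetic nuclei almost a direct readout of the planted
fraction — reliably ranks first, and whether `min_intensity` or its
smoother cousin `p20` takes a top-3 slot varies with the seed. Conclusions
of the form "compaction features dominate morphology/texture" are robust;
conclusions about the exact rank of one compaction feature among its
near-duplicates are not.

## Spatial statistics

**Segregation/aggregation test.** Null: phenotype labels permuted over the
union of fixed positions — this preserves the tissue's density profile,
unlike resampling positions under CSR, and matches how randomized maps are
usually displayed. Statistic: the A→B nearest-neighbor distance set.
Primary p-value: each labeling (observed and each of the `n_perm`
permutations) is summarized by the mean rank of its distances within the
pooled set (midranks for ties), and the observed summary is ranked among
the permuted ones — two-sided via `2·min(lower, upper)` with the add-one
estimator. This is exactly calibrated under label exchangeability (type-I
error ≈ α, verified over 500 CSR maps). The asymptotic Mann–Whitney p of
observed vs pooled-null distances is also reported
(`p_pooled_ranksum`) because that is the form such comparisons are
conventionally reported in, but it treats autocorrelated distances as iid
and should not be used for calibration. Direction is read from the
observed vs pooled-null medians at the primary p. With 200 permutations
the smallest attainable two-sided p is 2/201 ≈ 0.00995.

**Interface.** The DZ region is the alpha-shape of the DZ (AID+) point
cloud: Delaunay triangles with circumradius ≤ α, α defaulting to 4× the
median DZ nearest-neighbor spacing. The raw shape is repaired before use —
largest component, holes filled, morphological closing of radius 3α —
because at realistic densities sampling dents and fragmentation otherwise
masquerade as interface structure (with the 2× spacing α that seemed
natural a priori, the hull fragments into many components and its edge
dents by several tens of μm; the repaired 4× version stays within ~15 μm
of the true chord on the half-plane fixture). The interface polyline is
the region boundary minus segments within 2α of the GC boundary (the
outward-facing edge); the band is |signed distance| ≤ band_width/2 with
the default 100 μm total width, i.e. 50 μm layers on each side. Signed
distance is negative inside the DZ region; distances are Euclidean μm.

**Profiles and distances.** Density bins are half-open [lo, hi) on signed
distance; bin areas come from buffering the boundary polyline and clipping
to the GC polygon and the DZ/LZ side (`area_method = "buffer_clip"`), so
densities are exact up to polygon resolution. Range-normalized distance
divides |signed distance| by the compartment's maximum (per-compartment,
matching the separate DZ and LZ regressions it feeds); cells below 0.4 are
"close" to the interface (threshold configurable). Single-cell
compartments have an undefined normalization and are flagged.

**Correlation.** Pearson or Kendall, permutation p from shuffling y
(two-sided on |r|, add-one estimator), switching to exhaustive enumeration
when n! ≤ n_perm (then the p is the exact fraction). CI: percentile
bootstrap over paired resamples (default b = 1000, level 0.95; degenerate
resamples skipped; the interval is widened to contain the point estimate
if a pathological bootstrap distribution would exclude it). In the
gradient-recovery checks the planted correlation is set exactly per
replicate by scaling the noise sd to the realized spread of the design
variable; coverage measured this way is ≈ 0.92 at n = 200.

## Expression analyses

**Paired moderated t.** One-sample empirical-Bayes t on within-pair DZ−LZ
differences: gene variance `s_g²` with `d_g = n_pairs − 1` df; prior
`(d0, s0²)` by method-of-moments on `log s_g²` (digamma/trigamma moment
equations, Newton inversion of the trigamma; a trimmed variant is exposed
for heavy-tailed variance mixtures); posterior variance
`(d0·s0² + d_g·s_g²)/(d0 + d_g)`; total df capped at the pooled residual
df `G·d_g`, matching the convention of the standard eBayes implementation
— the test suite cross-checks t, p, d0 and s0² against limma via Rscript
on a shared fixture and they agree to numerical precision. `d0 = 0`
recovers the ordinary paired t; an infinite `d0` (no excess dispersion of
the log variances — the usual outcome when all genes share one true
variance) orders genes exactly by |logFC|. BH adjustment within the
contrast; significance at adjusted p < α with an optional |logFC| cutoff.
The unpaired rank-sum variant (per-gene two-sided Mann–Whitney, BH,
|logFC| > 0.25 by convention) serves single-cell style contrasts.

**Scoring and stratification.** `mean_z` averages per-gene z-scores
(invariant to gene-wise affine rescaling; errors on zero-variance genes);
`total` sums log2 values. Tertiles cut at the empirical 1/3 and 2/3
quantiles with boundary ties assigned to the lower stratum. The
DZ-like/LZ-like/Intermediate assignment takes tertiles of
Δ = z(DZ score) − z(LZ score) — a declared, reproducible substitute for an
unstated clustering rule.

**Enrichment.** Weighted Kolmogorov–Smirnov running sum (hits weighted by
|stat|^weight, default 1; misses decrement uniformly), ES the signed
extremum, leading edge the hits up to it. The null permutes hit positions
over the ranked genes. The p is two-sided on |ES| with the add-one
estimator — a deliberate departure from the sign-conditional GSEA
convention, which roughly halves the p and would fail a uniformity check;
the two-sided form is exactly calibrated under the permutation null
(verified over 400 random signatures).

**Cross-cohort selection.** Per cohort: each DZ-signature gene correlated
(Pearson) with the cohort's mean-z T-cell score; BH within the cohort;
flagged when adjusted p < α with r < 0. Genes flagged in ≥ `min_datasets`
cohorts (default 3) are selected; selection is monotone in the threshold.
Cohorts under 10 samples are excluded with a warning.

## Pipeline

The YAML config is schema-validated (unknown keys rejected) and hashed;
every run writes a manifest with the config hash, seed, package version
and SHA-256 checksums of all result tables. All tables are byte-identical
across reruns of the same config (cell coordinates are written at %.17g
and read with round-trip float parsing so a cached table reproduces
downstream statistics bit for bit). Stage subsets re-use cached upstream
outputs when the config hash matches. Logging goes to stderr with
per-stage timing; exit codes are 0 (success), 2 (validation), 1 (runtime).

## Problem sizes

The bundled demo config and the test suite run everything at desk scale —
one simulated GC (~1600 cells), 300–400 rendered nuclei, 10 expression
pairs over 400–1800 genes, 4–8 cohorts of 120–300 samples, 200
permutations per randomization test, 500 CSR maps for type-I calibration,
1000 bootstrap resamples — sizes at which every calibration band in the
acceptance checks is readable while a full run of the suite stays in the
minutes range on one CPU.

## Known limitations

* The chrometric feature inventory is a declared 14-feature set, not a
  reconstruction of any published supplementary list; likewise the HC/EC
  estimator (per-nucleus mean + k·sd threshold) is a declared choice.
* The interface is a 2-D polyline from one marker's point cloud; no
  3-D continuity, no multi-marker fusion.
* The randomization test's pooled Mann–Whitney p is descriptive only (see
  above); the calibrated permutation p is the inferential quantity.
* Synthetic cohorts carry known cell fractions by construction;
  deconvolution of real bulk profiles is out of scope.
* No survival analysis, batch correction, or cross-platform harmonization.
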