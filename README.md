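# gcniche

Quantitative analysis of germinal-center (GC) dark-zone / light-zone niches.

Germinal centers are the lymphoid microstructures where B cells proliferate,
mutate their antibody genes and are selected. They are split into a dark
zone (DZ — proliferation and hypermutation, AID+ cells) and a light zone
(LZ — selection, FDC-rich). `gcniche` implements, as a tested and reusable
pipeline, the quantitative machinery needed to characterize how these two
compartments differ and how T cells distribute between them:

* **Spatial statistics** (`gcniche.spatial`) — a nearest-neighbor
  randomization test for cell-type segregation/aggregation (labels shuffled
  over fixed positions), concave-hull delineation of the DZ/LZ interface
  with a 100 μm band, density profiles across the interface,
  range-normalized distances, and permutation-p / bootstrap-CI correlations
  (Pearson and Kendall).
* **Chrometric profiling** (`gcniche.chrometrics`) — nuclear segmentation
  and a fixed 14-feature table of per-nucleus chromatin/morphology
  descriptors, including the minimum DNA intensity, the 80th/20th intensity
  percentile ratio and the heterochromatin-to-euchromatin (HC/EC) pixel
  ratio (per-nucleus threshold at mean + k·sd).
* **DZ/LZ classification** (`gcniche.classifier`) — a random forest over
  the chrometric features evaluated by balanced subsampling, 10-fold
  stratified cross-validation with row-normalized confusion matrices, the
  no-information rate (NIR) baseline and an exact one-sided Wilcoxon
  signed-rank test of the fold accuracies against it.
* **Expression signatures** (`gcniche.signatures`) — paired DZ−LZ
  differential expression by an empirical-Bayes moderated t
  (posterior variance s̃² = (d₀s₀² + d_g s_g²)/(d₀+d_g), prior estimated by
  method-of-moments on log variances, BH-adjusted), signature scoring
  (mean z or total expression), tertile stratification, weighted-KS set
  enrichment with a gene-permutation null, and a cross-cohort analysis
  counting in how many tumor cohorts each DZ gene anti-correlates with a
  T-cell signature score.
* **Synthetic data** (`gcniche.synthetic`) — generators that plant
  recorded ground truth for every stage: GC point patterns with tunable
  T-cell repulsion from the DZ (independent thinning), DNA-stain nuclei
  whose heterochromatin fraction differs between compartments (with total
  DNA conserved, so compaction dims the euchromatin floor), paired-ROI
  expression with planted log-fold-changes, and tumor cohorts whose latent
  DZ activity is linked to a latent T-cell fraction.
* **Pipeline & I/O** (`gcniche.pipeline`, `gcniche.io`, `gcniche` CLI) — a
  YAML-configured runner chaining simulation → chrometrics → classification
  → spatial statistics → signatures into one reproducible report with a
  checksummed manifest.

## Worked example

```python
import gcniche as g

# a GC with strong T-cell exclusion from the DZ
cm, truth = g.simulate_gc_map(g.TissueSimConfig(seed=21, dz_t_retention=0.1))
res = g.nn_randomization_test(g.with_aid_labels(cm), "T", "AID",
                              n_perm=200, seed=0)
print(res.direction, round(res.p, 4),
      round(res.median_observed, 1), round(res.median_null, 1))
```

prints

```
segregation 0.01 100.9 6.8
```

— the observed median CD3-like → AID-like nearest-neighbor distance
(100.9 μm) is far larger than under label randomization (6.8 μm); the
calibrated two-sided permutation p of 0.01 is the smallest value 200
permutations can resolve, so the map is called segregated.

```python
# classify DZ vs LZ nuclei from chrometric features
grid = g.grid_cell_map(200, 200, spacing_um=9.0)
cfg = g.NucleiSimConfig(seed=1)                    # f_hc 0.35 (DZ) vs 0.15 (LZ)
img, labels, nt = g.simulate_nuclei_image(grid, cfg)
feats = g.extract_chrometric_features(img, labels, pixel_size=cfg.pixel_size)
X = feats.loc[~feats.flagged, g.FEATURE_NAMES]
y = nt.compartment.iloc[X.index - 1].set_axis(X.index)
cv = g.run_stratified_cv(X, y, g.ModelConfig(n_trees=500, seed=1), k=10)
print(round(cv.accuracy, 3), cv.nir, round(cv.nir_p, 6))
```

prints

```
0.975 0.5 0.000977
```

— with a planted heterochromatin-fraction gap of 0.20 the forest separates
the compartments almost perfectly; the balanced sample has NIR = 0.5, and
all ten folds beating it gives the exact signed-rank floor p = 1/1024.

The full demonstration pipeline:

```sh
gcniche run --outdir demo_out        # ~1 minute; report in demo_out/report.md
```

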