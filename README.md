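# habitatomics

Longitudinal **spatial-habitat radiomics** for predicting pathological
complete response (pCR) to neoadjuvant treatment in breast cancer — as a
tested, reusable Python pipeline.

Whole-tumor ("traditional") radiomics summarizes a tumor as one region and
misses intratumoral heterogeneity. Spatial-habitat radiomics (SHR) first
partitions each tumor into *habitats* — subregions with distinct perfusion /
enhancement characteristics — and extracts features per habitat at multiple
treatment timepoints, so that compositional and geometric changes during
therapy become measurable. This package implements the full analysis chain:

1. **Preprocessing** (`habitatomics.preprocess`) — N4 bias-field correction,
   B-spline resampling to 1 mm³ isotropic voxels, Nyul-style histogram
   standardization.
2. **Habitat delineation** (`habitatomics.habitats`) — SLIC supervoxel
   over-segmentation restricted to the tumor mask; k-means on per-supervoxel
   summaries; cluster count chosen by the Calinski-Harabasz index
   CH(K) = [B/(K−1)]/[W/(N−K)] and validated by silhouette scores; habitats
   relabelled by descending enhancement (Region I = high-enhancement,
   Region II = transitional, Region III = marginal/necrotic).
3. **Feature extraction** (`habitatomics.radiomics`) — an IBSI-style panel of
   14 shape + 93 intensity/texture features (18 first-order, 24 GLCM,
   16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) on 13 filter channels (original,
   8 stationary-wavelet sub-bands, 4 Laplacian-of-Gaussian scales):
   **1223 features per region**, 3669 per timepoint for three habitats,
   **9784 per patient** over two timepoints.
4. **Feature selection** (`habitatomics.selection`) — ICC(2,1) reliability
   filter (> 0.8 intra- and inter-reader), variance/Spearman-redundancy
   pruning (|ρ| > 0.9), Mann-Whitney univariate filter (p < 0.05), and
   L1-penalized logistic regression with cross-validated λ.
5. **Response models** (`habitatomics.models`) — statsmodels-style
   `ResponseModel(...).fit() → ResponseResults` wrapping gradient-boosted
   trees; four single-timepoint models (pre/mid × TR/SHR) and two fused
   models (Clin-SHR, Clin-TR) that add clinical covariates (cT stage, ER,
   HER2). Evaluation: AUC with DeLong CIs, sensitivity/specificity at a
   Youden threshold, calibration curves, decision-curve analysis
   NB(t) = TP/n − (FP/n)·t/(1−t), and subgroup evaluation.
6. **Immune association** (`habitatomics.immune`) — TPM normalization,
   moderated-t differential expression, preranked GSEA, MCPcounter-style
   marker indices, Spearman feature–immune correlation, ssGSEA B-cell
   scoring, and Ro/e (observed/expected cell-count) enrichment.

Because the study's patient data are not deposited, `habitatomics.synthetic`
generates phantom cohorts carrying the exact statistical structure the
pipeline assumes — three latent perfusion classes per tumor, longitudinal
composition shifts, outcomes causally linked to *subregional* (not
whole-tumor) image statistics, simulated re-delineations for ICC, and
expression/cell-count tables with group-dependent B-cell shifts — so every
stage is testable end-to-end (`habitatomics.benchmarks`).

## Worked example

```python
from habitatomics.synthetic import generate_phantom_pair
from habitatomics.habitats import supervoxel_segment, select_k, cluster_habitats, habitat_composition

pv, pm, mv, mm, truth = generate_phantom_pair(seed=11, fractions_pre=(0.5, 0.3, 0.2))
sv = supervoxel_segment(pv, pm)
sel = select_k(sv.features, candidate_ks=(2, 3, 4, 5, 6), seed=0)
print("chosen K:", sel.chosen_k)
hmap = cluster_habitats(sv, k=3, seed=0)
print("habitat fractions:", habitat_composition(hmap).round(3))
print("planted fractions:", truth.empirical_fractions("pre").round(3))
```

prints

```
chosen K: 3
habitat fractions: [0.5 0.3 0.2]
planted fractions: [0.5 0.3 0.2]
```

i.e. the Calinski-Harabasz rule recovers the planted three-class structure
and the recovered habitat volume fractions match the planted composition to
the rounding precision shown. Fitting the fused response model on a
synthetic cohort (`habitatomics.benchmarks.fusion_benchmark`) reproduces the
qualitative ordering that motivates habitat analysis: the habitat-based
Clin-SHR model outperforms the whole-tumor Clin-TR model on held-out
patients when the outcome signal is subregional.

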