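# stcem

Computational toolbox for **spatial transcriptomics-correlated electron
microscopy (STcEM)**: anchoring single-cell spatial transcriptomics
(MERFISH-style gene panels) to ultrastructural morphometrics measured on
an adjacent tissue section by volume EM, so that transcriptional cell
states and organelle-scale morphology can be analysed in one coordinate
frame. The motivating setting is a focal demyelinating brain lesion, in
which microglia adopt distinct damage-associated states — DAM-like,
interferon-responsive, and lipid-droplet-laden "foamy" cells — with
characteristic spatial niches and ultrastructure.

The package is aimed at computational biologists who have (i) a per-cell
spatial expression table, (ii) per-cell organelle measurements from a
neighbouring EM section, and (iii) optionally a deeper scRNA-seq
reference, and who want to run the full integration: QC, clustering,
spatial statistics, registration, cross-modal transfer, and correlation
analysis. A synthetic-data generator reproduces the coupled statistical
structure of such a study, and every stage is validated against it.

## What it computes

* **QC & expression** (`stcem.expression`) — cell filtering on
  transcript counts, detected genes, cell volume and blank-probe noise
  (defaults: 30 ≤ counts ≤ 2500, ≥5 genes, 40 < volume < 2500 µm³,
  blank mean ≤ 1); normalization `ln(1 + 10⁴·x/total)`; binned-control
  module scores; contamination-signature OLS regression; Wilcoxon
  rank-sum markers with BH adjustment; PCA → SNN → Leiden clustering;
  k-NN label transfer and gene imputation from a full-transcriptome
  reference.
* **Lesion geometry** (`stcem.lesion`) — kernel-density-difference
  segmentation of the lesion core and the exact 50 µm ring expansions
  (inner/outer lesion edge), plus priority-ordered region assignment.
* **Spatial statistics** (`stcem.spatial`) — k-NN neighbourhood label
  enrichment with a 10,000-permutation null, and the cross-type Ripley
  statistic L(r) = √(K(r)/π) in a polygonal window with permutation
  envelopes; centred values L_obs − E[L_perm] > 0 indicate attraction.
* **Registration** (`stcem.registration`) — staged landmark alignment:
  rigid → similarity (closed-form Procrustes, or ICP when
  correspondences are withheld) → interpolating thin-plate spline
  (kernel U(r) = r² log r).
* **Pattern similarity** (`stcem.pattern`) — multiscale Earth Mover's
  Distance: per-class Gaussian density maps at σ = 25/50/75/100 µm,
  exact optimal-transport cost between them (Euclidean ground metric,
  HiGHS LP), averaged over scales.
* **Cross-modal transfer** (`stcem.crossmodal`) — bisquare-kernel
  distance-weighted smoothing, w(d) = (1 − (d/75 µm)²)² within 75 µm,
  rendering genes and structural features on all cells; Spearman
  correlation for every gene×feature pair; hypergeometric
  over-representation of gene sets among the top correlates.
* **Ultrastructure** (`stcem.ultrastructure`) — organelle areas, ER
  skeleton arc length and empty-cytoplasm subtraction from binary label
  masks; a 32-metric feature manifest (9 base measures + 23 ratios);
  structural clustering; nearest-coordinate expert-label matching with
  one-sided Fisher exact overlap tests.
* **Metacells & GSEA** (`stcem.metacell`) — k = 20 metacell aggregation,
  Pearson correlation of gene expression with a log10 lipid-stain
  (BODIPY) value, and preranked GSEA with the weighted running-sum
  statistic.
* **Synthetic data** (`stcem.synthetic`) — the coupled generator:
  lesion-centred point pattern (five cell classes, Thomas-process
  niches with planted T-cell/IFN co-clustering), negative-binomial
  counts with class marker programs and blank probes, an EM section
  related by a known similarity + smooth deformation with exact
  landmarks, organelle features with a planted gene–feature latent
  correlation (ρ = 0.6), and a scRNA-seq set with BODIPY values driven
  by the foamy program.

## Worked example

```python
import numpy as np
from stcem import SynthConfig, generate_bundle, expression, registration, spatial, pattern

bundle = generate_bundle(SynthConfig(seed=2, n_cells_st=2000, n_cells_em=600))

# QC + normalization
cells, counts, report = expression.qc_filter(bundle.st_cells, bundle.st_counts)
norm = expression.normalize(counts)

# neighbourhood enrichment: are T-cells surrounded by IFN-responsive glia?
enr = spatial.knn_enrichment(cells, k=5, n_perm=10_000, seed=0)
row = enr.query("query_class == 'T-cell' and target_class == 'IFN-responsive'")
print(row[["observed_fraction", "fold_enrichment", "empirical_p"]])
#    observed_fraction  fold_enrichment  empirical_p
#            0.440984         4.273389       0.0001

# register the EM section onto the ST frame and match spatial patterns
chain = registration.fit_chain(bundle.landmarks)
print([round(r, 3) for r in chain.rmse_per_stage])
# [25.234, 8.254, 0.0]            # rigid -> similarity -> TPS residual (µm)
em = bundle.em_cells.copy()
em[["x", "y"]] = registration.apply_chain(chain, em[["x", "y"]].to_numpy())
emd = pattern.emd_matrix(cells, em, (0, 0, 1200, 1200), grid_size=12)
print(emd.to_frame().round(1))     # multiscale EMD (µm); diagonal is smallest
```

The enrichment row says that 44% of the five nearest neighbours of
T-cells are IFN-responsive cells — 4.3-fold more than under random
labelling (empirical p = 1e-4 at 10,000 permutations), the planted
co-clustering. The registration residuals show the similarity stage
absorbing the global transform and the thin-plate spline interpolating
the landmarks exactly; in the EMD matrix each spatial-transcriptomics
class is closest to its own EM counterpart.

A command-line interface mirrors the library
(`stcem synth|qc|normalize|cluster|lesion|neigh|ripley|register|emd|xmodal|metacell|pipeline`).

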