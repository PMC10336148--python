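# Methods

This note documents the models and procedures implemented in `stcem`,
the parameter defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical decisions
that shape the results.

## Study design being modelled

A focal demyelinating lesion is profiled twice: a single-cell spatial
transcriptomics section (a ~150-gene MERFISH-style panel with
negative-control "blank" probes) and an adjacent section imaged by
volume EM, from which per-cell organelle inventories are segmented.
Because the sections are neighbours (~10 µm apart), most cell somata
appear in both, displaced by a global transform (stage placement,
scaling) plus smooth local tissue deformation. A deeper
full-transcriptome scRNA-seq dataset with an index-sorted lipid stain
(BODIPY) provides the reference for gene imputation and
lipid-correlation analysis.

## Expression processing

* **QC.** A cell is kept iff total transcripts ∈ [30, 2500], detected
  genes ≥ 5, volume ∈ (40, 2500) µm³ and mean blank-probe count ≤ 1.
  The counts/genes bounds are inclusive and the volume bounds exclusive
  (the boundary cell with exactly 30 counts is retained). Totals and
  detected genes are recomputed from the matrix, which makes the filter
  idempotent.
* **Normalization** is `ln(1 + 10⁴·x/total)` with totals over non-blank
  genes; blank pseudo-genes never enter normalization, PCA, markers, or
  any downstream feature space.
* **Module scores** use the binned-control procedure: genes are ranked
  by mean normalized expression into 24 bins and each signature gene
  contributes up to 100 control genes drawn (without replacement) from
  its bin; the score is mean(signature) − mean(controls). Deterministic
  under the supplied seed.
* **Signature regression** residualizes the normalized layer on score
  covariates with an intercept, dropping collinear covariates. When all
  scores are identically zero the matrix is returned unchanged — the
  intercept-only fit would otherwise merely center genes, which is not
  what "removing contamination" means when there is none.
* **Markers** use the two-sided Wilcoxon rank-sum test per gene with
  Benjamini–Hochberg adjustment; a gene constant across the compared
  cells gets p = 1 rather than NaN.
* **Clustering** is PCA (deterministic full SVD, default 20 PCs) → 
  shared-nearest-neighbour graph (k = 20, Jaccard edge weights) →
  Leiden with the RB-configuration objective (the Louvain-family
  modularity) at the given resolution and seed.
* **Label transfer / imputation** project reference and query onto a
  PCA basis fitted on their shared genes (reference scaling), then use
  distance-weighted k-NN voting (inverse-square weights; exact matches
  take all weight, so an identical query reproduces the reference with
  confidence 1). Imputation transfers the neighbour-weighted average of
  reference expression for genes absent from the panel; measured panel
  genes pass through untouched. Reference genes qualify for imputation
  when they carry ≥ 10 total counts and are detected in ≥ 20 cells —
  the detection-based reading of the eligibility rule, which behaves
  sensibly across sequencing depths. This anchor-free scheme is a
  deliberately simple stand-in for CCA/rPCA anchor transfer; it is
  validated by recovery on synthetic truth, not by equality with any
  specific toolkit.

## Lesion geometry

The lesion core is segmented as the largest connected component where
KDE(lesion-enriched class) − KDE(lesion-depleted class) exceeds a grid
quantile (bandwidth 50 µm; quantile exposed, default 0.90 — for a
lesion occupying ~⅓ of the frame the background fraction ≈ 0.7 is the
natural choice and recovers a planted 400 µm disk to within ~20 µm
centroid error and ~6% area). This density rule is an algorithmic
stand-in for an expert-drawn polygon and is validated only against
synthetic truth. Ring expansions are exact shapely buffers (64 segments
per quadrant): inner edge = buffer(core, 50 µm) ∖ core, outer edge =
buffer(core, 100) ∖ buffer(core, 50). Region assignment is
boundary-inclusive with priority core > inner > outer > controls.

## Spatial statistics

* **Neighbourhood enrichment.** For each query class the fraction of
  each target label among the pooled 5 nearest neighbours (Euclidean,
  self excluded) is compared to a null that permutes labels over fixed
  positions (default 10,000 permutations). p-values use the add-one
  convention (1 + #{perm ≥ obs})/(1 + n_perm); fold enrichment is
  observed / mean(permuted). Calibration: under random labels ~5% of
  class pairs fall below p = 0.05 and mean fold is 1.00.
* **Cross-type Ripley L.** K_ab(r) = |W|/(n_a n_b) Σ w_ij 1[d_ij ≤ r]
  over cross pairs in the polygon window, L = √(K/π), on a 5–250 µm
  grid (5 µm steps). The null relabels points within the pooled
  two-class set; envelopes are pointwise 2.5/97.5 percentiles of 200
  permutations. Curves are centred as L_obs − mean(L_perm) so that
  positive values indicate attraction. Edge correction is selectable:
  `none`, or `isotropic` — the per-pair reciprocal fraction of the
  circle around each endpoint lying inside the window, computed by
  128-angle arc sampling (≈1% accurate) once per pair and symmetrized
  over the two endpoints so L_ab = L_ba exactly. Because observed and
  permuted patterns use the same estimator, envelope calibration holds
  under either correction.

## Registration

Rigid and similarity stages have the closed-form Umeyama/Procrustes
solution when landmark pairs are given; with correspondences withheld
an ICP loop alternates nearest-neighbour matching, rejection of the
worst 10% residuals, and the closed-form fit until the rmse improvement
drops below tolerance. The thin-plate spline uses U(r) = r² log r with
an affine part and zero smoothing (exact interpolation; a smoothing λ
is exposed). Stages compose left-to-right; rmse is non-increasing along
the chain. A numerical-Jacobian diagnostic reports fold-over (negative
determinant) locations of the TPS warp. Coordinates are µm with y
increasing downward, matching image-derived frames.

## Multiscale Earth Mover's Distance

Per-class patterns are rendered as Gaussian KDEs on a regular grid over
the analysis window, clipped to the window and renormalized to mass 1,
at σ = 25, 50, 75 and 100 µm; the multiscale distance is the arithmetic
mean of the per-σ EMDs. The transport problem is solved exactly as a
linear program (HiGHS) on the pruned supports (bins below 1e-12 mass
dropped; induced error ≤ prune tolerance × grid diameter). The LP
presolve is disabled — it misdeclares infeasibility on histograms with
very small masses — and one redundant marginal constraint is dropped.
The default grid is 24×24, keeping a single exact solve at the seconds
scale; class-by-class matching analyses use coarser grids (12×12),
which resolves lesion-scale structure while keeping a 5×5 class matrix
at four scales under a minute. Problems above ~450k transport variables
fall back to a log-domain Sinkhorn approximation with a warning. Tests
verify the solver against an integer-scaled network-simplex oracle and
the metric axioms on small histograms.

## Cross-modal transfer and correlation

All cells (both modalities, common frame) receive, per column, the
bisquare-weighted average w(d) = (1 − (d/d_max)²)², d_max = 75 µm, of
the donor cells of the column's source modality. Same-modality
smoothing includes the cell itself (w(0) = 1 makes self-inclusion the
continuity-respecting choice); cross-modality transfer has no self by
construction. Cells without a donor in range are missing and reported;
correlation handles missing values pairwise. The ST cells entering the
analysis are restricted to the EM-covered area, operationalized as the
concave hull of the EM positions buffered by d_max. Gene×feature
association is Spearman's ρ with average ranks; over-representation of
gene sets among the top-200 correlates is the one-sided hypergeometric
tail with BH adjustment alongside nominal p.

## Ultrastructural morphometrics

Areas are pixel counts scaled by the pixel size; ER is summarized by
the arc length of its skeleton (sum of unit/√2 steps along the 1-px
curve, counted once per adjacency); empty cytoplasm = whole cell −
(nucleus + lysosomes + lipid droplets + mitochondria + ER pixels +
organellar cytoplasm), with heterochromatin nested inside the nucleus
and excluded from the subtraction so that pixel conservation is exact.
Components under 5 px are removed as stray pixels. The feature manifest
is 9 base measures plus a canonical list of 23 non-redundant ratios
(32 metrics); the exact composition of such a ratio list is a free
choice and is therefore manifest-driven and configurable. Missing
ratios (zero denominators) are imputed as 0 with a missingness
indicator before clustering. Expert-annotation validation matches each
expert cell to the nearest featured cell (many-to-one allowed but
flagged) and tests label overlap per class pair with a one-sided Fisher
exact test.

## Metacells, stain correlation, GSEA

Metacells are k-NN groups (k = 20) around seed cells sampled without
replacement in 20-PC space; a candidate sharing more than k/2 members
with an accepted metacell is rejected. The number of seeds defaults to
n/5. BODIPY values are log10-transformed before averaging; gene–stain
association is the Pearson correlation of metacell means, ranked with
gene-name tie-breaking for determinism. At k = 1 the construction
degenerates to single cells and the correlation equals the single-cell
correlation exactly. Preranked GSEA uses the weighted running sum (hit
increments ∝ |stat|^w, misses uniform), ES = signed maximal deviation,
a gene-permutation null (default 1000), add-one p within the matching
ES sign, and NES = ES / mean |same-sign permuted ES|.

## Synthetic data: what it emulates, and what it does not

The generator plants exactly the structures the pipeline is meant to
detect, under one seed (bit-identical bundles):

* **Spatial layout** (1200×1200 µm window, lesion disk of radius
  400 µm at the centre — a plausible focal-lesion scale): homeostatic
  cells uniform outside the lesion, DAM-like uniform inside, foamy
  cells from a Thomas cluster process (Poisson parents, Gaussian
  daughters, niche sd 30 µm) centred on the core, and IFN-responsive +
  T-cells sharing Thomas parents. T-cell infiltrates place ~60% of
  their mass on a few niches (Dirichlet-weighted parents) while IFN
  cells spread evenly — both classes co-cluster, as niche biology
  suggests, without being spatially indistinguishable.
* **Counts**: negative-binomial (gamma–Poisson, dispersion 0.3) with
  ~400 transcripts/cell and 12-gene marker programs per class at
  log-fold 2. Marker genes are lowly expressed outside their class
  (baseline ×0.3), as panel markers are in practice; this also keeps
  library sizes comparable across classes. The foamy program is driven
  multiplicatively by a continuous per-cell latent (elevated by the
  marker log-fold in foamy cells); the homeostatic program fades
  continuously with that latent, mirroring the loss of homeostatic
  signature in lipid-laden cells. Ten blank pseudo-genes are Poisson
  with 0.3 expected total blank counts per cell. Planted QC violators
  (when requested) each break exactly one criterion.
* **EM section**: a subsample of ST cells jittered by 5 µm (adjacent
  10 µm sections), mapped by a similarity transform (default 10°,
  scale 1.05, translation (30, −20) µm) plus 2–4 Gaussian displacement
  bumps of ~20 µm amplitude; a Lipschitz bound on the deformation
  guarantees injectivity or raises. Twelve landmark pairs map exactly
  under the true chain. Organelle features follow class templates
  (foamy: large lipid-droplet areas; T-cells: small, nucleus-dominated,
  near-zero organelles; IFN: high mitochondrial share and empty
  cytoplasm); lipid-droplet area is an affine function of a feature
  latent correlated at ρ = 0.6 with the foamy gene latent.
* **scRNA-seq + BODIPY**: the same class programs plus per-class
  non-panel markers over ~2000 genes; log10(BODIPY) is linear in the
  foamy latent with Gaussian noise (sd 0.3), hence strictly positive
  and monotone in the latent at zero noise.

Not emulated: raw images and spot decoding, cell-boundary segmentation
errors and the resulting doublet-like contamination profiles, section
damage/folds, batch effects between replicates, 3D structure, and any
within-class correlation structure beyond the single foamy latent.
Passing tests therefore certify the statistical machinery on data whose
generative assumptions are known to hold, not robustness to the
artefacts of real acquisitions.

## Problem sizes and numerical notes

Simulation-based checks use 2000 ST cells / 600 EM cells / ~600 SC
cells per replicate, with 10–50 replicates per property and 10,000
(neighbourhood) or 200 (Ripley) permutations — sizes at which every
planted effect is comfortably detectable while a full validation run
stays desk-scale. Degenerate inputs are handled explicitly: empty
classes and all-cells-removed QC raise; zero-variance z-score lines map
to 0 with a warning; constant genes yield p = 1 (rank-sum) or missing
correlations; collinear TPS landmarks raise; radius grids are truncated
at the window diameter with a warning.

## Known limitations

* The lesion-core segmentation is a density-difference formalization of
  an expert judgement; its threshold is geometry-dependent.
* Label transfer is anchor-free k-NN voting; on real data with batch
  effects a dedicated integration method may be preferable behind the
  same interface.
* The isotropic Ripley correction is arc-sampled (≈1% accuracy), not
  the exact circle–polygon intersection.
* Exact EMD cost grows steeply with grid resolution; fine grids switch
  to the entropic approximation.
* GSEA p-values use a gene-permutation null, which ignores inter-gene
  correlation; on metacell-averaged ranks this is anti-conservative in
  the same way it is for the standard preranked analysis.
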