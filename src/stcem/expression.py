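"""Per-cell QC, normalization, scoring, markers, clustering and transfer.

Conventions follow the standard single-cell toolchain: totals are taken
over non-blank genes, normalization is ln(1 + 1e4·x/total), module scores
use the binned-control procedure, markers use two-sided Wilcoxon
rank-sum with Benjamini–Hochberg adjustment, and clustering runs
PCA → shared-nearest-neighbour graph (Jaccard weights) → Leiden
(RB-configuration modularity, the Louvain family objective) with a fixed
seed. Cross-dataset label transfer and gene imputation use
distance-weighted k-NN voting in a joint PCA space fitted on shared
genes.
"""

from __future__ import annotations

import warnings
from typing import Dict, Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .types import CountsMatrix, GeneSignature, QcThresholds


# ----------------------------------------------------------------------
# QC
# ----------------------------------------------------------------------

def qc_filter(
    cells: pd.DataFrame,
    counts: CountsMatrix,
    thr: QcThresholds = QcThresholds(),
) -> tuple[pd.DataFrame, CountsMatrix, dict]:
    """Remove low-quality cells; returns (cells, counts, report).

    A cell is excluded iff total counts < min or > max, detected genes
    below the minimum, volume outside the open (min, max) interval, or
    mean blank-probe count above the cap. The report gives removal
    counts per criterion (non-exclusive) recomputed from the counts
    matrix, so the filter is idempotent by construction.
    """
    total = counts.total_counts()
    nonblank = counts.raw[:, ~counts.is_blank]
    n_genes = (nonblank > 0).sum(axis=1)
    n_blanks = int(counts.is_blank.sum())
    blank_mean = (
        counts.raw[:, counts.is_blank].mean(axis=1) if n_blanks else np.zeros(len(total))
    )
    volume = (
        cells["volume"].to_numpy(float)
        if "volume" in cells.columns
        else np.full(len(total), np.nan)
    )

    fail = {
        "low_counts": total < thr.min_counts,
        "high_counts": total > thr.max_counts,
        "low_genes": n_genes < thr.min_genes,
        "low_volume": volume <= thr.min_volume,
        "high_volume": volume >= thr.max_volume,
        "high_blank": blank_mean > thr.max_blank_mean,
    }
    # volume criteria only apply where a volume is recorded
    fail["low_volume"] &= np.isfinite(volume)
    fail["high_volume"] &= np.isfinite(volume)

    any_fail = np.zeros(len(total), dtype=bool)
    for m in fail.values():
        any_fail |= m
    keep = ~any_fail
    if not keep.any():
        raise ValueError("empty after QC: all cells removed")
    report = {k: int(m.sum()) for k, m in fail.items()}
    report["n_removed"] = int(any_fail.sum())
    report["n_kept"] = int(keep.sum())
    report["removed_cell_ids"] = list(counts.cell_ids[any_fail])
    return cells.loc[keep].reset_index(drop=True), counts.subset_cells(keep), report


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------

def normalize(counts: CountsMatrix, scale: float = 10_000.0) -> CountsMatrix:
    """Library-size normalization, ln(1 + scale · x / total).

    Blank pseudo-genes are dropped before totals are computed, so they
    never enter the normalized layer.
    """
    out = counts.subset_genes(~counts.is_blank)
    total = out.raw.sum(axis=1, dtype=float)
    if (total == 0).any():
        raise ValueError("cell with zero total counts; run qc_filter first")
    out.norm = np.log1p(out.raw * (scale / total[:, None]))
    return out


def _require_norm(counts: CountsMatrix) -> np.ndarray:
    if counts.norm is None:
        raise ValueError("normalized layer missing; call normalize() first")
    return counts.norm


# ----------------------------------------------------------------------
# module scores
# ----------------------------------------------------------------------

def module_score(
    counts: CountsMatrix,
    sig: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control module score per cell.

    score = mean(norm over signature genes) − mean(norm over control
    genes), where each signature gene contributes ``n_ctrl`` control
    genes sampled from its average-expression bin. Deterministic under
    ``seed``; genes absent from the matrix are dropped with a warning.
    """
    norm = _require_norm(counts)
    present = [g for g in sorted(sig.genes) if g in set(counts.gene_names)]
    missing = sorted(sig.genes - set(present))
    if missing:
        warnings.warn(f"signature genes absent and dropped: {missing}", stacklevel=2)
    if not present:
        raise ValueError(f"no signature gene of {sig.name!r} is measured")
    rng = np.random.default_rng(seed)
    avg = norm.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bins = np.empty(counts.n_genes, dtype=int)
    bins[order] = np.arange(counts.n_genes) * n_bins // counts.n_genes
    sig_idx = counts.gene_index(present)

    ctrl_cols: list[np.ndarray] = []
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        ctrl_cols.append(rng.choice(pool, size=min(n_ctrl, len(pool)), replace=False))
    ctrl = np.concatenate(ctrl_cols)
    return norm[:, sig_idx].mean(axis=1) - norm[:, ctrl].mean(axis=1)


# ----------------------------------------------------------------------
# contamination-signature regression
# ----------------------------------------------------------------------

def regress_signatures(counts: CountsMatrix, scores: np.ndarray | Sequence) -> CountsMatrix:
    """OLS-residualize the normalized layer on per-cell score covariates.

    Covariates enter with an intercept; collinear scores are dropped
    with a warning. If every supplied score is identically zero the
    matrix is returned unchanged (no-op contract when there is nothing
    to regress out).
    """
    norm = _require_norm(counts)
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[0] != counts.n_cells:
        X = X.T
    if X.shape[0] != counts.n_cells:
        raise ValueError("scores must align with cells")
    if not X.any():
        return counts.copy()

    # prune collinear covariates by greedy QR rank check
    keep: list[int] = []
    base = np.ones((counts.n_cells, 1))
    for j in range(X.shape[1]):
        cand = np.hstack([base, X[:, keep + [j]]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear score covariate {j}", stacklevel=2)
    design = np.hstack([base, X[:, keep]])
    beta, *_ = np.linalg.lstsq(design, norm, rcond=None)
    out = counts.copy()
    out.norm = norm - design @ beta
    return out


# ----------------------------------------------------------------------
# marker testing
# ----------------------------------------------------------------------

def rank_sum_markers(
    counts: CountsMatrix, labels: Sequence, group, other=None
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum markers of ``group`` vs the rest.

    Returns one row per gene with log-fold change on normalized means,
    the U statistic, nominal p and Benjamini–Hochberg adjusted p.
    Genes constant across both groups get p = 1 by convention.
    """
    norm = _require_norm(counts)
    labels = np.asarray(labels, dtype=object)
    in_g = labels == group
    in_rest = (labels == other) if other is not None else ~in_g
    if in_g.sum() < 2 or in_rest.sum() < 2:
        raise ValueError(f"need ≥2 cells in each compared group for {group!r}")
    a, b = norm[in_g], norm[in_rest]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    u, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    const = (norm.max(axis=0) - norm.min(axis=0)) == 0
    # also constant-within-comparison ties where mannwhitneyu yields nan
    p = np.where(const | ~np.isfinite(p), 1.0, p)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": counts.gene_names,
            "logFC": a.mean(axis=0) - b.mean(axis=0),
            "U": u,
            "p": p,
            "adj_p": adj,
        }
    ).sort_values("p", kind="stable", ignore_index=True)


# ----------------------------------------------------------------------
# graph clustering
# ----------------------------------------------------------------------

def snn_graph(features: np.ndarray, k_snn: int = 20) -> sparse.csr_matrix:
    """Shared-nearest-neighbour graph with Jaccard edge weights."""
    n = len(features)
    k = min(k_snn, n)
    nn = NearestNeighbors(n_neighbors=k).fit(features)
    adj = nn.kneighbors_graph(features, mode="connectivity")  # includes self
    shared = adj @ adj.T
    shared = shared.tocoo()
    jac = shared.data / (2 * k - shared.data)
    keep = jac > 0
    g = sparse.coo_matrix(
        (jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    ).tocsr()
    g.setdiag(0)
    g.eliminate_zeros()
    return g


def cluster_graph(
    features: np.ndarray,
    n_pcs: int = 20,
    k_snn: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """PCA → SNN graph → Leiden community labels (seed-deterministic).

    ``features`` should already be scaled; ``n_pcs`` is clamped (with a
    warning) when it exceeds the feature space.
    """
    features = np.asarray(features, dtype=float)
    n, d = features.shape
    max_pcs = min(d, n - 1)
    if n_pcs >= min(d, n) and n_pcs > max_pcs:
        warnings.warn(f"n_pcs clamped from {n_pcs} to {max_pcs}", stacklevel=2)
    n_pcs = min(n_pcs, max_pcs)
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(features)
    g = snn_graph(pcs, k_snn=k_snn)
    coo = sparse.triu(g, k=1).tocoo()
    graph = igraph.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


# ----------------------------------------------------------------------
# label transfer & imputation
# ----------------------------------------------------------------------

def _joint_pca(ref: CountsMatrix, query: CountsMatrix, n_dims: int):
    """Fit PCA on shared genes of the reference; project both sets."""
    shared = sorted(set(ref.gene_names) & set(query.gene_names))
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need ≥10")
    r = _require_norm(ref)[:, ref.gene_index(shared)]
    q = _require_norm(query)[:, query.gene_index(shared)]
    mu, sd = r.mean(axis=0), r.std(axis=0)
    sd[sd == 0] = 1.0
    n_dims = min(n_dims, len(shared), len(r) - 1)
    pca = PCA(n_components=n_dims, svd_solver="full").fit((r - mu) / sd)
    return pca.transform((r - mu) / sd), pca.transform((q - mu) / sd)


def _weighted_neighbors(ref_emb, query_emb, k):
    """k-NN of query in reference space with inverse-square-distance weights.

    Exact matches (distance ≈ 0) take all the weight, so a query
    identical to the reference reproduces it exactly.
    """
    k = min(k, len(ref_emb))
    nn = NearestNeighbors(n_neighbors=k).fit(ref_emb)
    dist, idx = nn.kneighbors(query_emb)
    zero = dist < 1e-9
    w = np.where(zero.any(axis=1)[:, None], zero.astype(float), 1.0 / (dist**2 + 1e-12))
    return idx, w / w.sum(axis=1, keepdims=True)


def transfer_labels(
    ref_counts: CountsMatrix,
    ref_labels: Sequence,
    query_counts: CountsMatrix,
    n_dims: int = 15,
    k: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-weighted k-NN label transfer in a joint PCA space.

    Returns per-query-cell labels and the winning vote share as a
    confidence in (0, 1].
    """
    ref_emb, query_emb = _joint_pca(ref_counts, query_counts, n_dims)
    idx, w = _weighted_neighbors(ref_emb, query_emb, k)
    ref_labels = np.asarray(ref_labels, dtype=object)
    classes = np.unique(ref_labels)
    votes = np.zeros((len(query_emb), len(classes)))
    neigh_lab = ref_labels[idx]
    for ci, c in enumerate(classes):
        votes[:, ci] = (w * (neigh_lab == c)).sum(axis=1)
    win = votes.argmax(axis=1)
    return classes[win], votes[np.arange(len(win)), win]


def impute_genes(
    ref_counts: CountsMatrix,
    query_counts: CountsMatrix,
    min_counts: int = 10,
    min_cells: int = 20,
    n_dims: int = 15,
    k: int = 20,
) -> tuple[CountsMatrix, pd.DataFrame]:
    """Impute unmeasured genes in the panel data from a full reference.

    Reference genes are eligible when they carry at least ``min_counts``
    counts in total and are detected in at least ``min_cells`` reference
    cells. Unmeasured eligible
    genes receive the distance-weighted average of the k nearest
    reference cells' normalized expression; measured panel genes pass
    through unchanged. Returns the combined matrix (norm layer) and a
    per-gene provenance table.
    """
    shared = set(ref_counts.gene_names) & set(query_counts.gene_names)
    if not shared:
        raise ValueError("no gene overlap between reference and query")
    eligible = (ref_counts.raw.sum(axis=0) >= min_counts) & (
        (ref_counts.raw > 0).sum(axis=0) >= min_cells
    )
    ref_norm = _require_norm(ref_counts)
    query_norm = _require_norm(query_counts)

    ref_emb, query_emb = _joint_pca(ref_counts, query_counts, n_dims)
    idx, w = _weighted_neighbors(ref_emb, query_emb, k)

    to_impute = [
        j
        for j, g in enumerate(ref_counts.gene_names)
        if eligible[j] and g not in shared
    ]
    imputed = np.einsum("qk,qkg->qg", w, ref_norm[:, to_impute][idx])

    genes = np.concatenate([query_counts.gene_names, ref_counts.gene_names[to_impute]])
    norm = np.hstack([query_norm, imputed])
    out = CountsMatrix(
        cell_ids=query_counts.cell_ids.copy(),
        gene_names=genes,
        raw=np.zeros_like(norm),
        is_blank=np.zeros(len(genes), dtype=bool),
        norm=norm,
    )
    out.raw = np.hstack(
        [query_counts.raw, np.zeros((query_counts.n_cells, len(to_impute)))]
    )
    provenance = pd.DataFrame(
        {
            "gene": genes,
            "provenance": ["measured"] * query_counts.n_genes
            + ["imputed"] * len(to_impute),
        }
    )
    return out, provenance


def scale_features(norm: np.ndarray) -> np.ndarray:
    """Z-score genes/features; zero-variance columns map to 0."""
    mu = norm.mean(axis=0)
    sd = norm.std(axis=0)
    sd[sd == 0] = 1.0
    return (norm - mu) / sd
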