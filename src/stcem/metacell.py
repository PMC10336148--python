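"""Metacell aggregation, gene–lipid-stain correlation, and preranked GSEA.

Single-cell counts are noisy enough to mask gene–phenotype correlations;
aggregating k transcriptionally similar cells into metacells (k-NN
groups in PCA space around sampled seed cells, with bounded overlap)
recovers them. Per-metacell mean expression is correlated (Pearson)
with the mean log10 lipid-stain (BODIPY) value, and the resulting
correlation ranking feeds a preranked gene-set enrichment analysis with
the weighted Kolmogorov–Smirnov running-sum statistic and a
gene-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .expression import _require_norm, scale_features
from .types import CountsMatrix


@dataclass
class MetacellTable:
    """Aggregated metacells: memberships, mean expression, mean stain."""

    members: List[np.ndarray]  # cell indices, k per metacell
    expression: pd.DataFrame  # metacells × genes mean normalized expression
    bodipy: np.ndarray  # mean log10 stain per metacell
    k: int

    def __len__(self) -> int:
        return len(self.members)


def build_metacells(
    counts: CountsMatrix,
    bodipy: np.ndarray,
    k: int = 20,
    seed: int = 0,
    n_seeds: int | None = None,
    max_shared: int | None = None,
    n_pcs: int = 20,
) -> MetacellTable:
    """Construct metacells as k-NN groups around sampled seed cells.

    Seed cells are sampled without replacement; each candidate metacell
    is the seed plus its k−1 nearest neighbours in PCA space and is
    rejected when it shares more than ``max_shared`` (default k/2)
    members with an already accepted metacell. BODIPY values are
    log10-transformed before averaging.
    """
    norm = _require_norm(counts)
    n = counts.n_cells
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available cells")
    bodipy = np.asarray(bodipy, dtype=float)
    if (bodipy <= 0).any():
        raise ValueError("stain values must be strictly positive")
    if n_seeds is None:
        n_seeds = max(n // 5, 1)
    if max_shared is None:
        max_shared = k // 2
    rng = np.random.default_rng(seed)

    if k == 1:
        member_idx = [np.array([i]) for i in rng.choice(n, min(n_seeds, n), replace=False)]
    else:
        n_pcs = min(n_pcs, counts.n_genes, n - 1)
        pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(
            scale_features(norm)
        )
        nn = NearestNeighbors(n_neighbors=k).fit(pcs)
        _, idx = nn.kneighbors(pcs)
        seeds = rng.choice(n, min(n_seeds, n), replace=False)
        member_idx = []
        accepted: list[set] = []
        for s in seeds:
            cand = idx[s]
            cand_set = set(cand.tolist())
            if any(len(cand_set & prev) > max_shared for prev in accepted):
                continue
            member_idx.append(np.sort(cand))
            accepted.append(cand_set)
    if not member_idx:
        raise ValueError("no metacell accepted; relax max_shared or add seeds")

    expr = np.stack([norm[m].mean(axis=0) for m in member_idx])
    stain = np.array([np.log10(bodipy[m]).mean() for m in member_idx])
    return MetacellTable(
        members=member_idx,
        expression=pd.DataFrame(expr, columns=list(counts.gene_names)),
        bodipy=stain,
        k=k,
    )


def stain_correlation(mc: MetacellTable) -> pd.DataFrame:
    """Pearson r of each gene's metacell means against the stain means.

    Constant genes get missing r. Returned sorted by r (descending),
    ties broken by gene name for a stable ranking.
    """
    if len(mc) < 3:
        raise ValueError("need at least 3 metacells for correlation")
    X = mc.expression.to_numpy(float)
    y = mc.bodipy - mc.bodipy.mean()
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ y) / (sx * sy)
    r[sx == 0] = np.nan
    out = pd.DataFrame({"gene": mc.expression.columns, "pearson_r": r})
    return out.sort_values(
        ["pearson_r", "gene"], ascending=[False, True], kind="stable", ignore_index=True
    )


# ----------------------------------------------------------------------
# preranked GSEA
# ----------------------------------------------------------------------


@dataclass
class GseaResult:
    term: str
    es: float
    nes: float
    p: float
    size: int
    leading_edge: List[str]


def _running_es(order_stat: np.ndarray, in_set: np.ndarray, weight: float):
    """Signed max deviation of the weighted KS running sum.

    ``order_stat`` are the rank metrics sorted descending; hit steps are
    proportional to |stat|^weight, miss steps uniform.
    """
    hit_w = np.abs(order_stat) ** weight * in_set
    hit_total = hit_w.sum()
    n_miss = len(in_set) - int(in_set.sum())
    if hit_total == 0 or n_miss == 0:
        return 0.0, np.zeros(len(in_set))
    run = np.cumsum(hit_w / hit_total - (~in_set.astype(bool)).astype(float) / n_miss)
    i = int(np.abs(run).argmax())
    return float(run[i]), run


def preranked_gsea(
    ranks: Dict[str, float] | pd.Series,
    gene_sets: Dict[str, Sequence[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-permutation null.

    Genes are ordered by the rank metric (descending; ties broken by
    gene name for determinism). For each set the enrichment score is
    the signed maximal deviation of the weighted running sum; the null
    redraws random gene sets of the same size, p uses the add-one
    convention within the matching ES sign, and NES = ES divided by the
    mean |ES| of same-sign permutations. Sets overlapping the universe
    in fewer than ``min_size`` genes are skipped.
    """
    if isinstance(ranks, dict):
        ranks = pd.Series(ranks)
    ranks = ranks.dropna()
    order = sorted(ranks.index, key=lambda g: (-ranks[g], g))
    stat = ranks.loc[order].to_numpy(float)
    genes = np.asarray(order, dtype=object)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for term, members in gene_sets.items():
        hit_idx = np.array(sorted({pos[g] for g in members if g in pos}), dtype=int)
        size = len(hit_idx)
        if size < min_size:
            continue
        in_set = np.zeros(len(genes), dtype=bool)
        in_set[hit_idx] = True
        es, run = _running_es(stat, in_set, weight)

        es_perm = np.empty(n_perm)
        for p_i in range(n_perm):
            perm = np.zeros(len(genes), dtype=bool)
            perm[rng.choice(len(genes), size=size, replace=False)] = True
            es_perm[p_i], _ = _running_es(stat, perm, weight)
        same_sign = es_perm[np.sign(es_perm) == np.sign(es)] if es != 0 else es_perm
        if len(same_sign) == 0:
            p = 1.0 / (1.0 + n_perm)
            nes = 0.0
        else:
            p = (1.0 + float((np.abs(same_sign) >= abs(es)).sum())) / (
                1.0 + len(same_sign)
            )
            nes = es / np.abs(same_sign).mean()
        peak = int(np.abs(run).argmax())
        if es >= 0:
            lead = [g for g in genes[: peak + 1] if g in set(members)]
        else:
            lead = [g for g in genes[peak:] if g in set(members)]
        rows.append(
            {
                "term": term,
                "ES": es,
                "NES": nes,
                "p": p,
                "size": size,
                "leading_edge": lead,
            }
        )
    return pd.DataFrame(rows)
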