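"""Ultrastructural morphometrics from per-cell organelle label masks.

Each EM cell arrives as a stack of binary masks (whole cell, nucleus,
heterochromatin, lysosome, lipid droplet, mitochondria, ER,
organellar cytoplasm) on the section plane with the largest cell area.
Organelle areas are pixel counts (converted to µm² by the pixel size),
ER is summarized by its skeleton arc length, and the empty cytoplasm is
the whole-cell area minus all other segmented areas (heterochromatin is
nested inside the nucleus and excluded from the subtraction). The
feature manifest — base measures plus a canonical list of non-redundant
ratios, 32 metrics by default — feeds PCA/SNN/Leiden clustering, and
cluster labels are validated against expert annotations by
nearest-coordinate matching and one-sided Fisher exact overlap tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from skimage import measure, morphology

from . import expression

logger = logging.getLogger(__name__)

ORGANELLE_KEYS = (
    "nucleus",
    "heterochromatin",
    "lysosome",
    "lipid_droplet",
    "mitochondria",
    "er",
    "organellar_cytoplasm",
)

#: minimum connected-component size kept when cleaning stray pixels
STRAY_PIXEL_MIN = 5

BASE_FEATURES = (
    "whole_cell_area",
    "nucleus_area",
    "heterochromatin_area",
    "lysosome_area",
    "lipid_droplet_area",
    "mitochondria_area",
    "er_length",
    "organellar_cytoplasm_area",
    "empty_cytoplasm_area",
)

#: canonical non-redundant ratio manifest (23 ratios + 9 base = 32 metrics)
DEFAULT_RATIOS: tuple[tuple[str, str], ...] = (
    ("nucleus_area", "whole_cell_area"),
    ("heterochromatin_area", "whole_cell_area"),
    ("lysosome_area", "whole_cell_area"),
    ("lipid_droplet_area", "whole_cell_area"),
    ("mitochondria_area", "whole_cell_area"),
    ("er_length", "whole_cell_area"),
    ("organellar_cytoplasm_area", "whole_cell_area"),
    ("empty_cytoplasm_area", "whole_cell_area"),
    ("heterochromatin_area", "nucleus_area"),
    ("nucleus_area", "empty_cytoplasm_area"),
    ("lysosome_area", "organellar_cytoplasm_area"),
    ("lipid_droplet_area", "organellar_cytoplasm_area"),
    ("mitochondria_area", "organellar_cytoplasm_area"),
    ("er_length", "organellar_cytoplasm_area"),
    ("lipid_droplet_area", "lysosome_area"),
    ("lipid_droplet_area", "mitochondria_area"),
    ("lysosome_area", "mitochondria_area"),
    ("empty_cytoplasm_area", "organellar_cytoplasm_area"),
    ("nucleus_area", "organellar_cytoplasm_area"),
    ("er_length", "mitochondria_area"),
    ("heterochromatin_area", "empty_cytoplasm_area"),
    ("lipid_droplet_area", "empty_cytoplasm_area"),
    ("mitochondria_area", "empty_cytoplasm_area"),
)


@dataclass
class LabelMaskStack:
    """Binary masks of one cell's organelle inventory on one plane.

    ``px_size_um`` converts pixel counts to µm / µm²; ``origin`` places
    the mask's (row 0, col 0) corner in global µm coordinates.
    """

    whole_cell: np.ndarray
    organelles: Dict[str, np.ndarray] = field(default_factory=dict)
    px_size_um: float = 0.02
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.whole_cell = np.asarray(self.whole_cell, dtype=bool)
        self.organelles = {
            k: np.asarray(v, dtype=bool) for k, v in self.organelles.items()
        }
        unknown = set(self.organelles) - set(ORGANELLE_KEYS)
        if unknown:
            raise ValueError(f"unknown organelle masks: {sorted(unknown)}")
        for k, v in self.organelles.items():
            if v.shape != self.whole_cell.shape:
                raise ValueError(f"mask {k!r} shape differs from whole_cell")


def _clean_stray(mask: np.ndarray, min_size: int = STRAY_PIXEL_MIN) -> np.ndarray:
    """Drop connected components below min_size pixels."""
    if not mask.any():
        return mask
    cleaned = morphology.remove_small_objects(
        measure.label(mask, connectivity=2), min_size=min_size
    )
    removed = int(mask.sum() - (cleaned > 0).sum())
    if removed:
        logger.info("removed %d stray pixels", removed)
    return cleaned > 0


def skeleton_arc_length(mask: np.ndarray, px_size: float = 1.0) -> float:
    """Arc length of a curvilinear structure via its skeleton.

    The mask is skeletonized to a 1-px-wide curve and the length is the
    sum of inter-pixel step lengths (1 for axis steps, √2 for diagonal
    steps), each adjacency counted once. A straight 50-px segment gives
    49 steps.
    """
    if not mask.any():
        return 0.0
    sk = morphology.skeletonize(mask)
    length = 0.0
    # forward-only offsets so each adjacency is counted once
    for (dr, dc), step in (
        ((0, 1), 1.0),
        ((1, 0), 1.0),
        ((1, 1), np.sqrt(2)),
        ((1, -1), np.sqrt(2)),
    ):
        shifted = np.zeros_like(sk)
        r0, r1 = max(dr, 0), sk.shape[0] + min(dr, 0)
        c0, c1 = max(dc, 0), sk.shape[1] + min(dc, 0)
        shifted[r0:r1, c0:c1] = sk[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        length += step * np.logical_and(sk, shifted).sum()
    return float(length * px_size)


def extract_features(masks: LabelMaskStack) -> pd.Series:
    """One feature-table row from a cell's mask stack.

    Areas are pixel counts × px² (µm²); ER is an arc length (µm);
    empty cytoplasm = whole cell − Σ(nucleus, lysosome, lipid droplet,
    mitochondria, ER pixels, organellar cytoplasm). Ratios with a zero
    denominator are missing (NaN). Stray components under 5 px are
    removed first.
    """
    whole = _clean_stray(masks.whole_cell)
    if not whole.any():
        raise ValueError("whole-cell mask is empty")
    org = {k: _clean_stray(v) for k, v in masks.organelles.items()}
    for k, v in org.items():
        if np.logical_and(v, ~whole).any():
            raise ValueError(f"organelle mask {k!r} extends beyond the whole-cell mask")
    nuc = org.get("nucleus", np.zeros_like(whole))
    het = org.get("heterochromatin", np.zeros_like(whole))
    if np.logical_and(het, ~nuc).any():
        raise ValueError("heterochromatin mask extends beyond the nucleus")

    px = masks.px_size_um
    px2 = px * px
    areas_px = {k: int(org.get(k, np.zeros_like(whole)).sum()) for k in ORGANELLE_KEYS}
    whole_px = int(whole.sum())
    # heterochromatin nests inside the nucleus; ER pixels count as area here
    subtracted = (
        areas_px["nucleus"]
        + areas_px["lysosome"]
        + areas_px["lipid_droplet"]
        + areas_px["mitochondria"]
        + areas_px["er"]
        + areas_px["organellar_cytoplasm"]
    )
    empty_px = whole_px - subtracted
    if empty_px < 0:
        raise ValueError("organelle areas exceed the whole-cell area; masks overlap")

    rows = measure.regionprops(whole.astype(int))[0]
    minr, minc, maxr, maxc = rows.bbox
    cy = masks.origin[1] + 0.5 * (minr + maxr) * px
    cx = masks.origin[0] + 0.5 * (minc + maxc) * px

    out = {
        "whole_cell_area": whole_px * px2,
        "whole_cell_area_px": whole_px,
        "nucleus_area": areas_px["nucleus"] * px2,
        "heterochromatin_area": areas_px["heterochromatin"] * px2,
        "lysosome_area": areas_px["lysosome"] * px2,
        "lipid_droplet_area": areas_px["lipid_droplet"] * px2,
        "mitochondria_area": areas_px["mitochondria"] * px2,
        "er_length": skeleton_arc_length(org.get("er", np.zeros_like(whole)), px),
        "organellar_cytoplasm_area": areas_px["organellar_cytoplasm"] * px2,
        "empty_cytoplasm_area": empty_px * px2,
        "x": cx,
        "y": cy,
    }
    for num, den in DEFAULT_RATIOS:
        v_num, v_den = out[num], out[den]
        out[f"{num}__per__{den}"] = v_num / v_den if v_den > 0 else np.nan
    return pd.Series(out)


def feature_manifest(ratios: Sequence[tuple[str, str]] = DEFAULT_RATIOS) -> list[str]:
    """Names of the structural metrics (base measures + ratio manifest)."""
    return list(BASE_FEATURES) + [f"{n}__per__{d}" for n, d in ratios]


def cluster_structural(
    table: pd.DataFrame,
    n_pcs: int = 20,
    resolution: float = 1.0,
    k_snn: int = 20,
    seed: int = 0,
    features: Sequence[str] | None = None,
) -> np.ndarray:
    """Cluster the structural feature table (PCA → SNN → Leiden).

    Features are z-scaled; missing ratios are imputed as 0 with an
    added missingness-indicator column per affected feature.
    """
    cols = [c for c in (features or feature_manifest()) if c in table.columns]
    X = table[cols].to_numpy(float)
    indicators = []
    for j in range(X.shape[1]):
        nan = np.isnan(X[:, j])
        if nan.any():
            X[nan, j] = 0.0
            indicators.append(nan.astype(float))
    if indicators:
        X = np.column_stack([X] + indicators)
    X = expression.scale_features(X)
    return expression.cluster_graph(
        X, n_pcs=n_pcs, k_snn=k_snn, resolution=resolution, seed=seed
    )


def match_expert_labels(
    expert: pd.DataFrame, featured: pd.DataFrame
) -> pd.DataFrame:
    """Assign each expert-annotated cell its nearest featured cell.

    Coordinates must share a frame; many-to-one matches are allowed but
    flagged in the ``shared_match`` column.
    """
    if len(expert) == 0 or len(featured) == 0:
        raise ValueError("both cell sets must be non-empty")
    exy = expert[["x", "y"]].to_numpy(float)
    fxy = featured[["x", "y"]].to_numpy(float)
    dist, idx = cKDTree(fxy).query(exy)
    counts = np.bincount(idx, minlength=len(fxy))
    out = pd.DataFrame(
        {
            "expert_index": np.arange(len(expert)),
            "featured_index": idx,
            "distance": dist,
            "shared_match": counts[idx] > 1,
        }
    )
    if out["shared_match"].any():
        warnings.warn(
            f"{int(out['shared_match'].sum())} expert cells share a nearest featured cell",
            stacklevel=2,
        )
    return out


def overlap_test(labels_a: Sequence, labels_b: Sequence) -> pd.DataFrame:
    """One-sided Fisher exact overlap between two labellings of the same cells.

    For every (class_a, class_b) pair the 2×2 table is membership in
    class_a × membership in class_b over the matched cells;
    p = P[overlap ≥ observed] (alternative='greater').
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if len(a) != len(b):
        raise ValueError("label vectors must be paired")
    ca, cb = np.unique(a), np.unique(b)
    if len(ca) < 2 or len(cb) < 2:
        raise ValueError("need at least 2 classes on each side")
    rows = []
    for x in ca:
        in_a = a == x
        for y in cb:
            in_b = b == y
            n11 = int(np.sum(in_a & in_b))
            n12 = int(np.sum(in_a & ~in_b))
            n21 = int(np.sum(~in_a & in_b))
            n22 = int(np.sum(~in_a & ~in_b))
            _, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="greater")
            rows.append(
                {"class_a": x, "class_b": y, "count": n11, "fisher_p": float(p)}
            )
    return pd.DataFrame(rows)
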