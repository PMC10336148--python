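"""Coupled synthetic MERFISH-like / EM-like / scRNA-seq-like data.

The generator emulates the statistical structure of a focal demyelinating
lesion profiled by single-cell spatial transcriptomics with an adjacent
section imaged by volume EM:

* a lesion-centred point pattern with five cell classes — homeostatic
  microglia outside the lesion, DAM-like cells filling it, foamy
  (lipid-droplet-laden) cells concentrated in the core via a Thomas
  cluster process, and IFN-responsive cells co-clustered with T-cells in
  shared niches;
* negative-binomial count matrices with class-specific marker programs
  and MERFISH-style blank (negative-control) pseudo-genes;
* an adjacent "EM" section whose cell positions are a jittered subsample
  of the ST cells mapped through a known similarity transform plus a
  smooth low-frequency deformation field, with exact landmark pairs;
* per-EM-cell organelle-area features with a planted latent correlation
  between the foamy gene program and lipid-droplet area;
* a full-transcriptome scRNA-seq set with per-cell lipid-stain (BODIPY)
  values driven by the foamy program latent.

Every stochastic choice flows from ``SynthConfig.seed``; a fixed seed
yields bit-identical bundles. The ``truth`` record carries everything a
downstream recovery test needs (class labels, transform parameters,
latents, program gene lists, planted QC violators).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .registration import LandmarkSet, SimilarityStage
from .types import BLANK_PREFIX, CountsMatrix, QcThresholds, new_cell_table

CLASSES = ("homeostatic", "DAM-like", "foamy", "IFN-responsive", "T-cell")

DEFAULT_PROPORTIONS = {
    "homeostatic": 0.40,
    "DAM-like": 0.28,
    "foamy": 0.15,
    "IFN-responsive": 0.10,
    "T-cell": 0.07,
}

#: Per-class ultrastructural templates. Areas in µm² expressed as fractions
#: of whole-cell area (ER length in µm, absolute). Foamy cells carry large
#: lipid-droplet areas via the planted latent; T-cells are small, nearly
#: organelle-free and nucleus-dominated; IFN-responsive cells show a high
#: mitochondrial share and abundant empty cytoplasm.
EM_CLASS_TEMPLATES: Dict[str, Dict[str, float]] = {
    "homeostatic": dict(area=150, nucleus=0.35, hetero=0.30, lyso=0.02, mito=0.05, org=0.20, er=30),
    "DAM-like": dict(area=220, nucleus=0.30, hetero=0.25, lyso=0.08, mito=0.07, org=0.25, er=40),
    "foamy": dict(area=300, nucleus=0.18, hetero=0.25, lyso=0.10, mito=0.05, org=0.28, er=25),
    "IFN-responsive": dict(area=180, nucleus=0.28, hetero=0.25, lyso=0.04, mito=0.14, org=0.12, er=35),
    "T-cell": dict(area=80, nucleus=0.65, hetero=0.45, lyso=0.003, mito=0.004, org=0.02, er=4),
}

QC_VIOLATION_KINDS = (
    "low_counts",
    "high_counts",
    "low_genes",
    "low_volume",
    "high_volume",
    "high_blank",
)


@dataclass
class SynthConfig:
    """Parameters of the coupled synthetic study.

    Spatial units are µm throughout; the imaged window is
    ``[0, window[0]] × [0, window[1]]`` with the lesion disk at
    ``lesion_center`` / ``lesion_radius``.
    """

    seed: int = 0
    n_cells_st: int = 2000
    n_cells_em: int = 600
    n_cells_sc: int = 500
    n_genes_panel: int = 150
    n_genes_full: int = 2000
    window: Tuple[float, float] = (1200.0, 1200.0)
    lesion_center: Tuple[float, float] = (600.0, 600.0)
    lesion_radius: float = 400.0
    class_proportions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    nb_dispersion: float = 0.3
    marker_logfc: float = 2.0
    target_total_counts: float = 400.0
    n_markers_per_class: int = 12
    n_sc_markers_per_class: int = 10
    niche_parent_rate: float = 1.5e-5  # parents / µm² of lesion area
    niche_sd: float = 30.0
    blank_rate: float = 0.3  # mean blank counts per cell (all blanks)
    n_blanks: int = 10
    em_similarity: Tuple[float, float, Tuple[float, float]] = (
        math.radians(10.0),
        1.05,
        (30.0, -20.0),
    )
    em_jitter_sd: float = 5.0
    em_deform_amp: float = 20.0
    em_n_bumps: int = 3
    n_landmarks: int = 12
    latent_gene_feature_rho: float = 0.6
    latent_coupling: float = 0.6
    bodipy_noise_sd: float = 0.3
    qc_violator_fraction: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValueError(f"class_proportions must sum to 1 (got {total})")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in proportions: {sorted(unknown)}")
        for name in ("n_cells_st", "n_cells_em", "n_cells_sc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.latent_gene_feature_rho) > 1:
            raise ValueError("latent_gene_feature_rho must lie in [-1, 1]")
        if not 0 <= self.qc_violator_fraction < 1:
            raise ValueError("qc_violator_fraction must lie in [0, 1)")


@dataclass
class SynthTruth:
    """Ground truth sufficient to score every downstream recovery test."""

    st_classes: np.ndarray
    em_classes: np.ndarray | None = None
    sc_classes: np.ndarray | None = None
    em_source_idx: np.ndarray | None = None
    similarity: Tuple[float, float, Tuple[float, float]] | None = None
    bumps: List[dict] = field(default_factory=list)
    st_foamy_latent: np.ndarray | None = None
    em_gene_latent: np.ndarray | None = None
    em_feature_latent: np.ndarray | None = None
    sc_foamy_latent: np.ndarray | None = None
    rho: float = 0.0
    programs: Dict[str, List[str]] = field(default_factory=dict)
    sc_programs: Dict[str, List[str]] = field(default_factory=dict)
    null_genes: List[str] = field(default_factory=list)
    qc_violators: Dict[str, List[str]] = field(default_factory=dict)


@dataclass
class SynthBundle:
    st_cells: pd.DataFrame
    st_counts: CountsMatrix
    em_cells: pd.DataFrame
    em_features: pd.DataFrame
    landmarks: LandmarkSet
    sc_counts: CountsMatrix
    bodipy: np.ndarray
    truth: SynthTruth


# ----------------------------------------------------------------------
# gene panel construction
# ----------------------------------------------------------------------

def _panel_genes(cfg: SynthConfig) -> tuple[list, dict]:
    """Panel gene names and per-class program membership."""
    programs = {}
    names: list[str] = []
    for cls in CLASSES:
        tag = cls.lower().replace("-", "")
        genes = [f"{tag}-mk{i:02d}" for i in range(1, cfg.n_markers_per_class + 1)]
        programs[cls] = genes
        names.extend(genes)
    n_null = cfg.n_genes_panel - len(names)
    if n_null < 0:
        raise ValueError("panel too small for the requested marker programs")
    names.extend(f"gene-{i:04d}" for i in range(1, n_null + 1))
    return names, programs


def _class_counts(cfg: SynthConfig, n: int, rng: np.random.Generator) -> dict:
    """Multinomial split of n cells over classes (zero-proportion ⇒ zero cells)."""
    classes = [c for c in CLASSES if cfg.class_proportions.get(c, 0.0) > 0]
    p = np.array([cfg.class_proportions[c] for c in classes], dtype=float)
    p = p / p.sum()
    draws = rng.multinomial(n, p)
    return dict(zip(classes, draws))


# ----------------------------------------------------------------------
# spatial layout
# ----------------------------------------------------------------------

def _uniform_outside(n, cfg, rng):
    cx, cy = cfg.lesion_center
    pts = np.empty((0, 2))
    while len(pts) < n:
        cand = rng.random((max(4 * n, 64), 2)) * np.asarray(cfg.window)
        d2 = (cand[:, 0] - cx) ** 2 + (cand[:, 1] - cy) ** 2
        pts = np.vstack([pts, cand[d2 > cfg.lesion_radius**2]])
    return pts[:n]


def _uniform_inside(n, cfg, rng):
    cx, cy = cfg.lesion_center
    r = cfg.lesion_radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    pts = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
    return np.clip(pts, [0, 0], cfg.window)


def _thomas(n, parents, sd, cfg, rng):
    """Daughter points around given parents, clipped to the window."""
    if len(parents) == 0 or n == 0:
        return np.empty((0, 2)), np.empty(0, dtype=int)
    which = rng.integers(0, len(parents), size=n)
    pts = parents[which] + rng.normal(0.0, sd, size=(n, 2))
    return np.clip(pts, [0, 0], cfg.window), which


def generate_st(cfg: SynthConfig) -> tuple[pd.DataFrame, CountsMatrix, SynthTruth]:
    """Lesion-centred ST point pattern plus negative-binomial counts.

    Homeostatic cells are uniform outside the lesion disk, DAM-like cells
    uniform inside it, foamy cells follow a Thomas cluster process centred
    on the core, and IFN-responsive cells share Thomas parents with
    T-cells (the planted co-clustering the spatial statistics recover).
    """
    root = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    rng_pos, rng_cnt, rng_qc = (
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(3)
    )
    counts_per_class = _class_counts(cfg, cfg.n_cells_st, rng_pos)
    del root

    cx, cy = cfg.lesion_center
    lesion_area = np.pi * cfg.lesion_radius**2
    positions, classes = [], []

    n_homeo = counts_per_class.get("homeostatic", 0)
    positions.append(_uniform_outside(n_homeo, cfg, rng_pos))
    classes += ["homeostatic"] * n_homeo

    n_dam = counts_per_class.get("DAM-like", 0)
    positions.append(_uniform_inside(n_dam, cfg, rng_pos))
    classes += ["DAM-like"] * n_dam

    # foamy: Thomas parents drawn around the lesion core
    n_foamy = counts_per_class.get("foamy", 0)
    n_par = max(1, rng_pos.poisson(cfg.niche_parent_rate * lesion_area))
    foamy_parents = np.column_stack(
        [
            rng_pos.normal(cx, cfg.lesion_radius / 4, n_par),
            rng_pos.normal(cy, cfg.lesion_radius / 4, n_par),
        ]
    )
    pts, _ = _thomas(n_foamy, foamy_parents, cfg.niche_sd, cfg, rng_pos)
    positions.append(pts)
    classes += ["foamy"] * n_foamy

    # IFN-responsive and T-cells share niche parents inside the lesion.
    # IFN cells spread evenly over the niches; T-cell infiltrates put
    # most of their mass on a few of them — every niche keeps some
    # T-cell presence (co-clustering) but the two density profiles stay
    # distinguishable.
    n_ifn = counts_per_class.get("IFN-responsive", 0)
    n_t = counts_per_class.get("T-cell", 0)
    n_par = max(2, rng_pos.poisson(cfg.niche_parent_rate * lesion_area))
    shared_parents = _uniform_inside(n_par, cfg, rng_pos)
    w_uniform = np.full(n_par, 1.0 / n_par)
    w_t = 0.4 * w_uniform + 0.6 * rng_pos.dirichlet(np.full(n_par, 0.3))
    pts_ifn, _ = _thomas(n_ifn, shared_parents, cfg.niche_sd, cfg, rng_pos)
    pts_t = np.clip(
        shared_parents[rng_pos.choice(n_par, size=n_t, p=w_t)]
        + rng_pos.normal(0.0, cfg.niche_sd, size=(n_t, 2)),
        [0, 0],
        cfg.window,
    )
    positions.append(pts_ifn)
    classes += ["IFN-responsive"] * n_ifn
    positions.append(pts_t)
    classes += ["T-cell"] * n_t

    xy = np.vstack(positions)
    classes = np.asarray(classes, dtype=object)
    order = rng_pos.permutation(len(classes))
    xy, classes = xy[order], classes[order]
    n = len(classes)

    # foamy program latent: elevated in foamy cells, continuous everywhere
    z = cfg.marker_logfc * (classes == "foamy").astype(float)
    z = z + rng_cnt.normal(0.0, 0.4, size=n)

    genes, programs = _panel_genes(cfg)
    raw = _sample_counts(cfg, classes, z, genes, programs, rng_cnt)

    # blank pseudo-genes
    blanks = rng_cnt.poisson(cfg.blank_rate / cfg.n_blanks, size=(n, cfg.n_blanks))
    blank_names = [f"{BLANK_PREFIX}{i}" for i in range(1, cfg.n_blanks + 1)]

    volumes = _truncated_lognormal(rng_cnt, n, math.log(300.0), 0.35, 40.0, 2500.0)

    violators = _plant_qc_violators(cfg, raw, blanks, volumes, rng_qc)

    all_genes = np.array(genes + blank_names, dtype=object)
    mat = CountsMatrix(
        cell_ids=np.array([f"st-{i:05d}" for i in range(n)], dtype=object),
        gene_names=all_genes,
        raw=np.hstack([raw, blanks]).astype(np.int64),
    )
    cells = new_cell_table(
        mat.cell_ids,
        xy[:, 0],
        xy[:, 1],
        volume=volumes,
        total_counts=mat.total_counts().astype(int),
        n_genes=(raw > 0).sum(axis=1),
        blank_mean=blanks.mean(axis=1),
        class_label=classes,
        modality="ST",
    )
    null_genes = [g for g in genes if g.startswith("gene-")]
    truth = SynthTruth(
        st_classes=classes,
        st_foamy_latent=z,
        programs={c: list(v) for c, v in programs.items()},
        null_genes=null_genes,
        qc_violators={k: [mat.cell_ids[i] for i in v] for k, v in violators.items()},
        rho=cfg.latent_gene_feature_rho,
    )
    return cells, mat, truth


def _sample_counts(cfg, classes, z, genes, programs, rng):
    """Negative-binomial counts with class marker programs.

    The foamy program is driven multiplicatively by the continuous latent
    ``z`` (which is elevated by ``marker_logfc`` in foamy cells); the other
    programs get a plain exp(marker_logfc) class multiplier.
    """
    n, g = len(classes), len(genes)
    base = rng.lognormal(0.0, 0.6, size=g)
    gene_idx = {name: j for j, name in enumerate(genes)}
    # marker genes are lowly expressed outside their class (panel markers
    # are cell-type specific), which also keeps library sizes comparable
    # across classes once the class multiplier kicks in
    marker_cols = [gene_idx[p] for prog in programs.values() for p in prog]
    base[marker_cols] *= 0.3
    base *= cfg.target_total_counts / base.sum()

    log_mu = np.tile(np.log(base), (n, 1))
    for cls, prog in programs.items():
        cols = [gene_idx[p] for p in prog]
        if cls == "foamy":
            log_mu[:, cols] += z[:, None]
        else:
            log_mu[np.ix_(classes == cls, cols)] += cfg.marker_logfc
            if cls == "homeostatic":
                # homeostatic signature fades continuously as cells become
                # lipid-laden, not just by class membership
                log_mu[:, cols] -= 0.5 * z[:, None]
    mu = np.exp(log_mu)
    alpha = cfg.nb_dispersion
    lam = rng.gamma(1.0 / alpha, alpha * mu)
    return rng.poisson(lam).astype(np.int64)


def _truncated_lognormal(rng, n, mean_log, sd_log, lo, hi):
    out = rng.lognormal(mean_log, sd_log, size=n)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.lognormal(mean_log, sd_log, size=int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def _plant_qc_violators(cfg, raw, blanks, volumes, rng):
    """Rewrite a planted fraction of cells to violate one QC criterion each."""
    n = raw.shape[0]
    n_viol = int(round(cfg.qc_violator_fraction * n))
    violators: dict[str, list[int]] = {k: [] for k in QC_VIOLATION_KINDS}
    if n_viol == 0:
        return violators
    chosen = rng.choice(n, size=n_viol, replace=False)
    thr = QcThresholds()
    for j, i in enumerate(chosen):
        kind = QC_VIOLATION_KINDS[j % len(QC_VIOLATION_KINDS)]
        violators[kind].append(int(i))
        if kind == "low_counts":
            p = raw[i] / max(raw[i].sum(), 1)
            raw[i] = rng.multinomial(thr.min_counts - 5, p)
        elif kind == "high_counts":
            p = raw[i] / max(raw[i].sum(), 1)
            raw[i] = rng.multinomial(thr.max_counts + 500, p)
        elif kind == "low_genes":
            row = np.zeros(raw.shape[1], dtype=np.int64)
            cols = rng.choice(raw.shape[1], size=thr.min_genes - 2, replace=False)
            row[cols] = rng.integers(20, 60, size=len(cols))
            raw[i] = row
        elif kind == "low_volume":
            volumes[i] = rng.uniform(5.0, thr.min_volume - 2.0)
        elif kind == "high_volume":
            volumes[i] = rng.uniform(thr.max_volume + 100, thr.max_volume + 600)
        elif kind == "high_blank":
            blanks[i] = rng.poisson(3.0, size=blanks.shape[1]) + 1
    return violators


# ----------------------------------------------------------------------
# EM section
# ----------------------------------------------------------------------

def _deformation(xy: np.ndarray, bumps: list[dict]) -> np.ndarray:
    """Sum of smooth Gaussian displacement bumps evaluated at xy."""
    out = np.zeros_like(xy, dtype=float)
    for b in bumps:
        d2 = ((xy - np.asarray(b["center"])) ** 2).sum(axis=1)
        w = np.exp(-d2 / (2.0 * b["width"] ** 2))
        out += w[:, None] * np.asarray(b["amp"])
    return out


def true_em_transform(
    xy: np.ndarray, similarity: tuple, bumps: list[dict]
) -> np.ndarray:
    """Map ST-frame coordinates into the deformed EM frame."""
    theta, s, (tx, ty) = similarity
    stage = SimilarityStage.from_params(theta, s, (tx, ty))
    mapped = stage.apply(np.asarray(xy, dtype=float))
    return mapped + _deformation(mapped, bumps)


def generate_em(
    cfg: SynthConfig, st_cells: pd.DataFrame, truth: SynthTruth
) -> tuple[pd.DataFrame, pd.DataFrame, LandmarkSet]:
    """Adjacent-section EM cells, structural features and landmark pairs.

    EM cells are a jittered subsample of the ST cells (adjacent 10 µm
    sections sample largely the same cell somata) mapped through the true
    similarity transform plus a smooth deformation field. Updates
    ``truth`` in place with EM classes, latents, transform parameters and
    landmark provenance.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_st = len(st_cells)
    n_em = min(cfg.n_cells_em, n_st)
    idx = np.sort(rng.choice(n_st, size=n_em, replace=False))
    src_xy = st_cells[["x", "y"]].to_numpy(float)[idx]
    classes = st_cells["class_label"].to_numpy(object)[idx]
    jitter = rng.normal(0.0, cfg.em_jitter_sd, size=src_xy.shape)

    theta, s, _t = cfg.em_similarity
    bumps = []
    for _ in range(cfg.em_n_bumps):
        width = rng.uniform(150.0, 300.0)
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        amp = direction * cfg.em_deform_amp * rng.uniform(0.5, 1.0)
        center = rng.random(2) * np.asarray(cfg.window) * s
        bumps.append({"center": center.tolist(), "width": float(width), "amp": amp.tolist()})
    # Lipschitz bound of the deformation must stay below the similarity
    # scale, otherwise the composed map may fold (non-injective landmarks).
    lip = sum(
        np.linalg.norm(b["amp"]) / (b["width"] * math.sqrt(math.e)) for b in bumps
    )
    if lip >= s:
        raise ValueError(
            f"deformation amplitude too large for injectivity "
            f"(Lipschitz bound {lip:.3f} ≥ scale {s:.3f}); reduce em_deform_amp"
        )

    em_xy = true_em_transform(src_xy + jitter, cfg.em_similarity, bumps)

    # landmark pairs map exactly (no jitter) under the true transform chain
    w, h = cfg.window
    gx = np.linspace(0.1 * w, 0.9 * w, 4)
    gy = np.linspace(0.1 * h, 0.9 * h, 3)
    lm_src = np.array([(x, y) for y in gy for x in gx])[: cfg.n_landmarks]
    if len(lm_src) < cfg.n_landmarks:
        extra = rng.random((cfg.n_landmarks - len(lm_src), 2)) * np.asarray(cfg.window)
        lm_src = np.vstack([lm_src, extra])
    lm_dst = true_em_transform(lm_src, cfg.em_similarity, bumps)
    landmarks = LandmarkSet(source=lm_dst, target=lm_src)  # EM frame → ST frame

    # latents: gene-program latent inherited from the matched ST cells,
    # feature latent correlated at the planted rho
    z = truth.st_foamy_latent[idx]
    z_std = (z - z.mean()) / z.std()
    rho = cfg.latent_gene_feature_rho
    eps = rng.normal(size=n_em)
    feat_latent = rho * z_std + math.sqrt(max(0.0, 1 - rho**2)) * eps

    features = _em_features(cfg, classes, feat_latent, em_xy, rng)

    em_ids = np.array([f"em-{i:05d}" for i in range(n_em)], dtype=object)
    em_cells = new_cell_table(
        em_ids,
        em_xy[:, 0],
        em_xy[:, 1],
        volume=np.nan,
        class_label=classes,
        modality="EM",
    )
    features.insert(0, "cell_id", em_ids)

    truth.em_classes = classes
    truth.em_source_idx = idx
    truth.similarity = cfg.em_similarity
    truth.bumps = bumps
    truth.em_gene_latent = z
    truth.em_feature_latent = feat_latent
    return em_cells, features, landmarks


def _em_features(cfg, classes, feat_latent, em_xy, rng):
    """Per-cell organelle areas (µm²) from class templates.

    Lipid-droplet area is an affine function of the planted feature latent
    (independent of cell size) so the latent→feature Pearson correlation
    survives; all other areas are noisy fractions of whole-cell area.
    """
    n = len(classes)
    rows = {}
    area = np.empty(n)
    for cls in CLASSES:
        m = classes == cls
        if not m.any():
            continue
        t = EM_CLASS_TEMPLATES[cls]
        area[m] = np.maximum(rng.normal(t["area"], 0.12 * t["area"], m.sum()), 20.0)
    rows["whole_cell_area"] = area

    def frac(key, lo=0.0):
        out = np.empty(n)
        for cls in CLASSES:
            m = classes == cls
            if not m.any():
                continue
            f = EM_CLASS_TEMPLATES[cls][key]
            out[m] = np.clip(rng.normal(f, 0.12 * max(f, 1e-3), m.sum()), lo, None)
        return out

    nuc_frac = np.clip(frac("nucleus"), 0.05, 0.8)
    rows["nucleus_area"] = nuc_frac * area
    rows["heterochromatin_area"] = np.clip(frac("hetero"), 0.0, 0.9) * rows["nucleus_area"]
    rows["lysosome_area"] = frac("lyso") * area
    lipid = 20.0 + 12.0 * feat_latent
    rows["lipid_droplet_area"] = np.clip(lipid, 0.5, None)
    rows["mitochondria_area"] = frac("mito") * area
    er = np.empty(n)
    for cls in CLASSES:
        m = classes == cls
        if not m.any():
            continue
        t = EM_CLASS_TEMPLATES[cls]
        er[m] = np.maximum(rng.normal(t["er"], 0.15 * t["er"], m.sum()), 0.0)
    rows["er_length"] = er
    rows["organellar_cytoplasm_area"] = frac("org") * area
    occupied = (
        rows["nucleus_area"]
        + rows["lysosome_area"]
        + rows["lipid_droplet_area"]
        + rows["mitochondria_area"]
        + rows["organellar_cytoplasm_area"]
    )
    rows["empty_cytoplasm_area"] = np.maximum(area - occupied, 0.0)
    df = pd.DataFrame(rows)
    df["x"] = em_xy[:, 0]
    df["y"] = em_xy[:, 1]
    return df


# ----------------------------------------------------------------------
# scRNA-seq + BODIPY
# ----------------------------------------------------------------------

def generate_sc(cfg: SynthConfig) -> tuple[CountsMatrix, np.ndarray, SynthTruth]:
    """Full-transcriptome counts plus a BODIPY-like lipid stain.

    The stain is a strictly positive monotone function of the foamy
    program latent with log-scale Gaussian noise, matching index-sorted
    fluorescence values analysed on a log10 scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    counts_per_class = _class_counts(cfg, cfg.n_cells_sc, rng)
    classes = np.repeat(
        np.array(list(counts_per_class.keys()), dtype=object),
        list(counts_per_class.values()),
    )
    rng.shuffle(classes)
    n = len(classes)
    z = cfg.marker_logfc * (classes == "foamy").astype(float) + rng.normal(0.0, 0.4, n)

    panel, programs = _panel_genes(cfg)
    extra_programs = {}
    extra_names: list[str] = []
    for cls in CLASSES:
        tag = cls.lower().replace("-", "")
        genes = [f"{tag}-sc{i:02d}" for i in range(1, cfg.n_sc_markers_per_class + 1)]
        extra_programs[cls] = genes
        extra_names.extend(genes)
    n_fill = cfg.n_genes_full - cfg.n_genes_panel - len(extra_names)
    if n_fill < 0:
        raise ValueError("n_genes_full too small for panel + sc marker programs")
    extra_names.extend(f"scnull-{i:04d}" for i in range(1, n_fill + 1))
    all_genes = panel + extra_names

    merged = {c: programs[c] + extra_programs[c] for c in CLASSES}
    raw = _sample_counts(cfg, classes, z, all_genes, merged, rng)

    mat = CountsMatrix(
        cell_ids=np.array([f"sc-{i:05d}" for i in range(n)], dtype=object),
        gene_names=np.array(all_genes, dtype=object),
        raw=raw,
    )
    # log10(bodipy) = a + b·z + noise  →  strictly positive, monotone in z
    log10_b = 1.0 + 0.25 * z + rng.normal(0.0, cfg.bodipy_noise_sd, n)
    bodipy = 10.0**log10_b

    truth = SynthTruth(
        st_classes=np.empty(0, dtype=object),
        sc_classes=classes,
        sc_foamy_latent=z,
        programs={c: list(v) for c, v in programs.items()},
        sc_programs={c: list(v) for c, v in extra_programs.items()},
        null_genes=[g for g in all_genes if g.startswith(("gene-", "scnull-"))],
    )
    return mat, bodipy, truth


# ----------------------------------------------------------------------
# bundle
# ----------------------------------------------------------------------

def generate_bundle(cfg: SynthConfig) -> SynthBundle:
    """Generate the full coupled ST + EM + scRNA-seq bundle."""
    st_cells, st_counts, truth = generate_st(cfg)
    em_cells, em_features, landmarks = generate_em(cfg, st_cells, truth)
    sc_counts, bodipy, sc_truth = generate_sc(cfg)
    truth.sc_classes = sc_truth.sc_classes
    truth.sc_foamy_latent = sc_truth.sc_foamy_latent
    truth.sc_programs = sc_truth.sc_programs
    return SynthBundle(
        st_cells=st_cells,
        st_counts=st_counts,
        em_cells=em_cells,
        em_features=em_features,
        landmarks=landmarks,
        sc_counts=sc_counts,
        bodipy=bodipy,
        truth=truth,
    )
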