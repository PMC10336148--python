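"""Spatial statistics: k-NN neighbourhood enrichment and cross-type Ripley's L.

Both statistics compare the observed spatial mixing of cell-class labels
against a random-labelling null that holds positions fixed:

* ``knn_enrichment`` — for every (query, target) class pair, the
  fraction of the target label among the pooled k nearest neighbours of
  query cells, with an empirical p-value and fold enrichment from label
  permutations;
* ``cross_ripley_L`` — Besag's L transform of the cross-type Ripley K
  function in a polygonal window, with pointwise permutation envelopes.
  Centred values (L_obs − mean L_perm) above zero indicate attraction
  between the two classes at that distance, below zero repulsion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon


# ----------------------------------------------------------------------
# neighbourhood enrichment
# ----------------------------------------------------------------------

def knn_enrichment(
    cells: pd.DataFrame,
    k: int = 5,
    n_perm: int = 10_000,
    seed: int = 0,
    min_cells: int = 2,
    chunk: int = 200,
) -> pd.DataFrame:
    """Permutation enrichment of class labels among k nearest neighbours.

    For each query class, the observed fraction of every target label
    among the pooled k-NN (Euclidean, self excluded) of its cells is
    compared against ``n_perm`` label permutations. The one-sided
    empirical p uses the add-one convention,
    p = (1 + #{perm ≥ obs}) / (1 + n_perm), and
    fold_enrichment = observed / mean(permuted). Classes with fewer than
    ``min_cells`` cells are skipped with a warning.

    The caller is expected to restrict ``cells`` to the region of
    interest (e.g. the union of lesion core and edge rings) beforehand.
    """
    rng = np.random.default_rng(seed)
    labels = cells["class_label"].to_numpy(object)
    classes, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    ok = counts >= min_cells
    if not ok.all():
        warnings.warn(
            f"skipping classes with <{min_cells} cells: {list(classes[~ok])}",
            stacklevel=2,
        )
    xy = cells[["x", "y"]].to_numpy(float)
    n, C = len(xy), len(classes)
    k = min(k, n - 1)
    _, nbr = cKDTree(xy).query(xy, k=k + 1)
    nbr = nbr[:, 1:]  # drop self

    def fraction_matrix(code_vec: np.ndarray) -> np.ndarray:
        """(query, target) neighbour-label fractions for one labelling."""
        flat = code_vec[:, None].repeat(k, axis=1) * C + code_vec[nbr]
        m = np.bincount(flat.ravel(), minlength=C * C).reshape(C, C).astype(float)
        denom = counts * k
        return m / np.where(denom > 0, denom, 1)[:, None]

    obs = fraction_matrix(codes)

    perm_sum = np.zeros((C, C))
    perm_ge = np.zeros((C, C))
    done = 0
    while done < n_perm:
        p = min(chunk, n_perm - done)
        keys = rng.random((p, n)).argsort(axis=1)
        lp = codes[keys]  # permuted labels, class sizes preserved
        ql = lp[:, :, None].repeat(k, axis=2)
        tl = lp[:, nbr]
        flat = (np.arange(p)[:, None, None] * C * C + ql * C + tl).ravel()
        m = np.bincount(flat, minlength=p * C * C).reshape(p, C, C).astype(float)
        denom = (counts * k)[None, :, None]
        m = m / np.where(denom > 0, denom, 1)
        perm_sum += m.sum(axis=0)
        perm_ge += (m >= obs[None]).sum(axis=0)
        done += p

    perm_mean = perm_sum / n_perm
    rows = []
    for qi in np.flatnonzero(ok):
        for ti in np.flatnonzero(ok):
            mean = perm_mean[qi, ti]
            rows.append(
                {
                    "query_class": classes[qi],
                    "target_class": classes[ti],
                    "observed_fraction": obs[qi, ti],
                    "fold_enrichment": obs[qi, ti] / mean if mean > 0 else np.nan,
                    "empirical_p": (1.0 + perm_ge[qi, ti]) / (1.0 + n_perm),
                    "n_perm": n_perm,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# cross-type Ripley's L
# ----------------------------------------------------------------------


@dataclass
class RipleyCurve:
    radii: np.ndarray
    L_obs: np.ndarray
    L_perm_mean: np.ndarray
    envelope_lo: np.ndarray
    envelope_hi: np.ndarray
    centered: np.ndarray
    K_obs: np.ndarray
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius": self.radii,
                "K_obs": self.K_obs,
                "L_obs": self.L_obs,
                "L_perm_mean": self.L_perm_mean,
                "envelope_lo": self.envelope_lo,
                "envelope_hi": self.envelope_hi,
                "centered": self.centered,
            }
        )


def _isotropic_weights(pts, pi, pj, d, window: Polygon, n_angles: int = 128):
    """Symmetrized Ripley isotropic correction weights by arc sampling.

    The correction for a pair is 1/f, the reciprocal fraction of the
    circle of radius d around an endpoint that lies inside the window;
    sampled at ``n_angles`` angles and symmetrized over the two
    endpoints so the cross estimator is exactly symmetric in a↔b.
    """
    ang = (np.arange(n_angles) + 0.5) * (2 * np.pi / n_angles)
    ca, sa = np.cos(ang), np.sin(ang)

    def frac_inside(centers, radius):
        xs = centers[:, 0][:, None] + radius[:, None] * ca[None]
        ys = centers[:, 1][:, None] + radius[:, None] * sa[None]
        inside = shapely.intersects_xy(window, xs.ravel(), ys.ravel())
        f = inside.reshape(len(centers), n_angles).mean(axis=1)
        return np.maximum(f, 1.0 / n_angles)

    fi = frac_inside(pts[pi], d)
    fj = frac_inside(pts[pj], d)
    return 0.5 * (1.0 / fi + 1.0 / fj)


def cross_ripley_L(
    cells: pd.DataFrame,
    class_a: str,
    class_b: str,
    window: Polygon,
    radii: np.ndarray | None = None,
    n_perm: int = 200,
    seed: int = 0,
    correction: str = "isotropic",
    envelope_level: float = 0.05,
) -> RipleyCurve:
    """Cross-type Ripley K/L with random-labelling permutation envelopes.

    K_ab(r) = |W| / (n_a n_b) Σ_{i∈a} Σ_{j∈b} w_ij 1[d_ij ≤ r], with
    ``w_ij`` the (symmetrized) isotropic edge-correction weight, or 1
    for ``correction='none'``. L = sqrt(K/π). The null relabels points
    within the pooled two-class set holding positions fixed; envelopes
    are pointwise 2.5/97.5 percentiles at the default 0.05 level.
    """
    if correction not in ("isotropic", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if class_a == class_b:
        raise ValueError("cross_ripley_L requires two distinct classes")
    rng = np.random.default_rng(seed)
    lab = cells["class_label"].to_numpy(object)
    xy = cells[["x", "y"]].to_numpy(float)
    sel = (lab == class_a) | (lab == class_b)
    xy, lab = xy[sel], lab[sel]
    inside = shapely.intersects_xy(window, xy[:, 0], xy[:, 1])
    xy, lab = xy[inside], lab[inside]
    n_a = int((lab == class_a).sum())
    n_b = int((lab == class_b).sum())
    if n_a < 5 or n_b < 5:
        raise ValueError("need ≥5 points of each class inside the window")

    if radii is None:
        radii = np.arange(5.0, 250.0 + 1e-9, 5.0)
    radii = np.asarray(radii, dtype=float)
    minx, miny, maxx, maxy = window.bounds
    diam = float(np.hypot(maxx - minx, maxy - miny))
    if radii[-1] > diam:
        warnings.warn("radius grid exceeds window diameter; truncating", stacklevel=2)
        radii = radii[radii <= diam]

    # all unordered pooled pairs within max radius
    pairs = cKDTree(xy).query_pairs(r=float(radii[-1]), output_type="ndarray")
    pi, pj = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(xy[pi] - xy[pj], axis=1)
    if correction == "isotropic":
        w = _isotropic_weights(xy, pi, pj, d, window)
    else:
        w = np.ones(len(d))
    rbin = np.searchsorted(radii, d)  # first radius index with r >= d
    valid = rbin < len(radii)
    pi, pj, w, rbin = pi[valid], pj[valid], w[valid], rbin[valid]

    area = window.area
    scale = area / (n_a * n_b)
    nr = len(radii)

    def K_of(lab_codes: np.ndarray) -> np.ndarray:
        """K(r) for one labelling; unordered pairs count once per direction."""
        cross = (lab_codes[pi] == 0) & (lab_codes[pj] == 1)
        cross |= (lab_codes[pi] == 1) & (lab_codes[pj] == 0)
        per_bin = np.bincount(rbin[cross], weights=w[cross], minlength=nr)
        return scale * np.cumsum(per_bin)

    codes = (lab == class_b).astype(int)
    K_obs = K_of(codes)
    L_obs = np.sqrt(K_obs / np.pi)

    L_perm = np.empty((n_perm, nr))
    for p in range(n_perm):
        L_perm[p] = np.sqrt(K_of(rng.permutation(codes)) / np.pi)
    lo = np.percentile(L_perm, 100 * envelope_level / 2, axis=0)
    hi = np.percentile(L_perm, 100 * (1 - envelope_level / 2), axis=0)
    mean = L_perm.mean(axis=0)
    return RipleyCurve(
        radii=radii,
        L_obs=L_obs,
        L_perm_mean=mean,
        envelope_lo=lo,
        envelope_hi=hi,
        centered=L_obs - mean,
        K_obs=K_obs,
        n_perm=n_perm,
    )
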