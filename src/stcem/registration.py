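"""Landmark-based 2D registration: rigid / similarity ICP and thin-plate splines.

The alignment of an EM section onto the spatial-transcriptomics frame is
solved in stages, each refining the previous one: a rigid transform
(rotation + translation), a similarity transform (adds isotropic scale),
and finally an interpolating thin-plate-spline warp that absorbs smooth
local deformations. With paired landmarks the rigid/similarity stages
have the closed-form (Umeyama/Procrustes) solution; without
correspondences an ICP loop alternates nearest-neighbour matching and
the closed-form fit, rejecting the worst 10% residuals each iteration.

The TPS stage uses the standard kernel U(r) = r² log r with an affine
part and no smoothing, so it interpolates the landmarks exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class LandmarkSet:
    """Paired (x, y) landmark lists, source → target, in µm."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 2:
            raise ValueError("source/target must be equally sized (n, 2) arrays")
        if len(self.source) < 3:
            raise ValueError("need at least 3 landmark pairs")
        d = np.linalg.norm(self.source[:, None] - self.source[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        if (d < 1e-9).any():
            raise ValueError("duplicate source landmarks")

    def __len__(self) -> int:
        return len(self.source)


# ----------------------------------------------------------------------
# transform stages
# ----------------------------------------------------------------------


@dataclass
class RigidStage:
    R: np.ndarray  # (2, 2), det +1
    t: np.ndarray  # (2,)
    rmse: float = 0.0
    converged: bool = True

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.R.T + self.t

    @property
    def rotation(self) -> float:
        return math.atan2(self.R[1, 0], self.R[0, 0])


@dataclass
class SimilarityStage:
    s: float
    R: np.ndarray
    t: np.ndarray
    rmse: float = 0.0
    converged: bool = True

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return self.s * (np.asarray(pts, dtype=float) @ self.R.T) + self.t

    @property
    def rotation(self) -> float:
        return math.atan2(self.R[1, 0], self.R[0, 0])

    @classmethod
    def from_params(cls, theta: float, s: float, t) -> "SimilarityStage":
        R = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        return cls(s=float(s), R=R, t=np.asarray(t, dtype=float))


@dataclass
class TpsStage:
    """Interpolating thin-plate spline: f(x) = a0 + A x + Σ w_i U(|x − c_i|)."""

    control: np.ndarray  # (n, 2)
    weights: np.ndarray  # (n, 2)
    affine: np.ndarray  # (3, 2) rows: intercept, x, y
    rmse: float = 0.0
    converged: bool = True

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        K = _tps_kernel(pts, self.control)
        P = np.hstack([np.ones((len(pts), 1)), pts])
        return K @ self.weights + P @ self.affine

    def jacobian_sign(self, pts: np.ndarray, h: float = 0.5) -> np.ndarray:
        """Sign of the numerical Jacobian determinant (fold-over < 0)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        fx = (self.apply(pts + [h, 0.0]) - self.apply(pts - [h, 0.0])) / (2 * h)
        fy = (self.apply(pts + [0.0, h]) - self.apply(pts - [0.0, h])) / (2 * h)
        det = fx[:, 0] * fy[:, 1] - fx[:, 1] * fy[:, 0]
        return np.sign(det)


Stage = RigidStage | SimilarityStage | TpsStage


def _tps_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    r2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)  # r² log r = ½ r² log r²
    out[r2 == 0] = 0.0
    return out


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------


def _procrustes(src: np.ndarray, dst: np.ndarray, with_scale: bool):
    """Closed-form least-squares rigid/similarity fit (Umeyama)."""
    mu_s, mu_d = src.mean(0), dst.mean(0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U @ Vt) < 0:
        S[1, 1] = -1.0
    R = U @ S @ Vt
    if with_scale:
        var_s = (xs**2).sum() / len(src)
        s = float(np.trace(np.diag(D) @ S) / var_s)
    else:
        s = 1.0
    t = mu_d - s * (R @ mu_s)
    return s, R, t


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def fit_stage(
    lm: LandmarkSet,
    stage: str,
    *,
    correspondences: bool = True,
    max_iter: int = 100,
    tol: float = 1e-10,
    reject_fraction: float = 0.1,
    smoothing: float = 0.0,
) -> Stage:
    """Fit one transform stage on (already partially aligned) landmarks.

    With ``correspondences=True`` the paired landmarks are used directly
    (closed form for rigid/similarity, linear solve for TPS). With
    ``correspondences=False`` the pairing is withheld and recovered by
    ICP: nearest-neighbour matching against the target cloud, Procrustes
    update, and rejection of the worst ``reject_fraction`` residuals,
    iterated until the rmse improvement drops below ``tol``.
    """
    if stage not in ("rigid", "similarity", "tps"):
        raise ValueError(f"unknown stage {stage!r}")
    src, dst = lm.source, lm.target
    if stage == "tps":
        return _fit_tps(src, dst, smoothing=smoothing)
    with_scale = stage == "similarity"
    if correspondences:
        s, R, t = _procrustes(src, dst, with_scale)
        fitted = s * (src @ R.T) + t
        err = _rmse(fitted, dst)
        if with_scale:
            return SimilarityStage(s=s, R=R, t=t, rmse=err)
        return RigidStage(R=R, t=t, rmse=err)
    return _icp(src, dst, with_scale, max_iter, tol, reject_fraction)


def _icp(src, dst, with_scale, max_iter, tol, reject_fraction):
    tree = cKDTree(dst)
    s, R, t = 1.0, np.eye(2), np.zeros(2)
    cur = src.copy()
    prev_err = np.inf
    converged = False
    for _ in range(max_iter):
        d, j = tree.query(cur)
        keep = np.ones(len(cur), dtype=bool)
        n_rej = int(reject_fraction * len(cur))
        if n_rej and len(cur) - n_rej >= 3:
            keep[np.argsort(d)[-n_rej:]] = False
        s, R, t = _procrustes(src[keep], dst[j[keep]], with_scale)
        cur = s * (src @ R.T) + t
        err = _rmse(cur[keep], dst[j[keep]])
        if abs(prev_err - err) < tol:
            converged = True
            break
        prev_err = err
    else:
        warnings.warn("ICP did not converge within max_iter", stacklevel=2)
    d, j = cKDTree(dst).query(cur)
    err = float(np.sqrt((d**2).mean()))
    if with_scale:
        return SimilarityStage(s=s, R=R, t=t, rmse=err, converged=converged)
    return RigidStage(R=R, t=t, rmse=err, converged=converged)


def _fit_tps(src: np.ndarray, dst: np.ndarray, smoothing: float = 0.0) -> TpsStage:
    n = len(src)
    if n < 3:
        raise ValueError("TPS needs at least 3 landmarks")
    # collinearity check: affine part would be rank-deficient
    P = np.hstack([np.ones((n, 1)), src])
    if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise ValueError("landmarks are collinear; TPS is underdetermined")
    K = _tps_kernel(src, src) + smoothing * np.eye(n)
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = dst
    sol = np.linalg.solve(A, rhs)
    stage = TpsStage(control=src.copy(), weights=sol[:n], affine=sol[n:])
    stage.rmse = _rmse(stage.apply(src), dst)
    return stage


# ----------------------------------------------------------------------
# chains
# ----------------------------------------------------------------------


@dataclass
class TransformChain:
    """Ordered transform stages; applying them in order is the composed map."""

    stages: List[Stage] = field(default_factory=list)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        out = np.atleast_2d(np.asarray(pts, dtype=float))
        for st in self.stages:
            out = st.apply(out)
        return out

    @property
    def rmse_per_stage(self) -> list[float]:
        return [st.rmse for st in self.stages]

    # -- serialization ------------------------------------------------
    def to_json(self) -> str:
        def enc(st):
            if isinstance(st, RigidStage):
                return {"kind": "rigid", "R": st.R.tolist(), "t": st.t.tolist(), "rmse": st.rmse}
            if isinstance(st, SimilarityStage):
                return {
                    "kind": "similarity",
                    "s": st.s,
                    "R": st.R.tolist(),
                    "t": st.t.tolist(),
                    "rmse": st.rmse,
                }
            return {
                "kind": "tps",
                "control": st.control.tolist(),
                "weights": st.weights.tolist(),
                "affine": st.affine.tolist(),
                "rmse": st.rmse,
            }

        return json.dumps({"stages": [enc(s) for s in self.stages]}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TransformChain":
        stages: list[Stage] = []
        for d in json.loads(text)["stages"]:
            if d["kind"] == "rigid":
                stages.append(
                    RigidStage(R=np.array(d["R"]), t=np.array(d["t"]), rmse=d["rmse"])
                )
            elif d["kind"] == "similarity":
                stages.append(
                    SimilarityStage(
                        s=d["s"], R=np.array(d["R"]), t=np.array(d["t"]), rmse=d["rmse"]
                    )
                )
            else:
                stages.append(
                    TpsStage(
                        control=np.array(d["control"]),
                        weights=np.array(d["weights"]),
                        affine=np.array(d["affine"]),
                        rmse=d["rmse"],
                    )
                )
        return cls(stages=stages)


def fit_chain(
    lm: LandmarkSet,
    stages: Sequence[str] = ("rigid", "similarity", "tps"),
    **kwargs,
) -> TransformChain:
    """Fit the staged registration on one landmark set.

    Each stage is fitted on the source landmarks as mapped by the stages
    before it, so the chain composes left to right.
    """
    chain = TransformChain()
    cur = lm.source.copy()
    for name in stages:
        st = fit_stage(LandmarkSet(cur, lm.target), name, **kwargs)
        chain.stages.append(st)
        cur = st.apply(cur)
    return chain


def apply_chain(chain: TransformChain, pts: np.ndarray) -> np.ndarray:
    """Apply a fitted chain; an empty chain is the identity."""
    return chain.apply(pts)
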