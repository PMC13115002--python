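"""Landmark-based 2-D registration: rigid/similarity/affine fits and
regularized thin-plate splines (TPS).

Histology rings are first aligned to their reference slice with a
least-squares rigid (Procrustes) fit on paired anatomical landmarks, then
deformable residual distortion from tissue processing is absorbed by a TPS
whose regularization weight trades landmark residual against bending
energy (lambda = 0 interpolates exactly; lambda -> infinity approaches the
best affine fit).

Points are (x, y) = (column, row), 0-based pixel units. A Transform2D maps
source coordinates to target coordinates; images are resampled by inverse
mapping (for TPS, via a spline fit in the reverse direction, since TPS has
no closed-form inverse).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LandmarkPairs",
    "Transform2D",
    "fit_rigid",
    "fit_affine",
    "fit_tps",
    "transform_points",
    "invert_transform",
    "apply_transform",
    "load_landmarks_csv",
]


@dataclass
class LandmarkPairs:
    """Paired (x, y) landmarks: ``source`` in ring coordinates, ``target``
    in reference-slice coordinates."""

    source: np.ndarray  # (n, 2)
    target: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=np.float64))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=np.float64))
        if self.source.shape != self.target.shape or self.source.shape[1] != 2:
            raise ValueError("source and target must both be (n, 2) point arrays")

    def __len__(self) -> int:
        return len(self.source)

    def swapped(self) -> "LandmarkPairs":
        return LandmarkPairs(self.target.copy(), self.source.copy())


def load_landmarks_csv(path: str) -> LandmarkPairs:
    """Read a landmark file with columns x_src, y_src, x_dst, y_dst."""
    arr = np.genfromtxt(path, delimiter=",", names=True, dtype=np.float64)
    cols = ("x_src", "y_src", "x_dst", "y_dst")
    if arr.dtype.names is None or any(c not in arr.dtype.names for c in cols):
        raise ValueError(f"landmark CSV must have columns {cols}")
    arr = np.atleast_1d(arr)
    src = np.column_stack([arr["x_src"], arr["y_src"]])
    dst = np.column_stack([arr["x_dst"], arr["y_dst"]])
    return LandmarkPairs(src, dst)


@dataclass
class Transform2D:
    """A 2-D spatial mapping p -> A p + t (+ TPS kernel term).

    kind : "rigid" | "similarity" | "affine" | "tps"
    matrix, translation : the linear part (for tps, its affine component)
    control_points, weights : TPS kernel centres and per-axis weights
    lam : TPS regularization (>= 0)
    reverse : for tps, a reverse-direction transform used for image
        resampling (target -> source); None otherwise.
    """

    kind: str
    matrix: np.ndarray
    translation: np.ndarray
    control_points: np.ndarray | None = None
    weights: np.ndarray | None = None
    lam: float = 0.0
    reverse: "Transform2D | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(2)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return transform_points(self, points)

    def to_json(self) -> str:
        d = {
            "kind": self.kind,
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "lam": self.lam,
        }
        if self.control_points is not None:
            d["control_points"] = self.control_points.tolist()
            d["weights"] = self.weights.tolist()
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Transform2D":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            matrix=np.asarray(d["matrix"]),
            translation=np.asarray(d["translation"]),
            control_points=np.asarray(d["control_points"]) if "control_points" in d else None,
            weights=np.asarray(d["weights"]) if "weights" in d else None,
            lam=d.get("lam", 0.0),
        )


def fit_rigid(
    pairs: LandmarkPairs,
    allow_scale: bool = False,
    allow_reflection: bool = False,
) -> Transform2D:
    """Least-squares (Procrustes) rotation + translation, optionally with
    a uniform scale, minimising the mean squared landmark residual.

    Reflections are disallowed by default (histology flips can be enabled
    with ``allow_reflection``). Requires >= 2 pairs with non-coincident
    source points.
    """
    if len(pairs) < 2:
        raise ValueError("rigid fit needs at least 2 landmark pairs")
    src, dst = pairs.source, pairs.target
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    s0, d0 = src - sc, dst - dc
    denom = float(np.sum(s0 * s0))
    if denom == 0:
        raise ValueError("all source landmarks coincide; rotation undefined")
    h = s0.T @ d0
    u, sig, vt = np.linalg.svd(h)
    d = np.ones(2)
    if not allow_reflection and np.linalg.det(vt.T @ u.T) < 0:
        d[-1] = -1.0
    rot = vt.T @ np.diag(d) @ u.T
    scale = float(np.sum(sig * d) / denom) if allow_scale else 1.0
    a = scale * rot
    t = dc - a @ sc
    return Transform2D(kind="similarity" if allow_scale else "rigid", matrix=a, translation=t)


def fit_affine(pairs: LandmarkPairs) -> Transform2D:
    """Least-squares general affine fit; needs >= 3 non-collinear pairs."""
    if len(pairs) < 3:
        raise ValueError("affine fit needs at least 3 landmark pairs")
    src = pairs.source
    p = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(p) < 3:
        raise ValueError("source landmarks are collinear; affine fit degenerate")
    sol, *_ = np.linalg.lstsq(p, pairs.target, rcond=None)
    return Transform2D(kind="affine", matrix=sol[:2].T, translation=sol[2])


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r = 0.5 r^2 log r^2, with U(0) = 0
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = 0.5 * r2[nz] * np.log(r2[nz])
    return out


def _fit_tps_oneway(src: np.ndarray, dst: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(src)
    d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=-1)
    k = _tps_kernel(d2)
    p = np.column_stack([np.ones(n), src])
    if np.linalg.matrix_rank(p) < 3:
        raise ValueError("landmarks are collinear; TPS degenerate")
    sys = np.zeros((n + 3, n + 3))
    sys[:n, :n] = k + lam * np.eye(n)
    sys[:n, n:] = p
    sys[n:, :n] = p.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = dst
    sol = np.linalg.solve(sys, rhs)
    w = sol[:n]  # kernel weights, satisfy P^T w = 0 (side conditions)
    affine = sol[n:]  # rows: constant, x, y
    matrix = affine[1:].T
    translation = affine[0]
    return w, matrix, translation


def fit_tps(pairs: LandmarkPairs, lam: float = 0.0) -> Transform2D:
    """Regularized thin-plate-spline mapping source -> target.

    lam = 0 interpolates the landmarks exactly; lam > 0 smooths, trading
    residual against bending energy. Needs >= 3 non-collinear pairs.
    A reverse-direction TPS (target -> source) is fitted alongside for
    image resampling by inverse mapping.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if len(pairs) < 3:
        raise ValueError("TPS needs at least 3 landmark pairs")
    w, a, t = _fit_tps_oneway(pairs.source, pairs.target, lam)
    wr, ar, tr = _fit_tps_oneway(pairs.target, pairs.source, lam)
    rev = Transform2D(kind="tps", matrix=ar, translation=tr,
                      control_points=pairs.target.copy(), weights=wr, lam=lam)
    return Transform2D(kind="tps", matrix=a, translation=t,
                       control_points=pairs.source.copy(), weights=w, lam=lam,
                       reverse=rev)


def transform_points(t: Transform2D, points: np.ndarray) -> np.ndarray:
    """Map (n, 2) points through the transform."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = pts @ t.matrix.T + t.translation
    if t.kind == "tps":
        d2 = np.sum((pts[:, None, :] - t.control_points[None, :, :]) ** 2, axis=-1)
        out = out + _tps_kernel(d2) @ t.weights
    return out


def bending_energy(t: Transform2D) -> float:
    """TPS bending energy w^T K w (summed over x and y); 0 for linear maps."""
    if t.kind != "tps":
        return 0.0
    d2 = np.sum((t.control_points[:, None, :] - t.control_points[None, :, :]) ** 2, axis=-1)
    k = _tps_kernel(d2)
    return float(np.sum(t.weights * (k @ t.weights)))


def invert_transform(t: Transform2D) -> Transform2D:
    """Closed-form inverse for linear transforms; the reverse-direction
    spline for TPS."""
    if t.kind == "tps":
        if t.reverse is None:
            raise ValueError("TPS transform carries no reverse-direction fit")
        return t.reverse
    a_inv = np.linalg.inv(t.matrix)
    return Transform2D(kind=t.kind, matrix=a_inv, translation=-a_inv @ t.translation)


def apply_transform(
    grid: np.ndarray,
    t: Transform2D,
    target_shape: tuple[int, int],
    interpolation: str = "nearest",
    fill: float = 0.0,
) -> np.ndarray:
    """Resample ``grid`` onto the target lattice under the transform.

    The output at target pixel p is grid[t^-1(p)] (inverse mapping);
    samples falling outside the source domain get ``fill``. Binary masks
    and density grids should use nearest interpolation so the value range
    is preserved.
    """
    if interpolation not in ("nearest", "bilinear"):
        raise ValueError("interpolation must be 'nearest' or 'bilinear'")
    th, tw = target_shape
    if th < 1 or tw < 1:
        raise ValueError("target_shape must be positive")
    grid = np.asarray(grid)
    inv = invert_transform(t)
    yy, xx = np.mgrid[0:th, 0:tw]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    src = transform_points(inv, pts)
    sx = src[:, 0].reshape(th, tw)
    sy = src[:, 1].reshape(th, tw)
    order = 0 if interpolation == "nearest" else 1

    def _sample(channel: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            channel.astype(np.float64), [sy, sx],
            order=order, mode="constant", cval=fill,
        )

    if grid.ndim == 2:
        out = _sample(grid)
        if order == 0 and grid.dtype != np.float64:
            out = out.astype(grid.dtype)
        return out
    if grid.ndim == 3:
        out = np.stack([_sample(grid[..., c]) for c in range(grid.shape[2])], axis=-1)
        if order == 0 and grid.dtype != np.float64:
            out = out.astype(grid.dtype)
        return out
    raise ValueError("grid must be 2-D or 3-D (H, W[, C])")
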