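"""The 3D Local Weighted Mean (LWM) scattered-landmark transformation.

Given N control-point correspondences (x_i, y_i, z_i) -> (X_i, Y_i, Z_i),
one second-order 3D polynomial with ten coefficients (monomial basis
1, x, y, z, x^2, y^2, z^2, xy, xz, yz) is least-squares fitted per control
point over that point and its (n - 1) nearest neighbours, separately for
each output component.  A query point p is then mapped to the weighted mean
of all local polynomials whose influence region covers p,

    X(p) = sum_i W(d_i / R_i) Poly_i(p)  /  sum_i W(d_i / R_i),

with d_i the distance from p to control point i, R_i the influence radius,
and the C^1 weight kernel

    W(R) = 1 - 3 R^2 + 2 R^3   for 0 <= R <= 1,   W(R) = 0 for R > 1,

whose derivative vanishes at R = 0 and R = 1, making the weighted mean
smooth everywhere, including across influence-region boundaries.  Because no
global system is solved, the transformation adapts to local geometric
differences and is insensitive to irregular control-point spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["weight", "LWMTransform", "fit_lwm"]

N_COEFFS = 10  # second-order 3D polynomial

#: Influence-radius conventions.  "control" (the default) stores, per control
#: point i, the distance from i to its (n-1)-th nearest control point.
#: "evaluation" recomputes the radius at each query point p as the distance
#: from p to its (n-1)-th nearest control point, which makes the radius a
#: field over the image rather than a property of the landmarks.
RADIUS_MODES = ("control", "evaluation")


def weight(R) -> np.ndarray | float:
    """C^1 weight kernel of the normalized distance R (unitless, >= 0)."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("normalized distance R must be >= 0")
    w = np.where(R <= 1.0, 1.0 - 3.0 * R**2 + 2.0 * R**3, 0.0)
    return float(w) if w.ndim == 0 else w


def _monomials(d: np.ndarray) -> np.ndarray:
    """Second-order monomial basis of centered offsets d = p - p_i, shape (..., 10)."""
    x, y, z = d[..., 0], d[..., 1], d[..., 2]
    return np.stack(
        [np.ones_like(x), x, y, z, x * x, y * y, z * z, x * y, x * z, y * z], axis=-1
    )


@dataclass
class LWMTransform:
    """A fitted LWM map, evaluable at any 3D point.

    Coefficients are stored in centered form: ``Poly_i`` acts on offsets
    ``p - source[i]`` (centering improves conditioning without changing the
    represented polynomial).
    """

    source: np.ndarray  # (N, 3) control points in the input space
    target: np.ndarray  # (N, 3) mapped points
    n: int  # local neighborhood size
    coeffs: np.ndarray  # (N, 3, 10)
    radii: np.ndarray  # (N,) influence radii (same units as source)
    direction: str = "moving_to_reference"
    radius_mode: str = "control"
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float).reshape(-1, 3)
        self.target = np.asarray(self.target, dtype=float).reshape(-1, 3)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if self.coeffs.shape != (len(self.source), 3, N_COEFFS):
            raise ValueError("coeffs must have shape (N, 3, 10)")
        if np.any(self.radii <= 0):
            raise ValueError("influence radii must be positive")
        if self.radius_mode not in RADIUS_MODES:
            raise ValueError(f"radius_mode must be one of {RADIUS_MODES}")

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.source)
        return self._tree

    def _poly(self, idx: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Evaluate polynomials of control points ``idx`` at one point p -> (k, 3)."""
        mono = _monomials(p[None, :] - self.source[idx])  # (k, 10)
        return np.einsum("kcj,kj->kc", self.coeffs[idx], mono)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Map points (.., 3) through the transformation."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = np.empty_like(pts)
        rmax = float(self.radii.max())
        if self.radius_mode == "evaluation":
            k = min(self.n - 1, len(self.source))
            d_eval, _ = self.tree.query(pts, k=k)
            eval_radii = np.atleast_2d(d_eval)[:, -1]
            rmax = float(eval_radii.max())
        neighbor_lists = self.tree.query_ball_point(pts, rmax)
        for j, idx in enumerate(neighbor_lists):
            p = pts[j]
            idx = np.asarray(idx, dtype=int)
            if idx.size:
                d = np.linalg.norm(self.source[idx] - p, axis=1)
                R = self.radii[idx] if self.radius_mode == "control" else eval_radii[j]
                w = weight(d / R)
                pos = w > 0.0
            else:
                pos = np.zeros(0, dtype=bool)
            if not np.any(pos):
                # p beyond every influence region: fall back to the nearest
                # control point's polynomial (keeps the map total).
                _, i0 = self.tree.query(p)
                out[j] = self._poly(np.array([i0]), p)[0]
                continue
            vals = self._poly(idx[pos], p)
            wp = w[pos]
            out[j] = wp @ vals / wp.sum()
        return out[0] if single else out.reshape(np.asarray(points, dtype=float).shape)

    __call__ = evaluate

    def jacobian(self, points: np.ndarray, h: float = 0.25) -> np.ndarray:
        """Central finite-difference Jacobian(s) at points, shape (.., 3, 3).

        Exact (to rounding) for globally affine maps; O(h^2) otherwise.
        """
        if h <= 0:
            raise ValueError("step h must be positive")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = len(pts)
        probes = np.repeat(pts, 6, axis=0)
        for ax in range(3):
            probes[2 * ax::6, ax] += h
            probes[2 * ax + 1::6, ax] -= h
        vals = self.evaluate(probes).reshape(m, 6, 3)
        J = np.empty((m, 3, 3))
        for ax in range(3):
            J[:, :, ax] = (vals[:, 2 * ax] - vals[:, 2 * ax + 1]) / (2 * h)
        return J[0] if np.asarray(points).ndim == 1 else J

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "lwm-transform-v1",
            "direction": self.direction,
            "n": int(self.n),
            "radius_mode": self.radius_mode,
            "centering": "per-control-point",
            "basis": "1,x,y,z,x2,y2,z2,xy,xz,yz",
            "source": self.source.tolist(),
            "target": self.target.tolist(),
            "coeffs": self.coeffs.tolist(),
            "radii": self.radii.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LWMTransform":
        return cls(
            source=np.array(d["source"]),
            target=np.array(d["target"]),
            n=int(d["n"]),
            coeffs=np.array(d["coeffs"]),
            radii=np.array(d["radii"]),
            direction=d.get("direction", "moving_to_reference"),
            radius_mode=d.get("radius_mode", "control"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "LWMTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_lwm(
    source: np.ndarray,
    target: np.ndarray,
    n: int = 100,
    *,
    direction: str = "moving_to_reference",
    radius_mode: str = "control",
) -> LWMTransform:
    """Fit per-control-point second-order polynomials by least squares.

    ``source``/``target`` are matched (N, 3) point sets.  Exact-duplicate
    source positions are collapsed (keeping the first occurrence) before
    fitting, since duplicates make neighbourhood design matrices rank
    deficient.  ``n`` defaults to 100 local control points, the neighbourhood
    size at which myocardial tracking error bottoms out on cardiac data;
    n >= 10 is required to determine the ten coefficients.
    """
    source = np.asarray(source, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if len(source) != len(target):
        raise ValueError("source and target must pair one-to-one")
    if n < N_COEFFS:
        raise ValueError(f"neighborhood size n={n} must be >= {N_COEFFS}")
    _, keep = np.unique(np.round(source, 12), axis=0, return_index=True)
    keep.sort()
    source, target = source[keep], target[keep]
    N = len(source)
    if N < n:
        raise ValueError(f"need at least n={n} distinct control points, got {N}")

    tree = cKDTree(source)
    dists, idx = tree.query(source, k=n)
    radii = dists[:, -1].astype(float)  # distance from point i to its (n-1)-th neighbour
    coeffs = np.empty((N, 3, N_COEFFS))
    for i in range(N):
        nb = idx[i]
        A = _monomials(source[nb] - source[i])  # (n, 10)
        sol, _, rank, _ = np.linalg.lstsq(A, target[nb], rcond=None)
        if rank < N_COEFFS:
            raise ValueError(
                f"rank-deficient neighbourhood around control point {i} at "
                f"{tuple(source[i])}: design matrix rank {rank} < {N_COEFFS}"
            )
        coeffs[i] = sol.T  # (3, 10)
    return LWMTransform(
        source=source,
        target=target,
        n=n,
        coeffs=coeffs,
        radii=radii,
        direction=direction,
        radius_mode=radius_mode,
    )
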