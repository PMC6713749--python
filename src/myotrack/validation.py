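"""Tracking-accuracy metrics: landmark error, inter-observer consensus
filtering, and point-to-surface displacement.

Landmark tracking error is the per-landmark, per-frame Euclidean distance
(mm) between predicted and ground-truth positions, summarised by median and
maximum over three frame categories: all tracked frames, the end-systolic
frame(s), and the final frame(s).

Consensus filtering reproduces the ground-truth selection rule used with
manually annotated landmarks from two observers: a landmark qualifies if
(a) each observer's final position is relatively close to the initial
position and (b) the two observers' final positions are relatively close to
each other, where "relatively close" means strictly below the 75th
percentile (nearest-rank) of the pooled population of all such distances.

Point-to-surface distance is the exact minimum Euclidean distance from a
point to a triangulated surface (closest point on any triangle, not merely
the closest vertex); it is the displacement measure used to compare
end-systolic against final-frame wall motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import LandmarkTrajectories, SurfaceMesh

__all__ = [
    "ErrorSummary",
    "landmark_error",
    "nearest_rank_percentile",
    "consensus_landmarks",
    "point_to_surface",
]


@dataclass
class ErrorSummary:
    """Per-landmark/per-frame tracking errors (mm) with category summaries."""

    errors: np.ndarray  # (L, T) mm
    frames_all: np.ndarray  # frame indices counted in the "all" category
    frames_end_systolic: np.ndarray
    frames_final: np.ndarray

    def _cat(self, frames: np.ndarray) -> np.ndarray:
        return self.errors[:, frames].ravel()

    @property
    def medians(self) -> dict[str, float]:
        return {
            "all": float(np.median(self._cat(self.frames_all))),
            "end_systolic": float(np.median(self._cat(self.frames_end_systolic))),
            "final": float(np.median(self._cat(self.frames_final))),
        }

    @property
    def maxima(self) -> dict[str, float]:
        return {
            "all": float(np.max(self._cat(self.frames_all))),
            "end_systolic": float(np.max(self._cat(self.frames_end_systolic))),
            "final": float(np.max(self._cat(self.frames_final))),
        }

    def to_dict(self) -> dict:
        return {
            "units": "mm",
            "median": self.medians,
            "max": self.maxima,
            "n_landmarks": int(self.errors.shape[0]),
            "frames_all": [int(f) for f in self.frames_all],
            "frames_end_systolic": [int(f) for f in self.frames_end_systolic],
            "frames_final": [int(f) for f in self.frames_final],
        }


def landmark_error(
    predicted: LandmarkTrajectories,
    truth: LandmarkTrajectories,
    end_systolic_index: int,
    final_index: int | None = None,
    reference_index: int = 0,
) -> ErrorSummary:
    """Euclidean tracking error per landmark and frame, in mm.

    The "all frames" category excludes the reference frame, where both
    trajectories start from the same positions by construction and the error
    is identically zero.
    """
    if predicted.ids != truth.ids:
        raise ValueError("landmark ID sets differ between predicted and truth")
    if predicted.n_frames != truth.n_frames:
        raise ValueError("frame counts differ between predicted and truth")
    T = truth.n_frames
    if final_index is None:
        final_index = T - 1
    if not (0 <= end_systolic_index < T and 0 <= final_index < T):
        raise ValueError("frame indices out of range")
    errors = np.linalg.norm(predicted.positions - truth.positions, axis=2)  # (L, T)
    frames_all = np.array([t for t in range(T) if t != reference_index], dtype=int)
    if frames_all.size == 0:
        frames_all = np.arange(T)
    return ErrorSummary(
        errors=errors,
        frames_all=frames_all,
        frames_end_systolic=np.array([end_systolic_index], dtype=int),
        frames_final=np.array([final_index], dtype=int),
    )


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * M)-th smallest value."""
    values = np.sort(np.asarray(values, dtype=float).ravel())
    if values.size == 0:
        raise ValueError("empty value set")
    rank = int(np.ceil(q / 100.0 * values.size))
    rank = min(max(rank, 1), values.size)
    return float(values[rank - 1])


def consensus_landmarks(
    obs1: LandmarkTrajectories,
    obs2: LandmarkTrajectories,
    percentile: float = 75.0,
    strict: bool = True,
) -> tuple[list[str], dict]:
    """Ground-truth landmark IDs by two-observer consensus.

    Per landmark, three distances are measured: each observer's final-vs-
    initial distance and the inter-observer distance between final
    positions.  All 3L distances are pooled; a landmark qualifies iff all
    three of its distances fall below the pooled percentile (strictly, by
    default).  Returns the qualifying IDs plus a detail dict.
    """
    if obs1.ids != obs2.ids:
        raise ValueError("observers annotate different landmark IDs")
    if obs1.n_frames != obs2.n_frames:
        raise ValueError("observers cover different frame sets")
    if obs1.n_landmarks < 2:
        raise ValueError("need at least 2 landmarks for consensus filtering")
    d1 = np.linalg.norm(obs1.positions[:, -1] - obs1.positions[:, 0], axis=1)
    d2 = np.linalg.norm(obs2.positions[:, -1] - obs2.positions[:, 0], axis=1)
    d12 = np.linalg.norm(obs1.positions[:, -1] - obs2.positions[:, -1], axis=1)
    pooled = np.concatenate([d1, d2, d12])
    thr = nearest_rank_percentile(pooled, percentile)
    per_lm = np.stack([d1, d2, d12], axis=1)
    if strict:
        ok = np.all(per_lm < thr, axis=1)
    else:
        ok = np.all(per_lm <= thr, axis=1)
    ids = [lid for lid, good in zip(obs1.ids, ok) if good]
    if not ids:
        warnings.warn(
            "consensus filter selected no landmarks (degenerate distance "
            "population, e.g. identical static observers)",
            stacklevel=2,
        )
    detail = {
        "threshold": thr,
        "pooled_distances": pooled,
        "per_landmark": {lid: per_lm[i] for i, lid in enumerate(obs1.ids)},
    }
    return ids, detail


def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances from each point to its nearest among all triangles.

    ``tri`` has shape (M, 3, 3).  Vectorised closest-point-on-triangle with
    barycentric region clamping; O(P*M) memory per chunk.
    """
    A = tri[:, 0]
    E0 = tri[:, 1] - A
    E1 = tri[:, 2] - A
    a = np.einsum("ij,ij->i", E0, E0)
    b = np.einsum("ij,ij->i", E0, E1)
    c = np.einsum("ij,ij->i", E1, E1)
    det = np.maximum(a * c - b * b, 1e-300)
    out = np.empty(len(points))
    chunk = max(1, int(2e6 / max(len(tri), 1)))
    for lo in range(0, len(points), chunk):
        P = points[lo : lo + chunk]
        D = A[None, :, :] - P[:, None, :]  # (p, m, 3)
        d = np.einsum("mj,pmj->pm", E0, D)
        e = np.einsum("mj,pmj->pm", E1, D)
        s = b * e - c * d
        t = b * d - a * e
        # clamp (s, t) barycentric coordinates to the triangle domain
        s = s / det
        t = t / det
        # interior region
        inside = (s >= 0) & (t >= 0) & (s + t <= 1)
        # project onto each edge and take the best of all candidates
        # edge AB: t=0, s = clip(-d/a)
        s_ab = np.clip(-d / a, 0.0, 1.0)
        # edge AC: s=0, t = clip(-e/c)
        t_ac = np.clip(-e / c, 0.0, 1.0)
        # edge BC: param u along B->C
        # Q(u) = A + E0 + u (E1 - E0); minimise |Q - P|
        E2 = E1 - E0
        ee = np.einsum("mj,mj->m", E2, E2)
        u = np.clip(
            -(np.einsum("mj,pmj->pm", E2, D + E0[None, :, :])) / np.maximum(ee, 1e-300),
            0.0,
            1.0,
        )

        def dist2(ss, tt):
            # |A + ss E0 + tt E1 - P|^2 via the quadratic form
            return (
                a * ss * ss
                + 2 * b * ss * tt
                + c * tt * tt
                + 2 * d * ss
                + 2 * e * tt
                + np.einsum("pmj,pmj->pm", D, D)
            )

        cands = np.stack(
            [
                np.where(inside, dist2(s, t), np.inf),
                dist2(s_ab, np.zeros_like(s_ab)),
                dist2(np.zeros_like(t_ac), t_ac),
                dist2(1.0 - u, u),
            ]
        )
        out[lo : lo + chunk] = np.sqrt(np.clip(cands.min(axis=0).min(axis=1), 0.0, None))
    return out


def point_to_surface(points: np.ndarray, surface: SurfaceMesh) -> np.ndarray:
    """Minimum Euclidean distance (mm) from each point to the surface."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if surface.triangles.size == 0:
        raise ValueError("surface mesh has no triangles")
    tri = surface.nodes[surface.triangles]  # (M, 3, 3)
    return _point_triangle_distances(points, tri)
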