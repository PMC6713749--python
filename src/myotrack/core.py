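"""Shared domain types and coordinate conventions.

Conventions used throughout the package:

* Voxel indices are 0-based.  A block ``[origin, origin + size)`` is
  half-open on each axis, so blocks of size ``s`` tile exactly.
* Image arrays are indexed ``[x, y, z]``; a coordinate triple always means
  ``(x, y, z)`` in that array order.
* All geometry (meshes, landmarks, strain) is carried in millimetres; image
  operations act on the voxel grid.  Conversion uses the voxel spacing with
  the image origin at voxel ``(0, 0, 0)``:  ``mm = voxel * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "VolumeSequence",
    "BlockSpec",
    "HierarchyParams",
    "SurfaceMesh",
    "LandmarkTrajectories",
    "LEVELS",
    "voxel_to_mm",
    "mm_to_voxel",
]

#: Nested block levels of the matching hierarchy, largest first.  Each level
#: halves the edge length of the previous one (t, t/2, t/4, t/8).
LEVELS = ("template", "segment", "chunk", "window")

_CHILD_LEVEL = {"template": "segment", "segment": "chunk", "chunk": "window"}


def voxel_to_mm(points: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Convert voxel coordinates to millimetres (origin at voxel 0,0,0)."""
    return np.asarray(points, dtype=float) * np.asarray(spacing, dtype=float)


def mm_to_voxel(points: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Convert millimetre coordinates to (fractional) voxel coordinates."""
    return np.asarray(points, dtype=float) / np.asarray(spacing, dtype=float)


@dataclass
class VolumeSequence:
    """A time-ordered sequence of 3D scalar volumes sharing one grid.

    Frame ``reference_index`` (default 0) is the end-diastolic reference; the
    most contracted phase is ``end_systolic_index``.
    """

    frames: np.ndarray  # (T, nx, ny, nz) float array
    voxel_spacing: tuple[float, float, float]
    end_systolic_index: int
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError(
                f"frames must be a (T, nx, ny, nz) array, got shape {self.frames.shape}"
            )
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be 3 positive values, got {self.voxel_spacing}")
        if not 0 <= self.end_systolic_index < self.n_frames:
            raise ValueError(
                f"end_systolic_index {self.end_systolic_index} outside [0, {self.n_frames})"
            )
        if not 0 <= self.reference_index < self.n_frames:
            raise ValueError(f"reference_index {self.reference_index} outside frame range")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[1:]

    @property
    def reference(self) -> np.ndarray:
        return self.frames[self.reference_index]

    def frame(self, t: int) -> np.ndarray:
        return self.frames[t]

    def voxel_to_mm(self, points: np.ndarray) -> np.ndarray:
        return voxel_to_mm(points, self.voxel_spacing)

    def mm_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return mm_to_voxel(points, self.voxel_spacing)


@dataclass(frozen=True)
class BlockSpec:
    """A cubic image block, half-open: ``[origin, origin + size)`` per axis."""

    origin: tuple[int, int, int]
    size: int
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS and self.level != "overlap":
            raise ValueError(f"unknown block level {self.level!r}")
        if self.size <= 0:
            raise ValueError("block size must be positive")
        object.__setattr__(self, "origin", tuple(int(o) for o in self.origin))

    @property
    def end(self) -> tuple[int, int, int]:
        return tuple(o + self.size for o in self.origin)

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + self.size) for o in self.origin)

    def inside(self, shape: Sequence[int]) -> bool:
        return all(o >= 0 and o + self.size <= s for o, s in zip(self.origin, shape))

    def contains(self, other: "BlockSpec") -> bool:
        return all(
            so >= o and so + other.size <= o + self.size
            for so, o in zip(other.origin, self.origin)
        )

    def children(self) -> list["BlockSpec"]:
        """The 8 half-size sub-blocks that exactly tile this block."""
        if self.level not in _CHILD_LEVEL:
            raise ValueError(f"{self.level!r} blocks have no children")
        if self.size % 2:
            raise ValueError("block size must be even to subdivide")
        h = self.size // 2
        lvl = _CHILD_LEVEL[self.level]
        out = []
        for dx in (0, h):
            for dy in (0, h):
                for dz in (0, h):
                    out.append(
                        BlockSpec(
                            (self.origin[0] + dx, self.origin[1] + dy, self.origin[2] + dz),
                            h,
                            lvl,
                        )
                    )
        return out

    @property
    def representative_point(self) -> tuple[int, int, int]:
        """The block's first (minimum-index) corner, used as its landmark."""
        return self.origin


@dataclass
class HierarchyParams:
    """Parameters of the template/segment/chunk/window matching hierarchy.

    ``template_size`` must be divisible by 8 so the four levels have integer
    edge lengths.  ``search_radius`` is the half-width (voxels) of the
    template-level search; ``None`` searches the whole reference image.
    ``cc_tolerance`` treats correlation values within this distance of the
    maximum as ties (resolved by smallest displacement).  ``cc_min`` is the
    minimum correlation for a match to be trusted at any hierarchy level —
    a weak peak means the block's content has no reliable counterpart (out
    of field, heavily distorted, or textureless), and the affected windows
    are emitted as non-displaced invalid pairs.
    ``pyramid_agreement_tol`` is the displacement agreement (voxels, Euclidean)
    required between a block and its overlapping validation blocks.
    """

    template_size: int = 16
    search_radius: int | None = 20
    cc_tolerance: float = 1e-6
    cc_min: float = 0.5
    pyramid_agreement_tol: float = 2.0

    def __post_init__(self) -> None:
        if self.template_size <= 0 or self.template_size % 8:
            raise ValueError("template_size must be a positive multiple of 8")
        if self.search_radius is not None and self.search_radius < 0:
            raise ValueError("search_radius must be >= 0 or None")
        if self.cc_tolerance < 0:
            raise ValueError("cc_tolerance must be >= 0")
        if not -1.0 <= self.cc_min <= 1.0:
            raise ValueError("cc_min must lie in [-1, 1]")
        if self.pyramid_agreement_tol < 0:
            raise ValueError("pyramid_agreement_tol must be >= 0")

    @property
    def level_sizes(self) -> dict[str, int]:
        t = self.template_size
        return {"template": t, "segment": t // 2, "chunk": t // 4, "window": t // 8}


def _triangle_normals(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a, b, c = nodes[triangles[:, 0]], nodes[triangles[:, 1]], nodes[triangles[:, 2]]
    return np.cross(b - a, c - a)  # area-weighted (twice the area)


@dataclass
class SurfaceMesh:
    """Triangulated LV surface in millimetres with anatomical anchor points.

    ``apex`` and ``mitral_center`` define the longitudinal axis
    (apex -> mitral-valve centre).  Outward unit normals per node are
    computed as area-weighted averages of incident triangle normals and
    oriented so that, on average, they point away from the mesh centroid.
    """

    nodes: np.ndarray  # (N, 3) mm
    triangles: np.ndarray  # (M, 3) int
    apex: np.ndarray  # (3,) mm
    mitral_center: np.ndarray  # (3,) mm
    normals: np.ndarray | None = None  # (N, 3) unit, outward

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.apex = np.asarray(self.apex, dtype=float)
        self.mitral_center = np.asarray(self.mitral_center, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (M, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.nodes)
        ):
            raise ValueError("triangle indices out of range")
        if np.allclose(self.apex, self.mitral_center):
            raise ValueError("apex and mitral_center must differ")
        if self.normals is None:
            self.normals = self._vertex_normals()
        else:
            self.normals = np.asarray(self.normals, dtype=float)

    def _vertex_normals(self) -> np.ndarray:
        tn = _triangle_normals(self.nodes, self.triangles)
        vn = np.zeros_like(self.nodes)
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], tn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        vn /= norms
        # orient outward: mean projection on (node - centroid) must be positive
        centroid = self.nodes.mean(axis=0)
        if np.mean(np.einsum("ij,ij->i", vn, self.nodes - centroid)) < 0:
            vn = -vn
        return vn

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class LandmarkTrajectories:
    """Per-landmark, per-frame 3D positions in millimetres."""

    positions: np.ndarray  # (L, T, 3) mm
    ids: list[str] = field(default_factory=list)
    observer_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (L, T, 3)")
        if not self.ids:
            self.ids = [f"L{i:02d}" for i in range(self.positions.shape[0])]
        if len(self.ids) != self.positions.shape[0]:
            raise ValueError("ids length must match number of landmarks")

    @property
    def n_landmarks(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(zip(self.ids, self.positions))
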