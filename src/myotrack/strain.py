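"""Mesh tracking, Lagrange strain and directional/eigenvalue strain curves.

The left-ventricle mesh segmented at end-diastole is carried forward through
the cycle with the per-frame LWM transformations (reference -> current).  At
the tracked positions x the displacement u(x, t) = x - X is differentiated
with respect to the *current* coordinates, giving the displacement gradient
U = I - J, where J is the Jacobian of the inverse (current -> reference)
map.  The deformation gradient and Lagrange strain then follow as

    F = (I - U)^(-1),        E = 1/2 (F^T F - I).

Under this (Eulerian-gradient) reading, F equals the true material
deformation gradient, so rigid motions produce E = 0 exactly.

Directional strains project E onto a local cardiac frame: the longitudinal
direction L runs from the apex to the mitral-valve centre (one global
vector); the radial direction at a node is its outward surface normal M with
the longitudinal component removed, R = M - (M.L)L; the circumferential
direction is C = L x R, parallel to the epicardial border in the short-axis
plane.  The projected strain along a unit direction p is E_p = p^T E p.
Aggregate curves report, per frame, the median (or mean) of E_L, E_C, E_R
over the LV nodes, plus the per-frame medians of the three sorted strain
eigenvalues (the principal strains).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SurfaceMesh
from .lwm import LWMTransform

__all__ = [
    "TrackedMesh",
    "StrainField",
    "LocalFrameField",
    "StrainCurves",
    "track_mesh",
    "displacement_gradient",
    "deformation_gradient",
    "lagrange_strain",
    "local_directions",
    "project_strain",
    "strain_fields_for_frames",
    "strain_curves",
    "eigen_analysis",
]

_I3 = np.eye(3)


@dataclass
class TrackedMesh:
    """Per-frame node positions (mm); frame 0 equals the reference mesh."""

    mesh: SurfaceMesh
    positions: np.ndarray  # (T, N, 3) mm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (T, N, 3)")
        if self.positions.shape[1] != self.mesh.n_nodes:
            raise ValueError("node count mismatch with mesh")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def displacements(self, t: int) -> np.ndarray:
        """u = current - reference positions (mm) at frame t."""
        return self.positions[t] - self.positions[0]


@dataclass
class StrainField:
    """Per-node displacement gradient U, deformation gradient F and strain E."""

    frame: int
    U: np.ndarray  # (N, 3, 3)
    F: np.ndarray  # (N, 3, 3)
    E: np.ndarray  # (N, 3, 3) symmetric


@dataclass
class LocalFrameField:
    """Longitudinal/radial/circumferential unit directions per mesh node."""

    L: np.ndarray  # (3,) global longitudinal direction
    R_dir: np.ndarray  # (N, 3) outward radial, perpendicular to L
    C: np.ndarray  # (N, 3) circumferential = L x R
    defined: np.ndarray  # (N,) False where the normal is parallel to L


@dataclass
class StrainCurves:
    """Per-frame aggregate directional strains and median principal strains."""

    E_L: np.ndarray  # (T,)
    E_C: np.ndarray  # (T,)
    E_R: np.ndarray  # (T,)
    eigenvalues: np.ndarray  # (T, 3) medians of sorted eigenvalues
    aggregation: str = "median"


def track_mesh(
    mesh: SurfaceMesh,
    forward_transforms: list[LWMTransform | None],
    voxel_spacing,
) -> TrackedMesh:
    """Carry mesh nodes forward through the cycle.

    ``forward_transforms[t]`` maps reference -> frame t in voxel coordinates
    (``None`` means identity, e.g. at the reference frame itself).  Tracking
    is forward from the reference positions at every frame; mesh coordinates
    are mm and are converted through the voxel spacing.
    """
    spacing = np.asarray(voxel_spacing, dtype=float)
    ref_vox = mesh.nodes / spacing
    positions = np.empty((len(forward_transforms), mesh.n_nodes, 3))
    for t, tr in enumerate(forward_transforms):
        if tr is None:
            positions[t] = mesh.nodes
            continue
        if tr.direction != "reference_to_moving":
            raise ValueError(
                f"frame {t}: forward tracking needs a reference->moving transform, "
                f"got direction {tr.direction!r}"
            )
        positions[t] = tr.evaluate(ref_vox) * spacing
    return TrackedMesh(mesh=mesh, positions=positions)


def displacement_gradient(
    inverse_transform: LWMTransform,
    x: np.ndarray,
    h: float = 0.25,
    voxel_spacing=None,
) -> np.ndarray:
    """Displacement gradient U = du/dx at current-frame point(s) x (voxels).

    ``inverse_transform`` maps current -> reference, so u(x) = x - inv(x) and
    U = I - J with J the inverse map's Jacobian (central differences, step h
    voxels).  With anisotropic spacing the gradient is returned with respect
    to physical (mm) coordinates via U_mm = S U_vox S^-1.
    """
    if inverse_transform.direction != "moving_to_reference":
        raise ValueError(
            "displacement gradient needs a current->reference (moving_to_reference) transform"
        )
    J = inverse_transform.jacobian(x, h=h)
    U = _I3 - J
    if voxel_spacing is not None:
        S = np.diag(np.asarray(voxel_spacing, dtype=float))
        Sinv = np.diag(1.0 / np.asarray(voxel_spacing, dtype=float))
        U = S @ U @ Sinv
    return U


def deformation_gradient(U: np.ndarray) -> np.ndarray:
    """F = (I - U)^(-1), per node.  Raises on (near-)singular I - U."""
    U = np.asarray(U, dtype=float)
    A = _I3 - U
    single = A.ndim == 2
    A = A.reshape(-1, 3, 3)
    dets = np.linalg.det(A)
    bad = np.abs(dets) < 1e-12
    if bad.any():
        i = int(np.argmax(bad))
        cond = np.linalg.cond(A[i])
        raise np.linalg.LinAlgError(
            f"(I - U) singular at node {i} (det={dets[i]:.3e}, cond={cond:.3e})"
        )
    F = np.linalg.inv(A)
    return F[0] if single else F


def lagrange_strain(F: np.ndarray) -> np.ndarray:
    """Lagrange (Green) strain E = 1/2 (F^T F - I), per node."""
    F = np.asarray(F, dtype=float)
    Ft = np.swapaxes(F, -1, -2)
    return 0.5 * (Ft @ F - _I3)


def local_directions(mesh: SurfaceMesh) -> LocalFrameField:
    """Longitudinal / radial / circumferential frame at each mesh node.

    Nodes whose outward normal is (numerically) parallel to L have no
    well-defined radial direction; they are flagged and excluded from
    aggregates.
    """
    L = mesh.mitral_center - mesh.apex
    L = L / np.linalg.norm(L)
    M = mesh.normals
    R = M - (M @ L)[:, None] * L[None, :]
    norms = np.linalg.norm(R, axis=1)
    defined = norms >= 1e-9
    R_dir = np.zeros_like(R)
    R_dir[defined] = R[defined] / norms[defined, None]
    C = np.cross(np.broadcast_to(L, R_dir.shape), R_dir)
    cn = np.linalg.norm(C, axis=1)
    C[defined] = C[defined] / cn[defined, None]
    return LocalFrameField(L=L, R_dir=R_dir, C=C, defined=defined)


def project_strain(E: np.ndarray, p: np.ndarray) -> np.ndarray | float:
    """Projected strain E_p = p^T E p along unit direction(s) p."""
    E = np.asarray(E, dtype=float)
    p = np.asarray(p, dtype=float)
    norms = np.linalg.norm(p, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-9):
        raise ValueError("direction p must be unit length")
    out = np.einsum("...i,...ij,...j->...", p, E, p)
    return float(out) if out.ndim == 0 else out


def strain_fields_for_frames(
    inverse_transforms: list[LWMTransform | None],
    tracked: TrackedMesh,
    voxel_spacing,
    h: float = 0.25,
) -> list[StrainField]:
    """Per-frame strain tensors at the tracked node positions.

    ``inverse_transforms[t]`` maps frame t -> reference in voxel coordinates
    (``None`` = identity).  Gradients are evaluated at the frame-t node
    positions, i.e. in current (deformed) coordinates.
    """
    spacing = np.asarray(voxel_spacing, dtype=float)
    fields = []
    for t, tr in enumerate(inverse_transforms):
        n = tracked.positions.shape[1]
        if tr is None:
            U = np.zeros((n, 3, 3))
        else:
            x_vox = tracked.positions[t] / spacing
            U = displacement_gradient(tr, x_vox, h=h, voxel_spacing=spacing)
        F = deformation_gradient(U)
        E = lagrange_strain(F)
        fields.append(StrainField(frame=t, U=U, F=F, E=E))
    return fields


def eigen_analysis(field: StrainField, sym_tol: float = 1e-8):
    """Sorted (ascending) strain eigenvalues per node and their medians.

    The three principal strains per node are pooled by sorted position
    across nodes and summarised by the median of each set.
    """
    E = np.asarray(field.E, dtype=float)
    asym = np.abs(E - np.swapaxes(E, -1, -2)).max()
    if asym > sym_tol:
        raise ValueError(f"strain tensors asymmetric beyond tolerance ({asym:.3e})")
    vals = np.linalg.eigvalsh(0.5 * (E + np.swapaxes(E, -1, -2)))  # ascending
    return vals, np.median(vals, axis=0)


def strain_curves(
    fields: list[StrainField],
    directions: LocalFrameField,
    aggregation: str = "median",
) -> StrainCurves:
    """Aggregate directional strain and principal-strain curves over frames."""
    if aggregation not in ("median", "mean"):
        raise ValueError("aggregation must be 'median' or 'mean'")
    agg = np.median if aggregation == "median" else np.mean
    ok = directions.defined
    if not ok.any():
        raise ValueError("no nodes with a defined local direction frame")
    T = len(fields)
    E_L = np.empty(T)
    E_C = np.empty(T)
    E_R = np.empty(T)
    eig = np.empty((T, 3))
    Lvec = np.broadcast_to(directions.L, directions.R_dir.shape)
    for t, f in enumerate(fields):
        E = f.E[ok]
        E_L[t] = agg(project_strain(E, Lvec[ok]))
        E_C[t] = agg(project_strain(E, directions.C[ok]))
        E_R[t] = agg(project_strain(E, directions.R_dir[ok]))
        _, eig[t] = eigen_analysis(StrainField(frame=t, U=f.U[ok], F=f.F[ok], E=E))
    return StrainCurves(E_L=E_L, E_C=E_C, E_R=E_R, eigenvalues=eig, aggregation=aggregation)
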