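"""End-to-end orchestration: matching -> LWM fitting -> tracking -> strain.

Thin glue over the library modules, shared by the command-line interface,
the test-suite and reproduction scripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import HierarchyParams, LandmarkTrajectories, SurfaceMesh, VolumeSequence
from .lwm import LWMTransform, fit_lwm
from .matching import ControlPointSet, hierarchical_match
from .strain import (
    LocalFrameField,
    StrainCurves,
    StrainField,
    TrackedMesh,
    local_directions,
    strain_curves,
    strain_fields_for_frames,
    track_mesh,
)

log = logging.getLogger("myotrack")

__all__ = ["TrackingResult", "track_sequence", "strain_analysis", "track_landmarks"]


@dataclass
class TrackingResult:
    """Per-frame control points and fitted LWM transforms (voxel space).

    Index t holds the correspondence frame t -> reference; at the reference
    frame itself the entries are ``None`` (identity).  ``forward[t]`` maps
    reference -> frame t (used for tracking), ``inverse[t]`` maps frame t ->
    reference (used for strain gradients).
    """

    control_points: list[ControlPointSet | None]
    forward: list[LWMTransform | None]
    inverse: list[LWMTransform | None]
    params: HierarchyParams = field(default_factory=HierarchyParams)
    n: int = 100

    @property
    def n_frames(self) -> int:
        return len(self.forward)


def track_sequence(
    volumes: VolumeSequence,
    params: HierarchyParams | None = None,
    n: int = 100,
    *,
    radius_mode: str = "control",
    fit_on: str = "valid",
) -> TrackingResult:
    """Match every frame against the reference and fit LWM transforms.

    Each non-reference frame is the moving image of one hierarchical
    matching pass.  From the resulting window correspondences two LWM
    transforms are fitted per frame: moving -> reference (for strain
    gradients in current coordinates) and reference -> moving (for forward
    mesh tracking).

    ``fit_on`` selects which window pairs feed the fits: "valid" (default)
    uses only pyramid-validated matches — a window that failed validation
    or carried no texture contributes no displacement measurement;
    "informative" additionally includes validation failures as
    non-displaced points; "all" also includes textureless windows as
    non-displaced points.
    """
    params = params or HierarchyParams()
    log.info(
        "tracking %d frames: t=%d search_radius=%s cc_tol=%g pyramid_tol=%g n=%d "
        "radius_mode=%s fit_on=%s",
        volumes.n_frames, params.template_size, params.search_radius,
        params.cc_tolerance, params.pyramid_agreement_tol, n, radius_mode, fit_on,
    )
    reference = volumes.reference
    cps_list: list[ControlPointSet | None] = []
    fwd: list[LWMTransform | None] = []
    inv: list[LWMTransform | None] = []
    for t in range(volumes.n_frames):
        if t == volumes.reference_index:
            cps_list.append(None)
            fwd.append(None)
            inv.append(None)
            continue
        cps = hierarchical_match(volumes.frame(t), reference, params)
        cps_list.append(cps)
        if fit_on == "all":
            use = cps
            m = use.moving.astype(float)
            r = use.reference.astype(float)
        elif fit_on == "informative":
            use = cps.informative()
            m = use.moving.astype(float)
            r = use.reference.astype(float)
        elif fit_on == "valid":
            use = cps
            m = use.moving[use.valid].astype(float)
            r = use.reference[use.valid].astype(float)
        else:
            raise ValueError("fit_on must be 'valid', 'informative' or 'all'")
        inv.append(fit_lwm(m, r, n=n, direction="moving_to_reference", radius_mode=radius_mode))
        fwd.append(fit_lwm(r, m, n=n, direction="reference_to_moving", radius_mode=radius_mode))
        log.info(
            "frame %d: %d control points (%d valid, %d textured)",
            t, len(cps), int(cps.valid.sum()), int((~cps.degenerate).sum()),
        )
    return TrackingResult(cps_list, fwd, inv, params=params, n=n)


def strain_analysis(
    mesh: SurfaceMesh,
    result: TrackingResult,
    volumes: VolumeSequence,
    h: float = 0.25,
    aggregation: str = "median",
) -> tuple[TrackedMesh, list[StrainField], LocalFrameField, StrainCurves]:
    """Track the mesh and compute per-frame strain fields and curves."""
    tracked = track_mesh(mesh, result.forward, volumes.voxel_spacing)
    fields = strain_fields_for_frames(result.inverse, tracked, volumes.voxel_spacing, h=h)
    dirs = local_directions(mesh)
    curves = strain_curves(fields, dirs, aggregation=aggregation)
    return tracked, fields, dirs, curves


def track_landmarks(
    reference_positions_mm: np.ndarray,
    result: TrackingResult,
    volumes: VolumeSequence,
    ids: list[str] | None = None,
    observer_id: str = "tracked",
) -> LandmarkTrajectories:
    """Forward-track reference-frame landmark positions through all frames."""
    spacing = np.asarray(volumes.voxel_spacing, dtype=float)
    ref_vox = np.atleast_2d(np.asarray(reference_positions_mm, dtype=float)) / spacing
    T = result.n_frames
    pos = np.empty((len(ref_vox), T, 3))
    for t in range(T):
        tr = result.forward[t]
        if tr is None:
            pos[:, t, :] = ref_vox * spacing
        else:
            pos[:, t, :] = tr.evaluate(ref_vox) * spacing
    return LandmarkTrajectories(positions=pos, ids=ids or [], observer_id=observer_id)
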