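"""Readers and writers for the on-disk formats the pipeline touches.

Conventions: volumes are NIfTI (one 4D file or a sorted series of 3D
files); meshes are Wavefront OBJ with a small JSON sidecar carrying the
apex/mitral anchor points; landmarks, control points and strain curves are
CSV with a leading comment line declaring units and index base.  Landmark
and mesh coordinates on disk are millimetres in the reference-image frame;
control points are 0-based voxel indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import LandmarkTrajectories, SurfaceMesh, VolumeSequence
from .matching import ControlPointSet
from .strain import StrainCurves, StrainField
from .validation import ErrorSummary

__all__ = [
    "read_volume_sequence",
    "write_volume_sequence",
    "read_mesh",
    "write_mesh",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "write_control_points_csv",
    "read_control_points_csv",
    "write_strain_csv",
    "write_curves_csv",
    "write_summary_json",
    "load_config",
]


def _spacing_from_header(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume_sequence(
    paths, end_systolic_index: int, reference_index: int = 0
) -> VolumeSequence:
    """Load a frame sequence from one 4D NIfTI file or a list of 3D files.

    Per-frame files are used in the order given (sort the list by name for
    the conventional ordering).  All frames must share shape and spacing.
    """
    if isinstance(paths, (str, Path)):
        img = nib.load(str(paths))
        data = np.asanyarray(img.dataobj).astype(float)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise ValueError(f"expected a 3D/4D NIfTI, got shape {data.shape}")
        frames = np.moveaxis(data, -1, 0)
        spacing = _spacing_from_header(img)
    else:
        frames = []
        spacing = None
        for p in paths:
            img = nib.load(str(p))
            arr = np.asanyarray(img.dataobj).astype(float)
            if arr.ndim != 3:
                raise ValueError(f"{p}: expected a 3D volume, got shape {arr.shape}")
            sp = _spacing_from_header(img)
            if spacing is None:
                spacing = sp
                shape = arr.shape
            else:
                if arr.shape != shape:
                    raise ValueError(f"{p}: frame shape {arr.shape} differs from {shape}")
                if not np.allclose(sp, spacing, rtol=1e-6):
                    raise ValueError(f"{p}: voxel spacing {sp} differs from {spacing}")
            frames.append(arr)
        frames = np.stack(frames)
    return VolumeSequence(
        frames=frames,
        voxel_spacing=spacing,
        end_systolic_index=end_systolic_index,
        reference_index=reference_index,
    )


def write_volume_sequence(volumes: VolumeSequence, path) -> None:
    """Write the sequence as one 4D NIfTI file with spacing in the affine."""
    affine = np.diag(list(volumes.voxel_spacing) + [1.0])
    data = np.moveaxis(volumes.frames, 0, -1)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(volumes.voxel_spacing) + (1.0,))
    nib.save(img, str(path))


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write an OBJ file plus a JSON sidecar with the anatomical anchors."""
    import trimesh

    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.nodes, faces=mesh.triangles, process=False)
    tm.export(str(path))
    sidecar = path.with_suffix(".anchors.json")
    sidecar.write_text(
        json.dumps(
            {
                "units": "mm",
                "apex": mesh.apex.tolist(),
                "mitral_center": mesh.mitral_center.tolist(),
            },
            indent=2,
        )
    )


def read_mesh(path, apex=None, mitral_center=None) -> SurfaceMesh:
    """Read a triangulated mesh (OBJ/PLY/STL via trimesh) in mm.

    Anchors come from the ``.anchors.json`` sidecar unless given explicitly;
    without either, they fall back to the extreme nodes along the mesh's
    first principal axis (apex = the end farther from the centroid-weighted
    bulk, mitral = the opposite end).
    """
    import trimesh

    path = Path(path)
    tm = trimesh.load(str(path), process=False, force="mesh")
    nodes = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=int)
    sidecar = path.with_suffix(".anchors.json")
    if apex is None and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        apex = np.asarray(meta["apex"], dtype=float)
        mitral_center = np.asarray(meta["mitral_center"], dtype=float)
    if apex is None:
        # Fallback for an open LV surface: outward normals of a bowl average
        # away from the basal opening, so the long axis (apex -> base) is the
        # negated mean normal; for nearly closed surfaces fall back to the
        # first principal axis of the node cloud.
        probe = SurfaceMesh(nodes=nodes, triangles=faces,
                            apex=nodes.min(axis=0) - 1.0, mitral_center=nodes.max(axis=0) + 1.0)
        mean_n = probe.normals.mean(axis=0)
        if np.linalg.norm(mean_n) > 0.2:
            axis = -mean_n / np.linalg.norm(mean_n)
        else:
            centered = nodes - nodes.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            axis = vt[0]
        proj = nodes @ axis
        span = np.ptp(proj)
        apex = nodes[int(np.argmin(proj))]
        rim = nodes[proj > proj.max() - 0.05 * span]
        mitral_center = rim.mean(axis=0)
    return SurfaceMesh(nodes=nodes, triangles=faces, apex=apex, mitral_center=mitral_center)


_LM_HEADER = "# landmark positions; units: mm; frames 0-based\n"


def write_landmarks_csv(lm: LandmarkTrajectories, path) -> None:
    rows = []
    for i, lid in enumerate(lm.ids):
        for t in range(lm.n_frames):
            x, y, z = lm.positions[i, t]
            rows.append({"landmark_id": lid, "frame": t, "x": x, "y": y, "z": z})
    with open(path, "w") as fh:
        fh.write(_LM_HEADER)
        pd.DataFrame(rows).to_csv(fh, index=False, lineterminator="\n")


def read_landmarks_csv(path, observer_id: str = "") -> LandmarkTrajectories:
    df = pd.read_csv(path, comment="#")
    ids = list(dict.fromkeys(df["landmark_id"]))
    frames = sorted(df["frame"].unique())
    pos = np.empty((len(ids), len(frames), 3))
    for i, lid in enumerate(ids):
        sub = df[df["landmark_id"] == lid].sort_values("frame")
        if list(sub["frame"]) != frames:
            raise ValueError(f"landmark {lid!r} does not cover the common frame set")
        pos[i] = sub[["x", "y", "z"]].to_numpy()
    return LandmarkTrajectories(positions=pos, ids=ids, observer_id=observer_id)


def write_control_points_csv(cps: ControlPointSet, frame: int, path) -> None:
    with open(path, "w") as fh:
        fh.write("# control points; units: voxels, 0-based; m=moving, r=reference\n")
        pd.DataFrame(
            {
                "frame": frame,
                "mx": cps.moving[:, 0], "my": cps.moving[:, 1], "mz": cps.moving[:, 2],
                "rx": cps.reference[:, 0], "ry": cps.reference[:, 1], "rz": cps.reference[:, 2],
                "cc": cps.cc,
                "valid": cps.valid.astype(int),
                "degenerate": cps.degenerate.astype(int),
            }
        ).to_csv(fh, index=False, lineterminator="\n")


def read_control_points_csv(path) -> ControlPointSet:
    df = pd.read_csv(path, comment="#")
    return ControlPointSet(
        moving=df[["mx", "my", "mz"]].to_numpy(),
        reference=df[["rx", "ry", "rz"]].to_numpy(),
        cc=df["cc"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
        degenerate=df["degenerate"].to_numpy().astype(bool),
    )


def write_strain_csv(fields: list[StrainField], path) -> None:
    rows = []
    for f in fields:
        E = f.E
        eig = np.linalg.eigvalsh(0.5 * (E + np.swapaxes(E, -1, -2)))
        for i in range(len(E)):
            rows.append(
                {
                    "frame": f.frame, "node": i,
                    "Exx": E[i, 0, 0], "Eyy": E[i, 1, 1], "Ezz": E[i, 2, 2],
                    "Exy": E[i, 0, 1], "Exz": E[i, 0, 2], "Eyz": E[i, 1, 2],
                    "eig1": eig[i, 0], "eig2": eig[i, 1], "eig3": eig[i, 2],
                }
            )
    with open(path, "w") as fh:
        fh.write("# per-node Lagrange strain tensors; unitless; nodes/frames 0-based\n")
        pd.DataFrame(rows).to_csv(fh, index=False, lineterminator="\n")


def write_curves_csv(curves: StrainCurves, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# aggregate strain curves ({curves.aggregation} over nodes); "
            "unitless; frames 0-based\n"
        )
        pd.DataFrame(
            {
                "frame": np.arange(len(curves.E_L)),
                "E_L": curves.E_L, "E_C": curves.E_C, "E_R": curves.E_R,
                "eig1": curves.eigenvalues[:, 0],
                "eig2": curves.eigenvalues[:, 1],
                "eig3": curves.eigenvalues[:, 2],
            }
        ).to_csv(fh, index=False, lineterminator="\n")


def write_summary_json(summary: ErrorSummary, path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2))


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    import yaml

    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
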