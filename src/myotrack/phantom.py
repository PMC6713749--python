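"""Synthetic 3D+t tagged left-ventricle phantoms with exact ground truth.

The phantom is a half-ellipsoidal LV wall (apex pointing down the long
axis) carrying a 3D tag-grid intensity pattern — the product of three
cosines, emulating the dark/bright tag lattice of 3D tagged MRI — on a
constant background.  Frames are deformed by an analytic, invertible motion
composed in shell-centred cylindrical coordinates of

1. a circumferential twist, scaled linearly along the long axis (zero at
   the apex, full at the base),
2. a radial contraction with a transmural gradient (the endocardium moves
   inward more than the epicardium, thickening the wall), and
3. a longitudinal shortening toward the base plane,

all modulated by a per-frame amplitude a(t) in [0, 1] that rises from 0 at
the reference frame to 1 at end-systole and relaxes to a small residual at
the final frame, mimicking systole/diastole.  The forward map, its inverse,
its deformation gradient and the Lagrange strain are all available
analytically (gradients via tight central differences), so every pipeline
stage can be checked against exact displacement and strain oracles.  A
rigid-motion variant supports objectivity tests.

Frames are rendered by backward mapping (sampling the reference image
through the inverse deformation with trilinear interpolation), which avoids
scattering artefacts.  Tag fading is modelled as geometric amplitude decay
per frame (off by default), and seeded Gaussian noise can be added last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import map_coordinates

from .core import LandmarkTrajectories, SurfaceMesh, VolumeSequence

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "RigidTruth",
    "make_deformation",
    "make_rigid_deformation",
    "render_frames",
    "export_truth",
]

_FD_STEP = 1e-4  # central-difference step for the oracle deformation gradient


@dataclass
class PhantomSpec:
    """Geometry, texture and motion parameters of the phantom (voxel units).

    The default motion (8 deg twist, 10% longitudinal shortening, radial
    contraction with transmural gradient) produces a peak displacement of
    roughly 8 voxels at the basal epicardium at end-systole.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: float = 0.96  # mm, isotropic
    center: tuple[float, float, float] = (32.0, 32.0, 46.0)  # base-plane centre
    outer_semiaxes: tuple[float, float, float] = (22.0, 22.0, 24.0)
    inner_semiaxes: tuple[float, float, float] = (12.5, 12.5, 14.5)
    tag_period: float = 7.0  # voxels
    tag_contrast: float = 0.5
    background_level: float = 0.25
    # Faint aperiodic tissue texture over the whole volume (amplitude in
    # intensity units; correlation length texture_sigma voxels).  It is a
    # material property — it deforms with the motion — and emulates the
    # structured appearance of the tissue surrounding the LV, without which
    # the constant background makes NCC degenerate (every real acquisition
    # has texture everywhere).  It also breaks the exact periodicity of the
    # tag lattice, which otherwise admits spurious period-offset matches.
    background_texture: float = 0.15
    # Correlation length of the tissue texture.  Near voxel scale: small
    # matching blocks need structure at their own scale, and smoother
    # fields let tiny blocks slide along iso-contours of the correlation
    # surface (real tissue has voxel-scale detail).
    texture_sigma: float = 1.2
    n_frames: int = 10
    end_systolic_index: int = 5
    final_amplitude: float = 0.1  # residual motion amplitude at the last frame
    twist_deg: float = 8.0
    shortening: float = 0.10
    # Peak endocardial radial scale reduction.  0.18 puts circumferential
    # strain at -0.16 endocardial / -0.12 epicardial, the level actually
    # measured on 3D tagged MRI; much larger contractions shrink a block's
    # reference footprint beyond its matched parent block and no
    # hierarchical matcher with nested search regions can represent them.
    radial_contraction: float = 0.18
    thickening: float = 0.3  # transmural gradient of the radial contraction
    # Bulk displacement (voxels) of the heart at peak amplitude — the
    # rocking/translation of the LV within the chest during systole.  It
    # raises the peak displacement while adding no strain inside the wall;
    # outside, it decays over an ellipsoidal envelope so the chest wall at
    # the image border stays (nearly) static, as in a real acquisition.
    bulk_translation: tuple[float, float, float] = (1.6, -1.6, 2.0)
    fade_rate: float = 0.0  # per-frame geometric tag-amplitude decay
    # Acquisition point-spread blur (voxels), applied identically to every
    # frame after warping.  Matching the blur of reference and moving
    # frames mirrors a real scanner, where all frames share one PSF; an
    # unblurred reference against interpolation-smoothed moving frames
    # would make the reference artificially sharper than any real image.
    psf_sigma: float = 0.6
    noise_sd: float = 0.0  # intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if any(i >= o for i, o in zip(self.inner_semiaxes, self.outer_semiaxes)):
            raise ValueError("inner semi-axes must be smaller than outer semi-axes")
        if not 0 <= self.fade_rate < 1:
            raise ValueError("fade_rate must be in [0, 1)")
        if not 0 < self.end_systolic_index < self.n_frames:
            raise ValueError("end_systolic_index must lie strictly inside the frame range")
        # radial map monotonicity (invertibility): d/dr [r (1 - a c beta(r))] > 0,
        # with beta' = -k/(ro-ri) inside the wall and beta constant outside it
        c, k = self.radial_contraction, self.thickening
        ri, ro = self.inner_semiaxes[0], self.outer_semiaxes[0]
        r = np.linspace(ri, ro, 50)
        beta = 1 - k * (r - ri) / (ro - ri)
        deriv = 1 - c * (beta - r * k / (ro - ri))
        if (1 - c) <= 0 or deriv.min() <= 0:
            raise ValueError("radial contraction parameters make the motion non-invertible")

    def amplitude(self, t: int) -> float:
        """a(t): 0 at the reference, 1 at end-systole, residual at the end."""
        tes, T = self.end_systolic_index, self.n_frames
        if t <= tes:
            return math.sin(math.pi * t / (2 * tes)) ** 2
        # mirrored decay from 1 at end-systole to final_amplitude at T-1
        frac = (T - 1 - t) / (T - 1 - tes)
        return self.final_amplitude + (1 - self.final_amplitude) * math.sin(
            math.pi * frac / 2
        ) ** 2

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([self.amplitude(t) for t in range(self.n_frames)])

    def to_dict(self) -> dict:
        return asdict(self)


class PhantomTruth:
    """Analytic deformation of the phantom: forward/inverse maps and strain."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        c = spec.center
        self._center = np.asarray(c, dtype=float)
        self._apex_z = -spec.outer_semiaxes[2]  # relative to the base plane
        self._twist = math.radians(spec.twist_deg)

    # --- coordinate helpers (voxel space, relative to the base-plane centre)
    # e-folding length (voxels) of the motion taper outside the wall: long
    # enough that the taper zone carries only mild artificial strain (a
    # sharp taper is an untrackable shear band), short enough that tissue
    # near the image border is nearly static and keeps an in-grid
    # correspondence
    _TAPER = 10.0

    def _beta(self, r: np.ndarray) -> np.ndarray:
        """Transmural profile of the radial contraction.

        1 at and inside the endocardium, decreasing linearly to (1 - k) at
        the epicardium, then decaying exponentially so the surrounding
        tissue moves progressively less (the map stays monotone in r).
        """
        ri = self.spec.inner_semiaxes[0]
        ro = self.spec.outer_semiaxes[0]
        r = np.asarray(r, dtype=float)
        frac = np.clip((r - ri) / (ro - ri), 0.0, 1.0)
        wall = 1.0 - self.spec.thickening * frac
        outside = (1.0 - self.spec.thickening) * np.exp(
            -np.clip(r - ro, 0.0, None) / self._TAPER
        )
        return np.where(r <= ro, wall, outside)

    def _axis_fraction(self, z: np.ndarray) -> np.ndarray:
        """0 at the apex, 1 at (and above) the base plane."""
        return np.clip((z - self._apex_z) / (0.0 - self._apex_z), 0.0, 1.0)

    def _twist_angle(self, r: np.ndarray, z: np.ndarray, a: float) -> np.ndarray:
        """Rotation angle: linear along the axis, tapered beyond the wall."""
        g = np.exp(-np.clip(np.asarray(r, dtype=float) - self.spec.outer_semiaxes[0],
                            0.0, None) / self._TAPER)
        return a * self._twist * self._axis_fraction(z) * g

    def _z_displacement(self, z: np.ndarray, a: float) -> np.ndarray:
        """Longitudinal displacement: -a*k*z in the wall's axial band
        (base plane fixed, apex drawn toward the base), decaying smoothly
        below the apex and above the base so distant tissue stays put."""
        z = np.asarray(z, dtype=float)
        k = a * self.spec.shortening
        za = self._apex_z
        band = -k * z * np.exp(-np.clip(z, 0.0, None) / self._TAPER)
        below = -k * za * np.exp((z - za) / self._TAPER)
        return np.where(z >= za, band, below)

    # decay rate of the bulk-translation envelope per unit of the
    # normalized ellipsoidal coordinate rho (rho = 1 on the epicardium)
    _BULK_DECAY = 1.2

    def _bulk_envelope(self, rel: np.ndarray) -> np.ndarray:
        """1 inside the outer ellipsoid, smooth exponential decay beyond."""
        rho = np.sqrt(np.sum((rel / np.asarray(self.spec.outer_semiaxes)) ** 2, axis=-1))
        return np.exp(-self._BULK_DECAY * np.clip(rho - 1.0, 0.0, None))

    def _cyl_forward(self, rel: np.ndarray, a: float) -> np.ndarray:
        # rotation applied directly to (x, y) so zero motion is bit-exact
        x, y, z = rel[:, 0], rel[:, 1], rel[:, 2]
        r = np.hypot(x, y)
        dth = self._twist_angle(r, z, a)
        c, s = np.cos(dth), np.sin(dth)
        scale = 1.0 - a * self.spec.radial_contraction * self._beta(r)
        x2 = scale * (x * c - y * s)
        y2 = scale * (x * s + y * c)
        z2 = z + self._z_displacement(z, a)
        return np.stack([x2, y2, z2], axis=1)

    def forward(self, X: np.ndarray, t: int) -> np.ndarray:
        """Map reference points X (voxels) to their frame-t positions."""
        a = self.spec.amplitude(t)
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        rel = np.atleast_2d(X) - self._center
        out = self._cyl_forward(rel, a)
        out += a * np.asarray(self.spec.bulk_translation) * self._bulk_envelope(rel)[:, None]
        out += self._center
        return out[0] if single else out

    def inverse(self, x: np.ndarray, t: int, max_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
        """Map frame-t points back to the reference configuration.

        Solved by fixed-point iteration on the forward map,
        X <- X + (x - forward(X)), which contracts because the deformation
        gradient of every admissible spec stays well inside (0, 2).
        """
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        xx = np.atleast_2d(x)
        X = xx.copy()
        for _ in range(max_iter):
            resid = xx - self.forward(X, t)
            X += resid
            if float(np.max(np.abs(resid))) < tol:
                break
        return X[0] if single else X

    def deformation_gradient(self, X: np.ndarray, t: int, h: float = _FD_STEP) -> np.ndarray:
        """Material deformation gradient F = d phi_t / d X (central differences)."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        pts = np.atleast_2d(X)
        m = len(pts)
        probes = np.repeat(pts, 6, axis=0)
        for ax in range(3):
            probes[2 * ax::6, ax] += h
            probes[2 * ax + 1::6, ax] -= h
        vals = self.forward(probes, t).reshape(m, 6, 3)
        F = np.empty((m, 3, 3))
        for ax in range(3):
            F[:, :, ax] = (vals[:, 2 * ax] - vals[:, 2 * ax + 1]) / (2 * h)
        return F[0] if single else F

    def strain(self, X: np.ndarray, t: int) -> np.ndarray:
        """Exact Lagrange strain E = 1/2 (F^T F - I) at reference points X."""
        F = self.deformation_gradient(X, t)
        Ft = np.swapaxes(F, -1, -2)
        return 0.5 * (Ft @ F - np.eye(3))

    def displacement(self, X: np.ndarray, t: int) -> np.ndarray:
        return self.forward(X, t) - np.asarray(X, dtype=float)

    # --- derived reference objects ------------------------------------
    def shell_mask_values(self, X: np.ndarray) -> np.ndarray:
        """True for points inside the LV wall (between the two half-ellipsoids)."""
        rel = np.atleast_2d(np.asarray(X, dtype=float)) - self._center
        eo = np.sum((rel / np.asarray(self.spec.outer_semiaxes)) ** 2, axis=1)
        ei = np.sum((rel / np.asarray(self.spec.inner_semiaxes)) ** 2, axis=1)
        return (eo <= 1.0) & (ei >= 1.0) & (rel[:, 2] <= 0.0)

    def sample_shell_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform random reference points inside the wall (voxel coords)."""
        out = []
        need = n
        lo = self._center - np.asarray(self.spec.outer_semiaxes)
        hi = self._center + np.asarray(self.spec.outer_semiaxes) * np.array([1, 1, 0])
        while need > 0:
            cand = rng.uniform(lo, hi, size=(max(4 * need, 64), 3))
            good = cand[self.shell_mask_values(cand)]
            out.append(good[:need])
            need -= len(good[:need])
        return np.concatenate(out)[:n]

    def mid_surface_point(self, psi: float, phi: float) -> np.ndarray:
        """Point on the mid-wall half-ellipsoid; psi=0 apex .. pi/2 base."""
        mid = 0.5 * (
            np.asarray(self.spec.inner_semiaxes) + np.asarray(self.spec.outer_semiaxes)
        )
        rel = np.array(
            [
                mid[0] * math.sin(psi) * math.cos(phi),
                mid[1] * math.sin(psi) * math.sin(phi),
                -mid[2] * math.cos(psi),
            ]
        )
        return self._center + rel

    def landmarks(self, observer_id: str = "truth") -> LandmarkTrajectories:
        """Twelve mid-wall landmarks (4 walls x basal/mid/apical) in mm."""
        spacing = self.spec.voxel_spacing
        pts = []
        ids = []
        for level, psi in (("basal", 1.45), ("mid", 1.05), ("apical", 0.55)):
            for wall, phi in (
                ("anterior", 0.0),
                ("septal", math.pi / 2),
                ("posterior", math.pi),
                ("lateral", 3 * math.pi / 2),
            ):
                pts.append(self.mid_surface_point(psi, phi))
                ids.append(f"{level}_{wall}")
        pts = np.asarray(pts)
        T = self.spec.n_frames
        pos = np.empty((len(pts), T, 3))
        for t in range(T):
            pos[:, t, :] = self.forward(pts, t) * spacing
        return LandmarkTrajectories(positions=pos, ids=ids, observer_id=observer_id)

    def mesh(self, n_azimuth: int = 28, n_rings: int = 12) -> SurfaceMesh:
        """Triangulated mid-wall surface in mm, with apex/mitral anchors."""
        spacing = self.spec.voxel_spacing
        mid = 0.5 * (
            np.asarray(self.spec.inner_semiaxes) + np.asarray(self.spec.outer_semiaxes)
        )
        psis = np.linspace(math.pi / 2 / n_rings, math.pi / 2, n_rings)
        nodes = [self._center + np.array([0.0, 0.0, -mid[2]])]  # apex vertex
        for psi in psis:
            for j in range(n_azimuth):
                phi = 2 * math.pi * j / n_azimuth
                nodes.append(self.mid_surface_point(psi, phi))
        nodes = np.asarray(nodes)
        tris = []
        for j in range(n_azimuth):  # apex fan
            tris.append([0, 1 + j, 1 + (j + 1) % n_azimuth])
        for k in range(n_rings - 1):
            base0 = 1 + k * n_azimuth
            base1 = 1 + (k + 1) * n_azimuth
            for j in range(n_azimuth):
                j2 = (j + 1) % n_azimuth
                tris.append([base0 + j, base1 + j, base1 + j2])
                tris.append([base0 + j, base1 + j2, base0 + j2])
        apex = self._center + np.array([0.0, 0.0, -mid[2]])
        mitral = self._center.copy()
        return SurfaceMesh(
            nodes=nodes * spacing,
            triangles=np.asarray(tris, dtype=int),
            apex=apex * spacing,
            mitral_center=mitral * spacing,
        )


class RigidTruth(PhantomTruth):
    """Rigid-motion variant: rotation about the long axis plus translation.

    Used for objectivity checks — a rigid motion must produce zero strain.
    The amplitude profile of the spec scales the rotation angle and
    translation per frame.
    """

    def __init__(self, spec: PhantomSpec, rotation_deg: float, translation=(0.0, 0.0, 0.0)):
        super().__init__(spec)
        self._angle = math.radians(rotation_deg)
        self._t_vec = np.asarray(translation, dtype=float)

    def _rot(self, t: int) -> np.ndarray:
        ang = self.spec.amplitude(t) * self._angle
        ca, sa = math.cos(ang), math.sin(ang)
        return np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])

    def forward(self, X: np.ndarray, t: int) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        rel = np.atleast_2d(X) - self._center
        out = rel @ self._rot(t).T + self.spec.amplitude(t) * self._t_vec + self._center
        return out[0] if single else out

    def inverse(self, x: np.ndarray, t: int, max_iter: int = 300, tol: float = 1e-12) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        rel = np.atleast_2d(x) - self._center - self.spec.amplitude(t) * self._t_vec
        out = rel @ self._rot(t) + self._center
        return out[0] if single else out

    def deformation_gradient(self, X: np.ndarray, t: int, h: float = _FD_STEP) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        R = self._rot(t)
        if X.ndim == 1:
            return R
        return np.broadcast_to(R, (len(np.atleast_2d(X)), 3, 3)).copy()


def make_deformation(spec: PhantomSpec) -> PhantomTruth:
    """Construct the analytic deformation oracle for a phantom spec."""
    return PhantomTruth(spec)


def make_rigid_deformation(
    spec: PhantomSpec, rotation_deg: float, translation=(0.0, 0.0, 0.0)
) -> RigidTruth:
    return RigidTruth(spec, rotation_deg, translation)


def reference_intensity(spec: PhantomSpec) -> np.ndarray:
    """Reference-frame image: tag-grid cosine product inside the LV wall,
    over a faint aperiodic tissue texture covering the whole volume.

    Both components are material properties (they deform with the motion);
    the tissue texture is a smoothed seeded random field, reproducible from
    the spec's seed.
    """
    from scipy.ndimage import gaussian_filter

    truth = PhantomTruth(spec)
    nx, ny, nz = spec.grid_shape
    grid = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), axis=-1
    ).reshape(-1, 3).astype(float)
    k = 2 * math.pi / spec.tag_period
    tags = np.cos(k * grid[:, 0]) * np.cos(k * grid[:, 1]) * np.cos(k * grid[:, 2])
    mask = truth.shell_mask_values(grid)
    vol = np.full(len(grid), spec.background_level)
    vol[mask] += spec.tag_contrast * tags[mask]
    vol = vol.reshape(spec.grid_shape)
    if spec.background_texture > 0:
        rng = np.random.default_rng([int(spec.seed), 0x7E57])
        field = gaussian_filter(rng.standard_normal(spec.grid_shape), spec.texture_sigma)
        field /= field.std()
        vol = vol + spec.background_texture * field
    return vol


def render_frames(spec: PhantomSpec, truth: PhantomTruth) -> VolumeSequence:
    """Render the frame sequence by backward mapping the reference image.

    Frame t samples the reference intensity at the inverse-deformed voxel
    positions (trilinear interpolation), scaled by the tag-fade factor
    ``(1 - fade_rate)^t``; Gaussian noise (seeded) is added last.
    """
    I0 = reference_intensity(spec)
    shape = spec.grid_shape
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3).astype(float)
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames,) + shape)
    for t in range(spec.n_frames):
        if t == 0:
            frame = I0.copy()
        else:
            src = truth.inverse(grid, t)
            frame = map_coordinates(
                I0, src.T, order=1, mode="constant", cval=spec.background_level
            ).reshape(shape)
        if spec.psf_sigma > 0:
            frame = gaussian_filter(frame, spec.psf_sigma)
        fade = (1.0 - spec.fade_rate) ** t
        if fade != 1.0:
            frame = spec.background_level + fade * (frame - spec.background_level)
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=shape)
        frames[t] = frame
    return VolumeSequence(
        frames=frames,
        voxel_spacing=(spec.voxel_spacing,) * 3,
        end_systolic_index=spec.end_systolic_index,
    )


def export_truth(
    truth: PhantomTruth, sample_points: np.ndarray, frames: list[int] | None = None
):
    """Exact trajectories and strain tensors at reference points (voxels).

    Returns ``(trajectories_df, strain_df, inside_mask)`` in the CSV schemas
    the pipeline emits (mm for positions, unitless strain).  Points outside
    the wall are still evaluated but flagged.
    """
    import pandas as pd

    spec = truth.spec
    pts = np.atleast_2d(np.asarray(sample_points, dtype=float))
    if frames is None:
        frames = list(range(spec.n_frames))
    inside = truth.shell_mask_values(pts)
    spacing = spec.voxel_spacing
    traj_rows = []
    strain_rows = []
    for t in frames:
        pos = truth.forward(pts, t) * spacing
        E = truth.strain(pts, t)
        for i in range(len(pts)):
            traj_rows.append(
                {"landmark_id": f"P{i:04d}", "frame": t,
                 "x": pos[i, 0], "y": pos[i, 1], "z": pos[i, 2]}
            )
            strain_rows.append(
                {
                    "frame": t, "point": i, "inside_wall": bool(inside[i]),
                    "Exx": E[i, 0, 0], "Eyy": E[i, 1, 1], "Ezz": E[i, 2, 2],
                    "Exy": E[i, 0, 1], "Exz": E[i, 0, 2], "Eyz": E[i, 1, 2],
                }
            )
    return pd.DataFrame(traj_rows), pd.DataFrame(strain_rows), inside
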