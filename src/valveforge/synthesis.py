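"""Synthetic time-resolved phase-contrast velocity data over the phantom
lumen.

The bulk flow is an incompressible parabolic (or plug) profile carried by
the axisymmetric backbone tube r = r_base(z): the axial component carries
exactly the programmed flux q(t) through every cross-section, and the
radial component v_r = v_z · r · R'(z)/R(z) follows from continuity, so the
analytic field is divergence-free.  The sinus bulge pockets outside the
backbone tube hold no bulk flow; there an optional diastolic vortex — an
azimuthal swirl about a circumferential axis through each sinus, which is
solenoidal for any radial amplitude profile — is gated on when the pump
flow drops below a fraction of its peak.

Velocity-to-phase encoding follows the phase-contrast convention
phase = wrap(π·v/venc) so velocities beyond ±venc alias by 2·venc.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, InputError, ParameterError
from .geometry import RootProfile
from .waveform import FlowWaveform

CM_PER_S_PER_UNIT_FLUX = 200.0 / np.pi  # v_axis = 2q/(πR²), q mL/s, R mm → cm/s


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid; ``origin`` is the center of voxel (0,0,0), mm."""

    origin: np.ndarray
    voxel_size: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=np.float64))
        object.__setattr__(self, "voxel_size",
                           np.asarray(self.voxel_size, dtype=np.float64))
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) \
            * self.voxel_size[axis]

    def meshgrid(self):
        return np.meshgrid(self.axis_centers(0), self.axis_centers(1),
                           self.axis_centers(2), indexing="ij")

    @property
    def bounds(self) -> np.ndarray:
        lo = self.origin
        hi = self.origin + (np.array(self.shape) - 1) * self.voxel_size
        return np.stack([lo, hi])


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition geometry and encoding settings.

    ``mode`` is ``"4d"`` (volume) or ``"2d_plane"`` (single transverse
    slice at ``plane_z``).  ``field_of_view`` and ``matrix_size`` must be
    consistent with ``voxel_size`` to within one voxel per axis.
    """

    voxel_size: tuple[float, float, float]
    field_of_view: tuple[float, float, float]
    matrix_size: tuple[int, int, int]
    n_frames: int = 20
    venc: float = 100.0
    noise_sd: float = 0.0
    mode: str = "4d"
    plane_z: float | None = None
    origin: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.venc <= 0:
            raise ParameterError("venc", "must be > 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames", "must be >= 2")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd", "must be >= 0")
        if self.mode not in ("4d", "2d_plane"):
            raise ParameterError("mode", "must be '4d' or '2d_plane'")
        if self.mode == "2d_plane" and self.plane_z is None:
            raise ParameterError("plane_z", "required in 2d_plane mode")
        for ax in range(3):
            extent = self.matrix_size[ax] * self.voxel_size[ax]
            if abs(extent - self.field_of_view[ax]) > self.voxel_size[ax]:
                raise ParameterError(
                    "field_of_view",
                    f"axis {ax}: matrix·voxel = {extent} vs FoV "
                    f"{self.field_of_view[ax]} differ by more than one voxel")

    def grid(self, profile: RootProfile | None = None) -> Grid:
        vox = np.asarray(self.voxel_size, dtype=np.float64)
        shape = tuple(self.matrix_size)
        if self.origin is not None:
            origin = np.asarray(self.origin, dtype=np.float64)
        else:
            # center the FoV on the flow axis; z spans the phantom
            extent = (np.array(shape) - 1) * vox
            z_lo = profile.z_min if profile is not None else -extent[2] / 2
            origin = np.array([-extent[0] / 2, -extent[1] / 2, z_lo])
        if self.mode == "2d_plane":
            shape = (shape[0], shape[1], 1)
            origin = origin.copy()
            origin[2] = self.plane_z
        return Grid(origin=origin, voxel_size=vox, shape=shape)

    @staticmethod
    def default_4d(profile: RootProfile, n: int = 64, n_frames: int = 20,
                   venc: float = 100.0,
                   noise_sd: float = 0.0) -> "AcquisitionParams":
        """Desk-scale 4D protocol: n³ matrix covering the phantom, with the
        4D-flow venc default of 100 cm/s."""
        p = profile.params
        xy = p.sinus_max_diameter + 6.0
        zlen = profile.z_max - profile.z_min
        vox = (xy / n, xy / n, zlen / n)
        return AcquisitionParams(voxel_size=vox,
                                 field_of_view=(xy, xy, zlen),
                                 matrix_size=(n, n, n), n_frames=n_frames,
                                 venc=venc, noise_sd=noise_sd)


@dataclass(frozen=True)
class VortexParams:
    """Diastolic sinus-vortex model.

    One swirl per sinus about the local circumferential axis, centered a
    fraction ``depth_fraction`` into the bulge pocket at the axial station
    of maximal bulge.  The swirl speed is Γ/(2πρ)·(1 − e^(−ρ²/a²)) with a
    smooth radial/axial taper keeping the support inside the pocket; any
    such azimuthal field is exactly divergence-free.  ``strength`` is the
    circulation Γ in cm²/s around a loop enclosing the core.
    """

    strength: float = 10.0
    core_radius: float = 0.75
    plateau_radius: float = 1.9
    support_radius: float = 2.4
    tube_half_length: float = 1.5
    tube_support: float = 3.0
    depth_fraction: float = 0.45
    gate_on_fraction: float = 0.1
    gate_full_fraction: float = 0.02

    def __post_init__(self):
        if self.core_radius <= 0 or self.support_radius <= self.plateau_radius:
            raise ParameterError("support_radius",
                                 "need core > 0 and support > plateau")


def _smootherstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * x * (x * (6.0 * x - 15.0) + 10.0)


def _taper(r: np.ndarray, flat: float, zero: float) -> np.ndarray:
    """1 for r ≤ flat, smooth C² descent to 0 at r ≥ zero."""
    return 1.0 - _smootherstep((r - flat) / (zero - flat))


def vortex_centers(profile: RootProfile,
                   vortex: VortexParams) -> tuple[np.ndarray, np.ndarray]:
    """Center point and circumferential tangent axis of each sinus vortex."""
    thetas = profile.sinus_centers_theta()
    z_c = profile.z_bulge_peak
    centers, tangents = [], []
    for th in thetas:
        r_in = profile.r_base(np.array([z_c]))[0]
        r_out = profile.radius_fn(np.array([z_c]), np.array([th]))[0]
        r_c = r_in + vortex.depth_fraction * (r_out - r_in)
        centers.append([r_c * np.cos(th), r_c * np.sin(th), z_c])
        tangents.append([-np.sin(th), np.cos(th), 0.0])
    return np.asarray(centers), np.asarray(tangents)


def vortex_velocity(points: np.ndarray, center: np.ndarray,
                    tangent: np.ndarray, vortex: VortexParams) -> np.ndarray:
    """Swirl velocity (cm/s) of one sinus vortex at ``points`` (m, 3) mm."""
    d = points - center
    s = d @ tangent
    d_perp = d - np.outer(s, tangent)
    rho = np.linalg.norm(d_perp, axis=1)
    safe = np.maximum(rho, 1e-12)
    a = vortex.core_radius
    # 10·Γ[cm²/s] / (2πρ[mm]) gives cm/s
    speed = 10.0 * vortex.strength / (2 * np.pi * safe) \
        * (1.0 - np.exp(-(rho / a) ** 2)) \
        * _taper(rho, vortex.plateau_radius, vortex.support_radius) \
        * _taper(np.abs(s), vortex.tube_half_length, vortex.tube_support)
    phi_hat = np.cross(np.broadcast_to(tangent, d_perp.shape),
                       d_perp / safe[:, None])
    return speed[:, None] * phi_hat


def vortex_gate(q: np.ndarray, peak_flow: float,
                vortex: VortexParams) -> np.ndarray:
    """Temporal activation in [0, 1]: 0 in systole, 1 at zero flow."""
    on = vortex.gate_on_fraction * peak_flow
    full = vortex.gate_full_fraction * peak_flow
    return _smootherstep((on - np.asarray(q)) / (on - full))


@dataclass
class VelocityField4D:
    """Time-resolved 3-component velocity (cm/s) on a regular grid.

    ``v`` has shape (n_frames, 3, nx, ny, nz); ``times`` are frame centers
    over one cycle; velocities vanish outside ``lumen_mask`` before noise.
    """

    grid: Grid
    times: np.ndarray
    v: np.ndarray
    lumen_mask: np.ndarray
    venc: float
    period: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.v = np.asarray(self.v)
        self.lumen_mask = np.asarray(self.lumen_mask, dtype=bool)
        if self.v.shape[0] != len(self.times) or self.v.shape[1] != 3:
            raise ParameterError("v", "expected shape (n_frames, 3, nx, ny, nz)")
        if self.v.shape[2:] != self.lumen_mask.shape:
            raise ParameterError("lumen_mask", "shape mismatch with v")
        if not np.all(np.isfinite(self.v)):
            raise ParameterError("v", "velocities must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.times)


def make_lumen_mask(profile: RootProfile, grid: Grid) -> np.ndarray:
    """Voxel-center membership of the lumen: r < radius_fn(z, θ) within the
    phantom's axial extent."""
    x, y, z = grid.meshgrid()
    if z.max() < profile.z_min or z.min() > profile.z_max:
        raise InputError("grid does not intersect the phantom axial extent")
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    inside = (z >= profile.z_min) & (z <= profile.z_max)
    radius = profile.radius_fn(np.clip(z, profile.z_min, profile.z_max),
                               theta)
    return inside & (r < radius)


def sample_velocity_field(profile: RootProfile, w: FlowWaveform,
                          acq: AcquisitionParams,
                          vortex: VortexParams | None = None,
                          shape: str = "parabolic") -> VelocityField4D:
    """Synthesize the noise-free velocity dataset for one cardiac cycle.

    ``shape`` selects the bulk-flow profile: ``parabolic`` (Poiseuille-like,
    v_axis = 2q/(πR²)·(1 − (r/R)²)), ``plug`` (uniform q/(πR²)), or
    ``none`` (vortex only).  Frame values are instantaneous samples of q at
    frame centers.
    """
    if shape not in ("parabolic", "plug", "none"):
        raise InputError(f"unknown profile shape {shape!r}")
    if w.q_fn is None:
        raise InputError("waveform lacks an analytic evaluator")
    grid = acq.grid(profile)
    mask = make_lumen_mask(profile, grid)
    nf = acq.n_frames
    times = (np.arange(nf) + 0.5) * (w.period / nf)
    q = np.asarray(w.q_fn(times), dtype=np.float64)

    x, y, z = grid.meshgrid()
    r = np.hypot(x, y)
    zc = np.clip(z, profile.z_min, profile.z_max)
    R = profile.r_base(zc)
    dR = profile.r_base_derivative(zc)
    core = mask & (r < R)
    with np.errstate(divide="ignore", invalid="ignore"):
        if shape == "parabolic":
            # per unit flux, cm/s
            unit_vz = np.where(core,
                               (200.0 / np.pi) / R ** 2 * (1 - (r / R) ** 2),
                               0.0)
        elif shape == "plug":
            unit_vz = np.where(core, (100.0 / np.pi) / R ** 2, 0.0)
        else:
            unit_vz = np.zeros_like(r)
        # v_r = v_z · r·R'/R  (exact continuity for both profiles)
        ratio = np.where(core, dR / R, 0.0)
    unit_vx = unit_vz * ratio * x
    unit_vy = unit_vz * ratio * y

    v = np.zeros((nf, 3) + grid.shape, dtype=np.float32)
    for k in range(nf):
        v[k, 0] = q[k] * unit_vx
        v[k, 1] = q[k] * unit_vy
        v[k, 2] = q[k] * unit_vz

    meta = {"shape": shape, "q_frames": q.tolist()}
    if vortex is not None:
        centers, tangents = vortex_centers(profile, vortex)
        gate = vortex_gate(q, w.peak_flow, vortex)
        pts = np.stack([x[mask], y[mask], z[mask]], axis=1)
        vv = np.zeros_like(pts)
        for c, t in zip(centers, tangents):
            near = np.linalg.norm(pts - c, axis=1) \
                <= vortex.support_radius + vortex.tube_support
            if near.any():
                vv[near] += vortex_velocity(pts[near], c, t, vortex)
        for k in range(nf):
            if gate[k] > 0:
                for comp in range(3):
                    v[k, comp][mask] += (gate[k] * vv[:, comp]).astype(
                        np.float32)
        meta.update({
            "vortex": asdict(vortex),
            "sinus_centers": centers.tolist(),
            "sinus_tangents": tangents.tolist(),
            "gate": gate.tolist(),
        })

    field4d = VelocityField4D(grid=grid, times=times, v=v, lumen_mask=mask,
                              venc=acq.venc, period=w.period, meta=meta)
    return field4d


def pc_encode(v: np.ndarray | VelocityField4D,
              venc: float | None = None) -> np.ndarray:
    """Velocity → phase (rad), wrapped to the half-open interval (−π, π].

    With this convention v = +venc and v = −venc both encode to +π.
    """
    if isinstance(v, VelocityField4D):
        venc = v.venc if venc is None else venc
        v = v.v
    if venc is None or venc <= 0:
        raise InputError("venc must be > 0")
    phase = np.pi * np.asarray(v, dtype=np.float64) / venc
    return np.pi - np.mod(np.pi - phase, 2 * np.pi)


def pc_decode(phase: np.ndarray, venc: float) -> np.ndarray:
    """Phase (rad) → velocity (cm/s); inverse of :func:`pc_encode` for
    |v| < venc, aliased by multiples of 2·venc beyond."""
    if venc <= 0:
        raise InputError("venc must be > 0")
    return np.asarray(phase, dtype=np.float64) * venc / np.pi


def add_noise(field4d: VelocityField4D, noise_sd: float,
              seed: int) -> VelocityField4D:
    """Gaussian velocity noise (cm/s) per component, inside the lumen only.

    Reproducible under a fixed seed; ``noise_sd = 0`` returns the field
    unchanged (bitwise)."""
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    if noise_sd == 0:
        return field4d
    rng = np.random.default_rng(seed)
    v = field4d.v.copy()
    mask = field4d.lumen_mask
    n_in = int(mask.sum())
    for k in range(field4d.n_frames):
        for comp in range(3):
            v[k, comp][mask] += rng.normal(
                0.0, noise_sd, size=n_in).astype(v.dtype)
    meta = dict(field4d.meta, noise_sd=noise_sd, noise_seed=int(seed))
    return VelocityField4D(grid=field4d.grid, times=field4d.times, v=v,
                           lumen_mask=mask, venc=field4d.venc,
                           period=field4d.period, meta=meta)


# --------------------------------------------------------------------------
# NIfTI interchange
# --------------------------------------------------------------------------

_COMPONENT_FILES = ("vx.nii.gz", "vy.nii.gz", "vz.nii.gz")


def export_nifti(field4d: VelocityField4D, out_dir: str | Path) -> Path:
    """One 4D NIfTI per velocity component plus the lumen mask and a JSON
    manifest (venc, frame times, units)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(field4d.grid.voxel_size)
    affine[:3, 3] = field4d.grid.origin
    for comp, name in enumerate(_COMPONENT_FILES):
        data = np.moveaxis(field4d.v[:, comp], 0, -1).astype(np.float32)
        img = nib.Nifti1Image(data, affine)
        img.header.set_xyzt_units("mm", "sec")
        dt = np.diff(field4d.times).mean() if field4d.n_frames > 1 else 1.0
        img.header["pixdim"][4] = dt
        nib.save(img, out / name)
    mask_img = nib.Nifti1Image(
        field4d.lumen_mask.astype(np.uint8), affine)
    mask_img.header.set_xyzt_units("mm", "sec")
    nib.save(mask_img, out / "mask.nii.gz")
    manifest = {
        "venc_cm_per_s": field4d.venc,
        "times_s": field4d.times.tolist(),
        "period_s": field4d.period,
        "velocity_units": "cm/s",
        "grid_units": "mm",
        "meta": field4d.meta,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def import_nifti(in_dir: str | Path) -> VelocityField4D:
    """Load a dataset written by :func:`export_nifti`."""
    src = Path(in_dir)
    manifest_path = src / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"missing manifest.json in {src}")
    manifest = json.loads(manifest_path.read_text())
    imgs = [nib.load(src / name) for name in _COMPONENT_FILES]
    affines = [img.affine for img in imgs]
    if not all(np.allclose(a, affines[0]) for a in affines):
        raise FormatError("inconsistent affines across velocity components")
    shapes = {img.shape for img in imgs}
    if len(shapes) != 1:
        raise FormatError("inconsistent frame counts across components")
    data = [np.asarray(img.dataobj, dtype=np.float32) for img in imgs]
    v = np.stack([np.moveaxis(d, -1, 0) for d in data], axis=1)
    mask = np.asarray(nib.load(src / "mask.nii.gz").dataobj) > 0
    affine = affines[0]
    grid = Grid(origin=affine[:3, 3], voxel_size=np.diag(affine[:3, :3]),
                shape=mask.shape)
    times = np.asarray(manifest["times_s"], dtype=np.float64)
    if len(times) != v.shape[0]:
        raise FormatError("manifest frame times disagree with data")
    return VelocityField4D(grid=grid, times=times, v=v, lumen_mask=mask,
                           venc=float(manifest["venc_cm_per_s"]),
                           period=float(manifest["period_s"]),
                           meta=manifest.get("meta", {}))


def divergence(field4d: VelocityField4D, frame: int) -> tuple[np.ndarray,
                                                              np.ndarray]:
    """Central-difference divergence (1/s) and the mask of voxels whose full
    6-neighbour stencil lies inside the lumen."""
    v = field4d.v[frame].astype(np.float64)
    d = field4d.grid.voxel_size
    div = np.zeros(v.shape[1:])
    # mm spacing with cm/s velocities: ∂v/∂x in (cm/s)/mm → ×10 for 1/s
    div[1:-1, :, :] += (v[0, 2:, :, :] - v[0, :-2, :, :]) / (2 * d[0]) * 10
    div[:, 1:-1, :] += (v[1, :, 2:, :] - v[1, :, :-2, :]) / (2 * d[1]) * 10
    div[:, :, 1:-1] += (v[2, :, :, 2:] - v[2, :, :, :-2]) / (2 * d[2]) * 10
    m = field4d.lumen_mask
    interior = np.zeros_like(m)
    interior[1:-1, 1:-1, 1:-1] = (
        m[1:-1, 1:-1, 1:-1]
        & m[2:, 1:-1, 1:-1] & m[:-2, 1:-1, 1:-1]
        & m[1:-1, 2:, 1:-1] & m[1:-1, :-2, 1:-1]
        & m[1:-1, 1:-1, 2:] & m[1:-1, 1:-1, :-2])
    return div, interior
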