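"""Parametric aortic-root and trileaflet-valve geometry.

The root lumen is a surface of revolution-like shape r(z, θ): a left
ventricular outflow tract (LVOT) cylinder below the annulus plane (z = 0),
three sinus-of-Valsalva bulges with n-fold symmetry over 0 ≤ z ≤
sinus_height, a sinotubular waist, and a tubular ascending aorta.  The
printable wall is the solid between the lumen surface and its outward
normal offset by ``wall_thickness``; leaflets are thin lofted shells of
``leaflet_thickness``.  All coordinates are mm, right-handed, z along the
flow axis with the annulus at z = 0.

Default dimensions are read off the engineering drawings of a normal adult
tricuspid aortic valve phantom (annulus ≈ 23 mm class); only the wall
(2 mm) and leaflet (0.6 mm) thicknesses are stated in text, so every other
value is figure-derived / literature-typical and overridable via config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


import numpy as np
import trimesh
from scipy.optimize import brentq, minimize_scalar

from ._rays import first_hit_distances
from .errors import FormatError, GeometryError, InputError, ParameterError

COORDINATE_CONVENTION = {
    "units": "mm",
    "handedness": "right",
    "z_axis": "flow axis, positive toward ascending aorta",
    "z_origin": "annulus plane",
}

#: exponent of the max(0, cos)^p sinus bulge shape (C1 at sector borders)
BULGE_SHARPNESS = 2.0


@dataclass(frozen=True)
class RootGeometryParams:
    """Named dimensions (mm) of the aortic root and valve leaflets."""

    annulus_diameter: float = 23.0
    sinus_max_diameter: float = 34.0
    sinus_height: float = 20.0
    sinotubular_diameter: float = 26.0
    ascending_aorta_diameter: float = 28.0
    ascending_aorta_length: float = 60.0
    lvot_diameter: float = 22.0
    lvot_length: float = 40.0
    wall_thickness: float = 2.0
    n_leaflets: int = 3
    leaflet_thickness: float = 0.6
    leaflet_height: float = 14.0
    leaflet_free_edge_sag: float = 3.0
    coaptation_height: float = 3.0
    commissure_radial_offset: float = 1.0

    def __post_init__(self):
        lengths = {
            "annulus_diameter": self.annulus_diameter,
            "sinus_max_diameter": self.sinus_max_diameter,
            "sinus_height": self.sinus_height,
            "sinotubular_diameter": self.sinotubular_diameter,
            "ascending_aorta_diameter": self.ascending_aorta_diameter,
            "ascending_aorta_length": self.ascending_aorta_length,
            "lvot_diameter": self.lvot_diameter,
            "lvot_length": self.lvot_length,
            "wall_thickness": self.wall_thickness,
            "leaflet_thickness": self.leaflet_thickness,
            "leaflet_height": self.leaflet_height,
            "leaflet_free_edge_sag": self.leaflet_free_edge_sag,
            "coaptation_height": self.coaptation_height,
            "commissure_radial_offset": self.commissure_radial_offset,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ParameterError(name, "must be > 0")
        if self.wall_thickness >= self.annulus_diameter / 4:
            raise ParameterError("wall_thickness",
                                 "must be < annulus_diameter/4")
        if self.leaflet_thickness >= self.wall_thickness:
            raise ParameterError("leaflet_thickness",
                                 "must be < wall_thickness")
        if self.sinus_max_diameter < self.annulus_diameter:
            raise ParameterError("sinus_max_diameter",
                                 "must be >= annulus_diameter")
        if self.sinus_max_diameter < self.sinotubular_diameter:
            raise ParameterError("sinus_max_diameter",
                                 "must be >= sinotubular_diameter")
        if self.n_leaflets < 2:
            raise ParameterError("n_leaflets", "must be >= 2")

    # convenience radii
    @property
    def annulus_radius(self) -> float:
        return self.annulus_diameter / 2

    @property
    def sinotubular_radius(self) -> float:
        return self.sinotubular_diameter / 2

    @property
    def lvot_radius(self) -> float:
        return self.lvot_diameter / 2

    @property
    def aorta_radius(self) -> float:
        return self.ascending_aorta_diameter / 2

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @staticmethod
    def from_json(path: str | Path) -> "RootGeometryParams":
        return RootGeometryParams(**json.loads(Path(path).read_text()))


@dataclass
class SurfaceMesh:
    """Triangle mesh in mm; faces wind counter-clockwise seen from outside.

    ``component_labels`` is an optional per-face array of strings such as
    ``wall`` / ``leaflet_1`` (assemblies) or ``inner`` / ``outer`` / ``cap``
    (shell surfaces).
    """

    vertices: np.ndarray
    faces: np.ndarray
    component_labels: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.component_labels is not None:
            self.component_labels = np.asarray(self.component_labels)
            if len(self.component_labels) != len(self.faces):
                raise ParameterError("component_labels",
                                     "must have one label per face")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @staticmethod
    def from_trimesh(tm: trimesh.Trimesh,
                     labels: np.ndarray | None = None) -> "SurfaceMesh":
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                           labels)

    def select(self, label: str) -> "SurfaceMesh":
        """Sub-mesh of faces carrying ``label`` (vertices are not pruned)."""
        if self.component_labels is None:
            raise InputError("mesh has no component labels")
        keep = self.component_labels == label
        return SurfaceMesh(self.vertices, self.faces[keep],
                           self.component_labels[keep])

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    @staticmethod
    def concatenate(meshes: list["SurfaceMesh"],
                    labels: list[str] | None = None) -> "SurfaceMesh":
        verts, faces, labs = [], [], []
        offset = 0
        for k, m in enumerate(meshes):
            verts.append(m.vertices)
            faces.append(m.faces + offset)
            if labels is not None:
                labs.append(np.full(len(m.faces), labels[k], dtype=object))
            offset += len(m.vertices)
        lab = np.concatenate(labs) if labels is not None else None
        return SurfaceMesh(np.vstack(verts), np.vstack(faces), lab)


@dataclass
class RootProfile:
    """Inner lumen radius r(z, θ) of the aortic root.

    ``r_base`` is the axisymmetric backbone (LVOT → annulus → sinotubular
    junction → ascending aorta, C1 cosine blends); the sinus bulge
    multiplies it by 1 + a(z)·max(0, cos(nθ − π))^p with a sine-arch a(z)
    vanishing at z = 0 and z = sinus_height.  The bulge amplitude is solved
    so max r over the sinus segment equals sinus_max_diameter/2.
    """

    params: RootGeometryParams
    bulge_amplitude: float
    z_bulge_peak: float
    axial_stations: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.axial_stations is None:
            self.axial_stations = np.array(
                [self.z_min, 0.0, self.params.sinus_height, self.z_max])

    @property
    def z_min(self) -> float:
        return -self.params.lvot_length

    @property
    def z_max(self) -> float:
        return self.params.sinus_height + self.params.ascending_aorta_length

    # --- axisymmetric backbone -------------------------------------------
    def r_base(self, z) -> np.ndarray:
        p = self.params
        z = np.asarray(z, dtype=np.float64)
        r = np.empty_like(z)
        ltr = min(0.4 * p.lvot_length, 6.0)       # annulus→LVOT blend length
        atr = min(0.4 * p.ascending_aorta_length, 8.0)  # STJ→aorta blend
        h = p.sinus_height

        below = z < -ltr
        r[below] = p.lvot_radius
        seg = (z >= -ltr) & (z < 0)
        zz = z[seg]
        r[seg] = p.lvot_radius + (p.annulus_radius - p.lvot_radius) * (
            1 - np.cos(np.pi * (zz + ltr) / ltr)) / 2
        seg = (z >= 0) & (z <= h)
        zz = z[seg]
        r[seg] = p.annulus_radius + (p.sinotubular_radius - p.annulus_radius
                                     ) * (1 - np.cos(np.pi * zz / h)) / 2
        seg = (z > h) & (z < h + atr)
        zz = z[seg]
        r[seg] = p.sinotubular_radius + (p.aorta_radius - p.sinotubular_radius
                                         ) * (1 - np.cos(np.pi * (zz - h) / atr)) / 2
        r[z >= h + atr] = p.aorta_radius
        return r

    def r_base_derivative(self, z, h_step: float = 1e-5) -> np.ndarray:
        return (self.r_base(np.asarray(z) + h_step)
                - self.r_base(np.asarray(z) - h_step)) / (2 * h_step)

    # --- full lumen radius ------------------------------------------------
    def bulge_envelope(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        h = self.params.sinus_height
        env = np.where((z >= 0) & (z <= h),
                       np.sin(np.pi * np.clip(z, 0, h) / h), 0.0)
        return self.bulge_amplitude * env

    def radius_fn(self, z, theta) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        theta = np.asarray(theta, dtype=np.float64)
        n = self.params.n_leaflets
        shape = np.maximum(0.0, np.cos(n * theta - np.pi)) ** BULGE_SHARPNESS
        return self.r_base(z) * (1.0 + self.bulge_envelope(z) * shape)

    def sinus_centers_theta(self) -> np.ndarray:
        """Azimuth of each sinus bulge maximum (sector centers)."""
        n = self.params.n_leaflets
        return (np.arange(n) + 0.5) * 2 * np.pi / n


def build_root_profile(params: RootGeometryParams) -> RootProfile:
    """Construct the lumen radius function for a parameter set.

    Solves the sinus bulge amplitude so the maximal lumen radius over the
    sinus segment equals ``sinus_max_diameter / 2`` (to ~1e-9 mm).
    """
    h = params.sinus_height
    r_target = params.sinus_max_diameter / 2

    probe = RootProfile(params=params, bulge_amplitude=0.0, z_bulge_peak=h / 2)

    def max_radius(amplitude: float) -> tuple[float, float]:
        def neg(z):
            return -(probe.r_base(z) * (1 + amplitude * np.sin(np.pi * z / h)))
        zs = np.linspace(0.0, h, 2001)
        vals = -neg(zs)
        k = int(np.argmax(vals))
        lo, hi = zs[max(0, k - 2)], zs[min(len(zs) - 1, k + 2)]
        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        return -res.fun, res.x

    base_max, z_at = max_radius(0.0)
    if r_target <= base_max + 1e-12:
        amplitude, z_peak = 0.0, z_at
    else:
        upper = 2.0 * r_target / probe.r_base(np.array([h / 2]))[0]
        amplitude = brentq(lambda a: max_radius(a)[0] - r_target,
                           0.0, upper, xtol=1e-13, rtol=8.9e-16)
        # Newton polish: at fixed z*, ∂max/∂a = r_base(z*)·sin(πz*/h)
        for _ in range(3):
            mx, z_peak = max_radius(amplitude)
            slope = probe.r_base(np.array([z_peak]))[0] \
                * np.sin(np.pi * z_peak / h)
            amplitude += (r_target - mx) / slope
        z_peak = max_radius(amplitude)[1]
    return RootProfile(params=params, bulge_amplitude=float(amplitude),
                       z_bulge_peak=float(z_peak))


# --------------------------------------------------------------------------
# root shell
# --------------------------------------------------------------------------

def _lumen_surface_points_normals(profile: RootProfile, z: np.ndarray,
                                  theta: np.ndarray):
    """Vertices and outward unit normals of the lumen surface on a (z, θ)
    grid.  Normal of the implicit surface r = ρ(z, θ):
    n ∝ e_r − (ρ_θ/ρ) e_θ − ρ_z e_z."""
    zz, tt = np.meshgrid(z, theta, indexing="ij")
    rho = profile.radius_fn(zz, tt)
    hs = 1e-5
    rho_z = (profile.radius_fn(zz + hs, tt)
             - profile.radius_fn(zz - hs, tt)) / (2 * hs)
    rho_t = (profile.radius_fn(zz, tt + hs)
             - profile.radius_fn(zz, tt - hs)) / (2 * hs)
    ct, st = np.cos(tt), np.sin(tt)
    e_r = np.stack([ct, st, np.zeros_like(ct)], axis=-1)
    e_t = np.stack([-st, ct, np.zeros_like(ct)], axis=-1)
    e_z = np.stack([np.zeros_like(ct), np.zeros_like(ct),
                    np.ones_like(ct)], axis=-1)
    n = e_r - (rho_t / rho)[..., None] * e_t - rho_z[..., None] * e_z
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    pts = rho[..., None] * e_r + zz[..., None] * e_z
    return pts, n, rho


def _grid_faces(n_rows: int, n_cols: int, wrap: bool,
                offset: int = 0) -> np.ndarray:
    """Triangulate an (n_rows x n_cols) vertex grid stored row-major."""
    faces = []
    cols = n_cols if wrap else n_cols - 1
    for i in range(n_rows - 1):
        for j in range(cols):
            j1 = (j + 1) % n_cols
            a = offset + i * n_cols + j
            b = offset + i * n_cols + j1
            c = offset + (i + 1) * n_cols + j1
            d = offset + (i + 1) * n_cols + j
            faces.append([a, b, c])
            faces.append([a, c, d])
    return np.asarray(faces, dtype=np.int64)


def _signed_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    return float(np.einsum("ij,ij->", tri[:, 0],
                           np.cross(tri[:, 1], tri[:, 2])) / 6.0)


def _orient_outward(mesh: SurfaceMesh) -> SurfaceMesh:
    tm = mesh.to_trimesh()
    trimesh.repair.fix_normals(tm)
    if tm.is_watertight and tm.volume < 0:
        tm.invert()
    return SurfaceMesh.from_trimesh(tm, mesh.component_labels)


def build_root_mesh(profile: RootProfile,
                    params: RootGeometryParams | None = None,
                    resolution: dict | None = None) -> SurfaceMesh:
    """Closed printable shell of the root wall.

    Inner lumen surface plus an outer surface offset outward by
    ``wall_thickness`` along local surface normals, closed with annular
    caps at the LVOT inlet and aortic outlet rims.  The lumen stays open;
    the *solid wall* is the closed (genus-1) body.
    """
    params = params or profile.params
    resolution = resolution or {}
    n_axial = int(resolution.get("n_axial", 120))
    n_circ = int(resolution.get("n_circumferential", 192))
    if n_axial < 8:
        raise ParameterError("n_axial", "must be >= 8")
    if n_circ < 24:
        raise ParameterError("n_circumferential", "must be >= 24")

    z = np.linspace(profile.z_min, profile.z_max, n_axial + 1)
    theta = np.arange(n_circ) * (2 * np.pi / n_circ)
    inner, normals, rho = _lumen_surface_points_normals(profile, z, theta)
    t = params.wall_thickness
    if np.any(rho <= t * 0.5):
        raise GeometryError("wall_thickness too large for the lumen radius")
    outer = inner + t * normals

    n_rows = n_axial + 1
    n_verts = n_rows * n_circ
    inner_v = inner.reshape(-1, 3)
    outer_v = outer.reshape(-1, 3)

    # sanity: offsetting must not flip the surface (local curvature check)
    def face_normals(verts, faces):
        tri = verts[faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return n

    grid_f = _grid_faces(n_rows, n_circ, wrap=True)
    if np.any(np.einsum("ij,ij->i", face_normals(inner_v, grid_f),
                        face_normals(outer_v, grid_f)) <= 0):
        raise GeometryError(
            "wall offset self-intersects (wall_thickness too large for "
            "local curvature)")

    # orientation by construction: the grid winding points away from the
    # z axis, so the solid wall needs the inner surface reversed and the
    # outer kept; caps close the rims pointing -z (inlet) and +z (outlet)
    inner_faces = grid_f[:, ::-1]
    outer_faces = grid_f + n_verts

    def cap_faces(row: int, flip: bool) -> np.ndarray:
        faces = []
        for j in range(n_circ):
            j1 = (j + 1) % n_circ
            a = row * n_circ + j
            b = row * n_circ + j1
            c = n_verts + row * n_circ + j1
            d = n_verts + row * n_circ + j
            faces.append([a, b, c])
            faces.append([a, c, d])
        f = np.asarray(faces, dtype=np.int64)
        return f[:, ::-1] if flip else f

    faces = np.vstack([inner_faces, outer_faces,
                       cap_faces(0, flip=False),
                       cap_faces(n_rows - 1, flip=True)])
    labels = np.concatenate([
        np.full(len(inner_faces), "inner", dtype=object),
        np.full(len(outer_faces), "outer", dtype=object),
        np.full(2 * 2 * n_circ, "cap", dtype=object),
    ])
    verts = np.vstack([inner_v, outer_v])
    if _signed_volume(verts, faces) < 0:
        raise GeometryError("root shell came out inside-out")
    return SurfaceMesh(verts, faces, labels)


def wall_thickness_stats(mesh: SurfaceMesh, n_samples: int = 1500) -> dict:
    """Inner→outer offset distances of a labelled root shell.

    Rays are cast from inner-surface face centroids along the direction
    into the wall (away from the lumen) and intersected with the outer
    surface; returns summary statistics in mm.
    """
    inner = mesh.select("inner")
    outer = mesh.select("outer")
    tri = inner.triangles
    centroids = tri.mean(axis=1)
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    fn /= np.linalg.norm(fn, axis=1, keepdims=True)
    # inner faces of an outward-oriented solid point toward the lumen axis;
    # flip so rays run into the wall (radially away from the z axis)
    radial = centroids.copy()
    radial[:, 2] = 0.0
    sign = np.sign(np.einsum("ij,ij->i", fn, radial))
    sign[sign == 0] = 1.0
    dirs = fn * sign[:, None]
    if len(centroids) > n_samples:
        stride = max(1, len(centroids) // n_samples)
        centroids, dirs = centroids[::stride], dirs[::stride]
    d = first_hit_distances(centroids, dirs, outer.triangles)
    d = d[np.isfinite(d)]
    if len(d) == 0:
        raise GeometryError("no inner-to-outer intersections found")
    return {"median_mm": float(np.median(d)), "mean_mm": float(np.mean(d)),
            "min_mm": float(np.min(d)), "max_mm": float(np.max(d)),
            "n_rays": int(len(d))}


# --------------------------------------------------------------------------
# leaflets
# --------------------------------------------------------------------------

def _normalize_state(state) -> float:
    """Map closed/open(fraction) state spec to an opening fraction α."""
    if state == "closed" or state is None:
        return 0.0
    if isinstance(state, (tuple, list)) and len(state) == 2 and state[0] == "open":
        state = state[1]
    if state == "open":
        state = 1.0
    try:
        alpha = float(state)
    except (TypeError, ValueError):
        raise InputError(f"unrecognized leaflet state {state!r}")
    if not (0.0 <= alpha <= 1.0):
        raise InputError("opening fraction must lie in [0, 1]")
    return alpha


def _leaflet_midsurface(profile: RootProfile, alpha: float,
                        nu: int, nv: int) -> np.ndarray:
    """Midsurface grid of leaflet 0 (sector θ ∈ [0, 2π/n]).

    Closed state: a smooth graph over the sector — a quadratic dome rising
    from the coaptation apex on the axis (z = leaflet_height − sag) to the
    wall attachment, whose height profile h·cos²(πθ/Δθ) dips to the
    annulus at the sector center and drops smoothly (Gaussian blend) to
    the commissure coaptation point.  A graph with bounded Hessian has
    bounded curvature, so the ±t/2 thickness offset cannot self-intersect
    anywhere, including the commissure corners.

    Open state: a ruled loft from the same attachment row to a wall-
    hugging free-edge arc.  Intermediate ``alpha`` blends the two grids
    kinematically (a morph, not mechanics).

    Grid layout: u (axis 0) runs along the leaflet from commissure to
    commissure; v (axis 1) runs from the free edge (v = 0) to the
    attachment (v = 1).
    """
    p = profile.params
    n = p.n_leaflets
    dtheta = 2 * np.pi / n
    h = p.leaflet_height
    if h > p.sinus_height:
        raise GeometryError(
            "leaflet_height exceeds sinus_height: attachment curve leaves "
            "the sinus segment")

    u = np.linspace(0.0, 1.0, nu + 1)
    v = np.linspace(0.0, 1.0, nv + 1)
    theta_u = u * dtheta
    z_apex = h - p.leaflet_free_edge_sag
    drop = 0.35 * p.coaptation_height       # commissure coaptation drop
    z_comm = h - drop

    # effective attachment height: cos² arch with a smooth commissure drop
    sigma = 0.18
    K = np.exp(-(u / sigma) ** 2) + np.exp(-((1.0 - u) / sigma) ** 2)
    z_att = h * np.cos(np.pi * u) ** 2 - drop * K
    r_att = profile.radius_fn(z_att, theta_u)
    att = np.stack([r_att * np.cos(theta_u), r_att * np.sin(theta_u),
                    z_att], axis=-1)

    # closed dome: radial coordinate ρ ∈ [ρ_min, 1] of the polar graph;
    # ρ_min keeps the coaptation midpoints of all leaflets within a few
    # hundredths of a mm of the axis
    rho_min = 0.002
    rho = rho_min + (1.0 - rho_min) * v
    rr = rho[None, :]
    z_closed = z_apex + rr ** 2 * (z_att[:, None] - z_apex)
    r_closed = rr * r_att[:, None]
    closed = np.stack([r_closed * np.cos(theta_u)[:, None],
                       r_closed * np.sin(theta_u)[:, None],
                       z_closed], axis=-1)
    if alpha == 0.0:
        # exact unit normals of the graph z(r, θ): n ∝ (−∇z, 1).  Using the
        # analytic normal field (instead of discrete vertex normals) keeps
        # the offset boundary walls free of spurious micro-overhangs at the
        # coaptation apex and commissures.
        dz_att = np.gradient(z_att, u) / dtheta      # dz_att/dθ
        dR_att = np.gradient(r_att, u) / dtheta
        dzdr = 2.0 * rr * (z_att[:, None] - z_apex) / r_att[:, None]
        dzdtheta_over_r = rr * (dz_att[:, None]
                                - 2.0 * (z_att[:, None] - z_apex)
                                * dR_att[:, None] / r_att[:, None]) \
            / r_att[:, None]
        ct = np.cos(theta_u)[:, None]
        st = np.sin(theta_u)[:, None]
        gx = dzdr * ct - dzdtheta_over_r * st
        gy = dzdr * st + dzdtheta_over_r * ct
        normals = np.stack([-gx, -gy, np.ones_like(gx)], axis=-1)
        normals /= np.linalg.norm(normals, axis=-1, keepdims=True)
        return closed, normals


    # fully open free edge: near-wall arc at the commissure level, with
    # enough radial clearance that the loft never degenerates
    margin = max(3.0 * p.leaflet_thickness, 1.8)
    r_open = profile.radius_fn(np.full_like(u, z_comm), theta_u) - margin
    free_open = np.stack([r_open * np.cos(theta_u),
                          r_open * np.sin(theta_u),
                          np.full_like(u, z_comm)], axis=-1)
    vv = v[None, :, None]
    open_ = (1 - vv) * free_open[:, None, :] + vv * att[:, None, :]
    return (1 - alpha) * closed + alpha * open_, None


def _thicken_sheet(surf: np.ndarray, thickness: float,
                   collapse_v0: bool = False,
                   normals_grid: np.ndarray | None = None) -> SurfaceMesh:
    """Closed genus-0 shell from a midsurface grid by ±t/2 normal offset.

    With ``collapse_v0`` the v = 0 row is welded into a single apex vertex
    (used for the closed leaflet whose free-edge rows converge on the
    coaptation point at the axis).
    """
    nu1, nv1, _ = surf.shape
    if collapse_v0:
        apex = surf[:, 0, :].mean(axis=0)
        grid = surf[:, 1:, :].reshape(-1, 3)
        verts = np.vstack([apex[None, :], grid])
        nvg = nv1 - 1

        def idx(i, j):  # j in [1, nv1-1]
            return 1 + i * nvg + (j - 1)

        faces = [[0, idx(i, 1), idx(i + 1, 1)] for i in range(nu1 - 1)]
        for i in range(nu1 - 1):
            for j in range(1, nv1 - 1):
                a, b = idx(i, j), idx(i, j + 1)
                c, d = idx(i + 1, j + 1), idx(i + 1, j)
                faces.append([a, b, c])
                faces.append([a, c, d])
        faces = np.asarray(faces, dtype=np.int64)
        loop = ([0]
                + [idx(0, j) for j in range(1, nv1)]
                + [idx(i, nv1 - 1) for i in range(1, nu1)]
                + [idx(nu1 - 1, j) for j in range(nv1 - 2, 0, -1)])
    else:
        verts = surf.reshape(-1, 3)
        faces = _grid_faces(nu1, nv1, wrap=False)

        def idx(i, j):
            return i * nv1 + j

        loop = ([idx(i, 0) for i in range(nu1)]
                + [idx(nu1 - 1, j) for j in range(1, nv1)]
                + [idx(i, nv1 - 1) for i in range(nu1 - 2, -1, -1)]
                + [idx(0, j) for j in range(nv1 - 2, 0, -1)])

    if normals_grid is not None:
        if collapse_v0:
            apex_n = normals_grid[:, 0, :].mean(axis=0)
            apex_n /= np.linalg.norm(apex_n)
            normals = np.vstack([apex_n[None, :],
                                 normals_grid[:, 1:, :].reshape(-1, 3)])
        else:
            normals = normals_grid.reshape(-1, 3)
    else:
        mid = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        normals = np.asarray(mid.vertex_normals)
    top = verts + 0.5 * thickness * normals
    bottom = verts - 0.5 * thickness * normals

    n_verts = len(verts)
    top_faces = faces
    bottom_faces = faces[:, ::-1] + n_verts
    band = []
    for a, b in zip(loop, loop[1:] + loop[:1]):
        band.append([a, b, b + n_verts])
        band.append([a, b + n_verts, a + n_verts])
    band = np.asarray(band, dtype=np.int64)

    mesh = SurfaceMesh(np.vstack([top, bottom]),
                       np.vstack([top_faces, bottom_faces, band]))
    return _orient_outward(mesh)


def build_leaflet_mesh(params: RootGeometryParams, leaflet_index: int = 0,
                       state="closed", profile: RootProfile | None = None,
                       resolution: dict | None = None) -> SurfaceMesh:
    """Closed thin shell of one valve leaflet.

    In the closed state the free edges of all leaflets meet at the
    centerline (coaptation); ``state=("open", f)`` morphs kinematically
    toward a wall-hugging free edge.  Leaflet ``i`` is leaflet 0 rotated by
    i·2π/n about the flow axis, so the assembly is exactly n-fold symmetric.
    """
    if leaflet_index >= params.n_leaflets or leaflet_index < 0:
        raise InputError("leaflet_index must be in [0, n_leaflets)")
    alpha = _normalize_state(state)
    profile = profile or build_root_profile(params)
    resolution = resolution or {}
    nu = int(resolution.get("n_u", 64))
    nv = int(resolution.get("n_v", 20))
    surf, normals = _leaflet_midsurface(profile, alpha, nu, nv)
    mesh = _thicken_sheet(surf, params.leaflet_thickness,
                          collapse_v0=(alpha == 0.0), normals_grid=normals)
    if leaflet_index:
        ang = leaflet_index * 2 * np.pi / params.n_leaflets
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        mesh = SurfaceMesh(mesh.vertices @ rot.T, mesh.faces,
                           mesh.component_labels)
    return mesh


def orifice_area(params: RootGeometryParams, state="open",
                 n_samples: int = 400) -> float:
    """Planar area (mm²) enclosed by the projected free edges of all
    leaflets — the valve orifice seen from above."""
    alpha = _normalize_state("open" if state == "open" else state)
    profile = build_root_profile(params)
    n = params.n_leaflets
    pts = []
    surf, _ = _leaflet_midsurface(profile, alpha, n_samples - 1, 1)
    free = surf[:, 0, :]     # v = 0 row is the free edge
    for i in range(n):
        ang = i * 2 * np.pi / n
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s], [s, c]])
        pts.append(free[:-1, :2] @ rot.T)
    poly = np.vstack(pts)
    x, y = poly[:, 0], poly[:, 1]
    return float(0.5 * np.abs(np.dot(x, np.roll(y, -1))
                              - np.dot(y, np.roll(x, -1))))


# --------------------------------------------------------------------------
# assembly + diagnostics
# --------------------------------------------------------------------------

def assemble_phantom(params: RootGeometryParams, state="closed",
                     resolution: dict | None = None) -> SurfaceMesh:
    """Root shell plus n leaflet shells as one labelled mesh collection.

    Components are disjoint watertight bodies (no boolean union), matching
    a multi-material print of wall and leaflets.
    """
    profile = build_root_profile(params)
    root = build_root_mesh(profile, params, resolution)
    pieces = [SurfaceMesh(root.vertices, root.faces)]
    labels = ["wall"]
    for i in range(params.n_leaflets):
        pieces.append(build_leaflet_mesh(params, i, state, profile,
                                         resolution))
        labels.append(f"leaflet_{i + 1}")
    return SurfaceMesh.concatenate(pieces, labels)


def mesh_diagnostics(mesh: SurfaceMesh, max_rays: int | None = 4000) -> dict:
    """Printability checks: watertightness, Euler characteristic, volume,
    minimum shell thickness (inward ray casting from face centroids), and
    connected-component count."""
    if len(mesh.faces) == 0:
        raise InputError("empty mesh")
    tm = mesh.to_trimesh()
    watertight = bool(tm.is_watertight)
    euler = int(tm.euler_number)
    volume = float(tm.volume) if watertight else float(abs(tm.volume))
    n_components = int(tm.body_count)

    # thickness per body: components of an assembly may interpenetrate
    # (coapting leaflets), so each shell is ray-cast against itself only
    if mesh.component_labels is not None:
        groups = [mesh.select(lab).faces
                  for lab in dict.fromkeys(mesh.component_labels)]
    elif n_components > 1:
        comp = trimesh.graph.connected_component_labels(
            tm.face_adjacency, node_count=len(mesh.faces))
        groups = [mesh.faces[comp == c] for c in np.unique(comp)]
    else:
        groups = [mesh.faces]
    min_thickness = np.inf
    for faces in groups:
        tri = mesh.vertices[faces]
        centroids = tri.mean(axis=1)
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norms = np.linalg.norm(fn, axis=1, keepdims=True)
        ok = norms[:, 0] > 1e-12
        fn = fn[ok] / norms[ok]
        centroids = centroids[ok]
        budget = None if max_rays is None else max(
            1, max_rays // len(groups))
        if budget is not None and len(centroids) > budget:
            stride = max(1, len(centroids) // budget)
            centroids, fn = centroids[::stride], fn[::stride]
        d = first_hit_distances(centroids, -fn, tri)
        finite = np.isfinite(d)
        if finite.any():
            min_thickness = min(min_thickness, float(np.min(d[finite])))
    min_thickness = float(min_thickness) if np.isfinite(min_thickness) \
        else float("nan")
    return {
        "watertight": watertight,
        "euler_characteristic": euler,
        "volume_mm3": volume,
        "min_thickness_mm": min_thickness,
        "n_components": n_components,
    }


# --------------------------------------------------------------------------
# STL I/O
# --------------------------------------------------------------------------

def export_stl(mesh: SurfaceMesh, path: str | Path, ascii: bool = False,
               sidecar: bool = True, provenance: dict | None = None) -> Path:
    """Write binary (default) or ASCII STL plus a JSON metadata sidecar.

    STL is unit-less; the sidecar records the mm/flow-axis convention and
    any parameter provenance the caller supplies.
    """
    path = Path(path)
    tm = mesh.to_trimesh()
    try:
        if ascii:
            path.write_text(
                trimesh.exchange.stl.export_stl_ascii(tm))
        else:
            path.write_bytes(trimesh.exchange.stl.export_stl(tm))
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
    if sidecar:
        meta = {"coordinate_convention": COORDINATE_CONVENTION,
                "n_faces": int(len(mesh.faces)),
                "provenance": provenance or {}}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def import_stl(path: str | Path) -> SurfaceMesh:
    """Read an STL file (binary or ASCII, sniffed by dialect)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        with open(path, "rb") as fh:
            data = trimesh.exchange.stl.load_stl(fh)
    except Exception as exc:  # malformed payload
        raise FormatError(f"malformed STL {path}: {exc}",
                          byte_offset=0) from exc
    if not len(data.get("faces", ())):
        raise FormatError(f"no facets parsed from {path}", byte_offset=0)
    tm = trimesh.Trimesh(**data, process=False)
    # STL stores a triangle soup; weld coincident vertices to recover the
    # shared-vertex mesh (coordinates and face count are unchanged)
    tm.merge_vertices()
    return SurfaceMesh.from_trimesh(tm)
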