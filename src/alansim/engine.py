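"""Monte Carlo radiative transfer engine.

Photon packets carry a share ``w = L/N`` of their source's radiant flux
(the unit-time normalisation, Delta-t = 1 s).  As a packet travels a chord
``l`` through a voxel of volume ``V`` in a medium of refractive index
``n_v``, it adds ``w * l * n_v / (c * V)`` to that voxel's time-averaged
energy density, reported in W m^-3.  Packet lifetimes end by absorption at
a surface (reflectance draw fails) or by pruning at the domain boundary.

The per-packet loop is compiled with numba (:mod:`alansim._kernels`); the
operations here are the readable reference path and the public API.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from ._rng import PcgStream, stream_seed
from .errors import ConfigurationError
from .photometry import (
    DirectionSampler,
    EmissionSpectrum,
    sample_direction,
    sample_wavelength,
    spectrum_cdf,
)
from .twin import Scene, SurfaceAttribute

SPEED_OF_LIGHT = K.SPEED_OF_LIGHT
RAY_EPS = K.RAY_EPS

#: Clear-air scattering coefficient (m^-1): effectively scatter-free air.
AIR_MU_S = 1e-6

_WL_GRID = np.arange(380.0, 781.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Material:
    """Bulk optical properties of a propagation medium."""

    name: str
    refractive_index: float = 1.0
    scattering_coefficient: float = 0.0  # mu_s, m^-1
    anisotropy: float = 0.0              # Henyey-Greenstein g

    def __post_init__(self):
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.scattering_coefficient < 0:
            raise ValueError("scattering coefficient must be >= 0")
        if not -1.0 < self.anisotropy < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")


def air(mu_s: float = AIR_MU_S) -> Material:
    return Material("air", 1.0, mu_s, 0.0)


@dataclass
class PhotonPacket:
    """The Monte Carlo sampling unit."""

    position: np.ndarray
    direction: np.ndarray
    wavelength: float          # nm
    power: float               # W; the per-packet share L/N
    material: int = 0          # index into the compiled material table
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.alive and self.power <= 0:
            raise ValueError("live packet must carry positive power")


class VoxelGrid:
    """Regular isotropic voxel accumulator of time-averaged energy density."""

    def __init__(self, origin, voxel_size: float, shape):
        self.origin = np.asarray(origin, dtype=float)
        self.voxel_size = float(voxel_size)
        self.shape = tuple(int(s) for s in shape)
        if self.voxel_size <= 0 or any(s < 1 for s in self.shape):
            raise ValueError("voxel_size must be > 0 and shape positive")
        self.data = np.zeros(self.shape)
        self.stats: dict = {}

    @property
    def bounds(self):
        hi = self.origin + np.asarray(self.shape) * self.voxel_size
        return self.origin.copy(), hi

    def voxel_of(self, position) -> tuple[int, int, int] | None:
        """Integer voxel index of a point, or None outside the grid."""
        idx = np.floor((np.asarray(position) - self.origin) / self.voxel_size).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            return None
        return tuple(idx)

    def contains(self, position) -> bool:
        return self.voxel_of(position) is not None

    def slice_isoheight(self, height: float) -> np.ndarray:
        """The voxel layer containing `height`, row-major north-up (row 0 = max y)."""
        z0 = self.origin[2]
        z1 = z0 + self.shape[2] * self.voxel_size
        if not (z0 <= height <= z1):
            raise ValueError(f"height {height} outside grid z-range [{z0}, {z1}]")
        k = min(int(math.floor((height - z0) / self.voxel_size)), self.shape[2] - 1)
        return self.data[:, :, k].T[::-1].copy()

    def to_netcdf(self, path, seed=None, n_packets=None) -> None:
        import xarray as xr

        xs = self.origin[0] + (np.arange(self.shape[0]) + 0.5) * self.voxel_size
        ys = self.origin[1] + (np.arange(self.shape[1]) + 0.5) * self.voxel_size
        zs = self.origin[2] + (np.arange(self.shape[2]) + 0.5) * self.voxel_size
        ds = xr.Dataset(
            {"energy_density": (("x", "y", "z"), self.data)},
            coords={"x": xs, "y": ys, "z": zs},
            attrs={
                "units": "W m-3",
                "voxel_size": self.voxel_size,
                "origin": [float(v) for v in self.origin],
                "seed": -1 if seed is None else int(seed),
                "n_packets": -1 if n_packets is None else int(n_packets),
            },
        )
        ds.to_netcdf(str(path), engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "VoxelGrid":
        import xarray as xr

        with xr.open_dataset(str(path), engine="scipy") as ds:
            origin = np.asarray(ds.attrs["origin"], dtype=float)
            vs = float(ds.attrs["voxel_size"])
            data = np.asarray(ds["energy_density"].values)
        grid = cls(origin, vs, data.shape)
        grid.data = data
        return grid

    def to_npz(self, path) -> None:
        np.savez_compressed(
            str(path), energy_density=self.data, origin=self.origin, voxel_size=self.voxel_size
        )

    @classmethod
    def from_npz(cls, path) -> "VoxelGrid":
        with np.load(str(path)) as z:
            grid = cls(z["origin"], float(z["voxel_size"]), z["energy_density"].shape)
            grid.data = z["energy_density"]
        return grid


@dataclass
class LightSourceInstance:
    """A posed luminaire: direction sampler + scaled spectrum + radiant flux."""

    sampler: DirectionSampler
    spectrum: EmissionSpectrum
    radiant_flux: float  # W (engine scale)
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    stream_id: int | None = None
    name: str = "lamp"

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.radiant_flux <= 0:
            raise ValueError("radiant flux must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")


@dataclass
class SimConfig:
    """Simulation parameters: packets per source, seed, domain, voxel size."""

    bounds_min: np.ndarray
    bounds_max: np.ndarray
    voxel_size: float = 1.0
    n_packets: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        self.bounds_min = np.asarray(self.bounds_min, dtype=float)
        self.bounds_max = np.asarray(self.bounds_max, dtype=float)
        if self.n_packets < 1:
            raise ValueError("need at least one packet per source")
        if np.any(self.bounds_max <= self.bounds_min):
            raise ValueError("domain bounds are empty")

    def make_grid(self) -> VoxelGrid:
        shape = np.ceil((self.bounds_max - self.bounds_min) / self.voxel_size - 1e-9).astype(int)
        return VoxelGrid(self.bounds_min, self.voxel_size, np.maximum(shape, 1))


# ---------------------------------------------------------------------------
# octree
# ---------------------------------------------------------------------------

class Octree:
    """Hit-scan octree over a triangle soup.

    The domain box is split recursively into eight equal-volume octants until
    a node holds at most ``max_per_leaf`` triangles or ``max_depth`` is
    reached; a triangle is registered in every leaf whose box its bounding
    box overlaps.
    """

    def __init__(self, triangles: np.ndarray, max_per_leaf: int = 16, max_depth: int = 10):
        tris = np.asarray(triangles, dtype=float)
        if tris.ndim != 3 or tris.shape[1:] != (3, 3):
            raise ValueError("triangles must be (T, 3, 3)")
        self.triangles = tris
        self.tri_v0 = np.ascontiguousarray(tris[:, 0])
        self.tri_v1 = np.ascontiguousarray(tris[:, 1])
        self.tri_v2 = np.ascontiguousarray(tris[:, 2])
        T = len(tris)
        if T == 0:
            self.node_min = np.zeros((0, 3))
            self.node_max = np.zeros((0, 3))
            self.node_child0 = np.zeros(0, dtype=np.int64)
            self.leaf_start = np.zeros(0, dtype=np.int64)
            self.leaf_count = np.zeros(0, dtype=np.int64)
            self.leaf_tris = np.zeros(0, dtype=np.int64)
            self.depth = 0
            return
        lo = tris.min(axis=(0, 1)) - 1e-6
        hi = tris.max(axis=(0, 1)) + 1e-6
        tb_lo = tris.min(axis=1)
        tb_hi = tris.max(axis=1)
        node_min, node_max, node_child0 = [], [], []
        leaf_start, leaf_count, leaf_tris = [], [], []
        max_seen_depth = [0]

        def build(bmin, bmax, idx, depth):
            node = len(node_min)
            node_min.append(bmin)
            node_max.append(bmax)
            node_child0.append(-1)
            leaf_start.append(0)
            leaf_count.append(0)
            max_seen_depth[0] = max(max_seen_depth[0], depth)
            if len(idx) <= max_per_leaf or depth >= max_depth:
                leaf_start[node] = len(leaf_tris)
                leaf_count[node] = len(idx)
                leaf_tris.extend(idx)
                return node
            mid = (bmin + bmax) / 2.0
            children = []
            for ox in range(2):
                for oy in range(2):
                    for oz in range(2):
                        cmin = np.array(
                            [bmin[0] if ox == 0 else mid[0],
                             bmin[1] if oy == 0 else mid[1],
                             bmin[2] if oz == 0 else mid[2]])
                        cmax = np.array(
                            [mid[0] if ox == 0 else bmax[0],
                             mid[1] if oy == 0 else bmax[1],
                             mid[2] if oz == 0 else bmax[2]])
                        sub = [t for t in idx
                               if np.all(tb_hi[t] >= cmin) and np.all(tb_lo[t] <= cmax)]
                        children.append((cmin, cmax, sub))
            # child nodes must be contiguous: reserve, then build
            child0 = len(node_min)
            node_child0[node] = child0
            for cmin, cmax, sub in children:
                node_min.append(cmin)
                node_max.append(cmax)
                node_child0.append(-1)
                leaf_start.append(0)
                leaf_count.append(0)
            for k, (cmin, cmax, sub) in enumerate(children):
                _fill(child0 + k, cmin, cmax, sub, depth + 1)
            return node

        def _fill(node, bmin, bmax, idx, depth):
            max_seen_depth[0] = max(max_seen_depth[0], depth)
            if len(idx) <= max_per_leaf or depth >= max_depth:
                leaf_start[node] = len(leaf_tris)
                leaf_count[node] = len(idx)
                leaf_tris.extend(idx)
                return
            mid = (bmin + bmax) / 2.0
            children = []
            for ox in range(2):
                for oy in range(2):
                    for oz in range(2):
                        cmin = np.array(
                            [bmin[0] if ox == 0 else mid[0],
                             bmin[1] if oy == 0 else mid[1],
                             bmin[2] if oz == 0 else mid[2]])
                        cmax = np.array(
                            [mid[0] if ox == 0 else bmax[0],
                             mid[1] if oy == 0 else bmax[1],
                             mid[2] if oz == 0 else bmax[2]])
                        sub = [t for t in idx
                               if np.all(tb_hi[t] >= cmin) and np.all(tb_lo[t] <= cmax)]
                        children.append((cmin, cmax, sub))
            child0 = len(node_min)
            node_child0[node] = child0
            for cmin, cmax, sub in children:
                node_min.append(cmin)
                node_max.append(cmax)
                node_child0.append(-1)
                leaf_start.append(0)
                leaf_count.append(0)
            for k, (cmin, cmax, sub) in enumerate(children):
                _fill(child0 + k, cmin, cmax, sub, depth + 1)

        build(lo, hi, list(range(T)), 0)
        self.node_min = np.asarray(node_min)
        self.node_max = np.asarray(node_max)
        self.node_child0 = np.asarray(node_child0, dtype=np.int64)
        self.leaf_start = np.asarray(leaf_start, dtype=np.int64)
        self.leaf_count = np.asarray(leaf_count, dtype=np.int64)
        self.leaf_tris = np.asarray(leaf_tris, dtype=np.int64)
        self.depth = max_seen_depth[0]

    def kernel_args(self):
        return (self.tri_v0, self.tri_v1, self.tri_v2,
                self.node_min, self.node_max, self.node_child0,
                self.leaf_start, self.leaf_count, self.leaf_tris)


def build_octree(triangles, max_per_leaf: int = 16, max_depth: int = 10) -> Octree:
    """Build a hit-scan octree over a (T, 3, 3) triangle array."""
    return Octree(triangles, max_per_leaf, max_depth)


@dataclass(frozen=True)
class SurfaceHit:
    distance: float
    triangle: int


def nearest_surface_hit(octree: Octree, origin, direction) -> SurfaceHit | None:
    """Nearest ray-triangle intersection beyond the ray epsilon, or None."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    t, tri = K.nearest_hit(o[0], o[1], o[2], d[0], d[1], d[2],
                           *octree.kernel_args())
    if tri < 0:
        return None
    return SurfaceHit(float(t), int(tri))


# ---------------------------------------------------------------------------
# scene compilation
# ---------------------------------------------------------------------------

class CompiledScene:
    """Arrays the kernels need: triangle soup + attributes + materials + octree.

    Material index 0 is always exterior air.
    """

    def __init__(self, scene: Scene | None, materials: dict[str, Material] | None = None,
                 diffuse_uniform: bool = False, max_per_leaf: int = 16, max_depth: int = 10):
        mats = {"air": air()}
        if scene is not None and scene.materials:
            for name, m in scene.materials.items():
                mats.setdefault(name, m)
        if materials:
            for name, m in materials.items():
                mats[name] = m
        self.material_names = ["air"] + [n for n in mats if n != "air"]
        self.material_index = {n: i for i, n in enumerate(self.material_names)}
        self.mat_n = np.array([mats[n].refractive_index for n in self.material_names])
        self.mat_mu_s = np.array([mats[n].scattering_coefficient for n in self.material_names])
        self.mat_g = np.array([mats[n].anisotropy for n in self.material_names])
        self.diffuse_uniform = diffuse_uniform
        self.wl_grid = _WL_GRID

        if scene is None:
            tris = np.zeros((0, 3, 3))
            tags: list[str] = []
            self.attributes: dict[str, SurfaceAttribute] = {}
        else:
            tris, tags = scene.all_triangles()
            self.attributes = scene.attributes
        tag_order = sorted(set(tags))
        self.tag_index = {t: i for i, t in enumerate(tag_order)}
        A = max(len(tag_order), 1)
        NW = len(self.wl_grid)
        self.attr_spec = np.zeros(A)
        self.attr_spec_refl = np.zeros((A, NW))
        self.attr_diff_refl = np.zeros((A, NW))
        self.attr_iface = np.full((A, 2), -1, dtype=np.int64)
        for tag, i in self.tag_index.items():
            a = self.attributes[tag]
            self.attr_spec[i] = a.specularity
            self.attr_spec_refl[i] = a.specular_reflectance(self.wl_grid)
            self.attr_diff_refl[i] = a.diffuse_reflectance(self.wl_grid)
            if a.interface is not None:
                m1, m2 = a.interface
                for m in (m1, m2):
                    if m not in self.material_index:
                        raise ConfigurationError(f"interface names unknown material {m!r}")
                self.attr_iface[i, 0] = self.material_index[m1]
                self.attr_iface[i, 1] = self.material_index[m2]
        self.tri_attr = np.array([self.tag_index[t] for t in tags], dtype=np.int64)
        self.octree = Octree(tris, max_per_leaf, max_depth)

    def reflectance_at(self, attr_index: int, wavelength: float, specular: bool) -> float:
        idx = int(np.clip(round(wavelength - self.wl_grid[0]), 0, len(self.wl_grid) - 1))
        table = self.attr_spec_refl if specular else self.attr_diff_refl
        return float(table[attr_index, idx])


def compile_scene(scene: Scene | None, materials=None, **kw) -> CompiledScene:
    return CompiledScene(scene, materials, **kw)


# ---------------------------------------------------------------------------
# single-step operations (reference path)
# ---------------------------------------------------------------------------

def emit_packet(source: LightSourceInstance, n_packets: int, rng) -> PhotonPacket:
    """Emit one packet carrying radiant_flux / n_packets watts."""
    d_local = sample_direction(source.sampler, rng)
    d = source.rotation @ d_local
    wl = sample_wavelength(source.spectrum, rng)
    return PhotonPacket(
        position=source.translation.copy(),
        direction=d / np.linalg.norm(d),
        wavelength=wl,
        power=source.radiant_flux / n_packets,
    )


def sample_scattering_distance(mu_s: float, rng) -> float:
    """Exponential free path -ln(U)/mu_s; infinite for mu_s = 0."""
    if mu_s < 0:
        raise ValueError("mu_s must be >= 0")
    if mu_s == 0:
        return math.inf
    u = rng.open_unit() if isinstance(rng, PcgStream) else max(float(rng.random()), 1e-300)
    return -math.log(u) / mu_s


def deposit(grid: VoxelGrid, packet: PhotonPacket, path_length: float,
            refractive_index: float = 1.0) -> None:
    """Add one within-voxel chord's energy-density contribution.

    The segment must lie inside a single voxel; callers splitting longer
    paths use the traversal in :func:`step` / the compiled kernel.
    """
    if path_length < 0:
        raise ValueError("path length must be >= 0")
    start = packet.position
    end = packet.position + packet.direction * path_length
    idx = grid.voxel_of(start)
    if idx is None:
        raise ValueError("segment start lies outside the grid")
    lo = grid.origin + np.asarray(idx) * grid.voxel_size
    hi = lo + grid.voxel_size
    tol = 1e-9 * max(1.0, grid.voxel_size)
    if np.any(end < lo - tol) or np.any(end > hi + tol):
        raise ValueError("segment crosses a voxel boundary; caller must split it")
    grid.data[idx] += (
        packet.power * path_length * refractive_index
        / (SPEED_OF_LIGHT * grid.voxel_size**3)
    )


def reflect(packet: PhotonPacket, surface_normal, attribute: SurfaceAttribute, rng,
            diffuse_uniform: bool = False) -> PhotonPacket | None:
    """Surface interaction: mode draw, survival draw, new direction.

    Returns the packet with its direction updated, or None when the packet
    is absorbed (killed).  The normal must be unit length and oppose the
    incident direction.
    """
    n = np.asarray(surface_normal, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("surface normal must be unit length")
    d = packet.direction
    if d @ n >= 0:
        raise ValueError("packet must be incident on the surface (direction . normal < 0)")
    u_mode = float(rng.random())
    u_surv = float(rng.random())
    specular = u_mode < attribute.specularity
    curve = attribute.specular_reflectance if specular else attribute.diffuse_reflectance
    if u_surv >= float(curve(packet.wavelength)):
        packet.alive = False
        return None
    if specular:
        new_d = d - 2.0 * (d @ n) * n
    else:
        u1 = float(rng.random())
        u2 = float(rng.random())
        fn = K.uniform_hemisphere if diffuse_uniform else K.cosine_hemisphere
        new_d = np.array(fn(n[0], n[1], n[2], u1, u2))
    packet.direction = new_d / np.linalg.norm(new_d)
    packet.position = packet.position + n * RAY_EPS
    return packet


def cross_interface(packet: PhotonPacket, interface: tuple[str, str], surface_normal,
                    cscene: CompiledScene) -> PhotonPacket:
    """Cross a material interface: swap cached material and refract.

    Total internal reflection reflects specularly and keeps the material.
    """
    for m in interface:
        if m not in cscene.material_index:
            raise ConfigurationError(f"interface names unknown material {m!r}")
    m1, m2 = (cscene.material_index[m] for m in interface)
    other = m2 if packet.material == m1 else m1
    n = np.asarray(surface_normal, dtype=float)
    d = packet.direction
    if d @ n > 0:
        n = -n
    dx, dy, dz, crossed = K.refract(d[0], d[1], d[2], n[0], n[1], n[2],
                                    cscene.mat_n[packet.material], cscene.mat_n[other])
    packet.direction = np.array([dx, dy, dz])
    if crossed:
        packet.material = other
        packet.position = packet.position - n * RAY_EPS
    else:
        packet.position = packet.position + n * RAY_EPS
    return packet


def scatter(packet: PhotonPacket, material: Material, rng) -> PhotonPacket:
    """Henyey-Greenstein deflection about the current direction."""
    u1 = float(rng.random())
    u2 = float(rng.random())
    cos_t = K.hg_cosine(material.anisotropy, u1)
    d = packet.direction
    packet.direction = np.array(K.deflect(d[0], d[1], d[2], cos_t, 2.0 * math.pi * u2))
    return packet


def step(packet: PhotonPacket, cscene: CompiledScene, grid: VoxelGrid, rng,
         scatter_distance: float | None = None) -> str:
    """Advance a packet by one event; returns the event kind.

    The three distances of the propagation loop are compared: nearest
    surface, scattering free path, and current-voxel boundary.  The packet
    deposits along the traversed sub-segment (which by construction lies in
    one voxel) and the event is dispatched.  Event kinds: ``"surface"``,
    ``"scatter"``, ``"voxel-cross"``, ``"pruned"``.
    """
    if not packet.alive:
        raise ValueError("cannot step a dead packet")
    if not (np.all(np.isfinite(packet.position)) and np.all(np.isfinite(packet.direction))):
        raise AssertionError("packet state is not finite (internal invariant failure)")
    idx = grid.voxel_of(packet.position)
    if idx is None:
        packet.alive = False
        return "pruned"
    mu = cscene.mat_mu_s[packet.material]
    n_v = cscene.mat_n[packet.material]
    d_scat = scatter_distance if scatter_distance is not None else sample_scattering_distance(mu, rng)
    hit = nearest_surface_hit(cscene.octree, packet.position, packet.direction)
    d_surf = hit.distance if hit is not None else math.inf
    # distance to the boundary of the current voxel
    lo = grid.origin + np.asarray(idx) * grid.voxel_size
    hi = lo + grid.voxel_size
    d_vox = math.inf
    for ax in range(3):
        da = packet.direction[ax]
        if da > 0:
            d_vox = min(d_vox, (hi[ax] - packet.position[ax]) / da)
        elif da < 0:
            d_vox = min(d_vox, (lo[ax] - packet.position[ax]) / da)
    d_min = min(d_surf, d_scat, d_vox)
    grid.data[idx] += packet.power * d_min * n_v / (SPEED_OF_LIGHT * grid.voxel_size**3)
    packet.position = packet.position + packet.direction * d_min
    if d_surf <= d_scat and d_surf <= d_vox:
        tri = hit.triangle
        oct_ = cscene.octree
        nx, ny, nz = K.triangle_normal_against(
            oct_.tri_v0, oct_.tri_v1, oct_.tri_v2, tri,
            packet.direction[0], packet.direction[1], packet.direction[2])
        normal = np.array([nx, ny, nz])
        a = int(cscene.tri_attr[tri])
        tag = [t for t, i in cscene.tag_index.items() if i == a][0]
        attr = cscene.attributes[tag]
        if attr.interface is not None:
            cross_interface(packet, attr.interface, normal, cscene)
        else:
            reflect(packet, normal, attr, rng, cscene.diffuse_uniform)
        return "surface"
    if d_scat <= d_vox:
        mat = Material("m", cscene.mat_n[packet.material],
                       cscene.mat_mu_s[packet.material], cscene.mat_g[packet.material])
        scatter(packet, mat, rng)
        return "scatter"
    # nudge across the boundary so the next voxel lookup is unambiguous
    packet.position = packet.position + packet.direction * (1e-9 * grid.voxel_size)
    if grid.voxel_of(packet.position) is None:
        packet.alive = False
        return "pruned"
    return "voxel-cross"


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def _source_kernel_args(source: LightSourceInstance):
    s = source.sampler
    cdf = spectrum_cdf(source.spectrum)
    return (
        float(source.translation[0]), float(source.translation[1]), float(source.translation[2]),
        np.ascontiguousarray(source.rotation),
        s.azimuthal_cdf, s.azimuth_angles, s.azimuth_widths,
        s.polar_angles, np.ascontiguousarray(s.per_plane_polar_cdfs),
        source.spectrum.wavelengths, source.spectrum.spectral_flux, cdf,
    )


def run_simulation(scene: Scene | CompiledScene | None,
                   sources: list[LightSourceInstance],
                   config: SimConfig) -> VoxelGrid:
    """Run the full MCRT loop: sources x N packets to absorption or pruning.

    Deterministic for a fixed master seed; each source consumes an
    independent PCG stream keyed by its ``stream_id`` (its list position by
    default), so per-source contributions superpose exactly regardless of
    ordering or subsetting.
    """
    cscene = scene if isinstance(scene, CompiledScene) else compile_scene(scene)
    grid = config.make_grid()
    lo, hi = grid.bounds
    for src in sources:
        if np.any(src.translation < lo) or np.any(src.translation > hi):
            raise ConfigurationError(f"source {src.name!r} lies outside the domain")
    totals = {"pruned": 0, "killed": 0, "exhausted": 0, "emitted": 0}
    for i, src in enumerate(sources):
        sid = src.stream_id if src.stream_id is not None else i
        seed = stream_seed(config.seed, sid)
        n_pruned, n_killed, n_exh = K.run_source(
            *cscene.octree.kernel_args()[:3], cscene.tri_attr,
            *cscene.octree.kernel_args()[3:],
            cscene.attr_spec, cscene.attr_spec_refl, cscene.attr_diff_refl,
            cscene.attr_iface, cscene.diffuse_uniform,
            cscene.mat_n, cscene.mat_mu_s, cscene.mat_g,
            grid.data, float(grid.origin[0]), float(grid.origin[1]), float(grid.origin[2]),
            grid.voxel_size,
            *_source_kernel_args(src),
            src.radiant_flux / config.n_packets, config.n_packets, np.uint64(seed),
            float(cscene.wl_grid[0]), 1.0,
        )
        totals["pruned"] += n_pruned
        totals["killed"] += n_killed
        totals["exhausted"] += n_exh
        totals["emitted"] += config.n_packets
    grid.stats = totals
    return grid


def deposit_along_ray(grid: VoxelGrid, origin, direction, length: float,
                      power: float, refractive_index: float = 1.0) -> float:
    """Deposit a straight chord of given length through the grid (test and
    diagnostic surface over the compiled traversal).  Returns the parameter
    at which the walk stopped (== length unless the ray left the grid)."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    dep = power * refractive_index / (SPEED_OF_LIGHT * grid.voxel_size**3)
    t_stop, _ = K.deposit_segment_walk(
        grid.data, float(grid.origin[0]), float(grid.origin[1]), float(grid.origin[2]),
        grid.voxel_size, o[0], o[1], o[2], d[0], d[1], d[2], float(length), dep)
    return float(t_stop)


def slice_isoheight(grid: VoxelGrid, height: float) -> np.ndarray:
    """Extract the energy-density layer containing `height` (north-up)."""
    return grid.slice_isoheight(height)
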