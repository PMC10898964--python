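"""Digital-twin construction: terrain and building meshes with reflectances.

The simulated environment is a triangle soup built from a terrain height
raster (DTM), building footprints extruded by the maximum DTM/DSM
difference inside each footprint, and a per-tag attribute table giving each
surface its specularity and spectral reflectance curves.

Coordinates are right-handed metres, z up, rasters north-up row-major
(row 0 = northern row), origin at the raster's SW corner.
"""
from __future__ import annotations

import hashlib
import json
import warnings
import zipfile
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, shape as shapely_shape

from .errors import ConfigurationError, ExtentError, GeometryError, ParseError

# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


@dataclass
class HeightRaster:
    """Height grid in metres; ``values[0, :]`` is the northern row.

    No-data cells are NaN and excluded from building-height maxima; sampling
    a NaN cell raises :class:`ExtentError`.
    """

    origin: tuple[float, float]  # (x, y) of SW corner
    cell_size: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2D")
        if np.all(np.isnan(self.values)):
            raise ValueError("raster is entirely no-data")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x (ncols,) and y (nrows,) coordinates of cell centres (y follows rows, north first)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size
        return xs, ys

    def sample(self, x, y):
        """Bilinear sample at (x, y), edge-clamped; outside the raster
        footprint raises :class:`ExtentError`."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.bounds
        eps = 1e-9 * max(1.0, xmax - xmin, ymax - ymin)
        if np.any(x < xmin - eps) or np.any(x > xmax + eps) or np.any(y < ymin - eps) or np.any(y > ymax + eps):
            raise ExtentError("sample point outside raster extent")
        h = self.cell_size
        # fractional cell-centre coordinates, clamped to the centre lattice
        fc = np.clip((x - self.origin[0]) / h - 0.5, 0.0, self.ncols - 1.0)
        fr = np.clip((self.origin[1] + self.nrows * h - y) / h - 0.5, 0.0, self.nrows - 1.0)
        c0 = np.clip(np.floor(fc).astype(int), 0, max(self.ncols - 2, 0))
        r0 = np.clip(np.floor(fr).astype(int), 0, max(self.nrows - 2, 0))
        c1 = np.minimum(c0 + 1, self.ncols - 1)
        r1 = np.minimum(r0 + 1, self.nrows - 1)
        tx = fc - c0
        ty = fr - r0
        v = (
            self.values[r0, c0] * (1 - tx) * (1 - ty)
            + self.values[r0, c1] * tx * (1 - ty)
            + self.values[r1, c0] * (1 - tx) * ty
            + self.values[r1, c1] * tx * ty
        )
        if np.any(np.isnan(v)):
            raise ExtentError("sample touches a no-data raster cell")
        return v if v.ndim else float(v)


def read_esri_ascii(path) -> HeightRaster:
    """Read an ESRI ASCII grid (.asc)."""
    header = {}
    data_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) == 2 and toks[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[toks[0].lower()] = float(toks[1])
            else:
                try:
                    data_lines.append([float(t) for t in toks])
                except ValueError as exc:
                    raise ParseError(path, lineno, f"bad raster value: {exc}") from None
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ParseError(path, 1, f"missing ESRI ASCII header field {key!r}")
    vals = np.concatenate([np.asarray(r) for r in data_lines])
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if vals.size != nrows * ncols:
        raise ParseError(path, 1, f"expected {nrows * ncols} values, found {vals.size}")
    grid = vals.reshape(nrows, ncols)
    if "nodata_value" in header:
        grid = np.where(grid == header["nodata_value"], np.nan, grid)
    return HeightRaster((header["xllcorner"], header["yllcorner"]), header["cellsize"], grid)


def write_esri_ascii(raster: HeightRaster, path, nodata: float = -9999.0) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\nnrows {raster.nrows}\n")
        fh.write(f"xllcorner {float(raster.origin[0])!r}\nyllcorner {float(raster.origin[1])!r}\n")
        fh.write(f"cellsize {float(raster.cell_size)!r}\nNODATA_value {float(nodata)!r}\n")
        vals = np.where(np.isnan(raster.values), nodata, raster.values)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_geotiff(path) -> HeightRaster:
    """Read a single-band GeoTIFF; georeferencing from the ModelPixelScale
    and ModelTiepoint tags (plain TIFFs default to origin 0,0, cell 1 m)."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(float)
        scale_tag = page.tags.get(33550)
        tie_tag = page.tags.get(33922)
        scale = tuple(scale_tag.value) if scale_tag is not None else None
        tie = tuple(tie_tag.value) if tie_tag is not None else None
    cell = float(scale[0]) if scale is not None else 1.0
    if tie is not None:
        # tiepoint maps raster (0,0) [NW corner] to model (X, Y)
        _, _, _, gx, gy, _ = tie[:6]
        origin = (float(gx), float(gy) - values.shape[0] * cell)
    else:
        origin = (0.0, 0.0)
    return HeightRaster(origin, cell, values)


def write_geotiff(raster_or_plane, path, origin=None, cell_size=None) -> None:
    """Write a single-band float64 GeoTIFF with pixel-scale/tiepoint tags."""
    import tifffile

    if isinstance(raster_or_plane, HeightRaster):
        values = raster_or_plane.values
        origin = raster_or_plane.origin
        cell_size = raster_or_plane.cell_size
    else:
        values = np.asarray(raster_or_plane, dtype=float)
        origin = origin or (0.0, 0.0)
        cell_size = cell_size or 1.0
    top_y = origin[1] + values.shape[0] * cell_size
    tifffile.imwrite(
        str(path),
        values.astype(np.float64),
        extratags=[
            (33550, "d", 3, (float(cell_size), float(cell_size), 0.0)),
            (33922, "d", 6, (0.0, 0.0, 0.0, float(origin[0]), float(top_y), 0.0)),
        ],
    )


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------


@dataclass
class FootprintPolygon:
    """A simple polygon footprint (metres) with an attribute tag."""

    polygon: Polygon
    tag: str = "building"

    def __post_init__(self):
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid:
            raise GeometryError(f"footprint polygon is invalid: {shapely.is_valid_reason(self.polygon)}")
        if self.polygon.area <= 0:
            raise GeometryError("footprint polygon has zero area")


def load_footprints_geojson(path, tag: str = "building") -> list[FootprintPolygon]:
    """Load Polygon/MultiPolygon features from a GeoJSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [doc] if doc.get("type") in ("Polygon", "MultiPolygon") else [])
    out = []
    for feat in feats:
        geom = feat.get("geometry", feat)
        g = shapely_shape(geom)
        props = feat.get("properties") or {}
        t = props.get("tag", tag)
        if g.geom_type == "Polygon":
            out.append(FootprintPolygon(g, t))
        elif g.geom_type == "MultiPolygon":
            out.extend(FootprintPolygon(p, t) for p in g.geoms)
        else:
            raise GeometryError(f"unsupported GeoJSON geometry {g.geom_type!r}")
    return out


def write_footprints_geojson(footprints, path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"tag": fp.tag},
            "geometry": json.loads(shapely.to_geojson(fp.polygon)),
        }
        for fp in footprints
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# triangulation (ear clipping with hole bridging)
# ---------------------------------------------------------------------------


def _ring_coords(ring, ccw: bool) -> list[tuple[float, float]]:
    pts = list(ring.coords[:-1])
    area2 = 0.0
    n = len(pts)
    for i in range(n):
        x0, y0 = pts[i]
        x1, y1 = pts[(i + 1) % n]
        area2 += x0 * y1 - x1 * y0
    if (area2 > 0) != ccw:
        pts.reverse()
    return pts


def _bridge_holes(outer: list, holes: list[list]) -> list:
    """Merge holes into the outer ring through bridge edges (earcut-style)."""
    for hole in sorted(holes, key=lambda h: -max(p[0] for p in h)):
        # hole vertex with max x
        hi = max(range(len(hole)), key=lambda i: hole[i][0])
        hx, hy = hole[hi]
        # find visible outer vertex: nearest by connecting-segment validity
        best, best_d = None, np.inf
        for oi, (ox, oy) in enumerate(outer):
            if ox < hx:
                continue
            d = (ox - hx) ** 2 + (oy - hy) ** 2
            if d >= best_d:
                continue
            if _segment_clear(hole[hi], (ox, oy), outer, holes_done=None):
                best, best_d = oi, d
        if best is None:  # fall back to nearest vertex regardless
            best = min(range(len(outer)), key=lambda i: (outer[i][0] - hx) ** 2 + (outer[i][1] - hy) ** 2)
        rotated = hole[hi:] + hole[:hi]
        outer = outer[: best + 1] + rotated + [rotated[0], outer[best]] + outer[best + 1:]
    return outer


def _segment_clear(a, b, outer, holes_done) -> bool:
    """True if segment a-b crosses no outer-ring edge (interior test is
    approximate; adequate for bridge selection)."""
    ax, ay = a
    bx, by = b
    n = len(outer)
    for i in range(n):
        c = outer[i]
        d = outer[(i + 1) % n]
        if c == b or d == b:
            continue
        if _segments_cross(ax, ay, bx, by, c[0], c[1], d[0], d[1]):
            return False
    return True


def _segments_cross(ax, ay, bx, by, cx, cy, dx, dy) -> bool:
    def orient(px, py, qx, qy, rx, ry):
        return (qx - px) * (ry - py) - (qy - py) * (rx - px)

    o1 = orient(ax, ay, bx, by, cx, cy)
    o2 = orient(ax, ay, bx, by, dx, dy)
    o3 = orient(cx, cy, dx, dy, ax, ay)
    o4 = orient(cx, cy, dx, dy, bx, by)
    return (o1 * o2 < 0) and (o3 * o4 < 0)


def _ear_clip(ring: list) -> list[tuple[int, int, int]]:
    """Triangulate a simple CCW ring by ear clipping; returns index triples."""
    n = len(ring)
    idx = list(range(n))
    tris = []
    scale = max(abs(x) + abs(y) for x, y in ring) or 1.0
    eps = 1e-12 * scale * scale

    def cross(i, j, k):
        ax, ay = ring[i]
        bx, by = ring[j]
        cx, cy = ring[k]
        return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)

    def point_in_tri(p, i, j, k):
        px, py = ring[p]
        ax, ay = ring[i]
        bx, by = ring[j]
        cx, cy = ring[k]
        d1 = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
        d2 = (cx - bx) * (py - by) - (cy - by) * (px - bx)
        d3 = (ax - cx) * (py - cy) - (ay - cy) * (px - cx)
        return d1 >= -eps and d2 >= -eps and d3 >= -eps

    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 4 * n * n:
            raise GeometryError("ear clipping failed to converge (degenerate ring?)")
        m = len(idx)
        clipped = False
        for ii in range(m):
            i, j, k = idx[ii - 1], idx[ii], idx[(ii + 1) % m]
            c = cross(i, j, k)
            if c < -eps:
                continue  # reflex
            if abs(c) <= eps:
                # collinear ear: drop the middle vertex, zero-area triangle
                idx.pop(ii)
                clipped = True
                break
            if any(
                point_in_tri(p, i, j, k)
                for p in idx
                if p not in (i, j, k) and ring[p] not in (ring[i], ring[j], ring[k])
            ):
                continue
            tris.append((i, j, k))
            idx.pop(ii)
            clipped = True
            break
        if not clipped:
            # tolerance fallback: clip the least-reflex ear
            ii = max(range(len(idx)), key=lambda t: cross(idx[t - 1], idx[t], idx[(t + 1) % len(idx)]))
            i, j, k = idx[ii - 1], idx[ii], idx[(ii + 1) % len(idx)]
            if cross(i, j, k) > eps:
                tris.append((i, j, k))
            idx.pop(ii)
    if len(idx) == 3 and abs(cross(*idx)) > eps:
        tris.append(tuple(idx))
    return tris


def triangulate_footprint(
    footprint: FootprintPolygon | Polygon,
    max_triangle_area: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate a footprint polygon into a conforming 2D mesh.

    Returns ``(vertices (V, 2), faces (F, 3))``.  The triangles tile the
    polygon exactly (union area equals the polygon area); when
    ``max_triangle_area`` is given the mesh is uniformly midpoint-refined
    until every triangle is at or below the limit.
    """
    poly = footprint.polygon if isinstance(footprint, FootprintPolygon) else footprint
    if not poly.is_valid:
        raise GeometryError(f"polygon is invalid: {shapely.is_valid_reason(poly)}")
    if poly.area <= 0:
        raise GeometryError("polygon has zero area")
    outer = _ring_coords(poly.exterior, ccw=True)
    holes = [_ring_coords(r, ccw=False) for r in poly.interiors]
    ring = _bridge_holes(outer, holes) if holes else outer
    tris = _ear_clip(ring)
    verts = np.asarray(ring, dtype=float)
    faces = np.asarray(tris, dtype=np.int64)
    if faces.size == 0:
        raise GeometryError("triangulation produced no triangles")
    if max_triangle_area is not None:
        while _max_area(verts, faces) > max_triangle_area:
            verts, faces = _subdivide(verts, faces)
    return verts, faces


def _max_area(verts, faces) -> float:
    a = verts[faces[:, 0]]
    b = verts[faces[:, 1]]
    c = verts[faces[:, 2]]
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    return float(np.max(np.abs(cross) / 2.0))


def _subdivide(verts, faces):
    """Global 1->4 midpoint subdivision (conformal: all triangles split)."""
    edge_mid = {}
    verts = list(map(tuple, verts))

    def mid(i, j):
        key = (min(i, j), max(i, j))
        if key not in edge_mid:
            vi, vj = verts[i], verts[j]
            verts.append(((vi[0] + vj[0]) / 2.0, (vi[1] + vj[1]) / 2.0))
            edge_mid[key] = len(verts) - 1
        return edge_mid[key]

    new_faces = []
    for i, j, k in faces:
        ij, jk, ki = mid(i, j), mid(j, k), mid(k, i)
        new_faces += [(i, ij, ki), (ij, j, jk), (ki, jk, k), (ij, jk, ki)]
    return np.asarray(verts, dtype=float), np.asarray(new_faces, dtype=np.int64)


# ---------------------------------------------------------------------------
# surfaces and scene
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReflectanceCurve:
    """Spectral reflectance in [0, 1] on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.size < 1 or (wl.size > 1 and np.any(np.diff(wl) <= 0)):
            raise ValueError("wavelength grid must be strictly increasing")
        if v.shape != wl.shape or np.any(v < 0) or np.any(v > 1):
            raise ValueError("reflectance values must lie in [0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    @classmethod
    def flat(cls, value: float, wl_min: float = 380.0, wl_max: float = 780.0) -> "ReflectanceCurve":
        return cls(np.array([wl_min, wl_max]), np.array([value, value]))

    @classmethod
    def from_file(cls, path) -> "ReflectanceCurve":
        from .photometry import _load_two_column

        wl, v = _load_two_column(path)
        order = np.argsort(wl)
        return cls(wl[order], np.clip(v[order], 0.0, 1.0))

    def __call__(self, wavelengths_nm):
        """Evaluate (edge-held outside the tabulated range, clipped to [0,1])."""
        return np.clip(np.interp(wavelengths_nm, self.wavelengths, self.values), 0.0, 1.0)


@dataclass
class SurfaceAttribute:
    """How a tagged surface interacts with photon packets."""

    specularity: float
    specular_reflectance: ReflectanceCurve
    diffuse_reflectance: ReflectanceCurve
    interface: tuple[str, str] | None = None

    def __post_init__(self):
        if not 0.0 <= self.specularity <= 1.0:
            raise ValueError("specularity must lie in [0, 1]")


@dataclass
class SceneSurface:
    """A triangle mesh (metres) carrying one attribute tag."""

    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray     # (F, 3) int
    tag: str

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (F, 3)")

    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) vertex-triple view of the mesh."""
        return self.vertices[self.faces]

    def drop_degenerate(self, min_area: float = 1e-12) -> "SceneSurface":
        t = self.triangles
        areas = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
        return SceneSurface(self.vertices, self.faces[areas > min_area], self.tag)


@dataclass
class Scene:
    """All tagged surfaces plus the attribute table keyed by tag."""

    surfaces: list[SceneSurface]
    attributes: dict[str, SurfaceAttribute]
    materials: dict[str, "object"] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def all_triangles(self) -> tuple[np.ndarray, list[str]]:
        """Concatenated (T, 3, 3) triangle array and per-triangle tags."""
        tris, tags = [], []
        for s in self.surfaces:
            t = s.triangles
            tris.append(t)
            tags.extend([s.tag] * len(t))
        if not tris:
            return np.zeros((0, 3, 3)), []
        return np.concatenate(tris, axis=0), tags


#: Default specularities: tarmac terrain 1%, brick buildings 0.1%.
DEFAULT_SPECULARITY = {"tarmac": 0.01, "brick": 0.001}


def extrude_terrain(mesh2d: tuple[np.ndarray, np.ndarray], dtm: HeightRaster, tag: str = "tarmac") -> SceneSurface:
    """Lift a 2D mesh onto the DTM: each vertex z is the bilinear DTM sample."""
    verts2d, faces = mesh2d
    z = np.atleast_1d(dtm.sample(verts2d[:, 0], verts2d[:, 1]))
    verts = np.column_stack([verts2d, z])
    return SceneSurface(verts, faces, tag).drop_degenerate()


def building_height(footprint: FootprintPolygon, dtm: HeightRaster, dsm: HeightRaster) -> float:
    """Maximum DSM-DTM difference over raster cells inside the footprint."""
    xs, ys = dtm.cell_centers()
    xmin, ymin, xmax, ymax = footprint.polygon.bounds
    ci = np.where((xs >= xmin - dtm.cell_size) & (xs <= xmax + dtm.cell_size))[0]
    ri = np.where((ys >= ymin - dtm.cell_size) & (ys <= ymax + dtm.cell_size))[0]
    if ci.size == 0 or ri.size == 0:
        raise ExtentError("building footprint covers no raster cells")
    gx, gy = np.meshgrid(xs[ci], ys[ri])
    inside = shapely.contains_xy(footprint.polygon, gx.ravel(), gy.ravel()).reshape(gx.shape)
    if not inside.any():
        raise ExtentError("building footprint covers no raster cells")
    diff = (dsm.values[np.ix_(ri, ci)] - dtm.values[np.ix_(ri, ci)])[inside]
    diff = diff[~np.isnan(diff)]
    if diff.size == 0:
        raise ExtentError("all in-footprint raster cells are no-data")
    return float(np.max(diff))


def extrude_building(
    footprint: FootprintPolygon,
    dtm: HeightRaster,
    dsm: HeightRaster,
    max_triangle_area: float | None = None,
) -> SceneSurface | None:
    """Extrude a footprint into a flat-topped prism.

    Wall bases follow the terrain; the flat cap sits at (maximum in-footprint
    DTM) + h where h is the maximum DSM-DTM difference inside the footprint.
    Returns ``None`` (with a warning) when h <= 0.
    """
    h = building_height(footprint, dtm, dsm)
    if h <= 0:
        warnings.warn(f"building {footprint.tag!r} has non-positive height {h:.3f} m; skipped")
        return None
    verts2d, faces = triangulate_footprint(footprint, max_triangle_area)
    base_z = np.atleast_1d(dtm.sample(verts2d[:, 0], verts2d[:, 1]))
    xs, ys = dtm.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(footprint.polygon, gx.ravel(), gy.ravel()).reshape(gx.shape)
    cap_z = float(np.nanmax(np.where(inside, dtm.values, np.nan))) + h

    all_verts = [np.column_stack([verts2d, base_z])]
    all_faces = []
    n_base = len(verts2d)
    # cap (reuse footprint triangulation at cap height)
    all_verts.append(np.column_stack([verts2d, np.full(n_base, cap_z)]))
    all_faces.append(faces + n_base)
    # walls along each ring edge: two triangles per edge
    offset = 2 * n_base
    wall_verts = []
    wall_faces = []
    rings = [footprint.polygon.exterior, *footprint.polygon.interiors]
    for ring in rings:
        pts = np.asarray(ring.coords[:-1], dtype=float)
        zb = np.atleast_1d(dtm.sample(pts[:, 0], pts[:, 1]))
        n = len(pts)
        for i in range(n):
            j = (i + 1) % n
            a = (pts[i, 0], pts[i, 1], zb[i])
            b = (pts[j, 0], pts[j, 1], zb[j])
            at = (pts[i, 0], pts[i, 1], cap_z)
            bt = (pts[j, 0], pts[j, 1], cap_z)
            k = offset + len(wall_verts)
            wall_verts += [a, b, bt, at]
            wall_faces += [(k, k + 1, k + 2), (k, k + 2, k + 3)]
    all_verts.append(np.asarray(wall_verts).reshape(-1, 3))
    all_faces.append(np.asarray(wall_faces, dtype=np.int64))
    verts = np.concatenate(all_verts, axis=0)
    faces3 = np.concatenate(all_faces, axis=0)
    return SceneSurface(verts, faces3, footprint.tag).drop_degenerate()


def assemble_scene(
    terrain: SceneSurface,
    buildings: list[SceneSurface],
    attributes: dict[str, SurfaceAttribute],
    materials: dict | None = None,
    provenance: dict | None = None,
) -> Scene:
    """Combine surfaces into a scene, checking every tag has an attribute."""
    surfaces = [terrain] + [b for b in buildings if b is not None]
    for s in surfaces:
        if s.tag not in attributes:
            raise ConfigurationError(f"no attribute entry for surface tag {s.tag!r}")
    return Scene(surfaces, attributes, materials or {}, provenance or {})


def default_attributes(
    terrain_reflectance: ReflectanceCurve | None = None,
    building_reflectance: ReflectanceCurve | None = None,
) -> dict[str, SurfaceAttribute]:
    """Tarmac terrain (1% specular) and red-brick buildings (0.1% specular);
    flat 10% / 20% grey reflectance stand-ins unless measured curves are given."""
    tar = terrain_reflectance or ReflectanceCurve.flat(0.10)
    brick = building_reflectance or ReflectanceCurve.flat(0.20)
    return {
        "tarmac": SurfaceAttribute(DEFAULT_SPECULARITY["tarmac"], tar, tar),
        "brick": SurfaceAttribute(DEFAULT_SPECULARITY["brick"], brick, brick),
    }


# ---------------------------------------------------------------------------
# scene archive (zip: mesh OBJ + attributes YAML + provenance JSON)
# ---------------------------------------------------------------------------


def save_scene(scene: Scene, path) -> None:
    """Serialize a scene to a zip archive (OBJ mesh, YAML attributes,
    JSON provenance).  Float coordinates are written with repr so the
    archive round-trips bit-exactly."""
    import yaml

    obj_lines = []
    for s in scene.surfaces:
        obj_lines.append(f"o {s.tag}")
        for v in s.vertices:
            obj_lines.append(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}")
    base = 1
    for s in scene.surfaces:
        obj_lines.append(f"g {s.tag}")
        for f in s.faces:
            obj_lines.append(f"f {f[0] + base} {f[1] + base} {f[2] + base}")
        base += len(s.vertices)
    attr_doc = {}
    for tag, a in scene.attributes.items():
        attr_doc[tag] = {
            "specularity": float(a.specularity),
            "specular_reflectance": {
                "wavelengths": [float(x) for x in a.specular_reflectance.wavelengths],
                "values": [float(x) for x in a.specular_reflectance.values],
            },
            "diffuse_reflectance": {
                "wavelengths": [float(x) for x in a.diffuse_reflectance.wavelengths],
                "values": [float(x) for x in a.diffuse_reflectance.values],
            },
            "interface": list(a.interface) if a.interface else None,
        }
    surf_meta = [{"tag": s.tag, "n_vertices": int(len(s.vertices)), "n_faces": int(len(s.faces))}
                 for s in scene.surfaces]
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("mesh.obj", "\n".join(obj_lines) + "\n")
        zf.writestr("attributes.yaml", yaml.safe_dump({"attributes": attr_doc, "surfaces": surf_meta}))
        zf.writestr("provenance.json", json.dumps(scene.provenance, indent=2, sort_keys=True))


def load_scene(path) -> Scene:
    """Load a scene archive written by :func:`save_scene`."""
    import yaml

    with zipfile.ZipFile(path) as zf:
        obj_text = zf.read("mesh.obj").decode()
        meta = yaml.safe_load(zf.read("attributes.yaml").decode())
        provenance = json.loads(zf.read("provenance.json").decode())
    verts = []
    faces = []
    for line in obj_text.splitlines():
        toks = line.split()
        if not toks:
            continue
        if toks[0] == "v":
            verts.append([float(toks[1]), float(toks[2]), float(toks[3])])
        elif toks[0] == "f":
            faces.append([int(toks[1]) - 1, int(toks[2]) - 1, int(toks[3]) - 1])
    verts = np.asarray(verts)
    faces = np.asarray(faces, dtype=np.int64)
    attributes = {}
    for tag, a in meta["attributes"].items():
        attributes[tag] = SurfaceAttribute(
            a["specularity"],
            ReflectanceCurve(np.array(a["specular_reflectance"]["wavelengths"]),
                             np.array(a["specular_reflectance"]["values"])),
            ReflectanceCurve(np.array(a["diffuse_reflectance"]["wavelengths"]),
                             np.array(a["diffuse_reflectance"]["values"])),
            tuple(a["interface"]) if a.get("interface") else None,
        )
    surfaces = []
    v_off = 0
    f_off = 0
    for sm in meta["surfaces"]:
        nv, nf = sm["n_vertices"], sm["n_faces"]
        sub_faces = faces[f_off: f_off + nf] - v_off
        surfaces.append(SceneSurface(verts[v_off: v_off + nv], sub_faces, sm["tag"]))
        v_off += nv
        f_off += nf
    return Scene(surfaces, attributes, {}, provenance)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
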