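"""Synthetic inputs: toy luminaires, spectra, terrains and street scenarios.

Everything here is deterministic given its parameters (no hidden RNG), so
every other module can be exercised without proprietary photometric files,
measured lamp spectra or LiDAR data.  The street scenario mirrors the
road-crossing study design: lamps at regular spacings of 20-40 m along a
straight road, energy-density slices at 0/4/10 m, photophobic walkers
crossing from a dark south to a northern objective, optionally with one
mid-row lamp switched off to open a dark corridor.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box

from .engine import LightSourceInstance, Material, air
from .errors import ConfigurationError
from .photometry import (
    EmissionSpectrum,
    LIDWeb,
    build_direction_sampler,
    luminous_flux_from_power,
    luminous_to_radiant,
)
from .twin import (
    FootprintPolygon,
    HeightRaster,
    ReflectanceCurve,
    Scene,
    SceneSurface,
    SurfaceAttribute,
    assemble_scene,
    default_attributes,
    extrude_building,
    extrude_terrain,
    triangulate_footprint,
)

# ---------------------------------------------------------------------------
# published streetlight specifications (lamp/bulb technology table)
# ---------------------------------------------------------------------------

#: Representative street-lighting technologies: input power (W), nominal
#: luminous efficacy (lm/W), and the published radiant flux (W, engine
#: scale) each was assigned after spectral conversion.  The luminous flux
#: column is recomputable as power x efficacy; the radiant flux depends on
#: measured lamp spectra and is carried as a published constant.
LAMP_TABLE = {
    "HPS": {"input_power_w": 70.0, "efficacy_lm_per_w": 88.0, "radiant_flux_w": 12381.0},
    "CMH": {"input_power_w": 60.0, "efficacy_lm_per_w": 115.0, "radiant_flux_w": 20977.0},
    "LED": {"input_power_w": 73.0, "efficacy_lm_per_w": 139.0, "radiant_flux_w": 21080.0},
}


# ---------------------------------------------------------------------------
# toy photometric webs
# ---------------------------------------------------------------------------

def make_toy_lid(kind: str, intensity: float = 1.0, n_polar: int = 181,
                 half_angle_deg: float = 5.0) -> LIDWeb:
    """Closed-form webs standing in for measured luminaire photometry.

    kinds: ``isotropic`` (uniform over the full sphere), ``lower-hemisphere``
    (uniform downward), ``cosine-downlight`` (Lambertian downlight, peak at
    nadir), ``narrow-beam`` (uniform cone of the given half-angle about
    nadir).  Polar angle 180 deg is nadir.
    """
    if kind == "isotropic":
        phi = np.linspace(0.0, 180.0, n_polar)
        c = np.full((n_polar, 1), float(intensity))
    elif kind == "lower-hemisphere":
        phi = np.linspace(90.0, 180.0, max(n_polar // 2, 2))
        c = np.full((phi.size, 1), float(intensity))
    elif kind == "cosine-downlight":
        phi = np.linspace(90.0, 180.0, max(n_polar // 2, 2))
        c = np.clip(float(intensity) * -np.cos(np.radians(phi)), 0.0, None)[:, None]
    elif kind == "narrow-beam":
        phi = np.array([180.0 - half_angle_deg, 180.0])
        c = np.full((2, 1), float(intensity))
    else:
        raise ValueError(f"unknown toy LID kind {kind!r}")
    return LIDWeb(np.array([0.0]), phi, c)


def make_toy_spectrum(kind: str, wavelengths=(450.0, 600.0), energies=(0.4, 0.6),
                      peak_nm: float = 589.0, line_width_nm: float = 0.5,
                      temperature_k: float = 2700.0) -> EmissionSpectrum:
    """Stand-ins for measured lamp spectra.

    kinds: ``mono`` (one narrow line at peak_nm), ``flat`` (uniform
    380-780 nm), ``two-line`` (narrow lines at the given wavelengths with
    the given energy split), ``blackbody-like`` (Planck shape over the
    visible band, emulating an incandescent-ish continuum).
    """
    if kind == "mono":
        return _line_spectrum([peak_nm], [1.0], line_width_nm)
    if kind == "flat":
        return EmissionSpectrum(np.array([380.0, 780.0]), np.array([1.0, 1.0]))
    if kind == "two-line":
        return _line_spectrum(list(wavelengths), list(energies), line_width_nm)
    if kind == "blackbody-like":
        wl = np.linspace(380.0, 780.0, 201)
        lam = wl * 1e-9
        h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
        planck = 1.0 / (lam**5 * (np.expm1(h * c / (lam * kb * temperature_k))))
        return EmissionSpectrum(wl, planck / planck.max())
    raise ValueError(f"unknown toy spectrum kind {kind!r}")


def _line_spectrum(centers, energies, width):
    """Narrow triangular lines; each line's integral equals its energy."""
    wl = []
    f = []
    for c0, e in sorted(zip(centers, energies)):
        peak = 2.0 * e / width  # triangle area = width * peak / 2
        wl += [c0 - width / 2.0, c0, c0 + width / 2.0]
        f += [0.0, peak, 0.0]
    return EmissionSpectrum(np.array(wl), np.array(f))


# ---------------------------------------------------------------------------
# lamp library
# ---------------------------------------------------------------------------

@dataclass
class LampSpec:
    """A lamp type: photometric web, spectrum, power and efficacy."""

    name: str
    lid: LIDWeb
    spectrum: EmissionSpectrum
    input_power_w: float
    efficacy_lm_per_w: float

    def radiant_flux(self, mode: str = "as-printed") -> float:
        lumens = luminous_flux_from_power(self.input_power_w, self.efficacy_lm_per_w)
        flux, _ = luminous_to_radiant(lumens, self.spectrum, mode=mode)
        return flux


def toy_lamp_library() -> dict[str, LampSpec]:
    """Three synthetic stand-ins loosely shaped like the HPS/CMH/LED classes:
    a warm quasi-line lamp with broad trespass, a blackbody-like lamp, and a
    tightly controlled downlight."""
    return {
        "HPS": LampSpec("HPS", make_toy_lid("lower-hemisphere"),
                        make_toy_spectrum("two-line", wavelengths=(569.0, 589.0),
                                          energies=(0.3, 0.7)),
                        **_power(LAMP_TABLE["HPS"])),
        "CMH": LampSpec("CMH", make_toy_lid("cosine-downlight"),
                        make_toy_spectrum("blackbody-like", temperature_k=3000.0),
                        **_power(LAMP_TABLE["CMH"])),
        "LED": LampSpec("LED", make_toy_lid("cosine-downlight"),
                        make_toy_spectrum("blackbody-like", temperature_k=4000.0),
                        **_power(LAMP_TABLE["LED"])),
    }


def _power(row):
    return {"input_power_w": row["input_power_w"], "efficacy_lm_per_w": row["efficacy_lm_per_w"]}


# ---------------------------------------------------------------------------
# terrain fixtures
# ---------------------------------------------------------------------------

def flat_raster(width_m: float, height_m: float, cell_size: float = 1.0,
                value: float = 0.0, origin=(0.0, 0.0)) -> HeightRaster:
    nrows = int(round(height_m / cell_size))
    ncols = int(round(width_m / cell_size))
    return HeightRaster(origin, cell_size, np.full((nrows, ncols), float(value)))


def ramp_raster(width_m: float, height_m: float, slope_x: float,
                cell_size: float = 1.0, origin=(0.0, 0.0)) -> HeightRaster:
    nrows = int(round(height_m / cell_size))
    ncols = int(round(width_m / cell_size))
    xs = origin[0] + (np.arange(ncols) + 0.5) * cell_size
    return HeightRaster(origin, cell_size, np.tile(slope_x * xs, (nrows, 1)))


# ---------------------------------------------------------------------------
# street scenarios
# ---------------------------------------------------------------------------

@dataclass
class StreetScenario:
    """A straight east-west road with lamps at regular spacing.

    Defaults follow the road-crossing study design: spacings drawn from
    {20, 25, 30, 32, 35, 40} m, walkers crossing south to north, 100 m
    east/west walk margins.  Lamp height defaults to 8 m and the voxel
    grid to 1 m cells (values not fixed by the study design; recorded in
    scene provenance).
    """

    road_length_m: float = 120.0
    domain_depth_m: float = 60.0      # north-south extent
    domain_height_m: float = 20.0
    lamp_spacing_m: float = 32.0
    lamp_height_m: float = 8.0
    lamp_type: str = "HPS"
    deactivated: tuple = ()
    walk_margin_m: float = 100.0
    buildings_north: bool = False
    building_height_m: float = 8.0
    voxel_size_m: float = 1.0

    def __post_init__(self):
        if self.lamp_spacing_m <= 0:
            raise ConfigurationError("lamp spacing must be positive")
        if self.lamp_spacing_m > self.road_length_m:
            raise ConfigurationError("lamp spacing exceeds road length")

    @property
    def road_y(self) -> float:
        """Road axis position: mid-depth of the domain."""
        return self.domain_depth_m / 2.0

    def lamp_positions(self) -> np.ndarray:
        """Lamp x positions, both road ends inclusive."""
        n = int(np.floor(self.road_length_m / self.lamp_spacing_m + 1e-9)) + 1
        return np.arange(n) * self.lamp_spacing_m


def make_street_scene(scenario: StreetScenario,
                      lamp_library: dict[str, LampSpec] | None = None,
                      attributes: dict[str, SurfaceAttribute] | None = None,
                      ) -> tuple[Scene, list[LightSourceInstance], dict]:
    """Build the street digital twin and its light sources.

    Returns (scene, active sources, metadata).  Deactivated lamp indices are
    omitted from the sources but kept in the metadata; every lamp keeps its
    index as its RNG stream id, so switching one off leaves the photon
    streams of the others bit-identical.
    """
    lamp_library = lamp_library or toy_lamp_library()
    if scenario.lamp_type not in lamp_library:
        raise ConfigurationError(f"lamp type {scenario.lamp_type!r} not in library")
    lamp = lamp_library[scenario.lamp_type]

    dtm = flat_raster(scenario.road_length_m, scenario.domain_depth_m,
                      cell_size=scenario.voxel_size_m)
    terrain_fp = FootprintPolygon(box(0, 0, scenario.road_length_m, scenario.domain_depth_m),
                                  tag="tarmac")
    mesh2d = triangulate_footprint(terrain_fp, max_triangle_area=200.0)
    terrain = extrude_terrain(mesh2d, dtm, tag="tarmac")

    buildings = []
    if scenario.buildings_north:
        dsm = HeightRaster(dtm.origin, dtm.cell_size, dtm.values.copy())
        y0 = scenario.road_y + 10.0
        mask_rows = dsm.cell_centers()[1] >= y0
        dsm.values[mask_rows, :] += scenario.building_height_m
        fp = FootprintPolygon(
            Polygon([(5, y0), (scenario.road_length_m - 5, y0),
                     (scenario.road_length_m - 5, y0 + 10), (5, y0 + 10)]),
            tag="brick")
        buildings.append(extrude_building(fp, dtm, dsm))

    attrs = attributes or default_attributes()
    provenance = {
        "generator": "alansim.fixtures.make_street_scene",
        "lamp_type": scenario.lamp_type,
        "lamp_spacing_m": scenario.lamp_spacing_m,
        "lamp_height_m": scenario.lamp_height_m,
        "deactivated": list(scenario.deactivated),
        "voxel_size_m": scenario.voxel_size_m,
    }
    scene = assemble_scene(terrain, buildings, attrs, provenance=provenance)

    sampler = build_direction_sampler(lamp.lid)
    radiant = lamp.radiant_flux()
    _, scaled = luminous_to_radiant(
        luminous_flux_from_power(lamp.input_power_w, lamp.efficacy_lm_per_w), lamp.spectrum)
    sources = []
    all_lamps = []
    for i, x in enumerate(scenario.lamp_positions()):
        pos = np.array([x, scenario.road_y, scenario.lamp_height_m])
        all_lamps.append({"index": i, "x": float(x), "active": i not in scenario.deactivated})
        if i in scenario.deactivated:
            continue
        sources.append(LightSourceInstance(
            sampler=sampler, spectrum=scaled, radiant_flux=radiant,
            translation=pos, stream_id=i, name=f"{scenario.lamp_type}-{i}"))
    meta = dict(provenance)
    meta["lamps"] = all_lamps
    meta["n_active"] = len(sources)
    return scene, sources, meta


def scene_materials() -> dict[str, Material]:
    """Default material table: exterior clear air only."""
    return {"air": air()}
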