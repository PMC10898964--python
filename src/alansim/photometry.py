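"""Luminaire photometry: intensity webs, emission spectra, flux conversion.

A luminaire's light intensity distribution (LID, or "photometric web") is a
goniometric table of luminous intensities C(phi, theta) in candela, organised
in vertical C-planes around the polar axis.  This module loads such webs
(IES LM-63 subset, EULUMDAT subset, or a simple csv-grid dialect), turns them
into emission-direction samplers, integrates them to total luminous flux, and
converts luminous to radiant flux through an emission spectrum weighted by
the Judd-Vos modified photopic efficiency curve.

Angle convention: polar angle ``phi`` in degrees with **180 deg = nadir**
(straight down) and 0 deg = zenith; azimuth ``theta`` in degrees in
[0, 360).  IES/EULUMDAT vertical angles (0 = nadir) are mapped on load.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import (
    DegenerateLIDError,
    InvisibleSpectrumError,
    ParseError,
    UnsupportedPhotometryError,
)

#: Maximum luminous efficacy of radiation, lm/W at 555 nm.
MAX_LUMINOUS_EFFICACY = 683.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LIDWeb:
    """Goniometric candela matrix ``C(phi, theta)``.

    Parameters
    ----------
    azimuth_angles : (P,) array, degrees in [0, 360), strictly increasing
    polar_angles : (K,) array, degrees in [0, 180], strictly increasing;
        180 deg is nadir.
    intensities : (K, P) array, candela; one column per C-plane.
    """

    azimuth_angles: np.ndarray
    polar_angles: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        az = np.asarray(self.azimuth_angles, dtype=float)
        po = np.asarray(self.polar_angles, dtype=float)
        c = np.asarray(self.intensities, dtype=float)
        if az.ndim != 1 or az.size < 1:
            raise ValueError("need at least one C-plane")
        if po.ndim != 1 or po.size < 2:
            raise ValueError("need at least two polar angles")
        if np.any(np.diff(az) <= 0) or np.any(np.diff(po) <= 0):
            raise ValueError("angle grids must be strictly increasing")
        if az[0] < 0 or az[-1] >= 360:
            raise ValueError("azimuths must lie in [0, 360)")
        if po[0] < 0 or po[-1] > 180:
            raise ValueError("polar angles must lie in [0, 180]")
        if c.shape != (po.size, az.size):
            raise ValueError(
                f"intensity matrix shape {c.shape} != (n_polar={po.size}, n_planes={az.size})"
            )
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "azimuth_angles", az)
        object.__setattr__(self, "polar_angles", po)
        object.__setattr__(self, "intensities", c)

    @property
    def n_planes(self) -> int:
        return self.azimuth_angles.size

    def scaled(self, factor: float) -> "LIDWeb":
        return LIDWeb(self.azimuth_angles, self.polar_angles, self.intensities * factor)


@dataclass(frozen=True)
class DirectionSampler:
    """Inverse-CDF sampler for emission directions of a :class:`LIDWeb`.

    ``azimuthal_cdf`` is the cumulative probability of each C-plane
    (solid-angle-weighted plane flux); ``per_plane_polar_cdfs`` holds one
    cumulative curve per plane over the tabulated polar angles.
    """

    azimuth_angles: np.ndarray      # (P,) degrees
    azimuth_widths: np.ndarray      # (P,) degrees, periodic sector widths
    azimuthal_cdf: np.ndarray       # (P,)
    polar_angles: np.ndarray        # (K,) degrees
    per_plane_polar_cdfs: np.ndarray  # (P, K)

    def __post_init__(self):
        for cdf in [self.azimuthal_cdf, *self.per_plane_polar_cdfs]:
            if np.any(np.diff(cdf) < -1e-15) or cdf[0] < -1e-15 or abs(cdf[-1] - 1) > 1e-12:
                raise ValueError("CDF must be non-decreasing from >=0 to 1 (within 1e-12)")


@dataclass(frozen=True)
class EmissionSpectrum:
    """Relative spectral radiant flux per nm on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    spectral_flux: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        f = np.asarray(self.spectral_flux, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing, >= 2 points")
        if f.shape != wl.shape or np.any(f < 0) or not np.all(np.isfinite(f)):
            raise ValueError("spectral flux must be non-negative, finite, same shape")
        if np.trapezoid(f, wl) <= 0:
            raise ValueError("spectrum must carry positive integral flux")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "spectral_flux", f)

    def total(self) -> float:
        """Integral of the spectral flux over wavelength (trapezoidal)."""
        return float(np.trapezoid(self.spectral_flux, self.wavelengths))

    def scaled_to(self, radiant_flux: float) -> "EmissionSpectrum":
        """Rescale so the spectral integral equals ``radiant_flux`` (W)."""
        return EmissionSpectrum(self.wavelengths, self.spectral_flux * (radiant_flux / self.total()))


@dataclass(frozen=True)
class PhotopicCurve:
    """Photopic luminous efficiency V(lambda), dimensionless in [0, 1]."""

    wavelengths: np.ndarray
    efficiency: np.ndarray

    def __call__(self, wavelengths_nm) -> np.ndarray:
        """Evaluate by linear interpolation; zero outside the tabulated band."""
        return np.interp(wavelengths_nm, self.wavelengths, self.efficiency, left=0.0, right=0.0)


@lru_cache(maxsize=1)
def judd_vos_photopic() -> PhotopicCurve:
    """The Judd-Vos modified photopic curve shipped with the package,
    PCHIP-interpolated to a 1 nm grid over 380-780 nm."""
    with resources.files("alansim.data").joinpath("judd_vos_vm.csv").open() as fh:
        rows = [ln.split(",") for ln in fh if ln.strip() and not ln.startswith("#")]
    wl = np.array([float(r[0]) for r in rows])
    v = np.array([float(r[1]) for r in rows])
    grid = np.arange(380.0, 781.0)
    eff = np.clip(PchipInterpolator(wl, v)(grid), 0.0, None)
    return PhotopicCurve(grid, eff)


# ---------------------------------------------------------------------------
# solid-angle quadrature
# ---------------------------------------------------------------------------

def _segment_plane_flux(phi_deg: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Exact per-segment integral of piecewise-linear C(phi) * sin(phi) dphi.

    For C linear on a segment, int (a + b*phi) sin(phi) dphi has the
    antiderivative -(a + b*phi) cos(phi) + b sin(phi).
    """
    phi = np.radians(phi_deg)
    p0, p1 = phi[:-1], phi[1:]
    c0, c1 = c[:-1], c[1:]
    dp = p1 - p0
    b = (c1 - c0) / dp
    a = c0 - b * p0

    def antideriv(p):
        return -(a + b * p) * np.cos(p) + b * np.sin(p)

    return antideriv(p1) - antideriv(p0)


def _plane_fluxes(lid: LIDWeb) -> np.ndarray:
    """Per-plane luminous flux density: int C(phi) sin(phi) dphi (cd·rad)."""
    return np.array(
        [_segment_plane_flux(lid.polar_angles, lid.intensities[:, j]).sum()
         for j in range(lid.n_planes)]
    )


def _azimuth_widths_deg(azimuths: np.ndarray) -> np.ndarray:
    """Periodic sector width of each C-plane (degrees); 360 for one plane."""
    if azimuths.size == 1:
        return np.array([360.0])
    ext = np.concatenate([[azimuths[-1] - 360.0], azimuths, [azimuths[0] + 360.0]])
    return (ext[2:] - ext[:-2]) / 2.0


def lid_total_flux(lid: LIDWeb) -> float:
    """Total luminous flux of the web in lumens: Phi = int C dOmega.

    Polar quadrature is exact for piecewise-linear C(phi); azimuthal
    quadrature uses the periodic sector width of each C-plane.
    """
    fluxes = _plane_fluxes(lid)
    widths = np.radians(_azimuth_widths_deg(lid.azimuth_angles))
    return float(np.dot(fluxes, widths))


# ---------------------------------------------------------------------------
# direction sampling
# ---------------------------------------------------------------------------

def build_direction_sampler(lid: LIDWeb) -> DirectionSampler:
    """Build inverse-CDF tables for emission-direction sampling.

    Each C-plane is weighted by its solid-angle-integrated flux times its
    azimuthal sector width; within a plane, the cumulative distribution over
    polar angle is built from the exact segment integrals of C(phi) sin(phi).
    """
    fluxes = _plane_fluxes(lid)
    widths = _azimuth_widths_deg(lid.azimuth_angles)
    weights = fluxes * np.radians(widths)
    total = weights.sum()
    if total <= 0:
        raise DegenerateLIDError("intensity web carries no flux")
    az_cdf = np.cumsum(weights) / total
    az_cdf[-1] = 1.0

    K = lid.polar_angles.size
    polar_cdfs = np.empty((lid.n_planes, K))
    for j in range(lid.n_planes):
        seg = _segment_plane_flux(lid.polar_angles, lid.intensities[:, j])
        seg = np.clip(seg, 0.0, None)  # guard fp round-off on zero segments
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        if cum[-1] > 0:
            cum /= cum[-1]
        else:
            # zero-flux plane: never selected; store a uniform placeholder
            cum = np.linspace(0.0, 1.0, K)
        cum[-1] = 1.0
        polar_cdfs[j] = cum
    return DirectionSampler(
        azimuth_angles=lid.azimuth_angles,
        azimuth_widths=widths,
        azimuthal_cdf=az_cdf,
        polar_angles=lid.polar_angles,
        per_plane_polar_cdfs=polar_cdfs,
    )


def _invert_piecewise_cdf(nodes: np.ndarray, cdf: np.ndarray, u: float) -> float:
    """Linear-interpolation inversion of a piecewise-linear CDF."""
    i = int(np.searchsorted(cdf, u, side="left"))
    i = min(max(i, 1), nodes.size - 1)
    dc = cdf[i] - cdf[i - 1]
    if dc <= 0:
        return float(nodes[i])
    frac = (u - cdf[i - 1]) / dc
    return float(nodes[i - 1] + frac * (nodes[i] - nodes[i - 1]))


def sample_plane(sampler: DirectionSampler, rng) -> int:
    """Draw a C-plane index from the azimuthal CDF."""
    u = float(rng.random())
    return int(np.searchsorted(sampler.azimuthal_cdf, u, side="left"))


def sample_direction(sampler: DirectionSampler, rng) -> np.ndarray:
    """Draw a unit emission direction.

    A C-plane is drawn from the azimuthal CDF; the heading theta is jittered
    uniformly within that plane's azimuthal sector (so an isotropic web
    yields an exactly uniform heading while plane frequencies stay exactly
    proportional to plane flux); the polar angle comes from the selected
    plane's CDF with linear inversion, with no interpolation between planes.
    """
    j = sample_plane(sampler, rng)
    theta = sampler.azimuth_angles[j] + (float(rng.random()) - 0.5) * sampler.azimuth_widths[j]
    phi = _invert_piecewise_cdf(sampler.polar_angles, sampler.per_plane_polar_cdfs[j], float(rng.random()))
    return direction_from_angles(phi, theta % 360.0)


def direction_from_angles(phi_deg: float, theta_deg: float) -> np.ndarray:
    """Unit vector for polar angle phi (180 = nadir = -z) and azimuth theta."""
    phi = np.radians(phi_deg)
    theta = np.radians(theta_deg)
    s = np.sin(phi)
    return np.array([s * np.cos(theta), s * np.sin(theta), np.cos(phi)])


# ---------------------------------------------------------------------------
# flux conversion
# ---------------------------------------------------------------------------

def luminous_flux_from_power(input_power_w: float, efficacy_lm_per_w: float) -> float:
    """Luminous flux (lm) from lamp input power (W) and luminous efficacy (lm/W)."""
    if input_power_w < 0 or efficacy_lm_per_w < 0:
        raise ValueError("power and efficacy must be non-negative")
    return float(input_power_w) * float(efficacy_lm_per_w)


def luminous_to_radiant(
    luminous_flux_lm: float,
    spectrum: EmissionSpectrum,
    photopic: PhotopicCurve | None = None,
    mode: str = "as-printed",
) -> tuple[float, EmissionSpectrum]:
    """Convert luminous flux to radiant flux through the emission spectrum.

    Computes ``Phi_e = Phi_V * (int Phi_e,lambda dlambda) /
    (int V_M,lambda Phi_e,lambda dlambda)``, the photopically weighted
    inverse efficacy of the lamp's spectral shape.

    ``mode="as-printed"`` applies the ratio verbatim (the scale used for the
    streetlight radiant fluxes this package reproduces, in which a watt of
    "radiant flux" is really a lumen weighted by the inverse spectral
    overlap); ``mode="physical"`` additionally divides by the maximum
    luminous efficacy 683 lm/W, giving physically meaningful watts.

    Returns the radiant flux and the spectrum rescaled so its integral
    equals that flux.
    """
    if luminous_flux_lm < 0:
        raise ValueError("luminous flux must be non-negative")
    if mode not in ("as-printed", "physical"):
        raise ValueError(f"unknown mode {mode!r}")
    if photopic is None:
        photopic = judd_vos_photopic()
    # integrate V * Phi on the union of both tabulation grids so coarse
    # (e.g. two-node flat) spectra are weighted correctly
    wl = np.union1d(spectrum.wavelengths, photopic.wavelengths)
    wl = wl[(wl >= spectrum.wavelengths[0]) & (wl <= spectrum.wavelengths[-1])]
    f = np.interp(wl, spectrum.wavelengths, spectrum.spectral_flux)
    weighted = float(np.trapezoid(photopic(wl) * f, wl))
    if weighted <= 0:
        raise InvisibleSpectrumError(
            "spectrum has no overlap with the photopic band; luminous flux undefined"
        )
    ratio = spectrum.total() / weighted
    radiant = luminous_flux_lm * ratio
    if mode == "physical":
        radiant /= MAX_LUMINOUS_EFFICACY
    if radiant == 0.0:
        return 0.0, spectrum
    return radiant, spectrum.scaled_to(radiant)


# ---------------------------------------------------------------------------
# wavelength sampling
# ---------------------------------------------------------------------------

def spectrum_cdf(spectrum: EmissionSpectrum) -> np.ndarray:
    """Cumulative distribution at the spectrum's wavelength nodes (trapezoidal)."""
    wl, f = spectrum.wavelengths, spectrum.spectral_flux
    seg = 0.5 * (f[:-1] + f[1:]) * np.diff(wl)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    cum /= cum[-1]
    cum[-1] = 1.0
    return cum


def sample_wavelength(spectrum: EmissionSpectrum, rng) -> float:
    """Draw a wavelength (nm) from the spectrum's CDF.

    Within a segment the density is linear (trapezoidal model), so the local
    inverse solves the quadratic ``f0*t + (f1-f0)*t^2/2 = u_local``.
    """
    wl, f = spectrum.wavelengths, spectrum.spectral_flux
    cdf = spectrum_cdf(spectrum)
    u = float(rng.random())
    i = int(np.searchsorted(cdf, u, side="left"))
    i = min(max(i, 1), wl.size - 1)
    mass = cdf[i] - cdf[i - 1]
    if mass <= 0:
        return float(wl[i])
    ulocal = (u - cdf[i - 1]) / mass  # in [0, 1] within segment
    return _invert_segment(wl[i - 1], wl[i], f[i - 1], f[i], ulocal)


def _invert_segment(x0: float, x1: float, f0: float, f1: float, u: float) -> float:
    """Invert a linear-density segment; u in [0,1] is the local CDF value."""
    h = x1 - x0
    area = 0.5 * (f0 + f1) * h
    if area <= 0:
        return float(x0 + u * h)
    df = f1 - f0
    if abs(df) < 1e-300 * max(1.0, abs(f0)):
        return float(x0 + u * h)
    # solve f0*t + df*t^2/(2h) = u*area  for t in [0, h]
    a = df / (2.0 * h)
    disc = f0 * f0 + 4.0 * a * u * area
    t = (-f0 + np.sqrt(max(disc, 0.0))) / (2.0 * a)
    return float(x0 + min(max(t, 0.0), h))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_photometric_file(path, dialect: str | None = None) -> LIDWeb:
    """Load a photometric web from IES LM-63, EULUMDAT or csv-grid.

    ``dialect`` is one of ``"ies"``, ``"eulumdat"``, ``"csv-grid"``; when
    omitted it is inferred from the file extension (.ies / .ldt / .csv).
    """
    path = Path(path)
    if dialect is None:
        dialect = {".ies": "ies", ".ldt": "eulumdat", ".csv": "csv-grid"}.get(path.suffix.lower())
        if dialect is None:
            raise UnsupportedPhotometryError(f"cannot infer photometric dialect from {path.name!r}")
    if dialect == "csv-grid":
        return _load_csv_grid(path)
    if dialect == "ies":
        return _load_ies(path)
    if dialect == "eulumdat":
        return _load_eulumdat(path)
    raise UnsupportedPhotometryError(f"unknown photometric dialect {dialect!r}")


def _load_csv_grid(path: Path) -> LIDWeb:
    """csv-grid dialect: '#' comments; header row of azimuths; first column
    polar angles (180 = nadir); body candela."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            rows.append((lineno, s))
    if len(rows) < 3:
        raise ParseError(path, rows[-1][0] if rows else 0, "csv-grid needs a header and >= 2 rows")
    try:
        header = [float(tok) for tok in rows[0][1].split(",")[1:]]
    except ValueError as exc:
        raise ParseError(path, rows[0][0], f"bad azimuth header: {exc}") from None
    polar, body = [], []
    for lineno, s in rows[1:]:
        toks = s.split(",")
        try:
            polar.append(float(toks[0]))
            vals = [float(t) for t in toks[1:]]
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad numeric row: {exc}") from None
        if len(vals) != len(header):
            raise ParseError(path, lineno, f"expected {len(header)} candela values, got {len(vals)}")
        body.append(vals)
    try:
        return LIDWeb(np.array(header), np.array(polar), np.array(body))
    except ValueError as exc:
        raise ParseError(path, rows[1][0], str(exc)) from None


def write_csv_grid(lid: LIDWeb, path) -> None:
    """Write a web in the csv-grid dialect (round-trips bit-exactly)."""
    with open(path, "w") as fh:
        fh.write("# csv-grid photometric web: azimuth header, polar first column (180=nadir), candela body\n")
        fh.write("phi_deg," + ",".join(repr(float(a)) for a in lid.azimuth_angles) + "\n")
        for k, phi in enumerate(lid.polar_angles):
            fh.write(repr(float(phi)) + "," + ",".join(repr(float(v)) for v in lid.intensities[k]) + "\n")


def _load_ies(path: Path) -> LIDWeb:
    """IES LM-63 subset: TILT=NONE, photometric type C."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    tilt_line = None
    for i, ln in enumerate(lines):
        if ln.upper().startswith("TILT="):
            tilt_line = i
            break
    if tilt_line is None:
        raise ParseError(path, len(lines), "no TILT= line found")
    tilt = lines[tilt_line].split("=", 1)[1].strip().upper()
    if tilt != "NONE":
        raise UnsupportedPhotometryError(f"unsupported TILT={tilt!r}; only TILT=NONE is handled")
    tokens = " ".join(lines[tilt_line + 1:]).split()
    try:
        vals = [float(t) for t in tokens]
    except ValueError:
        raise ParseError(path, tilt_line + 2, "non-numeric data after TILT=NONE") from None
    if len(vals) < 13:
        raise ParseError(path, tilt_line + 2, "truncated IES data block")
    n_lamps, lumens_per_lamp, multiplier = vals[0], vals[1], vals[2]
    n_vert, n_horiz = int(vals[3]), int(vals[4])
    photometric_type = int(vals[5])
    if photometric_type != 1:
        raise UnsupportedPhotometryError(
            f"photometric type {photometric_type} unsupported; only type C (1) is handled"
        )
    # vals[6]=units, 7..9 luminous dims, 10..12 ballast block
    idx = 13
    need = n_vert + n_horiz + n_vert * n_horiz
    if len(vals) < idx + need:
        raise ParseError(path, len(lines), "IES candela block shorter than declared angle counts")
    vert = np.array(vals[idx: idx + n_vert]); idx += n_vert
    horiz = np.array(vals[idx: idx + n_horiz]); idx += n_horiz
    cand = np.array(vals[idx: idx + n_vert * n_horiz]).reshape(n_horiz, n_vert).T
    cand = cand * multiplier
    # IES gamma: 0 = nadir -> our phi = 180 - gamma
    phi = 180.0 - vert[::-1]
    cand = cand[::-1, :]
    horiz = np.mod(horiz, 360.0)
    if horiz.size > 1 and np.any(np.diff(horiz) <= 0):
        raise ParseError(path, len(lines), "horizontal angles not strictly increasing after wrap")
    _ = (n_lamps, lumens_per_lamp)
    try:
        return LIDWeb(horiz, phi, cand)
    except ValueError as exc:
        raise ParseError(path, len(lines), str(exc)) from None


def _load_eulumdat(path: Path) -> LIDWeb:
    """EULUMDAT subset: symmetry indicator 0 (none) or 1 (axisymmetric)."""
    with open(path, encoding="latin-1") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]

    def num(i, cast=float):
        try:
            return cast(lines[i].strip())
        except (ValueError, IndexError):
            raise ParseError(path, i + 1, "expected a number") from None

    isym = num(2, int)
    if isym not in (0, 1):
        raise UnsupportedPhotometryError(
            f"EULUMDAT symmetry indicator {isym} unsupported; only 0 (none) and 1 (axisymmetric)"
        )
    mc = num(3, int)   # number of C planes
    ng = num(5, int)   # number of G (polar) angles per plane
    n_sets = num(25, int)
    idx = 26
    total_lm = 0.0
    for _ in range(n_sets):
        # per lamp set: n lamps, type, total flux (lm), colour, CRI, wattage
        try:
            total_lm += float(lines[idx + 2].strip())
        except (ValueError, IndexError):
            raise ParseError(path, idx + 3, "bad lamp-set luminous flux") from None
        idx += 6
    idx += 10  # direct ratios for room indices
    c_angles = np.array([num(idx + i) for i in range(mc)]); idx += mc
    g_angles = np.array([num(idx + i) for i in range(ng)]); idx += ng
    n_planes_stored = 1 if isym == 1 else mc
    cand_klm = np.empty((ng, n_planes_stored))
    for j in range(n_planes_stored):
        for i in range(ng):
            cand_klm[i, j] = num(idx)
            idx += 1
    cand = cand_klm * (total_lm / 1000.0)  # cd/klm -> cd
    planes = np.array([0.0]) if isym == 1 else np.mod(c_angles, 360.0)
    phi = 180.0 - g_angles[::-1]
    cand = cand[::-1, :]
    try:
        return LIDWeb(planes, phi, cand)
    except ValueError as exc:
        raise ParseError(path, idx, str(exc)) from None


def load_spectrum(path) -> EmissionSpectrum:
    """Two-column delimited text (wavelength_nm, relative flux); '#' comments."""
    wl, f = _load_two_column(path)
    return EmissionSpectrum(wl, f)


def write_spectrum(spectrum: EmissionSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("# wavelength_nm value\n")
        for w, v in zip(spectrum.wavelengths, spectrum.spectral_flux):
            fh.write(f"{float(w)!r} {float(v)!r}\n")


def _load_two_column(path):
    wl, val = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            toks = s.replace(",", " ").split()
            if len(toks) < 2:
                raise ParseError(path, lineno, "expected two columns")
            try:
                wl.append(float(toks[0]))
                val.append(float(toks[1]))
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad number: {exc}") from None
    return np.array(wl), np.array(val)
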