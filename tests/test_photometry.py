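"""Photometric webs, direction/wavelength samplers, flux conversions."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from alansim.errors import (
    DegenerateLIDError,
    InvisibleSpectrumError,
    ParseError,
    UnsupportedPhotometryError,
)
from alansim.fixtures import make_toy_lid, make_toy_spectrum
from alansim.photometry import (
    EmissionSpectrum,
    LIDWeb,
    build_direction_sampler,
    judd_vos_photopic,
    lid_total_flux,
    load_photometric_file,
    luminous_flux_from_power,
    luminous_to_radiant,
    sample_direction,
    sample_plane,
    sample_wavelength,
    spectrum_cdf,
    write_csv_grid,
)

# ---------------------------------------------------------------------------
# file loading
# ---------------------------------------------------------------------------


def test_csv_grid_identity_readback(tmp_path):
    """A hand-written one-plane csv-grid reads back verbatim."""
    p = tmp_path / "web.csv"
    p.write_text("# comment\nphi,0\n0,0\n90,0\n180,1\n")
    lid = load_photometric_file(p)
    assert lid.n_planes == 1
    np.testing.assert_array_equal(lid.polar_angles, [0, 90, 180])
    np.testing.assert_array_equal(lid.intensities[:, 0], [0, 0, 1])


@pytest.mark.parametrize("kind", ["isotropic", "lower-hemisphere", "cosine-downlight", "narrow-beam"])
def test_csv_grid_round_trip_bit_exact(tmp_path, kind):
    lid = make_toy_lid(kind)
    p = tmp_path / "rt.csv"
    write_csv_grid(lid, p)
    back = load_photometric_file(p, dialect="csv-grid")
    np.testing.assert_array_equal(back.azimuth_angles, lid.azimuth_angles)
    np.testing.assert_array_equal(back.polar_angles, lid.polar_angles)
    np.testing.assert_array_equal(back.intensities, lid.intensities)


def test_csv_grid_malformed_names_line(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("phi,0\n0,0\nnot_a_number,1\n180,1\n")
    with pytest.raises(ParseError, match="bad.csv:3"):
        load_photometric_file(p)


_IES = """IESNA:LM-63-2002
[TEST] synthetic downlight
TILT={tilt}
1 1000 1 3 1 1 2 0.3 0.3 0.1
1.0 1.0 0
0 90 180
0
100 50 0
"""


def test_ies_load_maps_gamma_to_nadir_convention(tmp_path):
    """IES gamma = 0 (nadir) becomes polar angle 180 in this package."""
    p = tmp_path / "lamp.ies"
    p.write_text(_IES.format(tilt="NONE"))
    lid = load_photometric_file(p)
    np.testing.assert_array_equal(lid.polar_angles, [0, 90, 180])
    # gamma=0 carried 100 cd -> phi=180 (nadir) carries 100 cd
    np.testing.assert_array_equal(lid.intensities[:, 0], [0, 50, 100])


def test_ies_tilt_block_is_an_explicit_unsupported_error(tmp_path):
    p = tmp_path / "tilted.ies"
    p.write_text(_IES.format(tilt="INCLUDE"))
    with pytest.raises(UnsupportedPhotometryError, match="TILT"):
        load_photometric_file(p)


def test_eulumdat_axisymmetric_load(tmp_path):
    lines = ["synthetic", "1", "1", "1", "0", "3", "90", "rep", "lum", "num",
             "file", "date", "0", "0", "0", "0", "0", "0", "0", "0", "0",
             "100", "100", "1", "0", "1",
             # one lamp set: n, type, flux lm, colour, cri, wattage
             "1", "LED", "1000", "4000K", "80", "70"]
    lines += ["0"] * 10            # direct ratios
    lines += ["0"]                  # C angles (mc=1)
    lines += ["0", "90", "180"]     # G angles
    lines += ["200", "50", "0"]     # cd/klm at G = 0 (nadir), 90, 180
    p = tmp_path / "lamp.ldt"
    p.write_text("\n".join(lines) + "\n")
    lid = load_photometric_file(p)
    assert lid.n_planes == 1
    # cd/klm * 1 klm -> 200 cd at nadir (phi=180 in our convention)
    np.testing.assert_allclose(lid.intensities[:, 0], [0, 50, 200])


def test_eulumdat_unsupported_symmetry(tmp_path):
    p = tmp_path / "sym.ldt"
    p.write_text("x\n1\n3\n1\n0\n3\n90\n")
    with pytest.raises(UnsupportedPhotometryError, match="symmetry"):
        load_photometric_file(p)


# ---------------------------------------------------------------------------
# direction sampler construction
# ---------------------------------------------------------------------------


def _two_plane_web(ratio=2.0):
    phi = np.array([90.0, 180.0])
    c = np.column_stack([np.full(2, ratio), np.ones(2)])
    return LIDWeb(np.array([0.0, 180.0]), phi, c)


def test_azimuthal_cdf_weights_proportional_to_plane_flux():
    s = build_direction_sampler(_two_plane_web(2.0))
    np.testing.assert_allclose(s.azimuthal_cdf, [2 / 3, 1.0], atol=1e-12)


def test_single_plane_azimuthal_cdf_is_one(isotropic_sampler):
    np.testing.assert_allclose(isotropic_sampler.azimuthal_cdf, [1.0])


def test_isotropic_web_has_identical_plane_cdfs():
    phi = np.linspace(0, 180, 19)
    az = np.array([0.0, 90.0, 180.0, 270.0])
    lid = LIDWeb(az, phi, np.ones((19, 4)))
    s = build_direction_sampler(lid)
    for j in range(1, 4):
        np.testing.assert_allclose(s.per_plane_polar_cdfs[j], s.per_plane_polar_cdfs[0])


def test_all_zero_web_is_degenerate():
    lid = LIDWeb(np.array([0.0]), np.array([0.0, 180.0]), np.zeros((2, 1)))
    with pytest.raises(DegenerateLIDError):
        build_direction_sampler(lid)


@settings(max_examples=30, deadline=None)
@given(
    n_phi=st.integers(3, 12),
    n_az=st.integers(1, 8),
    seed=st.integers(0, 2**31 - 1),
)
def test_sampler_cdfs_normalised(n_phi, n_az, seed):
    """Every CDF of a random positive web ends at 1 within 1e-12."""
    r = np.random.default_rng(seed)
    phi = np.sort(r.uniform(0, 180, n_phi))
    if np.any(np.diff(phi) <= 1e-6):
        phi = np.linspace(5, 175, n_phi)
    az = np.linspace(0, 360, n_az, endpoint=False)
    lid = LIDWeb(az, phi, r.uniform(0.1, 10, (n_phi, n_az)))
    s = build_direction_sampler(lid)
    assert abs(s.azimuthal_cdf[-1] - 1) <= 1e-12
    assert np.all(np.abs(s.per_plane_polar_cdfs[:, -1] - 1) <= 1e-12)


# ---------------------------------------------------------------------------
# direction sampling
# ---------------------------------------------------------------------------


def test_narrow_beam_draws_are_nadir(rng):
    s = build_direction_sampler(make_toy_lid("narrow-beam", half_angle_deg=1e-4))
    for _ in range(100):
        d = sample_direction(s, rng)
        assert np.allclose(d, [0, 0, -1], atol=1e-5)


def test_isotropic_sampling_uniform_on_sphere(isotropic_sampler, rng):
    """KS on cos(polar) and heading against the uniform sphere at alpha=0.01."""
    n = 100_000
    d = np.array([sample_direction(isotropic_sampler, rng) for _ in range(n)])
    assert np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-9)
    assert kstest(d[:, 2], "uniform", args=(-1, 2)).pvalue > 0.01
    theta = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360
    assert kstest(theta, "uniform", args=(0, 360)).pvalue > 0.01


def test_two_plane_selection_frequencies(rng):
    s = build_direction_sampler(_two_plane_web(2.0))
    n = 100_000
    picks = np.array([sample_plane(s, rng) for _ in range(n)])
    p_hat = np.mean(picks == 0)
    se = np.sqrt((2 / 3) * (1 / 3) / n)
    assert abs(p_hat - 2 / 3) < 3 * se


# ---------------------------------------------------------------------------
# total flux
# ---------------------------------------------------------------------------


def test_total_flux_closed_forms():
    assert lid_total_flux(make_toy_lid("isotropic")) == pytest.approx(4 * np.pi, rel=1e-9)
    assert lid_total_flux(make_toy_lid("lower-hemisphere")) == pytest.approx(2 * np.pi, rel=1e-9)


def test_cosine_downlight_flux_matches_quadrature_oracle():
    lid = make_toy_lid("cosine-downlight")
    # dense solid-angle quadrature of the same tabulated web
    phi = np.linspace(np.pi / 2, np.pi, 20001)
    c = np.interp(np.degrees(phi), lid.polar_angles, lid.intensities[:, 0])
    oracle = 2 * np.pi * np.trapezoid(c * np.sin(phi), phi)
    assert lid_total_flux(lid) == pytest.approx(oracle, abs=1e-6)
    assert lid_total_flux(lid) == pytest.approx(np.pi, abs=1e-3)


def test_total_flux_scales_linearly(isotropic_lid):
    assert lid_total_flux(isotropic_lid.scaled(3.5)) == pytest.approx(
        3.5 * lid_total_flux(isotropic_lid), rel=1e-12)


# ---------------------------------------------------------------------------
# flux conversion
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("power,efficacy,lumens", [(70, 88, 6160), (60, 115, 6900),
                                                   (73, 139, 10147), (0, 139, 0)])
def test_luminous_flux_from_power(power, efficacy, lumens):
    assert luminous_flux_from_power(power, efficacy) == lumens


def test_luminous_flux_rejects_negative_inputs():
    with pytest.raises(ValueError):
        luminous_flux_from_power(-1, 100)


def test_monochromatic_555nm_physical_conversion():
    mono = make_toy_spectrum("mono", peak_nm=555.0, line_width_nm=0.02)
    w, scaled = luminous_to_radiant(683.0, mono, mode="physical")
    assert w == pytest.approx(1.0, abs=1e-3)
    assert scaled.total() == pytest.approx(w, rel=1e-12)


def test_as_printed_vs_physical_ratio_is_683(flat_spectrum):
    a, _ = luminous_to_radiant(1000.0, flat_spectrum, mode="as-printed")
    b, _ = luminous_to_radiant(1000.0, flat_spectrum, mode="physical")
    assert a / b == pytest.approx(683.0, rel=1e-12)


def test_invisible_spectrum_raises():
    ir = EmissionSpectrum(np.array([995.0, 1000.0, 1005.0]), np.array([0.0, 1.0, 0.0]))
    with pytest.raises(InvisibleSpectrumError):
        luminous_to_radiant(1000.0, ir)


def test_conversion_homogeneous_and_shape_invariant(flat_spectrum):
    w1, _ = luminous_to_radiant(100.0, flat_spectrum)
    w2, _ = luminous_to_radiant(200.0, flat_spectrum)
    assert w2 == pytest.approx(2 * w1, rel=1e-12)
    rescaled = EmissionSpectrum(flat_spectrum.wavelengths, flat_spectrum.spectral_flux * 7.0)
    w3, _ = luminous_to_radiant(100.0, rescaled)
    assert w3 == pytest.approx(w1, rel=1e-12)


def test_flat_spectrum_conversion_matches_quadrature(flat_spectrum):
    """Physical-mode conversion equals the direct ratio of trapezoidal
    integrals of the shipped photopic curve (independent quadrature)."""
    pc = judd_vos_photopic()
    wl = np.linspace(380.0, 780.0, 4001)
    oracle = 100.0 * np.trapezoid(np.ones_like(wl), wl) / np.trapezoid(pc(wl), wl) / 683.0
    w, _ = luminous_to_radiant(100.0, flat_spectrum, mode="physical")
    assert w == pytest.approx(oracle, rel=1e-6)


def test_photopic_curve_shape():
    pc = judd_vos_photopic()
    assert pc(555.0) == pytest.approx(1.0, abs=1e-6)
    assert pc(200.0) == 0.0 and pc(900.0) == 0.0
    assert np.all(pc.efficiency >= 0) and pc.efficiency.max() <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# wavelength sampling
# ---------------------------------------------------------------------------


def test_mono_spectrum_sampling(rng):
    mono = make_toy_spectrum("mono", peak_nm=589.0, line_width_nm=0.01)
    draws = [sample_wavelength(mono, rng) for _ in range(200)]
    assert np.allclose(draws, 589.0, atol=0.01)


def test_two_line_energy_split(rng):
    spec = make_toy_spectrum("two-line", wavelengths=(450, 600), energies=(0.4, 0.6))
    n = 100_000
    draws = np.array([sample_wavelength(spec, rng) for _ in range(n)])
    frac_blue = np.mean(draws < 500)
    se = np.sqrt(0.4 * 0.6 / n)
    assert abs(frac_blue - 0.4) < 3 * se


def test_continuous_spectrum_ks_against_input_cdf(rng):
    spec = make_toy_spectrum("blackbody-like", temperature_k=3000.0)
    n = 100_000
    draws = np.array([sample_wavelength(spec, rng) for _ in range(n)])
    cdf_nodes = spectrum_cdf(spec)

    def cdf(x):
        return np.interp(x, spec.wavelengths, cdf_nodes)

    assert kstest(draws, cdf).pvalue > 0.01
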