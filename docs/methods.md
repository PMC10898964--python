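# Methods

This note records the model, its numerical choices, and the reasoning
behind design decisions that were genuinely open. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Radiative-transfer model

The engine solves light transport stochastically: photon packets carry a
fixed share `w = L/N` of their source's radiant flux `L` (watts) and a
sampled wavelength; sufficient sampling converges on the radiation field
without solving the transfer equation directly. The per-packet loop
compares three distances — nearest surface, scattering free path, current
voxel boundary — advances by the minimum, and dispatches the corresponding
event.

**Energy-density estimator.** A chord `l` through a voxel of volume `V`
in a medium of refractive index `n_v` contributes `w·l·n_v/(c·V)`. This is
the standard path-length (track-length) fluence estimator under a
unit-time normalisation (Δt = 1 s), and the grid is labelled W m⁻³
accordingly. The alternative reading of the packet-energy relation as
joules differs only by the constant Δt; we fix the convention once and
use it everywhere, including the walker thresholds, which are defined on
the engine's own output scale.

**Luminous→radiant conversion.** The conversion applies the spectral ratio
`Φ_e = Φ_V · ∫Φ_λ dλ / ∫V_λ Φ_λ dλ` verbatim in its default `as-printed`
mode. On this scale a lamp's "radiant flux" exceeds its electrical input
power (e.g. 70 W in, ~12 kW out) because the maximum luminous efficacy
constant 683 lm W⁻¹ is not divided out; the published streetlight table
this package reproduces uses exactly that scale, so the default preserves
comparability. `mode="physical"` divides by 683 lm W⁻¹ and yields SI
watts; the two differ by exactly that constant. The shipped Judd–Vos
modified photopic curve is a 10 nm public tabulation, PCHIP-interpolated
to 1 nm, with the peak pinned to 1.0 at 555 nm; all spectral integrals
are trapezoidal. Because coarse spectra (e.g. a two-node flat spectrum)
must still be weighted correctly, the weighting integral runs on the
union of the spectrum and photopic grids.

**Direction sampling.** Per C-plane, the polar CDF is built from the
exact closed-form integral of the piecewise-linear intensity times
sin φ per tabulated segment, and inverted linearly between nodes. The
azimuthal draw is discrete over planes with solid-angle-weighted plane
fluxes (so plane-selection frequencies are exactly proportional to plane
flux), after which the heading is jittered uniformly within the selected
plane's azimuthal sector. The jitter makes an isotropic web produce an
exactly uniform heading while preserving the discrete plane frequencies;
polar sampling uses only the selected plane (no cross-plane
interpolation). A consequence of the continuous polar CDF is that a
"delta" beam must be represented as a narrow cone (the `narrow-beam`
fixture), not as a single nonzero node.

**Reflection.** A uniform draw against the surface's specularity selects
mirror vs diffuse; a second draw against that mode's spectral reflectance
at the packet wavelength decides survival (mode first, then survival).
Diffuse reflection is cosine-weighted (true Lambertian radiance, mean
cosine 2/3) rather than uniform-in-hemisphere; a uniform option
(`diffuse_uniform`) exists for fidelity experiments. Absorption happens
only at surfaces — air carries no volumetric absorption, only scattering.

**Interfaces and scattering.** Material interfaces swap the packet's
cached medium and refract by Snell's law; total internal reflection
mirrors and keeps the medium; Fresnel reflection probabilities are not
applied. Scattering deflects by Henyey–Greenstein with configurable
anisotropy `g` (default 0, i.e. isotropic); at the clear-air default
`μ_s = 10⁻⁶ m⁻¹` scattering is negligible over the domain sizes used.

## Numerical choices

- **Voxel traversal**: exact amortised 3D line walk (Amanatides–Woo
  style) with half-open voxel intervals; per-voxel chord deposits
  telescope to the total chord to floating-point round-off, which the
  tests check at 1e-12 relative.
- **Ray epsilon**: hits closer than 1e-9 m are ignored and reflected
  packets are offset 1e-9 m along the surface normal, preventing
  self-intersection.
- **Octree**: recursive equal-volume eight-way subdivision until ≤ 16
  triangles per leaf or depth 10; triangles register in every leaf their
  bounding box overlaps (a conservative superset of true overlap), so
  traversal candidates always contain the brute-force hit.
- **RNG**: PCG32 streams seeded via splitmix64 from (master seed,
  stream id), implemented identically in pure Python and in the compiled
  kernels. Each source and each walker owns a stream, so results are
  bit-reproducible, independent of execution order, and per-source
  contributions superpose exactly. Street fixtures key lamp streams by
  lamp index, which makes a lamp-off grid pixelwise ≤ the all-on grid —
  the corridor comparison is then exact rather than statistical.
- **Degenerate inputs**: all-zero webs raise a degenerate-LID error;
  spectra with no photopic overlap raise an invisible-spectrum error;
  zero-height buildings warn and are skipped; no-data raster cells are
  NaN, excluded from building-height maxima, and poisonous to sample.

## Digital twin

Footprints are triangulated by ear clipping with hole bridging — an
exact, area-conserving tiling of simple polygons (the area-conservation
property is tested on 100 random polygons); uniform midpoint subdivision
refines to a maximum triangle area where terrain needs vertices to
follow the DTM. DTM sampling at vertices is bilinear with edge clamping.
Building walls follow the terrain at their base and rise to a flat cap
at (max in-footprint DTM) + (max in-footprint DSM−DTM), avoiding gaps on
slopes; roofs are deliberately flat. Scenes serialize to a zip of OBJ
mesh + YAML attributes + JSON provenance, with `repr`-formatted floats
so archives round-trip bit-exactly.

## Walker model

Walkers are generic photophobes, not a species model: cardinal proposals
with weights (0.5, 0.2, 0.1, 0.2) for (N, E, S, W), rejection when the
target pixel is outside the region or its log₁₀ energy density is
*strictly above* the threshold (pixels exactly at the threshold are
passable; zero-density pixels are −∞ and always passable). Rejected
proposals consume an iteration — that keeps the 1000-iteration cap
meaningful — and failed walks report exactly the cap. Starts are uniform
over the southern edge; success is first arrival at the northern edge.
An east/west margin (in metres) can be trimmed from planes before
walking to avoid edge darkness artefacts.

The exact oracle builds the absorbing-chain transition structure implied
by the move rule (rejections as self-loops, north row absorbing) and
either solves the infinite-horizon absorption system sparsely — after a
reachability reduction that assigns probability 0 to states that cannot
reach the north, which also handles otherwise-singular isolated regions —
or runs truncated power iteration for the capped quantities the
ensembles actually estimate.

## What the fixtures emulate — and what they don't

The synthetic lamp library pairs closed-form webs (uniform lower
hemisphere, cosine downlight, narrow beam) with toy spectra (line pairs,
blackbody-like continua) at the published power/efficacy operating
points. Street scenarios place lamps at 20–40 m spacings (32 m is the
reference), 8 m above a flat tarmac road in a 120 × 60 × 20 m domain at
1 m voxels — lamp height and voxel size are package defaults, recorded
in scene provenance, since the study design fixes spacings and slice
heights (0/4/10 m) but not those two. Validation-scale runs use 10⁵
packets per lamp and the acceptance inverse-square run 10⁶ packets;
production-style sweeps default to 10⁶ packets per source.

Passing tests on these fixtures demonstrate the transport physics,
estimator exactness, and the qualitative corridor phenomenology (light
barrier, threshold/spacing monotonicity, lamp-off corridors). They do
not demonstrate fidelity to any real streetscape: real manufacturer
LIDs are far more structured than the toys, measured lamp spectra
differ from the stand-ins, and real terrain/building geometry shapes
shadows the flat fixtures cannot. Users with measured inputs supply
them through the IES/EULUMDAT/csv-grid readers, two-column spectra, and
GeoTIFF/ESRI-ASCII + GeoJSON twin builders.

## Known limitations

- No atmospheric profiles, aerosols, weather or skyglow; the clear-air
  scattering coefficient makes air effectively transparent.
- No foliage, roof pitch, CRS reprojection, or polarization.
- Walkers are panchromatic and memoryless; no field-of-view or spectral
  sensitivity weighting, and the forward bias can trap walkers in
  concave dark pockets.
- The `as-printed` flux scale is not SI-radiometric; use
  `mode="physical"` when absolute watts matter.
- Single-threaded execution; the per-source stream design would admit
  parallelism without changing results, but none is implemented.
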