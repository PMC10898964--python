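"""Luminaire photometry: webs, samplers and flux conversion.

Builds a toy photometric web, integrates it to total luminous flux, samples
emission directions from it, and converts a street lamp's electrical power
to the radiant flux the MCRT engine uses.
"""
import numpy as np

from alansim.fixtures import LAMP_TABLE, make_toy_lid, make_toy_spectrum
from alansim.photometry import (
    build_direction_sampler,
    lid_total_flux,
    luminous_flux_from_power,
    luminous_to_radiant,
    sample_direction,
)

# A Lambertian downlight: intensity proportional to cos(angle from nadir).
lid = make_toy_lid("cosine-downlight")
print(f"cosine downlight total flux: {lid_total_flux(lid):.4f} lm "
      f"(closed form: pi = {np.pi:.4f})")

sampler = build_direction_sampler(lid)
rng = np.random.default_rng(0)
dirs = np.array([sample_direction(sampler, rng) for _ in range(20000)])
print(f"sampled mean downward cosine: {-dirs[:, 2].mean():.3f} "
      "(cosine lobe about nadir -> 2/3)")

# Table-style lamp conversion: power x efficacy -> lumens -> engine watts.
for name, row in LAMP_TABLE.items():
    lm = luminous_flux_from_power(row["input_power_w"], row["efficacy_lm_per_w"])
    print(f"{name}: {row['input_power_w']:.0f} W x {row['efficacy_lm_per_w']:.0f} lm/W "
          f"= {lm:.0f} lm (published radiant flux {row['radiant_flux_w']:.0f} W)")

# Spectral conversion through the photopic curve (Judd-Vos modified).
spectrum = make_toy_spectrum("two-line", wavelengths=(569.0, 589.0), energies=(0.3, 0.7))
radiant, scaled = luminous_to_radiant(6160.0, spectrum)
print(f"6160 lm through a warm two-line spectrum -> {radiant:.0f} W (engine scale); "
      f"scaled spectrum integral {scaled.total():.0f} W")
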