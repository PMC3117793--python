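"""Discretize the frontal hemisphere and synthesize directional fields.

Builds the 256-cell equal-area partition, generates the synthetic head's
emission and hearing fields at 40 and 80 kHz, and prints how the beams
narrow with frequency.
"""

import numpy as np

import pinnasonar as ps

part = ps.partition_hemisphere(256)
print(f"partition: {part.n_cells} cells x {part.cell_solid_angle_sr:.4f} sr "
      f"= {part.n_cells * part.cell_solid_angle_sr:.4f} sr (2*pi)")
print(f"chance-level entropy log2(N) = {np.log2(part.n_cells):.1f} bits")

cfg = ps.SyntheticHeadConfig()
for f in (40.0, 80.0):
    em, hl, hr = ps.synthetic_head_fields(cfg, f, part)
    hp = np.sum(em.gain_db >= em.gain_db.max() - 3.0) * part.cell_solid_angle_sr
    total = em.linear_power.sum() * part.cell_solid_angle_sr
    print(f"{f:5.0f} kHz: emission half-power solid angle {hp:.3f} sr, "
          f"power integral {total:.6f}, left-ear peak {hl.gain_db.max():.1f} dB")

# the morphology-free control: two monopoles at the nostril spacing
iso = ps.two_source_emission(cfg, 80.0, part)
lam = ps.wavelength_mm(80.0)
print(f"two-source control at 80 kHz: first interference null at "
      f"azimuth {np.rad2deg(np.arcsin(lam / (2 * cfg.source_spacing_mm))):.1f} deg")

# The half-power solid angle shrinks as frequency rises: the same head
# focuses high frequencies into a smaller region of the hemisphere.
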