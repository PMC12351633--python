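"""The spherical forward model in isolation.

Computes the lead-field of the default 4-shell head (brain/CSF/skull/scalp,
outer radii 78/80/86/92 mm; conductivities 0.40/1.79/0.008/0.33 S/m) on a
cortical sphere, and checks two physical sanity properties: the cortical En
under an anode is positive (depolarising sign convention) and the
area-weighted flux through the closed cortical surface vanishes.
"""

import numpy as np

from tesgroup import Montage, SphericalHeadSpec, icosphere, spherical_leadfield

spec = SphericalHeadSpec()
surface = icosphere(3, spec.cortical_radius)
leadfield = spherical_leadfield(spec, surface)
print(f"lead-field: {leadfield.matrix.shape[0]} cortical nodes x "
      f"{leadfield.matrix.shape[1]} bipolar columns (reference {leadfield.reference_label})")

montage = Montage({"F3": 2.0, "Fp2": -2.0})
en = leadfield.matrix @ montage.current_vector(leadfield)
dirs = surface.unit_directions()
under_anode = int(np.argmax(dirs @ spec.electrode_positions["F3"]))
print(f"F3(+2 mA) / Fp2(-2 mA): En under the anode = {en[under_anode]:+.3f} V/m "
      f"(positive = field into the cortex)")
print(f"peak |En| = {np.abs(en).max():.3f} V/m")

areas = surface.node_areas
print(f"closed-surface flux / sum|En|A = {abs(en @ areas) / (np.abs(en) @ areas):.2e} "
      f"(zero up to quadrature: no sources inside the cortex)")
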