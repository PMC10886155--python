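"""Generate a synthetic eye and inspect its topography.

Builds one seeded patient (metadata + pre-wear conicoid topography with a
lash-gap coverage footprint + matched lens design), applies the Ortho-K
effect, and prints the headline numbers.
"""

import numpy as np

from orthok.synthetic import CohortSpec, apply_orthok_effect, generate_patient
from orthok.topography import write_topography

spec = CohortSpec(n=1, seed=7)
patient, pre, lens, effect = generate_patient(spec, 0)
post = apply_orthok_effect(pre, effect)

print(f"patient {patient.id}: {patient.eye} eye, age {patient.age:.1f} y, "
      f"IOP {patient.iop:.1f} mmHg, CCT {patient.cct * 1e3:.0f} um")
print(f"pre-wear Sim-K: {pre.simk_flat_d:.2f} / {pre.simk_steep_d:.2f} D "
      f"(flat axis {pre.flat_angle_deg:.0f} deg)")
print(f"coverage: {pre.coverage.mean() * 100:.1f}% of the 300 x 333 grid "
      f"(lid truncation + lash slits)")
print(f"lens: base curve {lens.base_radius} mm, reverse {lens.reverse_radius} mm, "
      f"diameter {lens.diameter} mm")
print(f"imposed effect: {effect.central_flattening:.2f} D central flattening, "
      f"+{effect.annulus_steepening:.2f} D annulus at {effect.annulus_radius:.2f} mm, "
      f"decentred ({effect.decentration[0]:+.2f}, {effect.decentration[1]:+.2f}) mm")
dz = post.elevation - pre.elevation
print(f"elevation change: min {np.nanmin(dz) * 1e3:.2f} um, "
      f"max {np.nanmax(dz) * 1e3:.2f} um (deep central depression, shallow annulus)")

write_topography(pre, "example_pre.topo")
write_topography(post, "example_post.topo")
print("wrote example_pre.topo / example_post.topo (text container)")
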