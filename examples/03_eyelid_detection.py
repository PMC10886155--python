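"""Eyelid boundary detection from a coverage footprint.

Generates a lash-gap coverage mask bounded by the cohort-mean lid
parabolas and recovers the second-order lid coefficients from the mask.
"""

from orthok.eyelid import EyelidBoundary, detect_eyelid_boundary
from orthok.synthetic import generate_coverage_mask
from orthok.topography import default_polar_grid

truth_upper = (-0.0832, -0.0262, 3.5809)    # y = a x^2 + b x + c, right eye
truth_lower = (0.0842, 0.0163, -3.9734)

az, r = default_polar_grid()
mask = generate_coverage_mask(EyelidBoundary(truth_upper, truth_lower),
                              az, r, slit_count=0)
det = detect_eyelid_boundary(mask, az, r)

print(f"coverage: {mask.mean() * 100:.1f}% of the measurement disc")
print(f"landmarks: {len(det.landmarks_upper)} upper / "
      f"{len(det.landmarks_lower)} lower lid points")
for lid, got, want in (("upper", det.upper, truth_upper),
                       ("lower", det.lower, truth_lower)):
    err = max(abs(g - w) / abs(w) for g, w in zip(got, want)) * 100
    print(f"{lid} lid fit: a={got[0]:+.4f} b={got[1]:+.4f} c={got[2]:+.4f} "
          f"(max coefficient error {err:.1f}%)")
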