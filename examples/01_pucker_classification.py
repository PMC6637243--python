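"""Classify the ring pucker of ideal pyranose geometries.

Builds idealized six-membered rings at chosen Cremer-Pople coordinates,
recomputes (Q, theta, phi) from the raw Cartesian coordinates, and assigns
the nearest canonical conformer.  The printed angular distance is the
great-circle separation (degrees) between the observation and the assigned
conformer's reference point on the puckering sphere.
"""

from puckertools import (
    build_conformer_library,
    classify,
    cremer_pople,
    inverse_cp,
)

library = build_conformer_library()

print(f"{'built as':>10s} {'Q (A)':>7s} {'theta':>7s} {'phi':>7s} "
      f"{'assigned':>9s} {'dist (deg)':>10s}")
for label in ("4C1", "1S3", "1,4B", "1S5", "4H3", "B2,5"):
    ref = library[label]
    ring = inverse_cp(0.57, ref.theta_ref, ref.phi_ref)
    pucker = cremer_pople(ring)
    assignment = classify(pucker, library)
    print(f"{label:>10s} {pucker.Q:7.3f} {pucker.theta:7.2f} "
          f"{pucker.phi:7.2f} {assignment.conformer:>9s} "
          f"{assignment.angular_distance:10.2e}")

# a slightly distorted chair still classifies as 4C1
ring = inverse_cp(0.55, 8.0, 123.0)
assignment = classify(cremer_pople(ring), library)
print(f"\nring at (0.55 A, theta=8, phi=123) -> {assignment.conformer} "
      f"({assignment.angular_distance:.1f} deg from reference)")
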