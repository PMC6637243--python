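"""From a simulated -1-subsite trajectory to an occupancy table and an
itinerary call.

Simulates a 1000-frame (20 ns-equivalent, 20 ps stride) puckering
trajectory that dwells 90% in the 4C1 chair and visits the 4H3 half-chair
and the 1S3 skew-boat, i.e. the distortion pattern expected for a GH2-type
beta-galactosidase.  The occupancy table is the percentage of frames in
each conformer; the itinerary call matches the equatorial anchor against
the three family-type ALPH paths.
"""

from puckertools import (
    PuckerPathSpec,
    assign_itinerary,
    excursions,
    occupancy,
    per_frame_conformers,
    simulate_pucker_path,
)

spec = PuckerPathSpec(
    waypoints=("4C1", "4H3", "1S3"),
    dwell_fractions=(0.90, 0.06, 0.04),
    n_frames=1000,
    angular_noise_sigma=3.0,
    seed=42,
)
path = simulate_pucker_path(spec)
assignments = per_frame_conformers(path.trajectory)

table = occupancy(assignments)
print(f"occupancy over {table.n_frames} frames "
      f"({path.trajectory.run_length_label}):")
for label, pct in sorted(table.percent.items(), key=lambda kv: -kv[1]):
    print(f"  {label:>6s} {pct:5.1f} %")
print(f"dominant conformer: {table.dominant}")

bursts = excursions(assignments)
equatorial = [e for e in bursts if e.reached_equator]
print(f"\n{len(bursts)} excursions away from 4C1, "
      f"{len(equatorial)} reaching the equatorial belt")

call = assign_itinerary(table)
print(f"\nitinerary: {call.itinerary}  (path {call.path})")
for name, s in call.support.items():
    print(f"  support {name:>14s}: {s:.2f}")
# support is each anchor's share of the equatorial occupancy; the call is
# ALPH-compatible because a skew-boat anchor (1S3) was actually visited
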