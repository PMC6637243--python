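"""Evaluate docking poses and select the MD starting structure.

Constructs a reference -1 galactosyl ring (as found in a crystallographic
complex), a pair of catalytic carboxylate oxygens, and five synthetic
docking poses of decreasing quality.  Each pose is scored against the four
selection criteria: (i) docking score, (ii) ring RMSD < 0.5 A versus the
reference, (iii) matching ring conformer, (iv) catalytic distances within
cutoff.  The selected seed is the best-scoring pose that passes the
geometric criteria -- which here is NOT the top-scoring pose.
"""

import numpy as np

from puckertools import DockPose, inverse_cp, select_md_seed
from puckertools.pucker import RING_ATOM_ORDER, RingCoordinates

# reference ring (4C1) in the receptor frame
ring = inverse_cp(0.57, 0.0, 0.0)
reference = RingCoordinates(positions=ring.positions + [10.0, 5.0, 2.0],
                            residue_id="X:1")
centroid = reference.positions.mean(axis=0)
c1 = reference.positions[1]
outward = (c1 - centroid) / np.linalg.norm(c1 - centroid)
nucleophile_O = np.array([c1 - [0.0, 0.0, 3.0]])
acidbase_O = np.array([c1 + 1.4 * outward + [0.0, 0.0, 2.8]])


def pose(rank, score, shift):
    xyz = reference.positions + [shift, 0.0, 0.0]
    o1 = xyz[1] + 1.4 * outward
    return DockPose(atoms={"X:1": (tuple(RING_ATOM_ORDER) + ("O1",),
                                   np.vstack([xyz, o1]))},
                    dock_score=score, pose_rank=rank, minus1_residue="X:1")


poses = [
    pose(1, -9.5, 1.2),   # best affinity but dislocated ring
    pose(2, -9.1, 0.8),
    pose(3, -8.7, 0.2),   # good fit, third-best score
    pose(4, -8.4, 0.0),   # perfect fit, worse score
    pose(5, -7.9, 2.0),
]
result = select_md_seed(poses, reference, nucleophile_O, acidbase_O)

print(f"{'rank':>4s} {'score':>6s} {'ringRMSD':>8s} {'conf':>5s} "
      f"{'optimal':>7s} {'passes':>6s}")
for e in result.evaluations:
    print(f"{e.pose_rank:4d} {e.dock_score:6.1f} {e.ring_rmsd:8.3f} "
          f"{e.conformer:>5s} {str(e.optimal_fit):>7s} "
          f"{str(e.passes_geometry):>6s}")
print(f"\n{result.message}")
# rank 3 wins: it is the best-scoring pose with ring RMSD < 0.5 A and
# sound catalytic geometry, even though ranks 1-2 score better
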