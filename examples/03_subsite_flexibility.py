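"""Per-subsite RMSD flexibility profile of a mock enzyme:disaccharide
complex.

Builds a multi-model mock complex in which the -1 galactosyl ring
oscillates between the 4C1 chair and the 1S3 skew-boat while the +1
residue is rigid, then superposes every frame on the protein heavy atoms
of frame 0 and reports RMSD series.  The -1 residue comes out more mobile
than the +1 residue -- the signature of a catalytically distorting
subsite.
"""

from puckertools import (
    MockComplexSpec,
    PuckerPathSpec,
    build_mock_complex,
    frames_from_structure,
    rmsd_series,
)

spec = MockComplexSpec(
    n_protein_residues=20,
    ligand_subsites=(("-1", False), ("+1", True)),
    pucker_spec=PuckerPathSpec(
        waypoints=("4C1", "1S3"),
        dwell_fractions=(0.6, 0.4),
        n_frames=200,
        seed=7,
    ),
    seed=7,
)
mock = build_mock_complex(spec)
print(f"mock complex: {mock.structure.stack_depth()} frames, "
      f"subsites {mock.subsite_map}")

frames = frames_from_structure(mock.structure)
profile = rmsd_series(frames, mock.subsite_map)

print(f"\nmean RMSD vs frame 0 (A), protein frame held:")
for entity in ("protein", "ligand", "-1", "+1"):
    print(f"  {entity:>8s} {profile.mean(entity):7.4f}")
print("\nthe puckering -1 residue fluctuates more than the rigid +1 "
      "residue,\nwhile the held protein stays at zero by construction")
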