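# Methods

This note documents the models, conventions and numerical choices behind
`puckertools`, and what the synthetic-data tests do and do not establish
about real trajectories.

## Cremer–Pople coordinates and the conformer library

The mean plane of a six-membered ring is defined through the geometric
centre by the two first-moment constraints Σ zⱼ sin(2πj/6) =
Σ zⱼ cos(2πj/6) = 0; its normal is taken along **R′** × **R″**, the cross
product of the sine- and cosine-weighted coordinate sums.  Displacements
zⱼ along that normal are decomposed as

    q2 cos φ2 = √(1/3) Σ zⱼ cos(4πj/6)
    q2 sin φ2 = −√(1/3) Σ zⱼ sin(4πj/6)
    q3        = √(1/6) Σ (−1)ʲ zⱼ          (j = 0 … 5)

with Q = √(q2² + q3²), θ = atan2(q2, q3) ∈ [0°, 180°], φ = φ2 ∈ [0°,
360°).  Angles are reported in degrees throughout the public API.

**Atom ordering.**  Rings are ordered O5, C1, C2, C3, C4, C5 (j = 0 at
O5), the standard convention for D-pyranoses; it places ⁴C₁ at the north
pole.  Cyclic relabeling changes (θ, φ) predictably (odd shifts mirror
the latitude), which is covered by tests against an independent
least-squares implementation.

**Conformer library.**  The 38 canonical conformers are not stored as
hardcoded angles.  Each IUPAC label is parsed into its above-plane
(superscript) and below-plane (subscript) atoms, the corresponding ±1
displacement pattern is pushed through the projection above, and the
resulting (θ, φ) becomes the reference point.  This reproduces the
standard Mercator layout — boats at even 60° meridians starting with
³,ᴼB at φ = 0°, skew-boats between them, envelopes at θ = 54.74° /
125.26° and half-chairs at θ = 50.77° / 129.23° — and guarantees the
library is internally consistent with the classifier.  The three
itinerary meridians align by construction (¹S₃/⁴H₃ at 210°, ¹,⁴B/⁴E at
240°, ¹S₅/⁴H₅ at 270°).

**Classification.**  Nearest reference by great-circle distance on the
unit sphere, computed with the atan2 form (stable near 0°).  Ties — a
measure-zero event — break to the lexicographically smallest label.
Rings with Q < 0.1 Å are reported UNDEFINED rather than forced onto the
sphere; near-planar pyranose rings do not occur in realistic data, so
this threshold only guards degenerate input.  Region boundaries between
adjacent conformers are therefore Voronoi cells of the reference points;
hybrid transition-state labels (⁴H₃/⁴E, ⁴E/⁴H₅) are display aliases in
the itinerary paths, never classification outputs.

**Inverse construction.**  `inverse_cp` places the six atoms on a
regular hexagon traversed clockwise (so the mean-plane normal of the
construction is +z) and adds the zⱼ pattern for the target (Q, θ, φ).
Because the m = 2 and m = 3 Fourier components are orthogonal to the
mean-plane constraints, the round trip through `cremer_pople` is exact
to floating-point rounding.  The hexagon side is shrunk by the midrange
of the squared z-offsets so that all bond lengths stay within 10% of the
target (default 1.54 Å) up to Q = 0.8 Å; amplitudes above 1.5 Å (or that
would collapse the hexagon) are rejected as chemically meaningless.

## Trajectory analytics

Occupancy tables report the percentage of frames per observed conformer;
unobserved conformers are omitted and rendered as an em-dash in tabular
output.  All frames are counted — no equilibration prefix is discarded;
callers wanting post-equilibration statistics should slice the
trajectory first.

Excursions are maximal contiguous runs of non-⁴C₁ frames (UNDEFINED
frames included, since intermediate envelope/half-chair forms en route
to the equator belong inside a burst), exported as 0-based half-open
intervals.

**Itinerary support** is a deliberate quantification of an otherwise
qualitative call: each family-type itinerary is anchored at its
equatorial pre-transition-state conformer (¹S₃ → GH2-type, ¹,⁴B →
GH1/GH35-type, ¹S₅ → GH42-type), support is the anchor's share of total
equatorial (boat + skew-boat) occupancy, an itinerary is supported iff
its anchor occupancy is nonzero, and the reported call is the argmax
(co-supported itineraries are listed).  A trajectory that never leaves
the chair/tropics is called NONE and flagged not ALPH-compatible.  This
rule reproduces the expected family calls on published-style conformer
inventories while remaining a pure function of the occupancy table.

## Flexibility profiles

Each frame is superposed on the protein heavy atoms of frame 0 by
least-squares rigid-body fitting (Kabsch, via scipy's
`Rotation.align_vectors`); the fitted transform is applied unchanged to
the ligand, i.e. the ligand is never re-superposed on itself.  Series
are reported for the protein, the complete ligand, and each sugar
residue keyed by subsite.  Heavy atoms means all non-hydrogen atoms
(waters excluded); a Cα-only protein mode is available.  Missing atoms
in any frame are an error — trajectory frames must be complete.  The
reference frame's RMSD is exactly 0 by construction; coordinates coming
from PDB files are promoted to double precision before fitting.  Tests
pin the fit to an independent quaternion-method (Kearsley) oracle.

## Pose evaluation

Ring RMSD is computed over the six −1 ring atoms in the receptor frame
without re-superposition, since docking poses and the reference complex
share the receptor coordinate system; < 0.5 Å counts as an optimal fit.
The four seed-selection criteria are operationalized as: (i) best
docking score in the run; (ii) ring RMSD below the optimal-fit bound;
(iii) the −1 ring classifies to the same canonical conformer as the
reference ring; (iv) nucleophile carboxylate O → anomeric C1 and
acid/base carboxylate O → glycosidic O1 both ≤ 3.5 Å, plus at least one
donor–acceptor contact (≤ 3.4 Å) between −1-residue O/N atoms and
protein polar atoms when those are supplied (the contact criterion is
vacuous otherwise).  All cutoffs are configurable (`SelectionCutoffs`)
and the distance defaults are ordinary catalytic-geometry values.  The
selected seed is the best-scoring pose passing (ii)–(iv), ties broken by
pose rank, making selection deterministic and input-order invariant.
Whole-residue RMSD can be obtained by passing the full residue as the
"ring" atom set, but ring-only is the default and the tested path.

## Structure trees

MaxSub is implemented as a seed-extension search: every contiguous
window of 4 correspondence pairs is superposed, refined in four passes
with the acceptance threshold ramping to d (default 3.5 Å), and the
final matched set M is scored as Σ_{i∈M} 1/(1 + (dᵢ/d)²) / N with N the
residue count of the first (query) structure — the source of the
asymmetry between the two comparison directions.  The reciprocal scores
are averaged and 1 − MaxSubAverage populates a symmetric distance matrix
in [0, 1].  Residue correspondence is an explicit input (identity by
index for equal-length structures): the sequence-independent alignment
search that finds correspondences for real, unequal chains is a
different problem and out of scope; the statistic of interest here is
the symmetrized distance.  Neighbor joining is delegated to scikit-bio's
Saitou–Nei implementation; negative branch lengths, which can arise on
non-additive input, are clamped to zero with a warning.  On additive
matrices the reconstruction is exact, which the tests verify by
comparing the tree's patristic distances against the input matrix (a
tree metric determines its tree uniquely).

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure of −1-subsite puckering
trajectories: programmed conformer waypoints with dwell fractions,
Gaussian noise on the sphere's tangent plane (default σ = 3°, a
conformer cloud comfortably inside a Voronoi cell) and on the amplitude
(σ = 0.02 Å around Q = 0.57 Å, a typical pyranose), 1000 frames per
20 ns-equivalent run at a 20 ps stride.  Frames are apportioned to
waypoints by largest remainder, so programmed fractions are exact before
noise; optional slerp ramps bridge waypoint blocks for path-style
figures.  The tangent-plane step uses a local orthonormal basis, so the
poles need no special casing.  Mock complexes embed such a ring (plus an
O1 stub for glycosidic-distance checks) next to rigid ideal rings and a
rigid poly-ALA helix scaffold; PDB output uses MODEL/ENDMDL records,
occupancy 1.00, B-factor 0.00, no hydrogens, and is byte-deterministic
per seed.

Chemistry is deliberately idealized: no substituents beyond the O1 stub,
no energetics, no solvent, no correlated protein–ligand motions.
Passing tests therefore demonstrate that the *analysis layer* is correct
(classification, counting, superposition, selection rules, tree
reconstruction) — not that any particular enzyme shows a particular
itinerary; conclusions about real systems still require real
trajectories.

## Problem sizes and numerical tolerances

Test fixtures use 20–1000 frames, 4–20 protein residues and 30–60 Cα
structures — sizes chosen so the full suite exercises every code path,
including two 1000-frame end-to-end occupancy recoveries through PDB
round trips, in seconds.  Statistical assertions use 3 binomial standard
errors at the programmed fractions; geometric round trips assert 1e−6°
or better; rigid-body invariance asserts 1e−8.  Stochastic tests are
seeded, and hypothesis runs derandomized.

## Known limitations

* Furanose (five-membered) puckering is not handled.
* No kinetic or free-energy modelling of conformer interconversion.
* MaxSub normalization follows the query-length convention; tools using
  shorter-chain normalization will differ on unequal-length pairs (the
  threshold and normalization are configurable/documented).
* The itinerary rule reads occupancy only; it does not check the
  temporal ordering of conformers along an excursion.
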