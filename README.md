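# puckertools

Ring-puckering analytics for glycoside hydrolase enzyme:substrate
dynamics.

Retaining glycosidases such as the clan GH-A β-galactosidases (families
GH1, GH2, GH35, GH42, GH59) distort the sugar ring bound at the lytic
subsite −1 on the way to the transition state.  Which distorted
conformers a trajectory visits — and in what proportions — encodes the
enzyme's conformational itinerary.  `puckertools` is a Python library for
analysing exactly that, from trajectory frames (multi-model PDB) down to
family-level structure trees, for computational glycobiologists who run
docking and MD elsewhere and need the downstream analysis to be tested
and reproducible.

## What it computes

**Cremer–Pople puckering coordinates.**  For a six-membered ring with
atoms ordered O5, C1…C5, the out-of-plane displacements *z*ⱼ from the
unique mean plane (Σ*z*ⱼ = 0 plus the two first-moment constraints) are
Fourier-decomposed into the boat/twist amplitude–phase pair (*q*₂, φ₂)
and the chair amplitude *q*₃ = 6^(−1/2) Σ(−1)^(j−1) *z*ⱼ, giving
spherical coordinates *Q* = √(*q*₂² + *q*₃²), θ = atan2(*q*₂, *q*₃),
φ = φ₂.  Chairs sit at the poles (⁴C₁ at θ = 0), the 6 boats and 6
skew-boats alternate every 30° around the θ = 90° equator, and the 12
envelopes and 12 half-chairs alternate on the two tropics — the 38
canonical conformers.  Classification is nearest-reference by
great-circle distance, with an inverse constructor (`inverse_cp`) that
builds ideal ring geometry at any (*Q*, θ, φ).

**Occupancy tables and ALPH itineraries.**  Per-frame conformer streams
become percentage occupancy tables, excursion segmentations (maximal
runs away from ⁴C₁), and itinerary calls.  The three family-type
reaction paths for β-galactosidases, all compatible with the
antiperiplanar lone pair hypothesis (ALPH), are

* GH2-type: ¹S₃ → ⁴H₃‡ → ⁴C₁
* GH1/GH35-type: ¹,⁴B → ⁴H₃/⁴E‡ → ⁴C₁
* GH42-type: ¹S₅ → ⁴E/⁴H₅‡ → ⁴C₁

A trajectory supports an itinerary when its equatorial anchor (¹S₃,
¹,⁴B or ¹S₅) is observed; support is the anchor's share of total
equatorial occupancy.

**Subsite flexibility.**  Frames are Kabsch-superposed on the protein
heavy atoms of frame 0 (the protein is held; no re-fit on the ligand)
and RMSD series are reported for the protein, the full ligand, and each
sugar residue by subsite label (−1, +1, +2, …).

**Docking-pose seed selection.**  Poses are evaluated against a
reference complex: ring RMSD of the −1 pyranose (optimal fit < 0.5 Å,
computed in the shared receptor frame), conformer agreement, catalytic
distances (nucleophile O → anomeric C1, acid/base O → glycosidic O,
default ≤ 3.5 Å) and hydrogen-bond contacts; the MD seed is the
best-scoring pose passing the geometric criteria, with an explicit
"no productive pose" result otherwise.

**Structure distance trees.**  MaxSub similarity (largest residue subset
superimposable within 3.5 Å, normalized by the query length, hence
asymmetric) is computed in both directions, averaged (MaxSubAverage) and
converted to the distance 1 − MaxSubAverage; the symmetric matrix feeds
Saitou–Nei neighbor joining with Newick export.

**Synthetic data.**  Because MD/docking engines are out of scope, a
first-class generator produces ideal rings, stochastic pucker
trajectories dwelling at programmed waypoints (default 1000 frames per
20 ns-equivalent run, 20 ps stride), and mock rigid-protein + ligand
complexes written as multi-model PDB — every fixture the analysis layer
needs, with ground truth attached.

## Worked example

```python
from puckertools import (PuckerPathSpec, simulate_pucker_path,
                         per_frame_conformers, occupancy, assign_itinerary)

spec = PuckerPathSpec(waypoints=("4C1", "4H3", "1S3"),
                      dwell_fractions=(0.90, 0.06, 0.04),
                      n_frames=1000, angular_noise_sigma=3.0, seed=42)
path = simulate_pucker_path(spec)
table = occupancy(per_frame_conformers(path.trajectory))
call = assign_itinerary(table)
```

This prints (via `python examples/02_occupancy_and_itinerary.py`):

```
occupancy over 1000 frames (20 ns):
     4C1  90.0 %
     4H3   6.0 %
     1S3   4.0 %
dominant conformer: 4C1

1 excursions away from 4C1, 1 reaching the equatorial belt

itinerary: GH2-type  (path 1S3 -> 4H3(ts) -> 4C1)
  support       GH2-type: 1.00
  support  GH1/GH35-type: 0.00
  support      GH42-type: 0.00
```

The table is the per-conformer share of frames; the trajectory reached
the equatorial skew-boat ¹S₃, so the run is ALPH-compatible and called
GH2-type.  The other examples cover classification
(`examples/01_pucker_classification.py`), flexibility profiling (`03`),
pose selection (`04`) and tree building (`05`).

A thin CLI mirrors the generator and the per-frame export:
`puckertools synth ring|path|complex`, `puckertools analyze`.

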