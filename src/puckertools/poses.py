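"""Docking-pose evaluation and MD seed selection.

Docked poses of an oligosaccharide in a glycosidase active site are
evaluated against a crystallographic reference complex: the pyranose-ring
RMSD of the -1 galactosyl residue (computed in the shared receptor frame,
no re-superposition), the geometry of the two catalytic carboxylates
(nucleophile oxygen to anomeric C1; acid/base oxygen to the glycosidic
oxygen), and hydrogen-bond contacts of the -1 residue.  The MD starting
pose is the best-scoring pose among those passing all geometric criteria:

(i)   best docking score (affinity; more negative is better),
(ii)  superposition with the reference ring (ring RMSD < 0.5 Angstrom),
(iii) the -1 ring in the same canonical conformer as the reference,
(iv)  catalytic distances within cutoff plus a minimum number of
      donor-acceptor contacts (when protein polar atoms are supplied).

When no pose passes, an explicit "no productive pose" result is returned
rather than a silent fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flexibility import rmsd
from .pucker import RING_ATOM_ORDER, RingCoordinates, cremer_pople
from .conformers import classify

__all__ = [
    "OPTIMAL_RING_RMSD",
    "DockPose",
    "SelectionCutoffs",
    "PoseEvaluation",
    "SelectionResult",
    "ring_rmsd",
    "evaluate_pose",
    "select_md_seed",
]

#: Ring-RMSD bound (Angstrom) below which a docked -1 ring counts as an
#: optimal fit to the reference complex.
OPTIMAL_RING_RMSD = 0.5


@dataclass(frozen=True)
class DockPose:
    """One docked ligand pose in the receptor coordinate frame.

    ``atoms`` maps residue identifiers to ``(atom_names, xyz)``; the -1
    residue must contain the six ring atoms (O5, C1..C5) plus, for
    catalytic-geometry checks, the glycosidic O1.
    """

    atoms: dict[str, tuple[tuple[str, ...], np.ndarray]]
    dock_score: float
    pose_rank: int
    minus1_residue: str

    def __post_init__(self):
        if self.minus1_residue not in self.atoms:
            raise ValueError(
                f"-1 residue {self.minus1_residue!r} missing from pose atoms")

    def atom_xyz(self, residue: str, atom_name: str) -> np.ndarray:
        names, xyz = self.atoms[residue]
        try:
            return xyz[names.index(atom_name)]
        except ValueError:
            raise KeyError(
                f"atom {atom_name!r} not found in residue {residue!r}"
            ) from None

    def ring(self, atom_order: tuple[str, ...] = RING_ATOM_ORDER,
             ) -> RingCoordinates:
        """The -1 residue's six ring atoms as :class:`RingCoordinates`."""
        xyz = np.array([self.atom_xyz(self.minus1_residue, a)
                        for a in atom_order])
        return RingCoordinates(positions=xyz, atom_labels=atom_order,
                               residue_id=self.minus1_residue)


@dataclass(frozen=True)
class SelectionCutoffs:
    """Geometric cutoffs of the MD-seed selection rule (Angstrom)."""

    ring_rmsd_max: float = OPTIMAL_RING_RMSD
    nucleophile_max: float = 3.5
    acidbase_max: float = 3.5
    hbond_max: float = 3.4
    min_hbonds: int = 1


@dataclass(frozen=True)
class PoseEvaluation:
    """All four selection criteria evaluated for one pose."""

    pose_rank: int
    dock_score: float
    ring_rmsd: float
    conformer: str
    nucleophile_distance: float
    acidbase_distance: float
    n_hbond_contacts: int | None
    criteria_flags: tuple[bool, bool, bool, bool]
    selected: bool = False

    def __post_init__(self):
        if self.nucleophile_distance < 0 or self.acidbase_distance < 0:
            raise ValueError("distances must be >= 0")

    @property
    def optimal_fit(self) -> bool:
        """Ring RMSD below the optimal-fit bound."""
        return self.ring_rmsd < OPTIMAL_RING_RMSD

    @property
    def passes_geometry(self) -> bool:
        """Criteria (ii)-(iv) all satisfied."""
        return all(self.criteria_flags[1:])


@dataclass(frozen=True)
class SelectionResult:
    """Ranked evaluations plus the selected MD seed, if any."""

    evaluations: tuple[PoseEvaluation, ...]
    selected: PoseEvaluation | None

    @property
    def productive(self) -> bool:
        return self.selected is not None

    @property
    def message(self) -> str:
        if self.productive:
            return (f"pose rank {self.selected.pose_rank} selected "
                    f"(score {self.selected.dock_score:g})")
        return ("no productive pose: no docking pose satisfies the "
                "geometric criteria (dislocated poses)")


def ring_rmsd(pose: DockPose, reference_ring: RingCoordinates) -> float:
    """RMSD over the six -1 ring atoms, pose versus reference complex.

    Poses and reference share the receptor coordinate system, so no
    re-superposition is applied.  Atom correspondence is by name.
    """
    pose_ring = pose.ring(atom_order=reference_ring.atom_labels)
    return rmsd(pose_ring.positions, reference_ring.positions)


def _min_distance(point: np.ndarray, targets: np.ndarray) -> float:
    targets = np.atleast_2d(targets)
    return float(np.min(np.linalg.norm(targets - point, axis=1)))


def _count_hbond_contacts(pose: DockPose, protein_polar_xyz: np.ndarray,
                          cutoff: float) -> int:
    """Donor-acceptor contacts between -1 residue O/N atoms and protein."""
    names, xyz = pose.atoms[pose.minus1_residue]
    polar = np.array([p for n, p in zip(names, xyz) if n[0] in ("O", "N")])
    if polar.size == 0:
        return 0
    d = np.linalg.norm(polar[:, None, :] - protein_polar_xyz[None, :, :],
                       axis=2)
    return int(np.sum(np.min(d, axis=1) <= cutoff))


def evaluate_pose(pose: DockPose,
                  reference_ring: RingCoordinates,
                  nucleophile_oxygens: np.ndarray,
                  acidbase_oxygens: np.ndarray,
                  protein_polar_xyz: np.ndarray | None = None,
                  cutoffs: SelectionCutoffs = SelectionCutoffs(),
                  best_score: float | None = None) -> PoseEvaluation:
    """Evaluate the four MD-seed criteria for a single pose.

    ``nucleophile_oxygens`` / ``acidbase_oxygens`` are the carboxylate
    oxygen coordinates of the two conserved catalytic glutamates; the
    nucleophile distance is measured to the anomeric C1 of the -1 residue
    and the acid/base distance to the glycosidic O1 (minimum over the
    supplied oxygens).  ``best_score`` marks criterion (i) relative to the
    whole docking run; when omitted the pose's own score is assumed best.
    """
    rr = ring_rmsd(pose, reference_ring)
    conformer = classify(cremer_pople(pose.ring())).conformer
    ref_conformer = classify(cremer_pople(reference_ring)).conformer
    c1 = pose.atom_xyz(pose.minus1_residue, "C1")
    d_nuc = _min_distance(c1, nucleophile_oxygens)
    try:
        o_gly = pose.atom_xyz(pose.minus1_residue, "O1")
        d_ab = _min_distance(o_gly, acidbase_oxygens)
    except KeyError:
        d_ab = _min_distance(c1, acidbase_oxygens)
    if protein_polar_xyz is not None:
        n_hb = _count_hbond_contacts(pose, protein_polar_xyz,
                                     cutoffs.hbond_max)
        hbond_ok = n_hb >= cutoffs.min_hbonds
    else:
        n_hb = None
        hbond_ok = True
    flags = (
        best_score is None or pose.dock_score <= best_score,  # (i)
        rr < cutoffs.ring_rmsd_max,                           # (ii)
        conformer == ref_conformer,                           # (iii)
        (d_nuc <= cutoffs.nucleophile_max
         and d_ab <= cutoffs.acidbase_max
         and hbond_ok),                                       # (iv)
    )
    return PoseEvaluation(
        pose_rank=pose.pose_rank,
        dock_score=pose.dock_score,
        ring_rmsd=rr,
        conformer=conformer,
        nucleophile_distance=d_nuc,
        acidbase_distance=d_ab,
        n_hbond_contacts=n_hb,
        criteria_flags=flags,
    )


def select_md_seed(poses: "list[DockPose]",
                   reference_ring: RingCoordinates,
                   nucleophile_oxygens: np.ndarray,
                   acidbase_oxygens: np.ndarray,
                   protein_polar_xyz: np.ndarray | None = None,
                   cutoffs: SelectionCutoffs = SelectionCutoffs(),
                   ) -> SelectionResult:
    """Pick the MD starting pose from a docking run.

    All poses are evaluated against criteria (i)-(iv); the selected pose
    is the one with the best (lowest) docking score among those passing
    the geometric criteria (ii)-(iv), ties broken by pose rank.  The
    result is deterministic and invariant to the input order of poses.
    """
    if not poses:
        raise ValueError("at least one pose required")
    ranks = [p.pose_rank for p in poses]
    if len(set(ranks)) != len(ranks):
        raise ValueError("pose ranks must be unique within a docking run")
    best_score = min(p.dock_score for p in poses)
    evals = [
        evaluate_pose(p, reference_ring, nucleophile_oxygens,
                      acidbase_oxygens, protein_polar_xyz, cutoffs,
                      best_score=best_score)
        for p in poses
    ]
    passing = [e for e in evals if e.passes_geometry]
    selected = None
    if passing:
        winner = min(passing, key=lambda e: (e.dock_score, e.pose_rank))
        selected = PoseEvaluation(**{**winner.__dict__, "selected": True})
    # ranked output: passing poses by score first, then the rest by score
    ordered = sorted(
        (selected if selected is not None and e.pose_rank == selected.pose_rank
         else e for e in evals),
        key=lambda e: (not e.passes_geometry, e.dock_score, e.pose_rank),
    )
    return SelectionResult(evaluations=tuple(ordered), selected=selected)
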