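"""Per-subsite flexibility profiling of enzyme:carbohydrate trajectories.

Every frame is rigid-body superposed onto the protein heavy atoms of the
reference (initial) frame -- the protein is "held" during alignment and
the ligand rides along with the fitted transform.  RMSD series are then
reported for the protein, the complete ligand, and each sugar residue
keyed by its subsite label (-1, +1, +2, ...).  Waters and hydrogens are
excluded upstream; missing atoms are an error, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "ComplexFrame",
    "FlexibilityProfile",
    "superpose",
    "rmsd_series",
    "frames_from_structure",
    "rmsd",
]


@dataclass(frozen=True)
class ComplexFrame:
    """Heavy-atom coordinates of one frame of a protein:ligand complex.

    ``protein_atom_ids`` are ``(chain, res_id, atom_name)`` tuples aligned
    with the rows of ``protein_xyz``; ``ligand`` maps residue identifiers
    (``"chain:res_id"``) to ``(atom_names, xyz)`` pairs.
    """

    protein_xyz: np.ndarray
    protein_atom_ids: tuple[tuple[str, int, str], ...]
    ligand: dict[str, tuple[tuple[str, ...], np.ndarray]]
    frame_index: int = 0

    def __post_init__(self):
        if len(self.protein_atom_ids) != len(self.protein_xyz):
            raise ValueError("one atom id per protein coordinate required")

    def ligand_xyz(self) -> np.ndarray:
        """All ligand heavy-atom coordinates, residues in key order."""
        return np.concatenate([xyz for _, xyz in self.ligand.values()])


@dataclass(frozen=True)
class FlexibilityProfile:
    """Per-frame RMSD series for protein, ligand and each subsite residue."""

    series: dict[str, np.ndarray]
    reference_frame: int = 0

    def __post_init__(self):
        lengths = {len(v) for v in self.series.values()}
        if len(lengths) > 1:
            raise ValueError("all series must have the same length")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.series.values())))

    def mean(self, entity: str) -> float:
        return float(np.mean(self.series[entity]))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain root-mean-square deviation between matched coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _check_matching_atoms(frame: ComplexFrame, reference: ComplexFrame) -> None:
    if frame.protein_atom_ids != reference.protein_atom_ids:
        only_frame = set(frame.protein_atom_ids) - set(reference.protein_atom_ids)
        only_ref = set(reference.protein_atom_ids) - set(frame.protein_atom_ids)
        raise ValueError(
            "protein atom sets differ between frame and reference; "
            f"only in frame: {sorted(only_frame)[:5]}, "
            f"only in reference: {sorted(only_ref)[:5]}"
        )


def superpose(frame: ComplexFrame, reference: ComplexFrame) -> ComplexFrame:
    """Least-squares (Kabsch) superposition onto the reference protein.

    The optimal rotation/translation is fitted on the protein heavy atoms
    only and the same rigid transform is applied to the ligand atoms.
    """
    _check_matching_atoms(frame, reference)
    ref_centroid = reference.protein_xyz.mean(axis=0)
    mov_centroid = frame.protein_xyz.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference.protein_xyz - ref_centroid,
                                    frame.protein_xyz - mov_centroid)

    def transform(xyz: np.ndarray) -> np.ndarray:
        return rot.apply(xyz - mov_centroid) + ref_centroid

    return ComplexFrame(
        protein_xyz=transform(frame.protein_xyz),
        protein_atom_ids=frame.protein_atom_ids,
        ligand={rid: (names, transform(xyz))
                for rid, (names, xyz) in frame.ligand.items()},
        frame_index=frame.frame_index,
    )


def rmsd_series(frames: "list[ComplexFrame]",
                subsite_map: dict[str, str],
                reference: ComplexFrame | None = None) -> FlexibilityProfile:
    """RMSD-versus-reference series for protein, ligand and each subsite.

    Parameters
    ----------
    frames:
        Trajectory frames; the first one is the reference unless an
        explicit ``reference`` is given.
    subsite_map:
        ``residue_id -> subsite label`` for every ligand residue.

    Returns
    -------
    FlexibilityProfile
        One series per entity: ``"protein"``, ``"ligand"`` and one per
        subsite label.  All series are 0 at the reference frame.
    """
    if len(frames) < 2:
        raise ValueError("at least two frames required for an RMSD series")
    if not subsite_map:
        raise ValueError("subsite map must not be empty")
    if reference is None:
        reference = frames[0]
    missing = set(reference.ligand) - set(subsite_map)
    if missing:
        raise ValueError(f"subsite map does not cover ligand residues: "
                         f"{sorted(missing)}")
    if "-1" not in subsite_map.values():
        raise ValueError("subsite map must contain a -1 subsite")

    entities = ["protein", "ligand"] + [subsite_map[r] for r in reference.ligand]
    series: dict[str, list[float]] = {e: [] for e in entities}
    for frame in frames:
        # the reference frame itself needs no fit; keeps its RMSD exactly 0
        fitted = frame if frame is reference else superpose(frame, reference)
        series["protein"].append(rmsd(fitted.protein_xyz, reference.protein_xyz))
        series["ligand"].append(rmsd(fitted.ligand_xyz(), reference.ligand_xyz()))
        for rid, (names, xyz) in fitted.ligand.items():
            ref_names, ref_xyz = reference.ligand[rid]
            if names != ref_names:
                raise ValueError(f"ligand atom names differ for {rid}")
            series[subsite_map[rid]].append(rmsd(xyz, ref_xyz))
    return FlexibilityProfile(
        series={e: np.array(v) for e, v in series.items()},
        reference_frame=reference.frame_index,
    )


def frames_from_structure(stack,
                          ligand_chain: str | None = None,
                          ca_only: bool = False) -> list[ComplexFrame]:
    """Split a biotite ``AtomArrayStack`` into heavy-atom complex frames.

    Ligand atoms are those flagged hetero (or on ``ligand_chain`` if
    given); everything else is protein.  Hydrogens and waters are dropped.
    With ``ca_only`` the protein part is reduced to C-alpha atoms.
    """
    element = np.asarray(stack.element)
    res_name = np.asarray(stack.res_name)
    heavy = (element != "H") & (res_name != "HOH") & (res_name != "WAT")
    if ligand_chain is not None:
        is_ligand = np.asarray(stack.chain_id) == ligand_chain
    else:
        is_ligand = np.asarray(stack.hetero)
    prot_mask = heavy & ~is_ligand
    if ca_only:
        prot_mask &= np.asarray(stack.atom_name) == "CA"
    lig_mask = heavy & is_ligand

    prot_ids = tuple(zip(stack.chain_id[prot_mask].tolist(),
                         stack.res_id[prot_mask].tolist(),
                         stack.atom_name[prot_mask].tolist()))
    lig_keys = [f"{c}:{r}" for c, r in zip(stack.chain_id[lig_mask],
                                           stack.res_id[lig_mask])]
    lig_names = stack.atom_name[lig_mask].tolist()
    # group ligand atom rows by residue, preserving order of appearance
    residue_rows: dict[str, list[int]] = {}
    for i, key in enumerate(lig_keys):
        residue_rows.setdefault(key, []).append(i)

    frames = []
    for f in range(stack.stack_depth()):
        # biotite stores float32; analysis runs in double precision
        coord = np.asarray(stack.coord[f], dtype=np.float64)
        lig_xyz = coord[lig_mask]
        ligand = {
            rid: (tuple(lig_names[i] for i in rows), lig_xyz[rows])
            for rid, rows in residue_rows.items()
        }
        frames.append(ComplexFrame(
            protein_xyz=coord[prot_mask],
            protein_atom_ids=prot_ids,
            ligand=ligand,
            frame_index=f,
        ))
    return frames
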