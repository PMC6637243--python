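"""File interfaces: multi-model PDB, TSV/CSV tables, PHYLIP and Newick.

PDB reading/writing is delegated to biotite (``AtomArrayStack`` with
MODEL/ENDMDL records, occupancy 1.00, B-factor 0.00).  Tabular outputs
follow the conventions of the analysis layer: per-frame pucker TSV,
occupancy tables with an em-dash for never-observed conformers, BED-like
0-based half-open excursion intervals, and a JSON itinerary report.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .conformers import build_conformer_library
from .pucker import RING_ATOM_ORDER, RingCoordinates
from .trajectory import (
    Excursion,
    ItineraryAssignment,
    OccupancyTable,
    RingTrajectory,
)

__all__ = [
    "write_multimodel_pdb",
    "read_multimodel_pdb",
    "trajectory_to_structure",
    "extract_ring_trajectory",
    "read_subsite_map",
    "write_subsite_map",
    "pucker_table",
    "write_pucker_tsv",
    "write_occupancy_tsv",
    "write_excursions_tsv",
    "write_itinerary_json",
    "write_flexibility_csv",
    "write_phylip",
    "write_newick",
]

ABSENT = "—"  # em-dash for conformers never observed


def write_multimodel_pdb(stack, path) -> None:
    """Write a biotite ``AtomArrayStack`` as a multi-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_multimodel_pdb(path):
    """Read a (multi-model) PDB file into a biotite ``AtomArrayStack``."""
    from biotite.structure.io.pdb import PDBFile

    return PDBFile.read(str(path)).get_structure(model=None)


def trajectory_to_structure(traj: RingTrajectory):
    """Pack a bare ring trajectory into an ``AtomArrayStack`` (chain X)."""
    import biotite.structure as struc

    n_frames = len(traj)
    labels = traj.frames[0].atom_labels
    stack = struc.AtomArrayStack(n_frames, len(labels))
    stack.chain_id = np.array(["X"] * len(labels))
    stack.res_id = np.array([1] * len(labels))
    stack.res_name = np.array(["GAL"] * len(labels))
    stack.atom_name = np.array(labels)
    stack.element = np.array([l[0] for l in labels])
    stack.hetero = np.array([True] * len(labels))
    stack.coord = np.stack([f.positions for f in traj.frames])
    return stack


def extract_ring_trajectory(stack,
                            chain_id: str = "X",
                            res_id: int = 1,
                            atom_order: tuple[str, ...] = RING_ATOM_ORDER,
                            time_step_ps: float = 20.0) -> RingTrajectory:
    """Pull one residue's six ring atoms out of every model of a stack.

    Atoms are selected by chain, residue number (1-based, as in PDB) and
    PDB atom names, reordered to ``atom_order``.
    """
    mask = (np.asarray(stack.chain_id) == chain_id) \
        & (np.asarray(stack.res_id) == res_id)
    names = list(np.asarray(stack.atom_name)[mask])
    try:
        order = [names.index(a) for a in atom_order]
    except ValueError as exc:
        raise ValueError(
            f"residue {chain_id}:{res_id} lacks ring atom: {exc}") from exc
    rows = np.flatnonzero(mask)[order]
    frames = tuple(
        RingCoordinates(positions=np.asarray(stack.coord[f][rows],
                                             dtype=np.float64),
                        atom_labels=atom_order,
                        frame_index=f,
                        residue_id=f"{chain_id}:{res_id}")
        for f in range(stack.stack_depth())
    )
    return RingTrajectory(frames=frames, time_step_ps=time_step_ps)


def read_subsite_map(path) -> dict[str, str]:
    """Two-column TSV (residue_id, subsite) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str,
                     names=["residue_id", "subsite"], header=0)
    return dict(zip(df["residue_id"], df["subsite"]))


def write_subsite_map(subsite_map: dict[str, str], path) -> None:
    pd.DataFrame(
        {"residue_id": list(subsite_map), "subsite": list(subsite_map.values())}
    ).to_csv(path, sep="\t", index=False)


def pucker_table(assignments) -> pd.DataFrame:
    """Per-frame (frame, Q, theta, phi, conformer) table."""
    return pd.DataFrame({
        "frame": range(len(assignments)),
        "Q": [a.pucker.Q for a in assignments],
        "theta": [a.pucker.theta for a in assignments],
        "phi": [a.pucker.phi for a in assignments],
        "conformer": [a.conformer for a in assignments],
    })


def write_pucker_tsv(assignments, path) -> None:
    pucker_table(assignments).to_csv(path, sep="\t", index=False,
                                     float_format="%.4f")


def write_occupancy_tsv(tables: dict[str, OccupancyTable], path) -> None:
    """Write occupancy tables as rows, conformers as columns.

    Columns follow canonical library order, restricted to conformers seen
    in at least one table; absent entries are rendered as an em-dash.
    """
    library = build_conformer_library()
    seen = set().union(*(t.percent.keys() for t in tables.values()))
    columns = [l for l in library.labels if l in seen]
    columns += sorted(seen - set(columns))  # e.g. UNDEFINED
    rows = {}
    for name, table in tables.items():
        rows[name] = [f"{table.percent[c]:.1f}" if c in table.percent else ABSENT
                      for c in columns]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.index.name = "run"
    df.to_csv(path, sep="\t")


def write_excursions_tsv(excursion_list: "list[Excursion]", path) -> None:
    """BED-like interval table: 0-based half-open frame coordinates."""
    pd.DataFrame({
        "start": [e.start_frame for e in excursion_list],
        "end": [e.end_frame + 1 for e in excursion_list],
        "reached_equator": [e.reached_equator for e in excursion_list],
        "conformers": [",".join(sorted(e.conformers_visited))
                       for e in excursion_list],
    }).to_csv(path, sep="\t", index=False)


def write_itinerary_json(assignment: ItineraryAssignment, path) -> None:
    Path(path).write_text(json.dumps({
        "itinerary": assignment.itinerary,
        "path": assignment.path,
        "support": assignment.support,
        "alph_compatible": assignment.alph_compatible,
        "co_supported": list(assignment.co_supported),
    }, indent=2))


def write_flexibility_csv(profile, path) -> None:
    """Long-format (frame, entity, rmsd_A) CSV of a flexibility profile."""
    records = [
        {"frame": i, "entity": entity, "rmsd_A": value}
        for entity, series in profile.series.items()
        for i, value in enumerate(series)
    ]
    pd.DataFrame(records).to_csv(path, index=False, float_format="%.6f")


def write_phylip(matrix, path) -> None:
    """Square PHYLIP-format distance matrix."""
    lines = [f"{len(matrix.ids)}"]
    for name, row in zip(matrix.ids, matrix.D):
        lines.append(f"{name:<10s} " + " ".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_newick(tree, path) -> None:
    from .tree import to_newick

    Path(path).write_text(to_newick(tree) + "\n")
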