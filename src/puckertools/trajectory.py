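"""From per-frame ring conformers to occupancy tables and itinerary calls.

Given a trajectory of six-membered-ring coordinates, this module classifies
every frame on the Cremer-Pople sphere, tabulates the percentage of frames
spent in each canonical conformer (an occupancy table), segments the frame
stream into excursions away from the ground-state 4C1 chair, and assigns
a catalytic conformational itinerary.

Itinerary assignment follows the logic used for retaining
beta-galactosidases in clan GH-A: the reaction paths compatible with the
antiperiplanar lone pair hypothesis (ALPH) start from an "equatorial"
skew-boat or boat pre-transition-state anchor and pass through a
half-chair/envelope transition state down to the 4C1 chair:

* GH2-type:      1S3 -> 4H3(ts) -> 4C1
* GH1/GH35-type: 1,4B -> 4H3/4E(ts) -> 4C1
* GH42-type:     1S5 -> 4E/4H5(ts) -> 4C1

A trajectory supports an itinerary when its equatorial anchor conformer is
observed at all; the support value is that anchor's share of the total
equatorial (boat + skew-boat) occupancy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .conformers import (
    EQUATORIAL_LABELS,
    UNDEFINED,
    ConformerAssignment,
    ConformerLibrary,
    build_conformer_library,
    classify,
)
from .pucker import RingCoordinates, cremer_pople

__all__ = [
    "GROUND_STATE",
    "ITINERARY_ANCHORS",
    "ITINERARY_PATHS",
    "RingTrajectory",
    "OccupancyTable",
    "Excursion",
    "ItineraryAssignment",
    "per_frame_conformers",
    "occupancy",
    "excursions",
    "assign_itinerary",
]

#: The relaxed ground-state chair of beta-D-pyranoses.
GROUND_STATE = "4C1"

#: Equatorial pre-transition-state anchor of each family-type itinerary.
ITINERARY_ANCHORS: dict[str, str] = {
    "GH2-type": "1S3",
    "GH1/GH35-type": "1,4B",
    "GH42-type": "1S5",
}

#: Full conformer path of each itinerary (ts = transition state).  The
#: hybrid transition-state labels are display aliases; classification
#: itself always reports the two separate canonical labels.
ITINERARY_PATHS: dict[str, str] = {
    "GH2-type": "1S3 -> 4H3(ts) -> 4C1",
    "GH1/GH35-type": "1,4B -> 4H3/4E(ts) -> 4C1",
    "GH42-type": "1S5 -> 4E/4H5(ts) -> 4C1",
}


@dataclass(frozen=True)
class RingTrajectory:
    """An ordered series of ring-coordinate frames for one residue.

    Defaults mirror the emulated sampling: one recorded frame per 20 ps,
    1000 frames per 20 ns run.
    """

    frames: tuple[RingCoordinates, ...]
    time_step_ps: float = 20.0
    run_length_label: str = ""

    def __post_init__(self):
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")
        residues = {f.residue_id for f in self.frames}
        if len(residues) > 1:
            raise ValueError(
                f"all frames must describe the same residue, got {residues}")
        if not self.run_length_label and self.frames:
            ns = len(self.frames) * self.time_step_ps / 1000.0
            object.__setattr__(self, "run_length_label", f"{ns:g} ns")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class OccupancyTable:
    """Percentage of trajectory frames spent in each observed conformer.

    Only observed conformers appear in ``percent``; absent conformers are
    rendered as an em-dash on tabular output.  Percentages sum to 100.
    """

    percent: dict[str, float]
    n_frames: int

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("occupancy requires at least one frame")
        if any(v < 0 for v in self.percent.values()):
            raise ValueError("percentages must be >= 0")
        total = sum(self.percent.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages must sum to 100, got {total}")

    @property
    def dominant(self) -> str:
        """Label of the most occupied conformer (ties break lexically)."""
        best = max(self.percent.values())
        return min(k for k, v in self.percent.items() if v == best)

    def get(self, label: str) -> float:
        return self.percent.get(label, 0.0)


@dataclass(frozen=True)
class Excursion:
    """A maximal contiguous run of non-ground-state frames."""

    start_frame: int
    end_frame: int  # inclusive
    conformers_visited: frozenset[str]
    reached_equator: bool

    def __post_init__(self):
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must be <= end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class ItineraryAssignment:
    """Result of matching an occupancy table against the ALPH itineraries."""

    itinerary: str  # one of ITINERARY_ANCHORS keys, or "NONE"
    support: dict[str, float]
    alph_compatible: bool
    co_supported: tuple[str, ...] = ()

    @property
    def path(self) -> str:
        return ITINERARY_PATHS.get(self.itinerary, "")


def per_frame_conformers(traj: RingTrajectory,
                         library: ConformerLibrary | None = None,
                         ) -> list[ConformerAssignment]:
    """Classify every frame of a ring trajectory, order preserved.

    Raises a ``ValueError`` naming the frame if Cremer-Pople analysis
    fails on any frame (degenerate geometry).
    """
    if len(traj) == 0:
        raise ValueError("cannot classify an empty trajectory")
    if library is None:
        library = build_conformer_library()
    out = []
    for frame in traj.frames:
        try:
            out.append(classify(cremer_pople(frame), library))
        except ValueError as exc:
            raise ValueError(
                f"ring analysis failed at frame {frame.frame_index}: {exc}"
            ) from exc
    return out


def occupancy(assignments: "list[ConformerAssignment] | list[str]",
              ) -> OccupancyTable:
    """Tabulate conformer occupancy percentages over a frame stream.

    Accepts either :class:`ConformerAssignment` objects or bare labels.
    """
    labels = [a.conformer if isinstance(a, ConformerAssignment) else a
              for a in assignments]
    if not labels:
        raise ValueError("occupancy requires at least one assignment")
    counts = Counter(labels)
    n = len(labels)
    percent = {label: 100.0 * c / n for label, c in counts.items()}
    return OccupancyTable(percent=percent, n_frames=n)


def excursions(assignments: "list[ConformerAssignment] | list[str]",
               equator_labels: frozenset[str] = EQUATORIAL_LABELS,
               ground_label: str = GROUND_STATE) -> list[Excursion]:
    """Segment a conformer stream into maximal non-ground-state runs.

    Any frame not classified as ``ground_label`` (including UNDEFINED
    frames) opens or extends an excursion; ``reached_equator`` is set when
    any visited conformer is a boat or skew-boat.  The frame indices of
    the underlying assignments' rings are positional (0-based within the
    stream).
    """
    labels = [a.conformer if isinstance(a, ConformerAssignment) else a
              for a in assignments]
    out: list[Excursion] = []
    start = None
    visited: set[str] = set()
    for i, label in enumerate(labels + [ground_label]):  # sentinel closes tail
        if label != ground_label:
            if start is None:
                start = i
                visited = set()
            visited.add(label)
        elif start is not None:
            out.append(Excursion(
                start_frame=start,
                end_frame=i - 1,
                conformers_visited=frozenset(visited),
                reached_equator=bool(visited & equator_labels),
            ))
            start = None
    return out


def assign_itinerary(table: OccupancyTable) -> ItineraryAssignment:
    """Assign the family-type ALPH itinerary supported by an occupancy table.

    Support for an itinerary is its equatorial anchor's share of the total
    equatorial (boat + skew-boat) occupancy; an itinerary counts as
    supported when its anchor occupancy is nonzero.  The reported
    itinerary is the argmax of support (all supported ones are listed in
    ``co_supported``); ``"NONE"`` with ``alph_compatible = False`` when no
    anchor conformer was observed at all.  Pure function of the table.
    """
    equatorial_total = sum(v for k, v in table.percent.items()
                           if k in EQUATORIAL_LABELS)
    support: dict[str, float] = {}
    for name, anchor in ITINERARY_ANCHORS.items():
        occ = table.get(anchor)
        support[name] = occ / equatorial_total if equatorial_total > 0 else 0.0
    supported = tuple(sorted((n for n, s in support.items() if s > 0),
                             key=lambda n: (-support[n], n)))
    if not supported:
        return ItineraryAssignment(itinerary="NONE", support=support,
                                   alph_compatible=False)
    return ItineraryAssignment(itinerary=supported[0], support=support,
                               alph_compatible=True, co_supported=supported)
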