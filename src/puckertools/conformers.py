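"""The 38 canonical six-membered-ring conformers and nearest-reference
classification on the Cremer-Pople sphere.

Canonical conformer labels follow IUPAC usage: superscript ring atoms lie
above the reference plane (written before the family letter) and subscript
atoms below (written after), e.g. ``4C1`` (C4 up, C1 down), ``1S3``
(C1 up, C3 down), ``1,4B`` (C1 and C4 up), ``B2,5`` (C2 and C5 down).
Labels here are plain ASCII: ``"4C1"``, ``"1S3"``, ``"1,4B"``, ``"B2,5"``,
``"OH5"`` and so on, with ``O`` denoting the ring oxygen O5.

Reference (theta, phi) positions are not hardcoded: each conformer's
idealized out-of-plane displacement pattern (+1 for superscript atoms,
-1 for subscript atoms, 0 otherwise) is pushed through the Cremer-Pople
Fourier projection, which reproduces the standard Mercator layout for the
O5, C1..C5 atom ordering -- 4C1 at the north pole, the 6 boats and 6
skew-boats alternating every 30 degrees around the equator, and the 12
half-chairs / 12 envelopes alternating every 30 degrees on the two tropics.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .pucker import PuckerCoords, Q_PLANAR, _pucker_from_displacements

__all__ = [
    "UNDEFINED",
    "CONFORMER_LABELS",
    "EQUATORIAL_LABELS",
    "CanonicalConformer",
    "ConformerLibrary",
    "ConformerAssignment",
    "build_conformer_library",
    "classify",
    "angular_distance",
]

#: Label returned for rings too flat to classify.
UNDEFINED = "UNDEFINED"

# All 38 canonical conformers: 2 chairs, 6 boats, 6 skew-boats,
# 12 envelopes, 12 half-chairs.
CONFORMER_LABELS: tuple[str, ...] = (
    # chairs (poles)
    "4C1", "1C4",
    # boats (equator, even 60-degree meridians alternating with skews)
    "3,OB", "B1,4", "2,5B", "B3,O", "1,4B", "B2,5",
    # skew-boats (equator)
    "3S1", "5S1", "2SO", "1S3", "1S5", "OS2",
    # envelopes, northern tropic
    "OE", "E1", "2E", "E3", "4E", "E5",
    # half-chairs, northern tropic
    "OH1", "2H1", "2H3", "4H3", "4H5", "OH5",
    # envelopes, southern tropic
    "3E", "E4", "5E", "EO", "1E", "E2",
    # half-chairs, southern tropic
    "3H4", "5H4", "5HO", "1HO", "1H2", "3H2",
)

_FAMILY_NAMES = {
    "C": "chair",
    "B": "boat",
    "S": "skew-boat",
    "H": "half-chair",
    "E": "envelope",
}

# Ring position of each atom token in the O5, C1..C5 ordering.
_ATOM_INDEX = {"O": 0, "1": 1, "2": 2, "3": 3, "4": 4, "5": 5}

_LABEL_RE = re.compile(r"^([O12345](?:,[O12345])?)?([CBSHE])([O12345](?:,[O12345])?)?$")


@dataclass(frozen=True)
class CanonicalConformer:
    """One idealized canonical conformer and its CP-sphere reference point."""

    label: str
    family: str
    theta_ref: float
    phi_ref: float
    band: str
    up_atoms: tuple[str, ...]
    down_atoms: tuple[str, ...]


@dataclass(frozen=True)
class ConformerAssignment:
    """Nearest-conformer classification of one pucker observation."""

    conformer: str
    angular_distance: float
    pucker: PuckerCoords


class ConformerLibrary:
    """Immutable collection of the 38 canonical conformers."""

    def __init__(self, conformers: "tuple[CanonicalConformer, ...]"):
        if not conformers:
            raise ValueError("conformer library must not be empty")
        self._conformers = tuple(conformers)
        self._by_label = {c.label: c for c in conformers}
        if len(self._by_label) != len(conformers):
            raise ValueError("conformer labels must be unique")
        # unit reference vectors for vectorized nearest-neighbour search
        theta = np.radians([c.theta_ref for c in conformers])
        phi = np.radians([c.phi_ref for c in conformers])
        self._ref_vectors = np.column_stack([
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        ])

    def __len__(self) -> int:
        return len(self._conformers)

    def __iter__(self):
        return iter(self._conformers)

    def __getitem__(self, label: str) -> CanonicalConformer:
        return self._by_label[label]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self._conformers)

    @property
    def reference_vectors(self) -> np.ndarray:
        return self._ref_vectors.copy()


def parse_conformer_label(label: str) -> tuple[str, tuple[str, ...], tuple[str, ...]]:
    """Split a conformer label into (family letter, up atoms, down atoms)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"unparseable conformer label: {label!r}")
    up = tuple(m.group(1).split(",")) if m.group(1) else ()
    down = tuple(m.group(3).split(",")) if m.group(3) else ()
    return m.group(2), up, down


def _ideal_pucker(up: tuple[str, ...], down: tuple[str, ...]) -> PuckerCoords:
    """CP coordinates of the idealized +/-1 displacement pattern of a label."""
    z = np.zeros(6)
    for a in up:
        z[_ATOM_INDEX[a]] = 1.0
    for a in down:
        z[_ATOM_INDEX[a]] = -1.0
    return _pucker_from_displacements(z)


def _band(theta: float) -> str:
    if theta < 10.0 or theta > 170.0:
        return "pole"
    if theta < 90.0:
        return "tropic-N"
    if theta > 90.0:
        return "tropic-S"
    return "equator"


@lru_cache(maxsize=1)
def build_conformer_library() -> ConformerLibrary:
    """Construct the canonical 38-conformer library.

    Reference latitudes come out of the projection itself: chairs at
    theta = 0/180, boats and skew-boats at 90, envelopes at
    ~54.74 degrees off the poles and half-chairs at ~50.77.
    """
    conformers = []
    for label in CONFORMER_LABELS:
        family, up, down = parse_conformer_label(label)
        p = _ideal_pucker(up, down)
        theta = 0.0 if math.isnan(p.theta) else p.theta
        if p.Q < 1e-9:
            raise ValueError(f"conformer {label} projects to a planar ring")
        # chairs have q2 == 0; pin them exactly to the poles
        if family == "C":
            theta = 0.0 if p.q3 > 0 else 180.0
        conformers.append(CanonicalConformer(
            label=label,
            family=_FAMILY_NAMES[family],
            theta_ref=theta,
            phi_ref=p.phi,
            band=_band(theta),
            up_atoms=up,
            down_atoms=down,
        ))
    return ConformerLibrary(tuple(conformers))


#: The 12 equatorial (boat + skew-boat) conformer labels.
EQUATORIAL_LABELS: frozenset[str] = frozenset(
    l for l in CONFORMER_LABELS
    if parse_conformer_label(l)[0] in ("B", "S")
)


def _unit_vector(theta_deg: float, phi_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    f = math.radians(phi_deg)
    return np.array([math.sin(t) * math.cos(f),
                     math.sin(t) * math.sin(f),
                     math.cos(t)])


def angular_distance(theta1: float, phi1: float,
                     theta2: float, phi2: float) -> float:
    """Great-circle distance (degrees) between two points on the CP sphere.

    Computed as atan2(|v1 x v2|, v1 . v2), which stays accurate near 0
    and 180 degrees where the arccosine form loses precision.
    """
    v1 = _unit_vector(theta1, phi1)
    v2 = _unit_vector(theta2, phi2)
    return math.degrees(math.atan2(np.linalg.norm(np.cross(v1, v2)),
                                   float(v1 @ v2)))


def classify(pucker: PuckerCoords,
             library: ConformerLibrary | None = None,
             q_min: float = Q_PLANAR) -> ConformerAssignment:
    """Assign the nearest canonical conformer to a pucker observation.

    Classification is by unweighted great-circle distance on the unit
    puckering sphere; ties (a measure-zero event on real data) break to
    the lexicographically smallest label.  Rings with ``Q < q_min`` are
    reported as :data:`UNDEFINED`.
    """
    if library is None:
        library = build_conformer_library()
    if len(library) == 0:
        raise ValueError("empty conformer library")
    if pucker.Q < q_min or math.isnan(pucker.theta):
        return ConformerAssignment(conformer=UNDEFINED,
                                   angular_distance=math.nan,
                                   pucker=pucker)
    v = _unit_vector(pucker.theta, pucker.phi)
    refs = library.reference_vectors
    cross = np.cross(refs, v)
    dists = np.degrees(np.arctan2(np.linalg.norm(cross, axis=1), refs @ v))
    best = np.min(dists)
    # lexicographic tie-break at exact numerical ties
    candidates = [library.labels[i] for i in np.flatnonzero(dists == best)]
    return ConformerAssignment(conformer=min(candidates),
                               angular_distance=float(best),
                               pucker=pucker)
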