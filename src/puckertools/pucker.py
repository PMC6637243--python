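"""Cremer-Pople puckering coordinates for six-membered (pyranose) rings.

The Cremer-Pople construction describes the out-of-plane geometry of an
N-membered ring by projecting the atom positions onto a unique mean plane
(the plane through the geometric centre whose first trigonometric moments
of the perpendicular displacements vanish) and Fourier-decomposing the
displacements ``z_j``.  For N = 6 this yields three numbers:

* ``q2``/``phi2`` - amplitude and phase of the m = 2 (boat/twist-boat)
  component,
* ``q3`` - the alternating (chair) component,

which are combined into spherical coordinates: total amplitude
``Q = sqrt(q2**2 + q3**2)``, polar angle ``theta = atan2(q2, q3)`` and
meridian angle ``phi = phi2``.  Chairs sit at the poles, boats and
skew-boats on the equator, envelopes and half-chairs on the tropics.

Ring atoms are ordered O5, C1, C2, C3, C4, C5 throughout, the standard
convention for D-pyranoses, which places the 4C1 chair at theta = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RING_ATOM_ORDER",
    "Q_PLANAR",
    "RingGeometryError",
    "RingCoordinates",
    "PuckerCoords",
    "cremer_pople",
    "mercator",
]

#: Canonical pyranose ring atom order (places 4C1 at the north pole).
RING_ATOM_ORDER = ("O5", "C1", "C2", "C3", "C4", "C5")

#: Puckering amplitude (Angstrom) below which the ring is treated as planar
#: and the polar/meridian angles carry no conformational meaning.
Q_PLANAR = 0.1

# Bond-length window (Angstrom) accepted between consecutive ring atoms.
_MIN_BOND = 0.5
_MAX_BOND = 3.0


class RingGeometryError(ValueError):
    """Raised for degenerate or chemically impossible ring geometry."""


@dataclass(frozen=True)
class RingCoordinates:
    """Ordered coordinates of the six ring atoms for a single frame.

    Parameters
    ----------
    positions:
        ``(6, 3)`` array of Cartesian coordinates in Angstrom, in ring
        order (O5, C1, ..., C5 by convention).
    atom_labels:
        The six atom names, in the same order as ``positions``.
    frame_index:
        Zero-based index of the trajectory frame this ring was taken from.
    residue_id:
        Chain/residue identifier, e.g. ``"X:1"``.
    """

    positions: np.ndarray
    atom_labels: tuple[str, ...] = RING_ATOM_ORDER
    frame_index: int = 0
    residue_id: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (6, 3):
            raise RingGeometryError(
                f"ring requires exactly 6 atoms with 3-D coordinates, "
                f"got array of shape {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            raise RingGeometryError("ring coordinates must be finite")
        if len(self.atom_labels) != 6:
            raise RingGeometryError("exactly 6 atom labels required")
        if self.frame_index < 0:
            raise RingGeometryError("frame_index must be >= 0")
        bonds = np.linalg.norm(pos - np.roll(pos, -1, axis=0), axis=1)
        if np.any(bonds <= _MIN_BOND) or np.any(bonds >= _MAX_BOND):
            raise RingGeometryError(
                f"consecutive ring-atom distances outside "
                f"({_MIN_BOND}, {_MAX_BOND}) Angstrom: {np.round(bonds, 3)}"
            )
        object.__setattr__(self, "positions", pos)


@dataclass(frozen=True)
class PuckerCoords:
    """Cremer-Pople puckering coordinates of one six-membered ring.

    ``theta`` is ``nan`` (undefined) for numerically planar rings; the
    :attr:`is_planar` flag additionally marks rings whose amplitude falls
    below the classification threshold ``Q_PLANAR``.
    """

    Q: float
    theta: float
    phi: float
    q2: float
    q3: float
    phi2: float
    planarity_threshold: float = field(default=Q_PLANAR, repr=False)

    @property
    def is_planar(self) -> bool:
        """True when Q is below the planarity threshold (theta undefined)."""
        return self.Q < self.planarity_threshold

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.Q, self.theta, self.phi)


# Precomputed Fourier basis for N = 6, m = 2 and the alternating component.
_J = np.arange(6)
_COS2 = np.cos(4.0 * np.pi * _J / 6.0)
_SIN2 = np.sin(4.0 * np.pi * _J / 6.0)
_SIGN = (-1.0) ** _J
_COS1 = np.cos(2.0 * np.pi * _J / 6.0)
_SIN1 = np.sin(2.0 * np.pi * _J / 6.0)


def _pucker_from_displacements(z: np.ndarray,
                               planarity_threshold: float = Q_PLANAR) -> PuckerCoords:
    """Fourier-decompose mean-plane displacements into CP coordinates."""
    qc = math.sqrt(1.0 / 3.0) * float(z @ _COS2)
    qs = -math.sqrt(1.0 / 3.0) * float(z @ _SIN2)
    q2 = math.hypot(qc, qs)
    q3 = math.sqrt(1.0 / 6.0) * float(z @ _SIGN)
    Q = math.hypot(q2, q3)
    if Q > 1e-12:
        theta = math.degrees(math.atan2(q2, q3))
    else:
        theta = math.nan
    if q2 > 1e-12:
        phi = math.degrees(math.atan2(qs, qc)) % 360.0
    else:
        phi = 0.0
    return PuckerCoords(Q=Q, theta=theta, phi=phi, q2=q2, q3=q3, phi2=phi,
                        planarity_threshold=planarity_threshold)


def ring_displacements(ring: RingCoordinates) -> np.ndarray:
    """Perpendicular displacements of the six atoms from the CP mean plane.

    The mean plane passes through the geometric centre with its normal
    orthogonal to both first-moment vectors R' and R'', so that
    ``sum(z_j) = sum(z_j sin(2 pi j / 6)) = sum(z_j cos(2 pi j / 6)) = 0``.
    """
    xyz = ring.positions - ring.positions.mean(axis=0)
    r_prime = _SIN1 @ xyz
    r_dprime = _COS1 @ xyz
    normal = np.cross(r_prime, r_dprime)
    norm = np.linalg.norm(normal)
    if norm < 1e-10:
        raise RingGeometryError(
            "degenerate ring geometry (collinear or coincident atoms): "
            "mean plane is undefined"
        )
    return xyz @ (normal / norm)


def cremer_pople(ring: RingCoordinates,
                 planarity_threshold: float = Q_PLANAR) -> PuckerCoords:
    """Compute Cremer-Pople puckering coordinates of a six-membered ring.

    The result is invariant under rigid-body rotation and translation of
    the input coordinates.

    Parameters
    ----------
    ring:
        Validated ring coordinates in the O5, C1..C5 atom order.
    planarity_threshold:
        Amplitude (Angstrom) below which the ring counts as planar.

    Returns
    -------
    PuckerCoords
        With ``Q**2 == q2**2 + q3**2`` and angles in degrees
        (theta in [0, 180], phi wrapped to [0, 360)).
    """
    z = ring_displacements(ring)
    return _pucker_from_displacements(z, planarity_threshold)


def mercator(pucker_series: "list[PuckerCoords]") -> list[tuple[float, float]]:
    """Project a pucker series onto the (phi, theta) Mercator-style map.

    Returns one ``(phi, theta)`` pair per input point, order preserved.
    This is the planar map conventionally used to trace puckering
    trajectories on the CP sphere (chairs at top/bottom edges, equatorial
    boat/skew-boat belt across the middle).
    """
    return [(p.phi, p.theta) for p in pucker_series]
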