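"""Synthetic ring trajectories and mock enzyme:ligand complexes.

This module generates every input the analysis layer consumes, without
external data: idealized six-membered rings at arbitrary Cremer-Pople
coordinates (:func:`inverse_cp`), stochastic puckering trajectories that
dwell at programmed conformer waypoints (:func:`simulate_pucker_path`),
and multi-model mock complexes with a rigid protein scaffold plus a
two-or-more-residue ligand whose subsite -1 ring follows such a path
(:func:`build_mock_complex`).

It is a geometry simulator, not an MD engine: there are no energies,
solvent or thermostats.  Defaults mirror the sampling regime of the
trajectories it emulates -- 1000 recorded frames per run at a 20 ps
stride (a 20 ns-equivalent run).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pucker import RING_ATOM_ORDER, PuckerCoords, RingCoordinates
from .conformers import ConformerLibrary, build_conformer_library

__all__ = [
    "PuckerPathSpec",
    "MockComplexSpec",
    "SimulatedPath",
    "MockComplex",
    "inverse_cp",
    "simulate_pucker_path",
    "build_mock_complex",
    "random_ca_structure",
]

# in-plane hexagon angles; clockwise placement so that the CP mean-plane
# normal computed from the first-moment vectors points along +z
_ALPHA = -2.0 * np.pi * np.arange(6) / 6.0
_COS2 = np.cos(4.0 * np.pi * np.arange(6) / 6.0)
_SIN2 = np.sin(4.0 * np.pi * np.arange(6) / 6.0)
_SIGN = (-1.0) ** np.arange(6)


def inverse_cp(Q: float, theta: float, phi: float,
               bond_length: float = 1.54) -> RingCoordinates:
    """Build idealized six-ring coordinates with given CP coordinates.

    The six atoms are placed on a regular hexagon of side ``bond_length``
    and displaced perpendicular to it by

    ``z_j = sqrt(1/3) * q2 * cos(phi + 4 pi j / 6) + sqrt(1/6) * q3 * (-1)**j``

    with ``q2 = Q sin(theta)``, ``q3 = Q cos(theta)``.  Because the m = 2
    and m = 3 Fourier components are orthogonal to the mean-plane
    constraints, :func:`puckertools.pucker.cremer_pople` recovers
    ``(Q, theta, phi)`` from the result exactly (to rounding).

    Parameters
    ----------
    Q, theta, phi:
        Target puckering amplitude (Angstrom) and angles (degrees).
    bond_length:
        Hexagon side in Angstrom (default 1.54, a C-C bond).
    """
    if Q < 0:
        raise ValueError("puckering amplitude Q must be >= 0")
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    if Q > 1.5:
        raise ValueError(
            f"Q = {Q} Angstrom would degenerate the ring bond geometry"
        )
    q2 = Q * math.sin(math.radians(theta))
    q3 = Q * math.cos(math.radians(theta))
    phi_r = math.radians(phi)
    z = (math.sqrt(1.0 / 3.0) * q2 * np.cos(phi_r + 4.0 * np.pi * np.arange(6) / 6.0)
         + math.sqrt(1.0 / 6.0) * q3 * _SIGN)
    # shrink the hexagon so that bond lengths stay near the target despite
    # the out-of-plane displacements; the midrange of the squared z-offsets
    # minimizes the worst-case bond deviation
    dz2 = (z - np.roll(z, -1)) ** 2
    side2 = bond_length**2 - 0.5 * (float(dz2.max()) + float(dz2.min()))
    if side2 <= (0.3 * bond_length) ** 2:
        raise ValueError(
            f"Q = {Q} Angstrom would degenerate the ring bond geometry")
    side = math.sqrt(side2)
    xy = side * np.column_stack([np.cos(_ALPHA), np.sin(_ALPHA)])
    return RingCoordinates(
        positions=np.column_stack([xy, z]),
        atom_labels=RING_ATOM_ORDER,
    )


@dataclass(frozen=True)
class PuckerPathSpec:
    """Programme for a stochastic trajectory on the puckering sphere.

    Waypoints are canonical conformer labels or explicit ``(Q, theta, phi)``
    triples; ``dwell_fractions`` give the share of frames spent at each
    waypoint (must sum to 1).  Consecutive waypoint blocks may be bridged
    by ``transition_frames`` great-circle (slerp) interpolation frames,
    taken from the tail of the leading block so the total frame count is
    preserved.  Gaussian noise is applied on the sphere's tangent plane
    (``angular_noise_sigma``, degrees) and on the amplitude
    (``q_noise_sigma``, Angstrom).
    """

    waypoints: tuple
    dwell_fractions: tuple[float, ...]
    n_frames: int = 1000
    angular_noise_sigma: float = 3.0
    q_noise_sigma: float = 0.02
    q_amplitude: float = 0.57
    transition_frames: int = 0
    seed: int = 0
    bond_length: float = 1.54
    time_step_ps: float = 20.0

    def __post_init__(self):
        if len(self.waypoints) != len(self.dwell_fractions):
            raise ValueError("one dwell fraction per waypoint required")
        if len(self.waypoints) == 0:
            raise ValueError("at least one waypoint required")
        if any(f < 0 for f in self.dwell_fractions):
            raise ValueError("dwell fractions must be >= 0")
        if abs(sum(self.dwell_fractions) - 1.0) > 1e-9:
            raise ValueError("dwell fractions must sum to 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass(frozen=True)
class SimulatedPath:
    """A simulated ring trajectory plus its generating ground truth."""

    trajectory: "RingTrajectory"
    intended_conformers: tuple[str, ...]
    puckers: tuple[PuckerCoords, ...]


def _waypoint_coords(waypoint, q_amplitude: float,
                     library: ConformerLibrary) -> tuple[float, float, float, str]:
    """Resolve a waypoint into (Q, theta, phi, intended label)."""
    if isinstance(waypoint, str):
        c = library[waypoint]
        return q_amplitude, c.theta_ref, c.phi_ref, waypoint
    Q, theta, phi = waypoint
    return float(Q), float(theta), float(phi), ""


def _unit(theta: float, phi: float) -> np.ndarray:
    t, f = math.radians(theta), math.radians(phi)
    return np.array([math.sin(t) * math.cos(f),
                     math.sin(t) * math.sin(f),
                     math.cos(t)])


def _angles(v: np.ndarray) -> tuple[float, float]:
    theta = math.degrees(math.acos(max(-1.0, min(1.0, v[2]))))
    phi = math.degrees(math.atan2(v[1], v[0])) % 360.0
    return theta, phi


def _slerp(v0: np.ndarray, v1: np.ndarray, t: float) -> np.ndarray:
    dot = max(-1.0, min(1.0, float(v0 @ v1)))
    omega = math.acos(dot)
    if omega < 1e-12:
        return v0
    return (math.sin((1 - t) * omega) * v0 + math.sin(t * omega) * v1) / math.sin(omega)


def _tangent_displace(v: np.ndarray, rng: np.random.Generator,
                      sigma_deg: float) -> np.ndarray:
    """Move a unit vector along a geodesic by a 2-D Gaussian tangent step.

    Handles the poles without special-casing: the step direction is drawn
    in the local tangent plane, so no reflection at theta = 0/180 is needed.
    """
    if sigma_deg <= 0:
        return v
    # orthonormal tangent basis
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(v, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    dx, dy = rng.normal(0.0, math.radians(sigma_deg), size=2)
    r = math.hypot(dx, dy)
    if r < 1e-15:
        return v
    direction = (dx * e1 + dy * e2) / r
    return math.cos(r) * v + math.sin(r) * direction


def simulate_pucker_path(spec: PuckerPathSpec) -> SimulatedPath:
    """Generate a ring trajectory dwelling at programmed pucker waypoints.

    Frames are allocated to waypoints in proportion to the dwell
    fractions (largest-remainder rounding so the total is exact); within a
    block the ring sits at the waypoint, perturbed by tangent-plane angular
    noise and amplitude noise.  Reproducible for a fixed seed.
    """
    from .trajectory import RingTrajectory  # local import to avoid a cycle

    library = build_conformer_library()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames

    # largest-remainder apportionment of frames to waypoints
    raw = np.array(spec.dwell_fractions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1

    targets = [_waypoint_coords(w, spec.q_amplitude, library)
               for w in spec.waypoints]

    # per-frame target (Q, unit vector, intended label)
    frame_targets: list[tuple[float, np.ndarray, str]] = []
    for i, ((Q, theta, phi, label), c) in enumerate(zip(targets, counts)):
        v = _unit(theta, phi)
        block = [(Q, v, label)] * c
        if spec.transition_frames > 0 and i + 1 < len(targets) and c > 0:
            # replace the block tail with a slerp ramp toward the next waypoint
            Qn, tn, fn, _ = targets[i + 1]
            vn = _unit(tn, fn)
            k = min(spec.transition_frames, c)
            for j in range(k):
                t = (j + 1) / (k + 1)
                block[c - k + j] = (Q + t * (Qn - Q), _slerp(v, vn, t), label)
        frame_targets.extend(block)

    frames = []
    intended = []
    puckers = []
    for idx, (Q, v, label) in enumerate(frame_targets):
        v_noisy = _tangent_displace(v, rng, spec.angular_noise_sigma)
        Q_noisy = max(1e-6, Q + rng.normal(0.0, spec.q_noise_sigma)) \
            if spec.q_noise_sigma > 0 else Q
        theta, phi = _angles(v_noisy)
        ring = inverse_cp(Q_noisy, theta, phi, bond_length=spec.bond_length)
        frames.append(RingCoordinates(positions=ring.positions,
                                      atom_labels=ring.atom_labels,
                                      frame_index=idx,
                                      residue_id="X:1"))
        intended.append(label)
        puckers.append(PuckerCoords(Q=Q_noisy, theta=theta, phi=phi,
                                    q2=Q_noisy * math.sin(math.radians(theta)),
                                    q3=Q_noisy * math.cos(math.radians(theta)),
                                    phi2=phi))

    traj = RingTrajectory(frames=tuple(frames),
                          time_step_ps=spec.time_step_ps)
    return SimulatedPath(trajectory=traj,
                         intended_conformers=tuple(intended),
                         puckers=tuple(puckers))


@dataclass(frozen=True)
class MockComplexSpec:
    """Recipe for a mock rigid protein + oligosaccharide ligand complex.

    ``ligand_subsites`` is an ordered tuple of ``(subsite_label, rigid)``
    pairs; exactly one subsite must be ``"-1"``.  The -1 residue's ring
    follows ``pucker_spec``; rigid residues are identical in every frame,
    non-rigid ones (other than -1) receive isotropic Gaussian jitter of
    ``jitter_sigma`` Angstrom.
    """

    n_protein_residues: int = 20
    ligand_subsites: tuple[tuple[str, bool], ...] = (("-1", False), ("+1", True))
    pucker_spec: PuckerPathSpec = field(
        default_factory=lambda: PuckerPathSpec(
            waypoints=("4C1",), dwell_fractions=(1.0,)))
    jitter_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        labels = [s for s, _ in self.ligand_subsites]
        if labels.count("-1") != 1:
            raise ValueError("exactly one -1 subsite required")
        if len(set(labels)) != len(labels):
            raise ValueError("subsite labels must be unique")
        if self.n_protein_residues < 1:
            raise ValueError("at least one protein residue required")


@dataclass(frozen=True)
class MockComplex:
    """A generated multi-model complex plus its ground truth."""

    structure: "object"  # biotite AtomArrayStack
    subsite_map: dict[str, str]  # residue_id ("chain:resid") -> subsite label
    intended_conformers: tuple[str, ...]
    ring_residue_id: str


def _helix_backbone(n_residues: int) -> tuple[np.ndarray, list[str], list[int]]:
    """Idealized poly-ALA alpha-helix backbone (N, CA, C, O per residue)."""
    coords = []
    names = []
    res_ids = []
    radius, rise, twist = 2.3, 1.5, math.radians(100.0)
    offsets = {"N": (-0.3, -0.4), "CA": (0.0, 0.0), "C": (0.35, 0.45),
               "O": (0.5, 1.3)}
    for i in range(n_residues):
        base = twist * i
        for name, (dang, dz) in offsets.items():
            a = base + dang
            coords.append([radius * math.cos(a), radius * math.sin(a),
                           rise * i + dz])
            names.append(name)
            res_ids.append(i + 1)
    return np.array(coords), names, res_ids


def _ideal_ring_with_stub(Q: float = 0.57, theta: float = 0.0,
                          phi: float = 0.0) -> tuple[np.ndarray, list[str]]:
    """A 4C1-style ring plus an O1 glycosidic stub off C1."""
    ring = inverse_cp(Q, theta, phi).positions
    centroid = ring.mean(axis=0)
    c1 = ring[1]
    direction = c1 - centroid
    direction /= np.linalg.norm(direction)
    o1 = c1 + 1.4 * direction
    return np.vstack([ring, o1]), list(RING_ATOM_ORDER) + ["O1"]


def build_mock_complex(spec: MockComplexSpec) -> MockComplex:
    """Assemble a multi-model mock complex as a biotite ``AtomArrayStack``.

    The protein scaffold (chain A, poly-ALA backbone heavy atoms) is rigid
    across frames.  Ligand residues (chain X, hetero) are pyranose rings
    with an O1 stub, placed 5 Angstrom apart; the -1 ring follows the
    pucker path of the spec.  Hydrogens are never generated.  Output is
    byte-deterministic for a fixed spec.
    """
    import biotite.structure as struc

    path = simulate_pucker_path(spec.pucker_spec)
    n_frames = spec.pucker_spec.n_frames
    rng = np.random.default_rng(spec.seed + 1)

    prot_xyz, prot_names, prot_res = _helix_backbone(spec.n_protein_residues)

    # static ligand templates and site origins
    ring_template, ring_names = _ideal_ring_with_stub()
    site_origin = {}
    ligand_origin = np.array([8.0, 0.0, 4.0])
    for k, (label, _) in enumerate(spec.ligand_subsites):
        site_origin[label] = ligand_origin + np.array([5.0 * k, 0.0, 0.0])

    n_lig_atoms = len(ring_names) * len(spec.ligand_subsites)
    n_atoms = len(prot_xyz) + n_lig_atoms

    stack = struc.AtomArrayStack(n_frames, n_atoms)
    chain_id = ["A"] * len(prot_xyz)
    res_id = list(prot_res)
    res_name = ["ALA"] * len(prot_xyz)
    atom_name = list(prot_names)
    hetero = [False] * len(prot_xyz)

    subsite_map: dict[str, str] = {}
    ring_residue_id = ""
    for k, (label, _) in enumerate(spec.ligand_subsites):
        chain_id += ["X"] * len(ring_names)
        res_id += [k + 1] * len(ring_names)
        res_name += ["GAL" if label == "-1" else "GLC"] * len(ring_names)
        atom_name += ring_names
        hetero += [True] * len(ring_names)
        rid = f"X:{k + 1}"
        subsite_map[rid] = label
        if label == "-1":
            ring_residue_id = rid

    stack.chain_id = np.array(chain_id)
    stack.res_id = np.array(res_id)
    stack.res_name = np.array(res_name)
    stack.atom_name = np.array(atom_name)
    stack.hetero = np.array(hetero)
    stack.element = np.array([n[0] for n in atom_name])

    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, :len(prot_xyz), :] = prot_xyz  # rigid protein

    offset = len(prot_xyz)
    for k, (label, rigid) in enumerate(spec.ligand_subsites):
        block = slice(offset + k * len(ring_names),
                      offset + (k + 1) * len(ring_names))
        if label == "-1":
            for f in range(n_frames):
                ring = path.trajectory.frames[f].positions
                centered = ring - ring.mean(axis=0)
                c1 = centered[1]
                direction = c1 / np.linalg.norm(c1)
                o1 = c1 + 1.4 * direction
                coords[f, block, :] = np.vstack([centered, o1]) + site_origin[label]
        else:
            base = ring_template - ring_template[:6].mean(axis=0) + site_origin[label]
            coords[:, block, :] = base
            if not rigid and spec.jitter_sigma > 0:
                coords[:, block, :] += rng.normal(
                    0.0, spec.jitter_sigma,
                    size=(n_frames, len(ring_names), 3))
    stack.coord = coords

    return MockComplex(structure=stack,
                       subsite_map=subsite_map,
                       intended_conformers=path.intended_conformers,
                       ring_residue_id=ring_residue_id)


def random_ca_structure(n_residues: int, seed: int = 0,
                        step: float = 3.8) -> np.ndarray:
    """Self-avoiding-ish random walk of C-alpha positions, ``(n, 3)``.

    A generic synthetic protein backbone trace for structure-comparison
    toys; consecutive C-alpha atoms are ``step`` Angstrom apart.
    """
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_residues, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n_residues):
        proposal = direction + 0.8 * rng.normal(size=3)
        proposal /= np.linalg.norm(proposal)
        coords[i] = coords[i - 1] + step * proposal
        direction = proposal
    return coords
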