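"""Structure distance trees from symmetrized MaxSub similarity.

MaxSub measures the structural similarity of two protein structures as the
largest subset of corresponding residues that superimposes within a
distance threshold ``d`` (default 3.5 Angstrom), scored as

    S = sum_{i in M} 1 / (1 + (d_i / d)**2) / N

over the matched set M after the final superposition, normalized by the
number of residues N of the *first* structure -- which makes the score
asymmetric between the two comparison directions.  The score lies in
[0, 1], with 1 attained at structural identity.

For tree building, the two reciprocal scores of each pair are averaged
(MaxSubAverage) and converted to a distance ``1 - MaxSubAverage``; the
resulting symmetric matrix feeds standard neighbor-joining (Saitou-Nei),
which is exact on additive matrices.

Residue correspondence between two structures is an explicit input
(identity by index for equal-length structures); the sequence-independent
alignment search that would produce it for real, unequal structures is
out of scope here.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

__all__ = [
    "DEFAULT_D_THRESHOLD",
    "StructurePair",
    "StructureDistanceMatrix",
    "maxsub_score",
    "structure_pair",
    "distance_matrix",
    "nj_tree",
    "to_newick",
]

#: Default MaxSub distance threshold in Angstrom.
DEFAULT_D_THRESHOLD = 3.5

_SEED_LEN = 4


@dataclass(frozen=True)
class StructurePair:
    """Reciprocal MaxSub scores and symmetrized distance for one pair."""

    id_a: str
    id_b: str
    maxsub_ab: float
    maxsub_ba: float

    @property
    def maxsub_average(self) -> float:
        return 0.5 * (self.maxsub_ab + self.maxsub_ba)

    @property
    def distance(self) -> float:
        return 1.0 - self.maxsub_average


@dataclass(frozen=True)
class StructureDistanceMatrix:
    """Symmetric 1-MaxSubAverage distance matrix over named structures."""

    ids: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match the number of ids")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise ValueError("self-distances must be zero")
        if D.min() < -1e-12 or D.max() > 1.0 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "D", D)


def _superpose_subset(a: np.ndarray, b: np.ndarray,
                      subset: np.ndarray) -> np.ndarray:
    """Distances |T(a_i) - b_i| after Kabsch-fitting a[subset] onto b[subset]."""
    ca = a[subset].mean(axis=0)
    cb = b[subset].mean(axis=0)
    rot, _ = Rotation.align_vectors(b[subset] - cb, a[subset] - ca)
    moved = rot.apply(a - ca) + cb
    return np.linalg.norm(moved - b, axis=1)


def maxsub_score(coords_a: np.ndarray,
                 coords_b: np.ndarray,
                 correspondence: "list[tuple[int, int]] | None" = None,
                 d_threshold: float = DEFAULT_D_THRESHOLD) -> float:
    """MaxSub similarity of structure A against structure B.

    Seed-extension search: every contiguous window of 4 correspondence
    pairs seeds a superposition that is refined in four passes with a
    threshold growing to ``d_threshold``; the best final matched set
    yields the score.  Deterministic; normalized by the residue count of
    ``coords_a`` (the query), hence asymmetric in general.

    Parameters
    ----------
    coords_a, coords_b:
        ``(n, 3)`` representative-atom coordinates (e.g. C-alpha).
    correspondence:
        Residue index pairs ``(i_a, i_b)``; identity by index when omitted
        (requires equal lengths).  At least 4 pairs.
    d_threshold:
        Match distance threshold in Angstrom (> 0).
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if d_threshold <= 0:
        raise ValueError("d_threshold must be positive")
    if correspondence is None:
        if len(coords_a) != len(coords_b):
            raise ValueError(
                "identity correspondence requires equal-length structures")
        correspondence = [(i, i) for i in range(len(coords_a))]
    if len(correspondence) < _SEED_LEN:
        raise ValueError(
            f"at least {_SEED_LEN} correspondence pairs required, "
            f"got {len(correspondence)}")
    ia = np.array([p[0] for p in correspondence])
    ib = np.array([p[1] for p in correspondence])
    a = coords_a[ia]
    b = coords_b[ib]
    n_pairs = len(correspondence)
    n_query = len(coords_a)

    best = 0.0
    for start in range(n_pairs - _SEED_LEN + 1):
        subset = np.arange(start, start + _SEED_LEN)
        # single-pass extension with a threshold ramp (4 refinement rounds)
        for k in range(1, 5):
            dists = _superpose_subset(a, b, subset)
            grown = np.flatnonzero(dists < d_threshold * k / 4.0)
            if len(grown) < _SEED_LEN:
                break
            subset = grown
        dists = _superpose_subset(a, b, subset)
        matched = dists[subset] < d_threshold
        score = float(np.sum(1.0 / (1.0 + (dists[subset][matched]
                                           / d_threshold) ** 2)) / n_query)
        best = max(best, score)
    return min(best, 1.0)


def structure_pair(id_a: str, coords_a: np.ndarray,
                   id_b: str, coords_b: np.ndarray,
                   correspondence: "list[tuple[int, int]] | None" = None,
                   d_threshold: float = DEFAULT_D_THRESHOLD) -> StructurePair:
    """Both reciprocal MaxSub scores for one structure pair."""
    reverse = None
    if correspondence is not None:
        reverse = [(j, i) for i, j in correspondence]
    return StructurePair(
        id_a=id_a, id_b=id_b,
        maxsub_ab=maxsub_score(coords_a, coords_b, correspondence, d_threshold),
        maxsub_ba=maxsub_score(coords_b, coords_a, reverse, d_threshold),
    )


def distance_matrix(structures: "dict[str, np.ndarray]",
                    correspondences: "dict[tuple[str, str], list] | None" = None,
                    d_threshold: float = DEFAULT_D_THRESHOLD,
                    ) -> StructureDistanceMatrix:
    """Symmetric 1-MaxSubAverage distance matrix over a structure set.

    ``correspondences`` may supply residue index pairs per ordered or
    unordered id pair; identity correspondence is used when absent.
    Errors raised for a pair are re-raised naming the pair.
    """
    ids = tuple(structures)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            corr = None
            if correspondences is not None:
                corr = correspondences.get((ids[i], ids[j]))
                if corr is None:
                    rev = correspondences.get((ids[j], ids[i]))
                    if rev is not None:
                        corr = [(b, a) for a, b in rev]
            try:
                pair = structure_pair(ids[i], structures[ids[i]],
                                      ids[j], structures[ids[j]],
                                      corr, d_threshold)
            except ValueError as exc:
                raise ValueError(
                    f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
            D[i, j] = D[j, i] = pair.distance
    return StructureDistanceMatrix(ids=ids, D=D)


def nj_tree(matrix: StructureDistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (Saitou-Nei) from a structure distance matrix.

    Exact on additive matrices: reconstructs the generating topology and
    branch lengths.  Negative branch lengths (possible on non-additive
    input) are clamped to zero with a warning.  Returns an unrooted
    ``skbio.TreeNode`` whose tips carry the structure ids.
    """
    if len(matrix.ids) < 3:
        raise ValueError("neighbor joining requires at least 3 structures")
    dm = DistanceMatrix(matrix.D, ids=list(matrix.ids))
    tree = nj(dm, neg_as_zero=False)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(
            f"{clamped} negative neighbor-joining branch length(s) "
            "clamped to 0 (non-additive input)",
            stacklevel=2,
        )
    return tree


def to_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string."""
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
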