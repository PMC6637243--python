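import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from puckertools import build_conformer_library

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def library():
    return build_conformer_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid_transform(rng):
    """A uniformly random rotation matrix plus a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.uniform(-50, 50, size=3)
    return R.as_matrix(), t


def kearsley_min_rmsd(mobile, reference):
    """Quaternion-method (Kearsley) minimal-RMSD oracle.

    Independent of the package's Kabsch/SVD route: builds the 4x4
    Kearsley matrix from coordinate sums/differences; the smallest
    eigenvalue equals the residual sum of squares of the optimal
    superposition, so the minimal RMSD is sqrt(lambda_min / N).
    """
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    m = mob_c - ref_c
    p = mob_c + ref_c
    xm, ym, zm = m.T
    xp, yp, zp = p.T
    K = np.array([
        [np.sum(xm**2 + ym**2 + zm**2),
         np.sum(yp * zm - ym * zp),
         np.sum(xm * zp - xp * zm),
         np.sum(xp * ym - xm * yp)],
        [0,
         np.sum(yp**2 + zp**2 + xm**2),
         np.sum(xm * ym - xp * yp),
         np.sum(xm * zm - xp * zp)],
        [0, 0,
         np.sum(xp**2 + zp**2 + ym**2),
         np.sum(ym * zm - yp * zp)],
        [0, 0, 0,
         np.sum(xp**2 + yp**2 + zm**2)],
    ])
    K = K + np.triu(K, 1).T
    w = np.linalg.eigvalsh(K)
    return float(np.sqrt(max(w[0], 0.0) / len(mobile)))


def brute_force_pucker(positions):
    """Independent Cremer-Pople computation via least squares.

    The mean-plane normal is obtained as the unit vector orthogonal to
    both first-moment combinations of the centred coordinates (via SVD of
    their span), then (q2 cos phi2, q2 sin phi2, q3) are recovered by
    solving the displacement model z = B c with lstsq instead of the
    closed-form Fourier sums.
    """
    xyz = np.asarray(positions, float)
    xyz = xyz - xyz.mean(axis=0)
    j = np.arange(6)
    r1 = np.sin(2 * np.pi * j / 6) @ xyz
    r2 = np.cos(2 * np.pi * j / 6) @ xyz
    # normal = basis vector of the orthogonal complement of span{r1, r2};
    # the SVD sign is arbitrary, so orient it along r1 x r2 (the convention)
    _, _, vt = np.linalg.svd(np.vstack([r1, r2]))
    n = vt[2]
    if np.dot(n, np.cross(r1, r2)) < 0:
        n = -n
    z = xyz @ n
    B = np.column_stack([
        np.sqrt(1 / 3) * np.cos(4 * np.pi * j / 6),
        -np.sqrt(1 / 3) * np.sin(4 * np.pi * j / 6),
        np.sqrt(1 / 6) * (-1.0) ** j,
    ])
    c, *_ = np.linalg.lstsq(B, z, rcond=None)
    q2 = float(np.hypot(c[0], c[1]))
    q3 = float(c[2])
    Q = float(np.hypot(q2, q3))
    theta = float(np.degrees(np.arctan2(q2, q3)))
    phi = float(np.degrees(np.arctan2(c[1], c[0])) % 360)
    return Q, theta, phi
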