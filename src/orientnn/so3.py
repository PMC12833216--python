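"""Rotation algebra on SO(3) and its Lie algebra so(3).

All public functions are vectorised over leading axes: rotation matrices have
shape ``(..., 3, 3)``, rotation vectors and Euler triples ``(..., 3)``.

Conventions
-----------
* Rotation vectors (axis-angle): direction = rotation axis, magnitude =
  rotation angle in radians; the canonical representative has magnitude in
  ``[0, pi]``.
* Euler angles use the intrinsic Z-Y-X sequence, ``R = Rz(z) @ Ry(y) @ Rx(x)``,
  the body-fixed convention used by OpenSim-style joint-angle reporting.
* Quaternions are Hamilton, scalar-first ``(w, x, y, z)``, canonicalised to
  ``w >= 0`` (q and -q denote the same rotation).
* Angles are radians throughout this module; degree conversion happens at the
  package's external interfaces.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "hat",
    "vee",
    "exp_map",
    "log_map",
    "euler_zyx_to_rot",
    "rot_to_euler_zyx",
    "geodesic_angle",
    "quat_to_rot",
    "rot_to_quat",
    "is_rotation",
    "check_rotation",
    "project_to_rotation",
    "random_rotation",
]

#: Frobenius tolerance beyond which a matrix is rejected as non-orthonormal.
ORTHO_TOL = 1e-6
#: Below this angle the Taylor expansions of the Rodrigues coefficients are used.
_SMALL_ANGLE = 1e-4


def hat(v: np.ndarray) -> np.ndarray:
    """Map a 3-vector to its skew-symmetric (cross-product) matrix."""
    v = np.asarray(v, dtype=float)
    K = np.zeros(v.shape[:-1] + (3, 3))
    K[..., 0, 1] = -v[..., 2]
    K[..., 0, 2] = v[..., 1]
    K[..., 1, 0] = v[..., 2]
    K[..., 1, 2] = -v[..., 0]
    K[..., 2, 0] = -v[..., 1]
    K[..., 2, 1] = v[..., 0]
    return K


def vee(K: np.ndarray) -> np.ndarray:
    """Inverse of :func:`hat` (takes the skew part of ``K``)."""
    K = np.asarray(K, dtype=float)
    return 0.5 * np.stack(
        [
            K[..., 2, 1] - K[..., 1, 2],
            K[..., 0, 2] - K[..., 2, 0],
            K[..., 1, 0] - K[..., 0, 1],
        ],
        axis=-1,
    )


def _rodrigues_coeffs(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients a = sin(t)/t and b = (1-cos(t))/t^2, Taylor-stable at 0."""
    theta = np.asarray(theta, dtype=float)
    small = theta < _SMALL_ANGLE
    t = np.where(small, 1.0, theta)  # avoid 0/0 in the untaken branch
    t2 = theta * theta
    a = np.where(small, 1.0 - t2 / 6.0 + t2 * t2 / 120.0, np.sin(t) / t)
    b = np.where(small, 0.5 - t2 / 24.0 + t2 * t2 / 720.0, (1.0 - np.cos(t)) / (t * t))
    return a, b


def exp_map(v: np.ndarray) -> np.ndarray:
    """Exponential map so(3) -> SO(3) via the Rodrigues formula.

    ``exp_map(v) = I + a(theta) K + b(theta) K^2`` with ``K = hat(v)`` and
    ``theta = |v|``; near zero the coefficients use their second-order Taylor
    expansions so the map is smooth through the identity.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError(f"rotation vector must have last dimension 3, got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("rotation vector contains non-finite entries")
    theta = np.linalg.norm(v, axis=-1)
    a, b = _rodrigues_coeffs(theta)
    K = hat(v)
    K2 = K @ K
    return (
        np.eye(3)
        + a[..., None, None] * K
        + b[..., None, None] * K2
    )


def is_rotation(R: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """True where ``R`` is orthonormal with determinant +1 within ``tol``."""
    R = np.asarray(R, dtype=float)
    err = np.linalg.norm(R @ np.swapaxes(R, -1, -2) - np.eye(3), axis=(-2, -1))
    det = np.linalg.det(R)
    return (err <= tol) & (np.abs(det - 1.0) <= tol)


def check_rotation(R: np.ndarray, tol: float = ORTHO_TOL) -> np.ndarray:
    """Validate rotation matrices; raises ``ValueError`` beyond ``tol``."""
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise ValueError(f"expected (..., 3, 3) matrices, got shape {R.shape}")
    if not np.all(np.isfinite(R)):
        raise ValueError("rotation matrix contains non-finite entries")
    err = np.linalg.norm(R @ np.swapaxes(R, -1, -2) - np.eye(3), axis=(-2, -1))
    if np.any(err > tol):
        raise ValueError(
            f"matrix is not orthonormal: max |R Rt - I|_F = {float(np.max(err)):.3e}"
        )
    if np.any(np.linalg.det(R) < 0):
        raise ValueError("matrix has negative determinant (improper rotation)")
    return R


def log_map(R: np.ndarray) -> np.ndarray:
    """Logarithm map SO(3) -> so(3); canonical output with magnitude in [0, pi].

    Away from pi the standard formula ``v = theta/(2 sin theta) * vee(R - Rt)``
    is used (Taylor-stabilised near 0). Within 1e-6 of pi the axis is recovered
    from the dominant diagonal of ``(R + I)/2``, which stays well-conditioned
    where the skew part vanishes.
    """
    R = check_rotation(np.asarray(R, dtype=float))
    c = np.clip((np.trace(R, axis1=-2, axis2=-1) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(c)
    w = np.stack(
        [
            R[..., 2, 1] - R[..., 1, 2],
            R[..., 0, 2] - R[..., 2, 0],
            R[..., 1, 0] - R[..., 0, 1],
        ],
        axis=-1,
    )
    small = theta < _SMALL_ANGLE
    near_pi = theta > np.pi - 1e-6
    safe_sin = np.where(small | near_pi, 1.0, np.sin(theta))
    gamma = np.where(
        small,
        0.5 + theta * theta / 12.0,
        theta / (2.0 * safe_sin),
    )
    v = gamma[..., None] * w

    if np.any(near_pi):
        B = (R + np.eye(3)) / 2.0  # = axis axis^T at theta = pi
        diag = np.stack([B[..., 0, 0], B[..., 1, 1], B[..., 2, 2]], axis=-1)
        k = np.argmax(diag, axis=-1)
        axis = np.take_along_axis(B, k[..., None, None].repeat(3, axis=-2), axis=-1)[
            ..., 0
        ]
        kk = np.take_along_axis(diag, k[..., None], axis=-1)[..., 0]
        axis = axis / np.sqrt(np.maximum(kk, 1e-300))[..., None]
        # canonical sign: first component of largest magnitude made positive
        lead = np.take_along_axis(
            axis, np.argmax(np.abs(axis), axis=-1)[..., None], axis=-1
        )[..., 0]
        axis = axis * np.where(lead < 0, -1.0, 1.0)[..., None]
        v = np.where(near_pi[..., None], axis * theta[..., None], v)
    return v


def euler_zyx_to_rot(e: np.ndarray) -> np.ndarray:
    """Intrinsic Z-Y-X Euler triple (z, y, x), radians -> rotation matrix."""
    e = np.asarray(e, dtype=float)
    if e.shape[-1] != 3:
        raise ValueError(f"Euler triple must have last dimension 3, got {e.shape}")
    if not np.all(np.isfinite(e)):
        raise ValueError("Euler angles contain non-finite entries")
    cz, sz = np.cos(e[..., 0]), np.sin(e[..., 0])
    cy, sy = np.cos(e[..., 1]), np.sin(e[..., 1])
    cx, sx = np.cos(e[..., 2]), np.sin(e[..., 2])
    R = np.empty(e.shape[:-1] + (3, 3))
    R[..., 0, 0] = cz * cy
    R[..., 0, 1] = cz * sy * sx - sz * cx
    R[..., 0, 2] = cz * sy * cx + sz * sx
    R[..., 1, 0] = sz * cy
    R[..., 1, 1] = sz * sy * sx + cz * cx
    R[..., 1, 2] = sz * sy * cx - cz * sx
    R[..., 2, 0] = -sy
    R[..., 2, 1] = cy * sx
    R[..., 2, 2] = cy * cx
    return R


def rot_to_euler_zyx(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Factor ``R = Rz(z) Ry(y) Rx(x)``; returns ``(zyx, gimbal_flag)``.

    ``zyx`` has z, x in (-pi, pi] and y in [-pi/2, pi/2]. At gimbal lock
    (|cos y| < 1e-7) only z - x (for y = +pi/2) resp. z + x is determined;
    the x = 0 representative is returned and the flag set — no exception, so
    downstream losses stay finite.
    """
    R = check_rotation(np.asarray(R, dtype=float))
    sy = np.clip(-R[..., 2, 0], -1.0, 1.0)
    cy = np.hypot(R[..., 0, 0], R[..., 1, 0])
    gimbal = cy < 1e-7
    y = np.arcsin(sy)
    z = np.where(gimbal, np.arctan2(-R[..., 0, 1], R[..., 1, 1]), np.arctan2(R[..., 1, 0], R[..., 0, 0]))
    x = np.where(gimbal, 0.0, np.arctan2(R[..., 2, 1], R[..., 2, 2]))
    return np.stack([z, y, x], axis=-1), gimbal


def geodesic_angle(R1: np.ndarray, R2: np.ndarray) -> np.ndarray:
    """Geodesic (angular) distance on SO(3): ``arccos((tr(R1t R2) - 1)/2)``."""
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    M = np.swapaxes(R1, -1, -2) @ R2
    c = np.clip((np.trace(M, axis1=-2, axis2=-1) - 1.0) / 2.0, -1.0, 1.0)
    return np.arccos(c)


def quat_to_rot(q: np.ndarray) -> np.ndarray:
    """Hamilton scalar-first unit quaternion -> rotation matrix.

    Quaternions are normalised on entry; near-zero norm is rejected.
    """
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"quaternion must have last dimension 4, got {q.shape}")
    n = np.linalg.norm(q, axis=-1)
    if np.any(n < 1e-8):
        raise ValueError("quaternion norm too close to zero")
    q = q / n[..., None]
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - w * z)
    R[..., 0, 2] = 2 * (x * z + w * y)
    R[..., 1, 0] = 2 * (x * y + w * z)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - w * x)
    R[..., 2, 0] = 2 * (x * z - w * y)
    R[..., 2, 1] = 2 * (y * z + w * x)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def rot_to_quat(R: np.ndarray) -> np.ndarray:
    """Rotation matrix -> canonical (w >= 0) Hamilton scalar-first quaternion.

    Uses Shepperd's method: the conversion branches on the largest of
    (1 + tr, 1 + 2 R_ii - tr) to stay well-conditioned for all rotations.
    """
    R = check_rotation(np.asarray(R, dtype=float))
    batch = R.shape[:-2]
    Rf = R.reshape((-1, 3, 3))
    q = np.empty((Rf.shape[0], 4))
    tr = np.trace(Rf, axis1=-2, axis2=-1)
    cand = np.stack(
        [1 + tr, 1 + 2 * Rf[:, 0, 0] - tr, 1 + 2 * Rf[:, 1, 1] - tr, 1 + 2 * Rf[:, 2, 2] - tr],
        axis=-1,
    )
    case = np.argmax(cand, axis=-1)
    for i in range(Rf.shape[0]):
        M = Rf[i]
        if case[i] == 0:
            s = 2.0 * np.sqrt(cand[i, 0])
            q[i] = [0.25 * s, (M[2, 1] - M[1, 2]) / s, (M[0, 2] - M[2, 0]) / s, (M[1, 0] - M[0, 1]) / s]
        elif case[i] == 1:
            s = 2.0 * np.sqrt(cand[i, 1])
            q[i] = [(M[2, 1] - M[1, 2]) / s, 0.25 * s, (M[0, 1] + M[1, 0]) / s, (M[0, 2] + M[2, 0]) / s]
        elif case[i] == 2:
            s = 2.0 * np.sqrt(cand[i, 2])
            q[i] = [(M[0, 2] - M[2, 0]) / s, (M[0, 1] + M[1, 0]) / s, 0.25 * s, (M[1, 2] + M[2, 1]) / s]
        else:
            s = 2.0 * np.sqrt(cand[i, 3])
            q[i] = [(M[1, 0] - M[0, 1]) / s, (M[0, 2] + M[2, 0]) / s, (M[1, 2] + M[2, 1]) / s, 0.25 * s]
    q /= np.linalg.norm(q, axis=-1, keepdims=True)
    q *= np.where(q[:, :1] < 0, -1.0, 1.0)
    return q.reshape(batch + (4,))


def project_to_rotation(M: np.ndarray) -> np.ndarray:
    """Nearest rotation matrix in Frobenius norm (via SVD)."""
    M = np.asarray(M, dtype=float)
    U, _, Vt = np.linalg.svd(M)
    d = np.linalg.det(U @ Vt)
    S = np.repeat(np.eye(3)[None], U.reshape(-1, 3, 3).shape[0], axis=0).reshape(M.shape)
    S[..., 2, 2] = d
    return U @ S @ Vt


def random_rotation(rng: np.random.Generator, size: tuple[int, ...] | int = ()) -> np.ndarray:
    """Haar-uniform random rotation matrices (unit-quaternion construction)."""
    if isinstance(size, int):
        size = (size,)
    q = rng.standard_normal(tuple(size) + (4,))
    q /= np.linalg.norm(q, axis=-1, keepdims=True)
    return quat_to_rot(q)
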