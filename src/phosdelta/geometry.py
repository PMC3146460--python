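"""Small-vector geometry: torsions, angles, internal-coordinate placement.

These helpers operate on plain numpy arrays of shape (3,) in Å and are the
shared substrate for dihedral extraction, side-chain building and the
synthetic peptide generator.
"""

from __future__ import annotations

import numpy as np


class CollinearGeometryError(ValueError):
    """Raised when a torsion is requested for (near-)collinear atoms."""


def bond_length(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(b - a))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def torsion(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray,
            collinear_tol: float = 1e-8) -> float:
    """Signed dihedral a–b–c–d in degrees, in [-180, 180).

    Uses the atan2 construction; positive sense follows the IUPAC
    convention (clockwise rotation of d relative to a looking b→c).
    """
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    if n1n < collinear_tol or n2n < collinear_tol:
        raise CollinearGeometryError("torsion undefined: three collinear atoms")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return wrap_angle(ang)


def wrap_angle(deg):
    """Wrap angle(s) into [-180, 180)."""
    return (np.asarray(deg) + 180.0) % 360.0 - 180.0 if np.ndim(deg) else float((deg + 180.0) % 360.0 - 180.0)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a new atom D bonded to C given internal coordinates.

    NeRF construction: |CD| = bond, angle(B,C,D) = angle_deg,
    dihedral(A,B,C,D) = torsion_deg.
    """
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # reference frame degenerate; pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, bc)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    # sign of the out-of-plane component chosen so that
    # torsion(a, b, c, d) measures back exactly torsion_deg
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(phi),
        -bond * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def tetrahedral_completion(center: np.ndarray, substituents: list[np.ndarray],
                           bond: float) -> np.ndarray:
    """Position a fourth substituent of a tetrahedral center.

    Direction is the negative vector sum of the unit vectors to the
    existing substituents; for ideally tetrahedral geometry this makes
    all substituent angles equal the tetrahedral angle (109.47°).
    """
    s = np.zeros(3)
    for p in substituents:
        u = p - center
        s += u / np.linalg.norm(u)
    norm = np.linalg.norm(s)
    if norm < 1e-8:
        raise ValueError("degenerate substituent arrangement")
    return center - bond * s / norm


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centered p onto centered q."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T
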