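"""Low-level backbone geometry: dihedrals, NeRF atom placement, Kabsch superposition.

All coordinates are in Ångström, all angles in degrees. Dihedral signs follow
the IUPAC convention with values in (−180, +180].
"""

from __future__ import annotations

import numpy as np

# Idealized backbone internal coordinates (Engh–Huber-like averages).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_C_CA_CB = 110.6
# Improper torsion N–C–CA–CB that puts CB on the L-amino-acid side.
TORSION_N_C_CA_CB = -122.6

# Peptide C–N distance window used to call chain breaks.
PEPTIDE_BOND_RANGE = (1.2, 1.5)


def normalize_angle(angle: float) -> float:
    """Map an angle in degrees to (−180, +180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    if a == -180.0:
        a = 180.0
    return a


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0–p1–p2–p3 in degrees, IUPAC sign, (−180, +180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return normalize_angle(np.degrees(np.arctan2(y, x)))


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0–p1–p2 in degrees."""
    u = np.asarray(p0, float) - np.asarray(p1, float)
    v = np.asarray(p2, float) - np.asarray(p1, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom D so that |C–D| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = torsion (natural-extension-of-reference-frame step)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("reference atoms A, B, C are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis_point: np.ndarray, axis_dir: np.ndarray, angle_rad: float):
    """Return a function rotating points about the given axis (Rodrigues)."""
    k = np.asarray(axis_dir, float)
    k = k / np.linalg.norm(k)
    p0 = np.asarray(axis_point, float)
    cos_t = np.cos(angle_rad)
    sin_t = np.sin(angle_rad)

    def rotate(points: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(points) - p0
        rotated = (
            v * cos_t
            + np.cross(k, v) * sin_t
            + np.outer(v @ k, k) * (1.0 - cos_t)
        )
        out = rotated + p0
        return out.reshape(np.shape(points))

    return rotate


class DegenerateGeometryError(ValueError):
    """Raised when a point set is too small or collinear for superposition."""


def kabsch_superpose(mobile: np.ndarray, fixed: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``fixed``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile points onto fixed with the
    minimum possible rmsd. The rotation is proper (det = +1).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(fixed, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(P) < 3:
        raise DegenerateGeometryError("need at least 3 points for superposition")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    for centered, label in ((Pc, "mobile"), (Qc, "fixed")):
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError(f"{label} point set is collinear")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    diff = (Pc @ R.T) - Qc
    rmsd = float(np.sqrt((diff * diff).sum() / len(P)))
    return R, t, rmsd


def coord_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain rmsd between two already-superposed coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = a - b
    return float(np.sqrt((d * d).sum() / len(a)))


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum rmsd between two coordinate sets after optimal superposition."""
    _, _, rmsd = kabsch_superpose(a, b)
    return rmsd
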