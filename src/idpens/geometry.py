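"""Internal-coordinate geometry helpers.

All coordinates are in nanometres, all angles in radians unless a function
name says otherwise.  These routines back the chain builder and the
structural analytics; they operate on plain ``numpy`` arrays so that callers
can vectorize over conformers.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "place_atom",
    "dihedral",
    "bond_angle",
    "unit",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` scaled to unit length (last axis)."""
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom D from internal coordinates relative to chain A-B-C.

    D is positioned such that |C-D| = ``bond``, the B-C-D angle equals
    ``angle`` and the A-B-C-D dihedral equals ``torsion`` (natural extension
    reference frame, aka NeRF).
    """
    # hand-rolled 3-vector algebra: this sits in the chain-growth inner loop
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nb = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / nb, bcy / nb, bcz / nb
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    # n = (b - a) x bc, normalized
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    # m = n x bc
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * math.cos(angle)
    sa = bond * math.sin(angle)
    d1 = sa * math.cos(torsion)
    d2 = sa * math.sin(torsion)
    return np.array(
        [
            c[0] + d0 * bcx + d1 * mx + d2 * nx,
            c[1] + d0 * bcy + d1 * my + d2 * ny,
            c[2] + d0 * bcz + d1 * mz + d2 * nz,
        ]
    )


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle of the four points, in radians in (-pi, pi]."""
    b0 = p1 - p0
    b1 = unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.arctan2(y, x))


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle at ``p1`` formed by p0-p1-p2, in radians in [0, pi]."""
    u = unit(p0 - p1)
    v = unit(p2 - p1)
    return float(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))
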