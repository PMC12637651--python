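"""Vectorized internal-coordinate values and analytic Cartesian gradients.

All functions take an ``(n_beads, 3)`` position array and integer index
arrays; they return per-tuple values and, where requested, the gradient of
each value with respect to each participating bead.  Degenerate tuples
(coincident beads, collinear dihedral frames) raise a structured error
instead of silently clamping: a NaN entering an integrator is a bug worth
surfacing.

Dihedrals follow the IUPAC convention: phi in (-pi, pi], zero at cis,
measured on the four beads exactly in the order given.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-10


class DegenerateGeometryError(ValueError):
    """A bond, angle or dihedral is geometrically undefined."""


def _norm(v: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", v, v))


def distances(pos: np.ndarray, a: np.ndarray, b: np.ndarray, *, grad: bool = False):
    """Pairwise distances |r_a - r_b|; optionally d(r)/d(r_a) (the b gradient
    is its negative)."""
    d = pos[a] - pos[b]
    r = _norm(d)
    if np.any(r < _EPS):
        bad = int(np.argmin(r))
        raise DegenerateGeometryError(f"coincident beads {a[bad]} and {b[bad]}")
    if not grad:
        return r
    return r, d / r[:, None]


def angles(pos: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray, *, grad: bool = False):
    """Angles at vertex b of the triples (a, b, c), in (0, pi].

    With ``grad=True`` also returns (ga, gb, gc), the gradients of each angle
    with respect to the three bead positions.
    """
    u = pos[a] - pos[b]
    v = pos[c] - pos[b]
    ru = _norm(u)
    rv = _norm(v)
    if np.any(ru < _EPS) or np.any(rv < _EPS):
        raise DegenerateGeometryError("coincident beads in angle tuple")
    uh = u / ru[:, None]
    vh = v / rv[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(cosang)
    if not grad:
        return theta
    sinang = np.sqrt(np.maximum(1.0 - cosang**2, 0.0))
    if np.any(sinang < _EPS):
        raise DegenerateGeometryError("collinear/degenerate angle: gradient undefined")
    ga = (cosang[:, None] * uh - vh) / (ru * sinang)[:, None]
    gc = (cosang[:, None] * vh - uh) / (rv * sinang)[:, None]
    gb = -(ga + gc)
    return theta, ga, gb, gc


def dihedrals(
    pos: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    *,
    grad: bool = False,
):
    """IUPAC dihedral angles on the tuples (a, b, c, d), in (-pi, pi].

    With ``grad=True`` also returns (ga, gb, gc, gd).
    """
    b1 = pos[b] - pos[a]
    b2 = pos[c] - pos[b]
    b3 = pos[d] - pos[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    r2 = _norm(b2)
    m1 = _norm(n1)
    m2 = _norm(n2)
    if np.any(r2 < _EPS):
        raise DegenerateGeometryError("coincident central beads in dihedral")
    if np.any(m1 < _EPS) or np.any(m2 < _EPS):
        raise DegenerateGeometryError("collinear frame: dihedral undefined")
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / r2[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    phi = np.arctan2(y, x)
    if not grad:
        return phi
    ga = -(r2 / m1**2)[:, None] * n1
    gd = (r2 / m2**2)[:, None] * n2
    s1 = (np.einsum("ij,ij->i", b1, b2) / r2**2)[:, None]
    s2 = (np.einsum("ij,ij->i", b3, b2) / r2**2)[:, None]
    gb = -(1.0 + s1) * ga + s2 * gd
    gc = -(ga + gb + gd)  # translation invariance
    return phi, ga, gb, gc, gd


def pair_distance_matrix(pos: np.ndarray) -> np.ndarray:
    """Full symmetric distance matrix (small systems only)."""
    diff = pos[:, None, :] - pos[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def kabsch_rmsd(x: np.ndarray, ref: np.ndarray, *, superpose: bool = True) -> float:
    """RMSD between two (n, 3) coordinate sets, optionally after optimal
    rigid superposition (rotation + translation)."""
    if x.shape != ref.shape:
        raise ValueError(f"bead-count mismatch: {x.shape} vs {ref.shape}")
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((x - ref) ** 2, axis=1))))
    xc = x - x.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    h = xc.T @ rc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    dmat = np.diag([1.0, 1.0, sign])
    rot = vt.T @ dmat @ u.T
    aligned = xc @ rot.T
    return float(np.sqrt(np.mean(np.sum((aligned - rc) ** 2, axis=1))))
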