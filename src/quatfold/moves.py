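"""Topology-preserving chain perturbations.

Three pivot-style moves evolve a chain: a planar-angle move rotates the
downstream tail about the normal of the plane through a hinge vertex, a
dihedral move rotates the tail about a segment direction, and a bond move
translates the tail along a bond.  Because the rotation maps the plane (or
axis) defining the targeted coordinate onto itself, every move changes
exactly one free internal coordinate and leaves all segment lengths, all
other planar angles and all other dihedrals untouched -- the chain
topology is maintained, so the only constraint left to check is spatial
interference between beads.
"""

from __future__ import annotations

import numpy as np

from .chain import Chain
from .quaternions import from_axis_angle, rotate_points

__all__ = [
    "DegenerateGeometryError",
    "FrozenCoordinateError",
    "perturb_planar_angle",
    "perturb_dihedral_angle",
    "perturb_bond_length",
]

_COLLINEAR_RTOL = 1e-9


class DegenerateGeometryError(RuntimeError):
    """The local geometry does not define the requested move (e.g. a
    collinear triple has no plane normal); the caller should retry with
    another move."""


class FrozenCoordinateError(ValueError):
    """The targeted internal coordinate is bead-internal and rigid."""


def _tail_rotate(chain: Chain, first_moving: int, q, pivot) -> Chain:
    new = chain.copy()
    new.points[first_moving:] = rotate_points(q, chain.points[first_moving:], pivot)
    return new


def perturb_planar_angle(chain: Chain, vertex_index: int, delta: float) -> Chain:
    """Open/close the planar angle at polyline vertex `vertex_index` by `delta` degrees.

    All points downstream of the vertex rotate rigidly about the normal of
    the flanking plane through the vertex; positive delta increases the
    angle.  Raises DegenerateGeometryError when the flanking triple is
    collinear and FrozenCoordinateError when the vertex is bead-internal.
    """
    m = chain.n_points
    if not (1 <= vertex_index <= m - 2):
        raise IndexError(f"vertex_index {vertex_index} not interior (1..{m - 2})")
    if not chain.free_vertices()[vertex_index - 1]:
        raise FrozenCoordinateError(f"vertex {vertex_index} is rigid bead geometry")
    p = chain.points
    u = p[vertex_index - 1] - p[vertex_index]
    w = p[vertex_index + 1] - p[vertex_index]
    axis = np.cross(u, w)
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    scale = nu * nw
    if scale == 0.0 or np.linalg.norm(axis) <= _COLLINEAR_RTOL * scale:
        raise DegenerateGeometryError(
            f"collinear triple at vertex {vertex_index}: plane normal undefined"
        )
    # the planar angle lives on (0, 180): a move crossing either end would
    # pass through a collinear singularity (the plane normal inverts,
    # flipping adjacent dihedral signs), so it is signalled like any other
    # degenerate geometry and the caller retries
    psi = np.degrees(np.arccos(np.clip(np.dot(u, w) / scale, -1.0, 1.0)))
    if not (1e-9 < psi + delta < 180.0 - 1e-9):
        raise DegenerateGeometryError(
            f"planar angle at vertex {vertex_index} would cross the collinear "
            f"singularity ({psi:.3f} + {delta:.3f} deg)"
        )
    # rotating the tail about u x w by +delta opens the angle (u, w)
    q = from_axis_angle(axis, delta)
    return _tail_rotate(chain, vertex_index + 1, q, p[vertex_index])


def perturb_dihedral_angle(chain: Chain, axis_index: int, delta: float) -> Chain:
    """Rotate the tail beyond bond (axis_index, axis_index+1) by `delta` degrees
    about the bond direction, changing the dihedral of the quadruple
    (axis_index-1 .. axis_index+2) by exactly delta (signed, mod 360)."""
    m = chain.n_points
    if not (1 <= axis_index <= m - 3):
        raise IndexError(f"axis_index {axis_index} out of range (1..{m - 3})")
    p = chain.points
    b2 = p[axis_index + 1] - p[axis_index]
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0:
        raise DegenerateGeometryError("zero-length axis bond")
    b1 = p[axis_index] - p[axis_index - 1]
    b3 = p[axis_index + 2] - p[axis_index + 1]
    if np.linalg.norm(np.cross(b1, b2)) <= _COLLINEAR_RTOL * np.linalg.norm(b1) * nb2:
        raise DegenerateGeometryError("first flanking triple collinear: dihedral undefined")
    if np.linalg.norm(np.cross(b2, b3)) <= _COLLINEAR_RTOL * np.linalg.norm(b3) * nb2:
        raise DegenerateGeometryError("second flanking triple collinear: dihedral undefined")
    q = from_axis_angle(b2, delta)
    return _tail_rotate(chain, axis_index + 2, q, p[axis_index])


def perturb_bond_length(chain: Chain, bond_index: int, delta: float) -> Chain:
    """Lengthen bond `bond_index` by `delta` nm, translating the tail rigidly
    along the bond direction; range checking is the caller's business."""
    m = chain.n_points
    if not (0 <= bond_index <= m - 2):
        raise IndexError(f"bond_index {bond_index} out of range (0..{m - 2})")
    if not chain.free_segments()[bond_index]:
        raise FrozenCoordinateError(f"segment {bond_index} is rigid bead geometry")
    p = chain.points
    v = p[bond_index + 1] - p[bond_index]
    n = np.linalg.norm(v)
    if n == 0.0:
        raise DegenerateGeometryError("zero-length bond has no direction")
    new = chain.copy()
    new.points[bond_index + 1 :] += (delta / n) * v
    return new
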