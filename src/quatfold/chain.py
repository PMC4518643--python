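"""Modified bead-chain chromatin model.

A chromatin segment is an ordered chain of beads.  At the finest genomic
resolution a bead is a single point (a sphere of some radius); at coarser
resolutions a bead is a rigid triple (start point, geometric centroid,
end point) summarizing a reconstructed subchain, whose two arm lengths and
arm angle are frozen for the rest of the procedure.  Consecutive beads are
linked by an explicit bond from one bead's end anchor to the next bead's
start anchor; bond lengths may vary inside a configured range so that
neighbouring beads neither interpenetrate nor drift apart.

Internally a chain is a single polyline of 3D points.  Each bead
contributes one point (degenerate) or three points (start, centroid, end).
Internal coordinates of the polyline -- segment lengths, planar angles,
dihedral angles -- split into *frozen* entries (inside a rigid bead) and
*free* entries (the degrees of freedom the sampler may perturb).  This
representation makes the topology-preservation property of the pivot-style
perturbations exact: each move touches a single free internal coordinate
and leaves every other entry untouched.

Units: nanometres for all coordinates and lengths, degrees for all angles
at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Bead",
    "Chain",
    "ConstraintSet",
    "Violation",
    "ConstraintReport",
    "InfeasibleChainError",
    "planar_angle",
    "dihedral_angle",
    "bead_radius_from_contacts",
    "check_constraints",
    "build_initial_chain",
    "chain_span",
    "write_chain_table",
    "read_chain_table",
    "write_pdb",
]

_COLLINEAR_TOL = 1e-12


class InfeasibleChainError(RuntimeError):
    """Raised when constrained chain growth cannot place a bead."""

    def __init__(self, bead_index: int, message: str | None = None):
        self.bead_index = bead_index
        super().__init__(message or f"chain growth stuck at bead {bead_index}")


# ---------------------------------------------------------------------------
# geometry primitives


def planar_angle(a, b, c) -> float:
    """Angle at vertex b between rays b->a and b->c, in degrees [0, 180]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    w = c - b
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    if nu == 0.0 or nw == 0.0:
        raise ValueError("planar angle undefined for coincident points")
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def dihedral_angle(a, b, c, d) -> float:
    """Signed dihedral between planes (a,b,c) and (b,c,d), degrees in (-180, 180].

    Sign convention: right-hand rule about the b->c axis; rotating d by a
    positive angle about b->c increases the dihedral.  Raises ValueError if
    either triple is collinear (undefined plane).
    """
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0:
        raise ValueError("dihedral undefined: axis points coincide")
    scale = max(np.linalg.norm(b1) * nb2, 1e-300)
    if np.linalg.norm(n1) <= _COLLINEAR_TOL * scale:
        raise ValueError("dihedral undefined: first triple is collinear")
    scale = max(np.linalg.norm(b3) * nb2, 1e-300)
    if np.linalg.norm(n2) <= _COLLINEAR_TOL * scale:
        raise ValueError("dihedral undefined: second triple is collinear")
    u = b2 / nb2
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(u, n1), n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang = 180.0
    return ang


# ---------------------------------------------------------------------------
# beads and chains


@dataclass(frozen=True)
class Bead:
    """One locus at some resolution: a rigid (start, centroid, end) triple.

    For a maximum-resolution locus the triple collapses into a single point
    (``degenerate`` is True).  Arm lengths and the arm angle are fixed at
    construction and preserved by every rigid motion of the bead.
    """

    start: np.ndarray
    centroid: np.ndarray
    end: np.ndarray
    radius: float
    genomic_span: tuple[int, int] = (0, 0)

    def __post_init__(self):
        object.__setattr__(self, "start", np.asarray(self.start, dtype=float))
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        object.__setattr__(self, "end", np.asarray(self.end, dtype=float))
        if not self.radius > 0:
            raise ValueError("bead radius must be positive")

    @classmethod
    def point(cls, p, radius: float, genomic_span: tuple[int, int] = (0, 0)) -> "Bead":
        p = np.asarray(p, dtype=float)
        return cls(p, p, p, radius, genomic_span)

    @property
    def degenerate(self) -> bool:
        return (
            np.array_equal(self.start, self.centroid)
            and np.array_equal(self.end, self.centroid)
        ) or (
            float(np.linalg.norm(self.start - self.centroid)) < 1e-12
            and float(np.linalg.norm(self.end - self.centroid)) < 1e-12
        )

    @property
    def arm_lengths(self) -> tuple[float, float]:
        return (
            float(np.linalg.norm(self.start - self.centroid)),
            float(np.linalg.norm(self.end - self.centroid)),
        )

    @property
    def arm_angle(self) -> float:
        """Angle start-centroid-end in degrees; NaN for a degenerate bead."""
        if self.degenerate:
            return float("nan")
        return planar_angle(self.start, self.centroid, self.end)

    @property
    def triple(self) -> np.ndarray:
        return np.vstack([self.start, self.centroid, self.end])


class Chain:
    """Ordered bead chain stored as a polyline with a bead index map.

    Parameters
    ----------
    points : (M, 3) array
        Polyline vertices in chain order.
    bead_points : sequence of (i_start, i_centroid, i_end)
        Point indices of each bead; a degenerate bead has all three equal.
    radii : (N,) array of positive bead radii (nm).
    spans : sequence of (start_bp, end_bp) genomic spans, one per bead.
    """

    def __init__(self, points, bead_points, radii, spans=None):
        self.points = np.array(points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (M, 3) array")
        self.bead_points = [tuple(int(i) for i in t) for t in bead_points]
        self.radii = np.asarray(radii, dtype=float)
        n = len(self.bead_points)
        if n < 1:
            raise ValueError("a chain needs at least one bead")
        if self.radii.shape != (n,):
            raise ValueError("radii must have one entry per bead")
        if np.any(self.radii <= 0):
            raise ValueError("bead radii must be positive")
        self.spans = list(spans) if spans is not None else [(0, 0)] * n
        if len(self.spans) != n:
            raise ValueError("spans must have one entry per bead")
        self._check_index_map()

    def _check_index_map(self):
        prev_end = -1
        for k, (i_s, i_c, i_e) in enumerate(self.bead_points):
            if not (i_s <= i_c <= i_e):
                raise ValueError(f"bead {k}: point indices out of order")
            if i_s != prev_end + 1:
                raise ValueError(f"bead {k}: polyline indices not contiguous")
            if i_e - i_s not in (0, 2):
                raise ValueError(f"bead {k}: a bead owns one or three points")
            prev_end = i_e
        if prev_end != len(self.points) - 1:
            raise ValueError("bead map does not cover the polyline")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_centroids(cls, coords, radii, spans=None) -> "Chain":
        """Finest-resolution chain: every bead is a single point."""
        coords = np.asarray(coords, dtype=float)
        bead_points = [(i, i, i) for i in range(len(coords))]
        return cls(coords, bead_points, radii, spans)

    @classmethod
    def from_beads(cls, beads: Sequence[Bead]) -> "Chain":
        pts: list[np.ndarray] = []
        bead_points = []
        for b in beads:
            i0 = len(pts)
            if b.degenerate:
                pts.append(b.centroid)
                bead_points.append((i0, i0, i0))
            else:
                pts.extend([b.start, b.centroid, b.end])
                bead_points.append((i0, i0 + 1, i0 + 2))
        return cls(
            np.vstack(pts),
            bead_points,
            [b.radius for b in beads],
            [b.genomic_span for b in beads],
        )

    # -- views --------------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.bead_points)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def centroids(self) -> np.ndarray:
        idx = [t[1] for t in self.bead_points]
        return self.points[idx]

    def bead(self, k: int) -> Bead:
        i_s, i_c, i_e = self.bead_points[k]
        return Bead(
            self.points[i_s], self.points[i_c], self.points[i_e],
            float(self.radii[k]), self.spans[k],
        )

    @property
    def beads(self) -> list[Bead]:
        return [self.bead(k) for k in range(self.n_beads)]

    def copy(self) -> "Chain":
        return Chain(self.points.copy(), self.bead_points, self.radii.copy(), list(self.spans))

    def point_bead_index(self) -> np.ndarray:
        """Owning bead index for every polyline point."""
        owner = np.empty(self.n_points, dtype=int)
        for k, (i_s, _, i_e) in enumerate(self.bead_points):
            owner[i_s : i_e + 1] = k
        return owner

    # -- internal coordinates ----------------------------------------------

    def segment_vectors(self) -> np.ndarray:
        return np.diff(self.points, axis=0)

    def bond_lengths(self) -> np.ndarray:
        """Lengths of all polyline segments (M-1,)."""
        return np.linalg.norm(self.segment_vectors(), axis=1)

    def planar_angles(self) -> np.ndarray:
        """Angles at interior polyline vertices (M-2,), degrees; NaN where undefined."""
        v = self.segment_vectors()
        u = -v[:-1]
        w = v[1:]
        nu = np.linalg.norm(u, axis=1)
        nw = np.linalg.norm(w, axis=1)
        denom = nu * nw
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ij->i", u, w) / denom
        cosang = np.clip(cosang, -1.0, 1.0)
        out = np.degrees(np.arccos(cosang))
        out[denom == 0.0] = np.nan
        return out

    def dihedral_angles(self) -> np.ndarray:
        """Signed dihedrals for consecutive point quadruples (M-3,), degrees; NaN where undefined."""
        m = self.n_points
        if m < 4:
            return np.empty(0)
        b = self.segment_vectors()
        b1, b2, b3 = b[:-2], b[1:-1], b[2:]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = b2 / nb2[:, None]
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(u, n1), n2)
        out = np.degrees(np.arctan2(y, x))
        bad = (np.linalg.norm(n1, axis=1) <= _COLLINEAR_TOL) | (
            np.linalg.norm(n2, axis=1) <= _COLLINEAR_TOL
        ) | (nb2 == 0.0)
        out[bad] = np.nan
        return out

    def internal_coordinates(self) -> np.ndarray:
        """Concatenated (bonds, planar angles, dihedrals) vector for audits."""
        return np.concatenate(
            [self.bond_lengths(), self.planar_angles(), self.dihedral_angles()]
        )

    def internal_coordinate_delta(self, other: "Chain") -> np.ndarray:
        """Elementwise |change| of the internal-coordinate vector against
        `other`, with dihedral entries compared modulo 360 (a value crossing
        the +-180 cut is not a change).  NaN entries (undefined angles on
        either side) compare as 0 when both are NaN."""
        a = self.internal_coordinates()
        b = other.internal_coordinates()
        d = np.abs(a - b)
        n_dih = len(self.dihedral_angles())
        if n_dih:
            dd = d[-n_dih:]
            d[-n_dih:] = np.minimum(dd, 360.0 - dd)
        both_nan = np.isnan(a) & np.isnan(b)
        d[both_nan] = 0.0
        return d

    # -- free/frozen masks ---------------------------------------------------

    def free_segments(self) -> np.ndarray:
        """Mask over segments: True where the segment links two beads (a bond)."""
        owner = self.point_bead_index()
        return owner[:-1] != owner[1:]

    def free_vertices(self) -> np.ndarray:
        """Mask over interior vertices: True unless the vertex is a rigid-bead
        centroid with both arms inside the same bead."""
        owner = self.point_bead_index()
        same = (owner[:-2] == owner[1:-1]) & (owner[1:-1] == owner[2:])
        return ~same

    def segment_bead_pair(self, j: int) -> tuple[int, int]:
        """Bead indices on either side of segment j (equal if internal)."""
        owner = self.point_bead_index()
        return int(owner[j]), int(owner[j + 1])


# ---------------------------------------------------------------------------
# bead sizing


def bead_radius_from_contacts(
    block,
    *,
    r_ref: float = 60.0,
    l_ref: float = 1e5,
    c_ref: float = 10.0,
    c_floor: float = 1.0,
) -> float:
    """Starting bead radius from a diagonal block of the contact matrix.

    Many contacts between fragments of the same locus mean a compact, hence
    small, bead; few internal contacts mean a loosely packed, large bead.
    The concrete law is a cube-root volume argument::

        r = r_ref * (L / l_ref)**(1/3) * (c_ref / max(c, c_floor))**(1/3)

    with L the genomic span of the block in bp and c its mean off-diagonal
    count per bin pair (the diagonal entry itself for a single-bin block).
    Strictly increasing in L, strictly decreasing in c.
    """
    counts = np.asarray(block.counts, dtype=float)
    n = counts.shape[0]
    if n == 0:
        raise ValueError("empty block")
    span_bp = float(block.bins["end_bp"].iloc[-1] - block.bins["start_bp"].iloc[0])
    if n == 1:
        c = float(counts[0, 0])
    else:
        off = counts.sum() - np.trace(counts)
        c = float(off / (n * (n - 1)))
    c = max(c, c_floor)
    return float(r_ref * (span_bp / l_ref) ** (1.0 / 3.0) * (c_ref / c) ** (1.0 / 3.0))


# ---------------------------------------------------------------------------
# constraints


@dataclass(frozen=True)
class ConstraintSet:
    """Geometric/biological constraints on a chain.

    min_pair_dist : steric exclusion between non-adjacent beads (nm); the
        effective bound for a pair is max(min_pair_dist, r_i + r_j).
    max_pair_dist : nuclear-size bound on any pairwise distance (nm).
    max_curvature_deg : bound on chain bending at free hinges.  Under the
        default convention "bend" the bending angle is 180 - psi (a straight
        chain bends by 0); convention "psi" bounds the planar angle itself.
    bond_range : (min, max) in nm applied to every bond, or None to derive
        per-bond ranges as bond_scale x (r_i + r_j) for the flanking beads.
    bond_scale : the (lo, hi) multipliers used when bond_range is None.
    """

    min_pair_dist: float = 120.0
    max_pair_dist: float = 10000.0
    max_curvature_deg: float = 100.0
    bond_range: tuple[float, float] | None = None
    bond_scale: tuple[float, float] = (0.8, 1.2)
    curvature_convention: str = "bend"

    def __post_init__(self):
        if self.min_pair_dist <= 0 or self.max_pair_dist <= 0:
            raise ValueError("distance bounds must be positive")
        if self.min_pair_dist >= self.max_pair_dist:
            raise ValueError("min_pair_dist must be below max_pair_dist")
        if not (0.0 < self.max_curvature_deg <= 180.0):
            raise ValueError("max_curvature_deg must lie in (0, 180]")
        if self.curvature_convention not in ("bend", "psi"):
            raise ValueError("curvature_convention must be 'bend' or 'psi'")
        if self.bond_range is not None and not (0 <= self.bond_range[0] < self.bond_range[1]):
            raise ValueError("bond_range must satisfy 0 <= min < max")

    def bond_bounds(self, chain: Chain) -> np.ndarray:
        """(n_segments, 2) lower/upper bond bounds; frozen segments get (-inf, inf)."""
        m = chain.n_points - 1
        out = np.empty((m, 2))
        out[:, 0] = -np.inf
        out[:, 1] = np.inf
        free = chain.free_segments()
        if self.bond_range is not None:
            out[free, 0] = self.bond_range[0]
            out[free, 1] = self.bond_range[1]
            return out
        owner = chain.point_bead_index()
        rsum = chain.radii[owner[:-1]] + chain.radii[owner[1:]]
        out[free, 0] = self.bond_scale[0] * rsum[free]
        out[free, 1] = self.bond_scale[1] * rsum[free]
        return out


@dataclass(frozen=True)
class Violation:
    kind: str  # "steric" | "span" | "curvature" | "bond"
    indices: tuple[int, ...]
    value: float
    bound: float


@dataclass
class ConstraintReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def __iter__(self):
        return iter(self.violations)

    def of_kind(self, kind: str) -> list[Violation]:
        return [v for v in self.violations if v.kind == kind]


def check_constraints(chain: Chain, constraints: ConstraintSet) -> ConstraintReport:
    """Exhaustive feasibility report; an empty report means the chain is feasible.

    Checks, in order: steric clashes between non-adjacent bead centroids,
    the nuclear-size bound on every centroid pair, curvature at every free
    hinge of the polyline, and every bond against its range.
    """
    report = ConstraintReport()
    cent = chain.centroids
    n = chain.n_beads
    if n >= 2:
        diff = cent[:, None, :] - cent[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        iu, ju = np.triu_indices(n, k=1)
        d = dist[iu, ju]
        nonadj = (ju - iu) > 1
        steric_bound = np.maximum(
            constraints.min_pair_dist, chain.radii[iu] + chain.radii[ju]
        )
        bad = nonadj & (d < steric_bound)
        for i, j, dd, bb in zip(iu[bad], ju[bad], d[bad], steric_bound[bad]):
            report.violations.append(Violation("steric", (int(i), int(j)), float(dd), float(bb)))
        far = d > constraints.max_pair_dist
        for i, j, dd in zip(iu[far], ju[far], d[far]):
            report.violations.append(
                Violation("span", (int(i), int(j)), float(dd), constraints.max_pair_dist)
            )
    psi = chain.planar_angles()
    freev = chain.free_vertices()
    for v in np.nonzero(freev)[0]:
        val = psi[v]
        if np.isnan(val):
            continue
        if constraints.curvature_convention == "bend":
            bend = 180.0 - val
            if bend > constraints.max_curvature_deg + 1e-9:
                report.violations.append(
                    Violation("curvature", (int(v) + 1,), float(bend), constraints.max_curvature_deg)
                )
        else:
            if val > constraints.max_curvature_deg + 1e-9:
                report.violations.append(
                    Violation("curvature", (int(v) + 1,), float(val), constraints.max_curvature_deg)
                )
    lengths = chain.bond_lengths()
    bounds = constraints.bond_bounds(chain)
    for j in np.nonzero(chain.free_segments())[0]:
        lo, hi = bounds[j]
        if lengths[j] < lo - 1e-9:
            report.violations.append(Violation("bond", (int(j),), float(lengths[j]), float(lo)))
        elif lengths[j] > hi + 1e-9:
            report.violations.append(Violation("bond", (int(j),), float(lengths[j]), float(hi)))
    return report


def chain_span(chain: Chain) -> float:
    """Maximum pairwise centroid distance (nm) -- the chain's overall size."""
    cent = chain.centroids
    if len(cent) < 2:
        return 0.0
    diff = cent[:, None, :] - cent[None, :, :]
    return float(np.linalg.norm(diff, axis=-1).max())


# ---------------------------------------------------------------------------
# initial configuration


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _bend_direction(prev_dir: np.ndarray, bend_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector at `bend_deg` from prev_dir, rolled by `azimuth_deg` about it."""
    # orthonormal frame around prev_dir
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, prev_dir)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(prev_dir, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(prev_dir, e1)
    t = math.radians(bend_deg)
    p = math.radians(azimuth_deg)
    return (
        math.cos(t) * prev_dir
        + math.sin(t) * (math.cos(p) * e1 + math.sin(p) * e2)
    )


def build_initial_chain(
    beads_spec: Sequence[tuple[float, tuple[int, int]]],
    constraints: ConstraintSet,
    rng: np.random.Generator,
    *,
    max_bead_retries: int = 200,
    max_restarts: int = 30,
    bias_targets: Sequence[np.ndarray] | None = None,
    bend_sigma: float | None = 30.0,
    bond_quantiles: tuple[float, float] = (0.0, 1.0),
) -> Chain:
    """Grow a feasible finest-resolution chain by constrained self-avoiding growth.

    beads_spec is a list of (radius_nm, genomic_span).  Beads are placed
    one by one: bond lengths uniform in the allowed range, a random bend at
    each new vertex, with rejection of placements that violate steric
    exclusion or the nuclear-size bound against the partial chain.
    Deterministic given `rng`.

    By default bends are half-normal with scale `bend_sigma` degrees,
    capped at the curvature bound: starts are randomized but not
    pre-folded, so compactness in the final ensemble comes from the data
    fit rather than from the initializer (a freely-rotating-chain start
    with modest persistence).  Pass ``bend_sigma=None`` for bends uniform
    up to the curvature cap (maximally folded growth); `bond_quantiles`
    restricts bond draws to a sub-interval of the allowed range.  The
    synthetic-data generator uses those two knobs, plus `bias_targets`
    (one 3-vector or None per bead, pulling candidate placements toward a
    target), to grow compact domains.

    Raises InfeasibleChainError naming the stuck bead after the configured
    number of retries and restarts.
    """
    radii = np.array([r for r, _ in beads_spec], dtype=float)
    spans = [s for _, s in beads_spec]
    n = len(radii)
    if n == 0:
        raise ValueError("beads_spec is empty")
    if constraints.curvature_convention == "bend":
        bend_lo, bend_hi = 0.0, min(constraints.max_curvature_deg, 179.0)
    else:  # psi convention: planar angle itself bounded above
        bend_lo, bend_hi = max(180.0 - constraints.max_curvature_deg, 0.0), 179.0

    def _draw_bend() -> float:
        if bend_sigma is None:
            return float(rng.uniform(bend_lo, bend_hi))
        b = bend_lo + abs(float(rng.normal(0.0, bend_sigma)))
        return min(b, bend_hi)

    stuck = 0
    for _ in range(max_restarts):
        pts = np.zeros((n, 3))
        ok = True
        prev_dir = _random_unit(rng)
        for k in range(1, n):
            if constraints.bond_range is not None:
                lo, hi = constraints.bond_range
            else:
                rsum = radii[k - 1] + radii[k]
                lo, hi = constraints.bond_scale[0] * rsum, constraints.bond_scale[1] * rsum
            q_lo = lo + bond_quantiles[0] * (hi - lo)
            q_hi = lo + bond_quantiles[1] * (hi - lo)
            placed = False
            for _try in range(max_bead_retries):
                blen = rng.uniform(q_lo, q_hi)
                if k == 1:
                    direction = prev_dir if _try == 0 else _random_unit(rng)
                else:
                    direction = _bend_direction(prev_dir, _draw_bend(), rng.uniform(0.0, 360.0))
                if bias_targets is not None and bias_targets[k] is not None:
                    # pick the better of two candidate directions
                    if k == 1:
                        alt = _random_unit(rng)
                    else:
                        alt = _bend_direction(prev_dir, _draw_bend(), rng.uniform(0.0, 360.0))
                    cand1 = pts[k - 1] + blen * direction
                    cand2 = pts[k - 1] + blen * alt
                    t = np.asarray(bias_targets[k], dtype=float)
                    if np.linalg.norm(cand2 - t) < np.linalg.norm(cand1 - t):
                        direction = alt
                cand = pts[k - 1] + blen * direction
                if k >= 2:
                    d = np.linalg.norm(pts[: k - 1] - cand, axis=1)
                    bound = np.maximum(constraints.min_pair_dist, radii[: k - 1] + radii[k])
                    if np.any(d < bound):
                        continue
                if k >= 1:
                    d_all = np.linalg.norm(pts[:k] - cand, axis=1)
                    if np.any(d_all > constraints.max_pair_dist):
                        continue
                pts[k] = cand
                prev_dir = direction
                placed = True
                break
            if not placed:
                stuck = k
                ok = False
                break
        if ok:
            chain = Chain.from_centroids(pts, radii, spans)
            if check_constraints(chain, constraints).ok:
                return chain
    raise InfeasibleChainError(stuck)


# ---------------------------------------------------------------------------
# serialization


_TABLE_COLUMNS = [
    "bead", "start_bp", "end_bp", "radius_nm",
    "cx_nm", "cy_nm", "cz_nm",
    "sx_nm", "sy_nm", "sz_nm",
    "ex_nm", "ey_nm", "ez_nm",
]


def write_chain_table(chain: Chain, path) -> None:
    """Plain-text TSV: one row per bead with centroid, start and end arm points."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TABLE_COLUMNS) + "\n")
        for k, b in enumerate(chain.beads):
            row = [str(k), str(chain.spans[k][0]), str(chain.spans[k][1]),
                   format(b.radius, ".17g")]
            for p in (b.centroid, b.start, b.end):
                row.extend(format(x, ".17g") for x in p)
            fh.write("\t".join(row) + "\n")


def read_chain_table(path) -> Chain:
    beads = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != len(_TABLE_COLUMNS):
                raise ValueError(f"malformed chain-table row: {line!r}")
            c = np.array([float(f[4]), float(f[5]), float(f[6])])
            s = np.array([float(f[7]), float(f[8]), float(f[9])])
            e = np.array([float(f[10]), float(f[11]), float(f[12])])
            beads.append(Bead(s, c, e, float(f[3]), (int(f[1]), int(f[2]))))
    if not beads:
        raise ValueError(f"no beads found in {path}")
    return Chain.from_beads(beads)


def write_pdb(chain: Chain, path) -> None:
    """Pseudo-atom PDB for molecular viewers: one CA per bead centroid,
    residue number = bead index + 1, B-factor = bead radius.  Coordinates
    are written in Angstrom-sized columns but remain in nm / 10 to fit the
    fixed-width fields."""
    with open(path, "w") as fh:
        for k, b in enumerate(chain.beads):
            x, y, z = b.centroid / 10.0
            fh.write(
                "ATOM  {serial:5d}  CA  BEA A{res:4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}\n".format(
                    serial=k + 1, res=(k % 9999) + 1, x=x, y=y, z=z,
                    occ=1.0, bf=min(b.radius, 999.99),
                )
            )
        for k in range(chain.n_beads - 1):
            fh.write("CONECT{:5d}{:5d}\n".format(k + 1, k + 2))
        fh.write("END\n")
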