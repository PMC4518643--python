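"""Recursive multi-resolution reconstruction.

Each diagonal block (TAD) of the contact matrix is reconstructed
independently at the current resolution; every reconstructed subchain is
then abstracted as a single rigid bead -- its start point, geometric
centroid and end point, plus an effective size -- the matrix is binned so
each block becomes a single entry, and the procedure recurses on the
coarser matrix.  The central structural assumption is that a subchain's
internal configuration is not modified by its interactions with the other
domains: hierarchical composition places each child rigidly onto its
coarse bead, preserving every intra-child distance exactly.

Coarse-level feasibility is checked on the *composed* finest-resolution
structure: because children ride rigidly on their beads, a coarse
configuration fully determines the fine one, so the fine constraint set
(steric exclusion, nuclear span, curvature, bond ranges) can be evaluated
directly during coarse sampling.  Every structure this module emits
therefore satisfies the finest-level constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .annealing import AnnealingSchedule, AnnealTrace, anneal, data_fit
from .chain import (
    Bead,
    Chain,
    ConstraintSet,
    InfeasibleChainError,
    bead_radius_from_contacts,
    build_initial_chain,
    check_constraints,
)
from .contact_data import (
    BlockPartition,
    ContactMatrix,
    FitSet,
    extract_blocks,
    bin_matrix,
    select_fit_set,
)
from .quaternions import Quaternion

__all__ = [
    "RigidTransform",
    "HierarchyNode",
    "ReconstructionResult",
    "summarize_subchain",
    "subchain_radius",
    "rigid_align_triple",
    "compose_hierarchy",
    "reconstruct_recursive",
]

_CONGRUENCE_TOL = 1e-6


# ---------------------------------------------------------------------------
# rigid transforms


def _quaternion_from_matrix(R: np.ndarray) -> Quaternion:
    """Shepperd's method; returns a unit quaternion for a proper rotation."""
    t = np.trace(R)
    if t > 0:
        s = math.sqrt(t + 1.0) * 2.0
        return Quaternion(
            0.25 * s,
            (R[2, 1] - R[1, 2]) / s,
            (R[0, 2] - R[2, 0]) / s,
            (R[1, 0] - R[0, 1]) / s,
        ).normalized()
    i = int(np.argmax(np.diag(R)))
    j, k = (i + 1) % 3, (i + 2) % 3
    s = math.sqrt(max(1.0 + R[i, i] - R[j, j] - R[k, k], 0.0)) * 2.0
    q = [0.0, 0.0, 0.0, 0.0]
    q[0] = (R[k, j] - R[j, k]) / s
    q[1 + i] = 0.25 * s
    q[1 + j] = (R[j, i] + R[i, j]) / s
    q[1 + k] = (R[k, i] + R[i, k]) / s
    return Quaternion(*q).normalized()


@dataclass(frozen=True)
class RigidTransform:
    """x -> R x + t, stored as a rotation quaternion plus translation."""

    rotation: Quaternion
    translation: np.ndarray

    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix().T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        R = self.matrix()
        return RigidTransform(
            self.rotation * other.rotation,
            R @ other.translation + self.translation,
        )


def _axis_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    from .quaternions import from_axis_angle

    return from_axis_angle(axis, math.degrees(angle_rad)).as_matrix()


def rigid_align_triple(
    source: np.ndarray,
    target: np.ndarray,
    *,
    roll_reference: np.ndarray | None = None,
) -> RigidTransform:
    """Rigid transform mapping the (start, centroid, end) triple `source`
    onto the congruent triple `target`.

    Congruence (equal arm lengths and arm angle, guaranteed upstream by
    bead rigidity) is verified; a mismatch beyond tolerance raises
    ValueError.  For collinear triples the rotation is free to roll about
    the line; the roll is fixed deterministically so that the image of
    `roll_reference` (default: the lab x-axis) is as close to the lab
    z-axis as possible.
    """
    src = np.asarray(source, dtype=float).reshape(3, 3)
    tgt = np.asarray(target, dtype=float).reshape(3, 3)
    # congruence: compare the three pairwise distances
    for a, b in ((0, 1), (1, 2), (0, 2)):
        ds = np.linalg.norm(src[a] - src[b])
        dt = np.linalg.norm(tgt[a] - tgt[b])
        if abs(ds - dt) > _CONGRUENCE_TOL * max(1.0, ds, dt):
            raise ValueError(
                f"triples not congruent: |p{a}p{b}| = {ds:.6g} vs {dt:.6g}"
            )
    cs = src.mean(axis=0)
    ct = tgt.mean(axis=0)
    P = src - cs
    Q = tgt - ct
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    # collinear (or degenerate) source: a roll about the target line is free
    scale = max(float(S[0]), 1e-300)
    if S[1] / scale < 1e-8:
        axis = Q[2] - Q[0]
        axis_norm = np.linalg.norm(axis)
        if axis_norm > 0:
            axis = axis / axis_norm
            ref = np.array([1.0, 0.0, 0.0]) if roll_reference is None else (
                np.asarray(roll_reference, dtype=float)
            )
            img = R @ ref
            zhat = np.array([0.0, 0.0, 1.0])
            # project the image of ref and z onto the plane normal to axis
            img_p = img - np.dot(img, axis) * axis
            z_p = zhat - np.dot(zhat, axis) * axis
            if np.linalg.norm(img_p) > 1e-12 and np.linalg.norm(z_p) > 1e-12:
                ang = math.atan2(
                    float(np.dot(np.cross(img_p, z_p), axis)),
                    float(np.dot(img_p, z_p)),
                )
                R = _axis_rotation(axis, ang) @ R
        else:
            R = np.eye(3)  # single point: translation only
    t = ct - R @ cs
    return RigidTransform(_quaternion_from_matrix(R), t)


# ---------------------------------------------------------------------------
# summarization


def subchain_radius(config: Chain) -> float:
    """Effective size of a reconstructed subchain: half its radius of
    gyration plus the mean child-bead radius."""
    cent = config.centroids
    rg = float(np.sqrt(np.mean(np.sum((cent - cent.mean(axis=0)) ** 2, axis=1))))
    return 0.5 * rg + float(np.mean(config.radii))


def summarize_subchain(config: Chain) -> Bead:
    """Abstract a reconstructed subchain as one rigid bead.

    centroid = mean of the bead centroids, start = the first bead's start
    point, end = the last bead's end point; the arm lengths and arm angle
    are frozen from here on.
    """
    cent = config.centroids
    centroid = cent.mean(axis=0)
    start = config.points[0]
    end = config.points[-1]
    span = (config.spans[0][0], config.spans[-1][1])
    return Bead(start, centroid, end, subchain_radius(config), span)


def _ls_plane_normal(points: np.ndarray) -> np.ndarray:
    """Least-squares plane normal of a point cloud (unit vector; x-hat fallback)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return np.array([1.0, 0.0, 0.0])
    X = pts - pts.mean(axis=0)
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    n = Vt[-1]
    norm = np.linalg.norm(n)
    return n / norm if norm > 0 else np.array([1.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# composition


def compose_hierarchy(lowres_chain: Chain, children: list[Chain]) -> Chain:
    """Place each child rigidly onto its coarse bead and concatenate.

    Child k's (start, centroid, end) summary triple is mapped onto bead k's
    triple; every intra-child internal coordinate is untouched by the
    rigid motion.  Raises ValueError naming the bead on a congruence
    failure (bead rigidity violated upstream).
    """
    if lowres_chain.n_beads != len(children):
        raise ValueError(
            f"{len(children)} children for {lowres_chain.n_beads} coarse beads"
        )
    placed: list[Chain] = []
    for k, child in enumerate(children):
        src = summarize_subchain(child).triple
        tgt = lowres_chain.bead(k).triple
        try:
            T = rigid_align_triple(
                src, tgt, roll_reference=_ls_plane_normal(child.centroids)
            )
        except ValueError as exc:
            raise ValueError(f"bead {k}: {exc}") from exc
        moved = child.copy()
        moved.points = T.apply(child.points)
        placed.append(moved)
    return _concatenate(placed)


def _concatenate(chains: list[Chain]) -> Chain:
    pts = []
    bead_points = []
    radii = []
    spans = []
    offset = 0
    for ch in chains:
        pts.append(ch.points)
        for (i_s, i_c, i_e) in ch.bead_points:
            bead_points.append((i_s + offset, i_c + offset, i_e + offset))
        radii.extend(ch.radii.tolist())
        spans.extend(ch.spans)
        offset += ch.n_points
    return Chain(np.vstack(pts), bead_points, radii, spans)


class ComposedChecker:
    """Feasibility test for a coarse chain: compose the rigid children and
    run the full finest-level constraint check on the result."""

    def __init__(self, children: list[Chain], fine_constraints: ConstraintSet):
        self.children = children
        self.fine_constraints = fine_constraints

    def compose(self, coarse_chain: Chain) -> Chain:
        return compose_hierarchy(coarse_chain, self.children)

    def __call__(self, coarse_chain: Chain) -> bool:
        try:
            fine = self.compose(coarse_chain)
        except ValueError:
            return False
        return check_constraints(fine, self.fine_constraints).ok


# ---------------------------------------------------------------------------
# coarse chain initialisation


def _direction_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u to unit vector v (minimal angle)."""
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    axis = np.cross(u, v)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180 deg about any perpendicular
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return _axis_rotation(perp, math.pi)
    return _axis_rotation(axis, math.atan2(n, c))


def _grow_coarse_chain(
    children: list[Chain],
    rng: np.random.Generator,
    checker: ComposedChecker,
    *,
    max_attempts: int = 300,
) -> Chain:
    """Initial coarse configuration: children chained seam-aligned.

    Each child is oriented so that its first finest-level bond continues
    the incoming seam bond (seam bending starts at zero), with a random
    roll about that direction and a small random tilt; the outgoing seam
    direction follows the placed child's last bond.  Candidates are
    rejected against the composed finest-level constraint check, with the
    tilt shrinking over attempts.
    """
    summaries = [summarize_subchain(ch) for ch in children]
    n = len(summaries)

    def _unit_or(v, fallback):
        nv = np.linalg.norm(v)
        return v / nv if nv > 0 else np.asarray(fallback, dtype=float)

    for attempt in range(max_attempts):
        tilt_scale = 25.0 * (0.75 ** (attempt // 10))
        beads: list[Bead] = []
        heading = None
        prev_end = None
        for k, (s, child) in enumerate(zip(summaries, children)):
            triple = s.triple
            if k == 0:
                beads.append(Bead(triple[0], triple[1], triple[2], s.radius, s.genomic_span))
                out_vec = child.points[-1] - child.points[-2] if child.n_points > 1 else None
                heading = _unit_or(
                    out_vec if out_vec is not None else triple[2] - triple[0],
                    [1.0, 0.0, 0.0],
                )
                prev_end = triple[2]
                continue
            # seam bond: fine rule between the terminal child beads
            fc = checker.fine_constraints
            if fc.bond_range is not None:
                bond = rng.uniform(*fc.bond_range)
            else:
                r_prev = float(children[k - 1].radii[-1])
                r_next = float(child.radii[0])
                lo, hi = fc.bond_scale
                bond = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo)) * (
                    r_prev + r_next
                )
            tilt = math.radians(rng.uniform(0.0, tilt_scale))
            az = rng.uniform(0.0, 2.0 * math.pi)
            perp1 = np.cross(heading, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp1) < 1e-6:
                perp1 = np.cross(heading, [0.0, 1.0, 0.0])
            perp1 /= np.linalg.norm(perp1)
            perp2 = np.cross(heading, perp1)
            d = (
                math.cos(tilt) * heading
                + math.sin(tilt) * (math.cos(az) * perp1 + math.sin(az) * perp2)
            )
            d /= np.linalg.norm(d)
            anchor = prev_end + bond * d
            # orient: first fine bond of the child continues along d
            in_vec = child.points[1] - child.points[0] if child.n_points > 1 else None
            u = _unit_or(in_vec if in_vec is not None else triple[2] - triple[0], d)
            R = _direction_rotation(u, d)
            R = _axis_rotation(d, rng.uniform(0.0, 2.0 * math.pi)) @ R
            moved = (triple - triple[0]) @ R.T + anchor
            beads.append(Bead(moved[0], moved[1], moved[2], s.radius, s.genomic_span))
            out_vec = child.points[-1] - child.points[-2] if child.n_points > 1 else None
            heading = _unit_or(
                (R @ out_vec) if out_vec is not None else (moved[2] - moved[0]), d
            )
            prev_end = moved[2]
        coarse = Chain.from_beads(beads)
        if checker(coarse):
            return coarse
    raise InfeasibleChainError(n - 1, "could not place coarse beads feasibly")


# ---------------------------------------------------------------------------
# the recursive procedure


@dataclass
class HierarchyNode:
    """Reconstruction record for one block at one level."""

    level: int
    block: int
    block_range: tuple[int, int]
    saved_configs: list[Chain]
    phi_values: list[float]
    traces: list[AnnealTrace]
    summary_bead: Bead | None = None
    #: the annealed coarse (one-bead-per-child) chains at levels > 0;
    #: saved_configs always hold finest-resolution structures
    lowres_configs: list[Chain] | None = None

    @property
    def representative(self) -> Chain:
        best = int(np.argmin(self.phi_values))
        return self.saved_configs[best]

    @property
    def phi_best(self) -> float:
        return float(min(self.phi_values))


@dataclass
class ReconstructionResult:
    """Finest-resolution structure plus the full multiscale bookkeeping.

    phi_initial_total / phi_best_total are the data fit at the data's own
    resolution (summed over the level-0 fit sets), before and after
    annealing.  Coarser levels optimise their own binned objectives -- a
    placement device whose weights aggregate many finest-level counts --
    so they are reported per-trace but not mixed into the headline Phi.
    """

    chain: Chain
    nodes: list[HierarchyNode]
    seed: int
    phi_initial_total: float
    phi_best_total: float

    @property
    def traces(self) -> list[AnnealTrace]:
        return [t for node in self.nodes for t in node.traces]


def _filter_weak_block_pairs(
    block: ContactMatrix, fine_resolution_bp: int, gamma: float = 0.2
) -> ContactMatrix:
    """Zero out binned block-pair counts explicable as background.

    High counts imply proximity, but low counts imply nothing; a weak
    positive count must not pull two domains together.  A block pair
    (k, l) keeps its count only if the mean count per cross pair,
    n_kl / (s_k * s_l), reaches `gamma` times the within-block per-pair
    rate (median over blocks of n_kk / s_k^2), with s the number of
    finest-resolution bins per block.  Background rates in contact data
    sit one to two orders of magnitude below within-domain rates, so the
    default gamma = 0.2 separates genuine interfaces from noise without
    touching them.
    """
    sizes = np.round(
        (block.bins["end_bp"].to_numpy() - block.bins["start_bp"].to_numpy())
        / fine_resolution_bp
    ).astype(int)
    sizes = np.maximum(sizes, 1)
    diag = np.diag(block.counts)
    rate = float(np.median(diag / sizes.astype(float) ** 2))
    if rate <= 0:
        return block
    floor = gamma * rate * np.outer(sizes, sizes).astype(float)
    counts = block.counts.copy()
    off = ~np.eye(len(counts), dtype=bool)
    counts[off & (counts < floor)] = 0.0
    return ContactMatrix(counts, block.resolution_bp, block.bins)


def _fine_block_chain(
    block: ContactMatrix,
    constraints: ConstraintSet,
    rng: np.random.Generator,
    *,
    r_ref: float,
    c_ref: float,
    c_floor: float,
) -> Chain:
    """Initial finest-level chain for one block: one spherical bead per bin,
    sized from the bin's internal (diagonal) contacts, grown self-avoiding."""
    spec = []
    for i in range(block.n_bins):
        sub = ContactMatrix(
            block.counts[i : i + 1, i : i + 1].copy(),
            block.resolution_bp,
            block.bins.iloc[i : i + 1].reset_index(drop=True),
        )
        span = (int(sub.bins["start_bp"].iloc[0]), int(sub.bins["end_bp"].iloc[0]))
        l_ref = float(block.resolution_bp)
        r = bead_radius_from_contacts(
            sub, r_ref=r_ref, l_ref=l_ref, c_ref=c_ref, c_floor=c_floor
        )
        spec.append((r, span))
    return build_initial_chain(spec, constraints, rng)


def reconstruct_recursive(
    matrix: ContactMatrix,
    partitions: list[BlockPartition],
    *,
    constraints: ConstraintSet | None = None,
    schedule: AnnealingSchedule | None = None,
    fit_k_high: int = 20,
    fit_k_low: int = 40,
    exclude_adjacent: bool = True,
    r_ref: float = 60.0,
    c_floor: float = 1.0,
    n_block_replicates: int = 1,
    seed: int = 0,
) -> ReconstructionResult:
    """Run the full recursive procedure on a contact matrix.

    partitions[0] tiles the input matrix; partitions[l] tiles the matrix
    binned through the first l partitions.  If the last partition leaves
    more than one block, an implicit final level with a single all-covering
    block is appended, so the default call with one TAD partition performs
    the two-level reconstruction.  Per-block fit sets take the
    `fit_k_high` largest counts; coarser levels use `fit_k_low`.  Blocks at
    each level are annealed independently with seeds spawned from `seed`
    (parallelizable; serial order is immaterial to the result).
    """
    if constraints is None:
        constraints = ConstraintSet()
    if schedule is None:
        schedule = AnnealingSchedule()
    if not partitions:
        raise ValueError("at least one partition level is required")
    for p in partitions:
        if p.n_blocks == 0:
            raise ValueError("empty partition")
    master = np.random.SeedSequence(seed)
    current = matrix
    children: list[Chain] | None = None
    nodes: list[HierarchyNode] = []
    phi_init_total = 0.0
    phi_best_total = 0.0

    # medians of per-bin diagonal density for bead sizing at the finest level
    diag = np.diag(matrix.counts)
    c_ref = float(max(np.median(diag), c_floor))

    level_partitions = list(partitions)
    if level_partitions[-1].n_blocks > 1:
        final_n = level_partitions[-1].n_blocks
        level_partitions.append(BlockPartition(((0, final_n),)))

    for level, partition in enumerate(level_partitions):
        if not partition.covers(current):
            raise ValueError(
                f"partition at level {level} does not cover the matrix at that level"
            )
        blocks = extract_blocks(current, partition)
        level_ss = master.spawn(len(blocks))
        k_pairs = fit_k_high if level == 0 else fit_k_low
        new_children: list[Chain] = []
        for b_idx, block in enumerate(blocks):
            block_ss = level_ss[b_idx].spawn(n_block_replicates)
            a, b = partition.blocks[b_idx]
            saved, phis, traces = [], [], []
            lowres: list[Chain] = []
            if block.n_bins == 1 and children is None:
                # single-bin block at the finest level: nothing to sample
                chain = _fine_block_chain(
                    block, constraints, np.random.default_rng(block_ss[0]),
                    r_ref=r_ref, c_ref=c_ref, c_floor=c_floor,
                )
                saved, phis, traces = [chain], [0.0], []
            else:
                if block.n_bins == 1:
                    fitset = FitSet(())
                elif children is None:
                    fitset = select_fit_set(block, k_pairs, exclude_adjacent)
                else:
                    # coarse levels: adjacent block pairs carry genuine
                    # proximity information (they dominate the strongest
                    # binned counts), and background-level pairs are
                    # excluded from L rather than allowed to pull distant
                    # domains together
                    filtered = _filter_weak_block_pairs(block, matrix.resolution_bp)
                    fitset = select_fit_set(filtered, k_pairs, exclude_adjacent=False)
                for rep_ss in block_ss:
                    rng = np.random.default_rng(rep_ss)
                    if children is None:
                        chain0 = _fine_block_chain(
                            block, constraints, rng,
                            r_ref=r_ref, c_ref=c_ref, c_floor=c_floor,
                        )
                        feasible = None
                        my_children = None
                    else:
                        my_children = [n.representative for n in prev_nodes[a:b]]
                        checker = ComposedChecker(my_children, constraints)
                        chain0 = _grow_coarse_chain(my_children, rng, checker)
                        feasible = checker
                    best, trace = anneal(
                        chain0, fitset, constraints, schedule, rng, feasible=feasible
                    )
                    if my_children is not None:
                        lowres.append(best)
                        best = compose_hierarchy(best, my_children)
                    saved.append(best)
                    phis.append(trace.phi_final_best)
                    traces.append(trace)
                if level == 0:
                    # headline Phi follows the representative (best) replicate
                    winner = int(np.argmin(phis))
                    phi_init_total += traces[winner].phi_initial
                    phi_best_total += float(phis[winner])
            node = HierarchyNode(
                level, b_idx, (a, b), saved, phis, traces,
                lowres_configs=lowres or None,
            )
            node.summary_bead = summarize_subchain(node.representative)
            nodes.append(node)
            new_children.append(node.representative)
        prev_nodes = [n for n in nodes if n.level == level]
        children = new_children
        if len(blocks) > 1:
            current = bin_matrix(current, partition)

    final = children[0]
    report = check_constraints(final, constraints)
    if not report.ok:
        raise RuntimeError(
            f"emitted structure violates constraints: {report.violations[:3]}"
        )
    return ReconstructionResult(final, nodes, seed, phi_init_total, phi_best_total)
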