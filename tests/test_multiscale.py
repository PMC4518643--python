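import numpy as np
import pytest

from quatfold.annealing import AnnealingSchedule, anneal
from quatfold.chain import Bead, Chain, ConstraintSet, check_constraints
from quatfold.contact_data import BlockPartition, ContactMatrix, select_fit_set
from quatfold.multiscale import (
    ComposedChecker,
    compose_hierarchy,
    reconstruct_recursive,
    rigid_align_triple,
    summarize_subchain,
)
from quatfold.simulate import SimulationSpec, make_tad_fixture

from conftest import random_chain


def _dist_matrix(points):
    return np.linalg.norm(points[:, None] - points[None, :], axis=-1)


class TestSummarize:
    def test_single_degenerate_bead(self):
        ch = Chain.from_centroids([[3.0, 4.0, 5.0]], [60.0])
        b = summarize_subchain(ch)
        assert b.degenerate
        assert np.allclose(b.centroid, [3, 4, 5])

    def test_collinear_equally_spaced(self):
        ch = Chain.from_centroids(
            [[0, 0, 0], [120.0, 0, 0], [240.0, 0, 0]], [60.0] * 3
        )
        b = summarize_subchain(ch)
        assert np.allclose(b.centroid, [120.0, 0, 0])
        assert np.allclose(b.start, [0, 0, 0])
        assert np.allclose(b.end, [240.0, 0, 0])

    def test_centroid_is_coordinate_mean(self):
        ch = random_chain(10, seed=7)
        b = summarize_subchain(ch)
        assert np.allclose(b.centroid, ch.centroids.mean(axis=0), atol=1e-12)

    def test_genomic_span_covers_children(self):
        ch = random_chain(5, seed=9)
        b = summarize_subchain(ch)
        assert b.genomic_span == (ch.spans[0][0], ch.spans[-1][1])


class TestRigidAlign:
    def test_identical_triples_identity(self):
        t = np.array([[0, 0, 0], [50.0, 40, 0], [100.0, 0, 0]])
        T = rigid_align_triple(t, t)
        assert np.allclose(T.apply(t), t, atol=1e-9)
        assert np.allclose(T.matrix(), np.eye(3), atol=1e-9)

    def test_pure_translation(self):
        t = np.array([[0, 0, 0], [50.0, 40, 0], [100.0, 0, 0]])
        shift = np.array([10.0, -20.0, 30.0])
        T = rigid_align_triple(t, t + shift)
        assert np.allclose(T.translation, shift, atol=1e-9)
        assert np.allclose(T.matrix(), np.eye(3), atol=1e-9)

    def test_round_trip_random_rigid_motion(self, rng):
        from quatfold.quaternions import from_axis_angle, rotate_points

        for _ in range(20):
            t = rng.normal(size=(3, 3)) * 100
            q = from_axis_angle(rng.normal(size=3), rng.uniform(0, 360))
            moved = rotate_points(q, t, rng.normal(size=3) * 50) + rng.normal(size=3) * 200
            T = rigid_align_triple(t, moved)
            assert np.abs(T.apply(t) - moved).max() < 1e-9

    def test_collinear_roll_is_deterministic(self):
        t = np.array([[0, 0, 0], [60.0, 0, 0], [120.0, 0, 0]])
        tgt = t + [5.0, 5.0, 5.0]
        T1 = rigid_align_triple(t, tgt, roll_reference=[0.0, 1.0, 0.0])
        T2 = rigid_align_triple(t, tgt, roll_reference=[0.0, 1.0, 0.0])
        assert np.allclose(T1.matrix(), T2.matrix(), atol=1e-12)
        assert np.abs(T1.apply(t) - tgt).max() < 1e-9

    def test_non_congruent_rejected(self):
        a = np.array([[0, 0, 0], [50.0, 0, 0], [100.0, 0, 0]])
        b = np.array([[0, 0, 0], [50.0, 0, 0], [300.0, 0, 0]])
        with pytest.raises(ValueError, match="congruent"):
            rigid_align_triple(a, b)


class TestCompose:
    def _coarse_from(self, children, rng):
        checker = ComposedChecker(children, ConstraintSet())
        from quatfold.multiscale import _grow_coarse_chain

        return _grow_coarse_chain(children, rng, checker)

    def test_identity_placement_returns_child(self):
        child = random_chain(6, seed=41)
        b = summarize_subchain(child)
        coarse = Chain.from_beads([b])
        out = compose_hierarchy(coarse, [child])
        assert np.allclose(out.points, child.points, atol=1e-9)

    def test_children_internally_rigid_after_placement(self):
        children = [random_chain(5, seed=s) for s in (1, 2)]
        coarse = self._coarse_from(children, np.random.default_rng(0))
        out = compose_hierarchy(coarse, children)
        for k, child in enumerate(children):
            placed = out.centroids[5 * k : 5 * (k + 1)]
            assert np.abs(
                _dist_matrix(placed) - _dist_matrix(child.centroids)
            ).max() < 1e-9

    def test_resummarized_children_match_placed_beads(self):
        children = [random_chain(4, seed=s) for s in (3, 4, 5, 6)]
        coarse = self._coarse_from(children, np.random.default_rng(1))
        out = compose_hierarchy(coarse, children)
        at = 0
        for k, child in enumerate(children):
            sub = Chain(
                out.points[at : at + child.n_points],
                [(i, i, i) for i in range(child.n_points)],
                child.radii,
                child.spans,
            )
            at += child.n_points
            again = summarize_subchain(sub)
            assert np.abs(again.triple - coarse.bead(k).triple).max() < 1e-6

    def test_child_count_mismatch_rejected(self):
        child = random_chain(4, seed=8)
        coarse = Chain.from_beads([summarize_subchain(child)])
        with pytest.raises(ValueError, match="children"):
            compose_hierarchy(coarse, [child, child])


class TestReconstructRecursive:
    def test_single_block_equals_direct_anneal(self):
        """Recursion base case: a one-block partition is exactly one anneal."""
        spec = SimulationSpec(n_bins=8, block_sizes=(8,), seed=3)
        matrix, partition, _ = make_tad_fixture(spec)
        sched = AnnealingSchedule(max_sweeps=50, moves_per_sweep=40)
        cons = ConstraintSet()
        res = reconstruct_recursive(
            matrix, [partition], constraints=cons, schedule=sched, seed=42
        )
        # replicate the engine's seeding by hand
        from quatfold.multiscale import _fine_block_chain

        ss = np.random.SeedSequence(42).spawn(1)[0].spawn(1)[0]
        rng = np.random.default_rng(ss)
        diag = np.diag(matrix.counts)
        c_ref = float(max(np.median(diag), 1.0))
        chain0 = _fine_block_chain(
            matrix, cons, rng, r_ref=60.0, c_ref=c_ref, c_floor=1.0
        )
        fs = select_fit_set(matrix, 20, True)
        best, _ = anneal(chain0, fs, cons, sched, rng)
        assert np.array_equal(res.chain.points, best.points)

    def test_two_level_reconstruction_properties(self):
        spec = SimulationSpec(n_bins=12, block_sizes=(4, 4, 4), seed=5)
        matrix, partition, _ = make_tad_fixture(spec)
        sched = AnnealingSchedule(max_sweeps=60, moves_per_sweep=40)
        cons = ConstraintSet()
        res = reconstruct_recursive(
            matrix, [partition], constraints=cons, schedule=sched, seed=7
        )
        assert res.chain.n_beads == 12
        assert check_constraints(res.chain, cons).ok
        # every block's internal distance matrix survives composition exactly
        for node in res.nodes:
            if node.level != 0:
                continue
            a, b = node.block_range
            placed = res.chain.centroids[a:b]
            assert np.abs(
                _dist_matrix(placed) - _dist_matrix(node.representative.centroids)
            ).max() < 1e-9
        # bead count at the coarse level equals the number of blocks
        coarse_nodes = [n for n in res.nodes if n.level == 1]
        assert len(coarse_nodes) == 1
        assert coarse_nodes[0].lowres_configs[0].n_beads == partition.n_blocks
        # and the saved config at that level is the composed fine structure
        assert coarse_nodes[0].representative.n_beads == 12

    def test_seeded_run_is_deterministic(self):
        spec = SimulationSpec(n_bins=12, block_sizes=(6, 6), seed=9)
        matrix, partition, _ = make_tad_fixture(spec)
        sched = AnnealingSchedule(max_sweeps=40, moves_per_sweep=30)
        r1 = reconstruct_recursive(matrix, [partition], schedule=sched, seed=11)
        r2 = reconstruct_recursive(matrix, [partition], schedule=sched, seed=11)
        assert np.array_equal(r1.chain.points, r2.chain.points)
        assert r1.phi_best_total == r2.phi_best_total

    def test_partition_mismatch_rejected(self):
        spec = SimulationSpec(n_bins=12, block_sizes=(6, 6), seed=1)
        matrix, _, _ = make_tad_fixture(spec)
        bad = BlockPartition(((0, 5), (5, 11)))
        with pytest.raises((ValueError,)):
            reconstruct_recursive(matrix, [bad], seed=0)
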