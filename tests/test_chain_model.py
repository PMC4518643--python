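import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quatfold.chain import (
    Bead,
    Chain,
    ConstraintSet,
    InfeasibleChainError,
    bead_radius_from_contacts,
    build_initial_chain,
    chain_span,
    check_constraints,
    dihedral_angle,
    planar_angle,
    read_chain_table,
    write_chain_table,
    write_pdb,
)
from quatfold.contact_data import ContactMatrix

from conftest import random_chain

finite3 = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=3, max_size=3
).map(np.array)


class TestAngles:
    def test_right_angle(self):
        assert planar_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)

    def test_collinear_through(self):
        assert planar_angle((-1, 0, 0), (0, 0, 0), (2, 0, 0)) == pytest.approx(180.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            planar_angle((0, 0, 0), (0, 0, 0), (1, 1, 1))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(finite3, finite3, finite3)
    def test_matches_arccos_oracle(self, a, b, c):
        u, w = a - b, c - b
        nu, nw = np.linalg.norm(u), np.linalg.norm(w)
        if nu < 1e-6 or nw < 1e-6:
            return
        expected = math.degrees(
            math.acos(np.clip(np.dot(u, w) / (nu * nw), -1, 1))
        )
        assert planar_angle(a, b, c) == pytest.approx(expected, abs=1e-10)

    def test_dihedral_cis_is_zero(self):
        assert dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_dihedral_trans_is_180(self):
        assert abs(
            dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0))
        ) == pytest.approx(180.0)

    def test_dihedral_staggered_oracle(self):
        # butane-like gauche geometry against the textbook atan2 formula
        a = np.array([1.0, 1.0, 0.0])
        b = np.array([0.0, 0.0, 0.0])
        c = np.array([1.0, 0.0, 1.0])
        d = np.array([2.0, -0.5, 1.2])
        b1, b2, b3 = b - a, c - b, d - c
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        u = b2 / np.linalg.norm(b2)
        expected = math.degrees(
            math.atan2(float(np.dot(np.cross(u, n1), n2)), float(np.dot(n1, n2)))
        )
        assert dihedral_angle(a, b, c, d) == pytest.approx(expected, abs=1e-10)

    def test_dihedral_collinear_rejected(self):
        with pytest.raises(ValueError):
            dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestBeadRadius:
    def _block(self, n, off_value, span_bp=100_000, res=100_000):
        m = np.full((n, n), float(off_value))
        np.fill_diagonal(m, 0.0)
        import pandas as pd

        starts = np.arange(n) * (span_bp // n)
        bins = pd.DataFrame(
            {"chrom": "chr1", "start_bp": starts, "end_bp": starts + span_bp // n}
        )
        return ContactMatrix(m, res, bins)

    def test_reference_case(self):
        blk = self._block(4, 10.0)  # c = 10 on a 100 kbp block
        r = bead_radius_from_contacts(blk, r_ref=60.0, l_ref=1e5, c_ref=10.0)
        assert r == pytest.approx(60.0)

    def test_eightfold_density_halves_radius(self):
        r1 = bead_radius_from_contacts(self._block(4, 10.0), c_ref=10.0)
        r2 = bead_radius_from_contacts(self._block(4, 80.0), c_ref=10.0)
        assert r2 == pytest.approx(r1 / 2.0)

    def test_doubling_span_and_density_cancels(self):
        r1 = bead_radius_from_contacts(self._block(4, 10.0, span_bp=100_000))
        r2 = bead_radius_from_contacts(self._block(4, 20.0, span_bp=200_000))
        assert r2 == pytest.approx(r1)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_monotone_in_density(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(1.0, 50.0)
        r_lo = bead_radius_from_contacts(self._block(5, base))
        r_hi = bead_radius_from_contacts(self._block(5, base * rng.uniform(1.01, 4.0)))
        assert r_hi < r_lo


class TestConstraints:
    def test_straight_well_separated_chain_ok(self):
        coords = np.arange(5)[:, None] * np.array([130.0, 0.0, 0.0])
        ch = Chain.from_centroids(coords, [60.0] * 5)
        cons = ConstraintSet(bond_range=(100.0, 150.0))
        assert check_constraints(ch, cons).ok

    def test_steric_violation_reported(self):
        # two non-adjacent beads 1 nm apart with a 120 nm floor
        coords = np.array(
            [[0, 0, 0], [130, 0, 0], [1.0, 0.0, 0.0], [131, 100, 0]], dtype=float
        )
        ch = Chain.from_centroids(coords, [1.0] * 4)
        report = check_constraints(ch, ConstraintSet(min_pair_dist=120.0, bond_range=(0.1, 1e4)))
        steric = report.of_kind("steric")
        assert any(v.indices == (0, 2) and v.value == pytest.approx(1.0) for v in steric)

    def test_matches_bruteforce_checker(self):
        cons = ConstraintSet(bond_range=(90.0, 150.0), max_pair_dist=800.0)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            coords = rng.uniform(0, 500, size=(8, 3))
            radii = rng.uniform(20, 70, size=8)
            ch = Chain.from_centroids(coords, radii)
            report = check_constraints(ch, cons)
            got = {(v.kind, v.indices) for v in report}
            # exhaustive O(N^2) oracle
            want = set()
            for i in range(8):
                for j in range(i + 1, 8):
                    d = np.linalg.norm(coords[i] - coords[j])
                    if j - i > 1 and d < max(120.0, radii[i] + radii[j]):
                        want.add(("steric", (i, j)))
                    if d > 800.0:
                        want.add(("span", (i, j)))
            for v in range(1, 7):
                psi = planar_angle(coords[v - 1], coords[v], coords[v + 1])
                if 180.0 - psi > 100.0 + 1e-9:
                    want.add(("curvature", (v,)))
            for b in range(7):
                d = np.linalg.norm(coords[b + 1] - coords[b])
                if d < 90.0 - 1e-9 or d > 150.0 + 1e-9:
                    want.add(("bond", (b,)))
            assert got == want

    def test_psi_convention(self):
        # a right-angle bend: psi = 90, bend = 90
        coords = np.array([[0, 0, 0], [130, 0, 0], [130, 130, 0]], dtype=float)
        ch = Chain.from_centroids(coords, [60.0] * 3)
        bend = ConstraintSet(max_curvature_deg=100.0, bond_range=(100, 150))
        psi = ConstraintSet(
            max_curvature_deg=85.0, bond_range=(100, 150), curvature_convention="psi"
        )
        assert check_constraints(ch, bend).ok  # bend 90 <= 100
        assert not check_constraints(ch, psi).ok  # psi 90 > 85


class TestGrowthAndSpan:
    def test_single_bead_at_origin(self):
        ch = build_initial_chain([(60.0, (0, 1))], ConstraintSet(), np.random.default_rng(0))
        assert ch.n_beads == 1
        assert np.array_equal(ch.centroids[0], [0, 0, 0])

    def test_same_seed_identical(self):
        a = random_chain(12, seed=3)
        b = random_chain(12, seed=3)
        assert np.array_equal(a.points, b.points)

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_grown_chains_feasible(self, seed):
        cons = ConstraintSet()
        ch = random_chain(50, seed=seed, constraints=cons)
        assert check_constraints(ch, cons).ok

    def test_infeasible_spec_raises_with_bead_index(self):
        # bond range too short for the steric floor: bead 2 can never be
        # placed 120 nm from bead 0 while bonded at <= 70 nm each
        cons = ConstraintSet(min_pair_dist=120.0, bond_range=(50.0, 60.0))
        with pytest.raises(InfeasibleChainError) as err:
            build_initial_chain(
                [(10.0, (0, 1))] * 5, cons, np.random.default_rng(0),
                max_bead_retries=50, max_restarts=3,
            )
        assert err.value.bead_index >= 1

    def test_span_trivial_cases(self):
        one = Chain.from_centroids([[0.0, 0.0, 0.0]], [60.0])
        assert chain_span(one) == 0.0
        two = Chain.from_centroids([[0, 0, 0], [0, 0, 500.0]], [60.0, 60.0])
        assert chain_span(two) == pytest.approx(500.0)

    def test_span_matches_bruteforce(self, rng):
        coords = rng.uniform(-400, 400, size=(20, 3))
        ch = Chain.from_centroids(coords, np.full(20, 60.0))
        want = max(
            np.linalg.norm(coords[i] - coords[j])
            for i in range(20)
            for j in range(i + 1, 20)
        )
        assert chain_span(ch) == pytest.approx(want, abs=1e-12)


class TestSerialization:
    def test_table_round_trip(self, tmp_path):
        ch = random_chain(9, seed=5)
        p = tmp_path / "chain.tsv"
        write_chain_table(ch, p)
        back = read_chain_table(p)
        assert np.array_equal(back.points, ch.points)
        assert np.array_equal(back.radii, ch.radii)
        assert back.spans == ch.spans

    def test_coarse_bead_round_trip(self, tmp_path):
        b1 = Bead([0, 0, 0], [50, 40, 0], [100, 0, 0], 80.0, (0, 400_000))
        b2 = Bead([120, 0, 0], [170, -30, 10], [220, 0, 0], 70.0, (400_000, 800_000))
        ch = Chain.from_beads([b1, b2])
        p = tmp_path / "coarse.tsv"
        write_chain_table(ch, p)
        back = read_chain_table(p)
        assert np.allclose(back.points, ch.points)
        assert back.bead_points == ch.bead_points

    def test_pdb_has_one_atom_per_bead(self, tmp_path):
        ch = random_chain(7, seed=1)
        p = tmp_path / "chain.pdb"
        write_pdb(ch, p)
        lines = p.read_text().splitlines()
        assert sum(1 for ln in lines if ln.startswith("ATOM")) == 7
        assert sum(1 for ln in lines if ln.startswith("CONECT")) == 6


class TestBeadRigidity:
    def test_bead_invariants(self):
        b = Bead([0, 0, 0], [50, 40, 0], [100, 0, 0], 80.0)
        assert not b.degenerate
        assert b.arm_lengths[0] == pytest.approx(math.hypot(50, 40))
        assert 0 < b.arm_angle < 180

    def test_degenerate_bead(self):
        b = Bead.point([1.0, 2.0, 3.0], 60.0)
        assert b.degenerate
        assert math.isnan(b.arm_angle)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            Bead.point([0, 0, 0], 0.0)
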