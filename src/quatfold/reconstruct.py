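"""Scikit-learn-style front end for the multiscale reconstruction.

`ChromatinReconstructor` treats a symmetric contact-count matrix as the
training data of an embedding problem (in the spirit of
:class:`sklearn.manifold.MDS`, but without converting counts to target
distances): ``fit(X)`` runs the multiscale annealing procedure and leaves
the reconstructed finest-resolution structure in ``structure_``.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, check_random_state

from .annealing import AnnealingSchedule, data_fit
from .chain import ConstraintSet
from .contact_data import BlockPartition, ContactMatrix, select_fit_set
from .multiscale import reconstruct_recursive

__all__ = ["ChromatinReconstructor"]


class ChromatinReconstructor(BaseEstimator):
    """Infer a 3D bead-chain configuration from a contact matrix.

    The estimator reconstructs each diagonal block of ``X`` (a TAD) by
    simulated annealing on the contact-weighted distance objective
    Phi(C) = sum_{(i,j) in L} n_ij * d_ij, abstracts each reconstructed
    subchain as a rigid (start, centroid, end) bead, bins the matrix and
    repeats at the coarser level, finally composing the full-resolution
    structure hierarchically.

    Parameters
    ----------
    partition : sequence of block sizes, sequence of (a, b) bin ranges,
        BlockPartition, or None
        Diagonal-block partition of the matrix (TAD calls).  None treats
        the whole matrix as a single block (plain single-level annealing).
    resolution_bp : genomic bin size of ``X`` in bp.
    fit_pairs_high, fit_pairs_low : cardinality of the data-fit pair set L
        for the finest-level subchains and for coarser chains.
    exclude_adjacent : drop |i-j| = 1 pairs from L (bonds already hold
        those pairs together).
    min_pair_dist, max_pair_dist, max_curvature_deg, curvature_convention,
    bond_range : geometric constraints, in nm / degrees.
    r_ref : reference bead radius (nm) for sizing beads from internal
        contact counts.
    t0, alpha, t_min, max_sweeps, moves_per_sweep, stall_sweeps,
    max_planar_delta, max_dihedral_delta, bond_delta_frac : annealing
        schedule; t0=None auto-calibrates from a pilot run.
    n_block_replicates : independent anneals saved per block.
    random_state : seed for the whole run (int or Generator).

    Attributes
    ----------
    structure_ : (n_bins, 3) reconstructed bead centroids (nm).
    radii_ : (n_bins,) bead radii (nm).
    chain_ : the full Chain object (arm points, spans).
    result_ : ReconstructionResult with per-level traces and saved configs.
    phi_initial_, phi_best_ : summed data-fit before / after annealing.
    """

    def __init__(
        self,
        partition=None,
        *,
        resolution_bp: int = 100_000,
        fit_pairs_high: int = 20,
        fit_pairs_low: int = 40,
        exclude_adjacent: bool = True,
        min_pair_dist: float = 120.0,
        max_pair_dist: float = 10_000.0,
        max_curvature_deg: float = 100.0,
        curvature_convention: str = "bend",
        bond_range=None,
        r_ref: float = 60.0,
        t0=None,
        alpha: float = 0.98,
        t_min=None,
        max_sweeps: int = 400,
        moves_per_sweep=None,
        stall_sweeps: int = 50,
        max_planar_delta: float = 15.0,
        max_dihedral_delta: float = 30.0,
        bond_delta_frac: float = 0.05,
        n_block_replicates: int = 1,
        random_state=None,
    ):
        self.partition = partition
        self.resolution_bp = resolution_bp
        self.fit_pairs_high = fit_pairs_high
        self.fit_pairs_low = fit_pairs_low
        self.exclude_adjacent = exclude_adjacent
        self.min_pair_dist = min_pair_dist
        self.max_pair_dist = max_pair_dist
        self.max_curvature_deg = max_curvature_deg
        self.curvature_convention = curvature_convention
        self.bond_range = bond_range
        self.r_ref = r_ref
        self.t0 = t0
        self.alpha = alpha
        self.t_min = t_min
        self.max_sweeps = max_sweeps
        self.moves_per_sweep = moves_per_sweep
        self.stall_sweeps = stall_sweeps
        self.max_planar_delta = max_planar_delta
        self.max_dihedral_delta = max_dihedral_delta
        self.bond_delta_frac = bond_delta_frac
        self.n_block_replicates = n_block_replicates
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------

    def _constraints(self) -> ConstraintSet:
        return ConstraintSet(
            min_pair_dist=self.min_pair_dist,
            max_pair_dist=self.max_pair_dist,
            max_curvature_deg=self.max_curvature_deg,
            bond_range=tuple(self.bond_range) if self.bond_range is not None else None,
            curvature_convention=self.curvature_convention,
        )

    def _schedule(self) -> AnnealingSchedule:
        return AnnealingSchedule(
            t0=self.t0,
            alpha=self.alpha,
            t_min=self.t_min,
            max_sweeps=self.max_sweeps,
            moves_per_sweep=self.moves_per_sweep,
            max_planar_delta=self.max_planar_delta,
            max_dihedral_delta=self.max_dihedral_delta,
            bond_delta_frac=self.bond_delta_frac,
            stall_sweeps=self.stall_sweeps,
        )

    def _partition(self, n_bins: int) -> BlockPartition:
        p = self.partition
        if p is None:
            return BlockPartition(((0, n_bins),))
        if isinstance(p, BlockPartition):
            return p
        p = list(p)
        if p and isinstance(p[0], numbers.Integral):
            return BlockPartition.from_sizes(p)
        return BlockPartition(tuple(tuple(r) for r in p))

    def _seed(self) -> int:
        rs = self.random_state
        if rs is None or isinstance(rs, numbers.Integral):
            return int(rs) if rs is not None else 0
        # Generator / RandomState: draw one root seed from it
        state = check_random_state(rs if not isinstance(rs, np.random.Generator) else None)
        if isinstance(rs, np.random.Generator):
            return int(rs.integers(2**31 - 1))
        return int(state.randint(2**31 - 1))

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        """Reconstruct a structure from the contact matrix ``X``.

        X is a square symmetric non-negative array (or ContactMatrix);
        y is ignored (present for pipeline compatibility).
        """
        if isinstance(X, ContactMatrix):
            matrix = X
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[0] != X.shape[1]:
                raise ValueError("X must be a square contact matrix")
            matrix = ContactMatrix(X, self.resolution_bp)
        partition = self._partition(matrix.n_bins)
        if not partition.covers(matrix):
            raise ValueError("partition does not cover the matrix")
        result = reconstruct_recursive(
            matrix,
            [partition],
            constraints=self._constraints(),
            schedule=self._schedule(),
            fit_k_high=self.fit_pairs_high,
            fit_k_low=self.fit_pairs_low,
            exclude_adjacent=self.exclude_adjacent,
            r_ref=self.r_ref,
            n_block_replicates=self.n_block_replicates,
            seed=self._seed(),
        )
        self.matrix_ = matrix
        self.result_ = result
        self.chain_ = result.chain
        self.structure_ = result.chain.centroids
        self.radii_ = result.chain.radii
        self.phi_initial_ = result.phi_initial_total
        self.phi_best_ = result.phi_best_total
        self.n_features_in_ = matrix.n_bins
        return self

    def fit_transform(self, X, y=None):
        """Fit and return the (n_bins, 3) centroid coordinates."""
        return self.fit(X).structure_

    def score(self, X, y=None) -> float:
        """Negative data fit of the learned structure under ``X``'s own
        strongest pairs (higher is better), for model selection."""
        check_is_fitted(self, "chain_")
        matrix = X if isinstance(X, ContactMatrix) else ContactMatrix(
            np.asarray(X, dtype=float), self.resolution_bp
        )
        fitset = select_fit_set(matrix, self.fit_pairs_high, self.exclude_adjacent)
        return -data_fit(self.chain_, fitset)
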