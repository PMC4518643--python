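"""Contact matrices, TAD block partitions and data-fit pair sets.

A contact matrix holds the pair-contact counts n_ij of a chromosome
conformation capture experiment at some genomic resolution.  Zeros are
permitted anywhere: a vanishing count carries no distance information and
simply removes the pair from the data fit.  Partitions split the bin range
into consecutive diagonal blocks (TADs), which the multiscale procedure
reconstructs independently before binning the matrix down a level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "BlockPartition",
    "FitSet",
    "MatrixFormatError",
    "PartitionError",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_partition",
    "write_partition",
    "extract_blocks",
    "bin_matrix",
    "select_fit_set",
]

ASYMMETRY_RTOL = 1e-9


class MatrixFormatError(ValueError):
    pass


class PartitionError(ValueError):
    pass


def _default_bins(n: int, resolution_bp: int, chrom: str = "chr1", offset_bp: int = 0) -> pd.DataFrame:
    starts = offset_bp + resolution_bp * np.arange(n, dtype=np.int64)
    return pd.DataFrame(
        {"chrom": chrom, "start_bp": starts, "end_bp": starts + resolution_bp}
    )


@dataclass
class ContactMatrix:
    """Symmetric non-negative count matrix with genomic bin annotation.

    counts : (N, N) symmetric array, entries >= 0.
    resolution_bp : nominal bin size; after binning by blocks the per-bin
        extents in `bins` become variable and are authoritative.
    bins : DataFrame with columns chrom, start_bp, end_bp -- consecutive,
        non-overlapping, ordered intervals.
    """

    counts: np.ndarray
    resolution_bp: int
    bins: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise MatrixFormatError("contact matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")
        if not self.resolution_bp > 0:
            raise ValueError("resolution_bp must be positive")
        n = self.counts.shape[0]
        if self.bins is None:
            self.bins = _default_bins(n, self.resolution_bp)
        if len(self.bins) != n:
            raise ValueError("bins must have one row per matrix row")
        starts = self.bins["start_bp"].to_numpy()
        ends = self.bins["end_bp"].to_numpy()
        if np.any(ends <= starts):
            raise ValueError("bin intervals must be non-empty")
        if np.any(starts[1:] != ends[:-1]):
            raise ValueError("bins must be consecutive and non-overlapping")
        self._symmetrize()

    def _symmetrize(self):
        M = self.counts
        scale = max(float(np.abs(M).max()), 1.0)
        asym = float(np.abs(M - M.T).max()) / scale
        if asym > ASYMMETRY_RTOL:
            warnings.warn(
                f"contact matrix asymmetric (relative deviation {asym:.3g}); "
                "symmetrizing as (M + M.T)/2",
                stacklevel=3,
            )
        self.counts = (M + M.T) / 2.0

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def span_bp(self) -> tuple[int, int]:
        return int(self.bins["start_bp"].iloc[0]), int(self.bins["end_bp"].iloc[-1])


@dataclass(frozen=True)
class BlockPartition:
    """Ordered half-open bin-index ranges [a_k, b_k) tiling a matrix."""

    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self):
        object.__setattr__(
            self, "blocks", tuple((int(a), int(b)) for a, b in self.blocks)
        )
        prev = None
        for a, b in self.blocks:
            if b <= a:
                raise PartitionError(f"empty block [{a}, {b})")
            if prev is not None and a != prev:
                raise PartitionError(f"gap or overlap before block [{a}, {b})")
            prev = b
        if not self.blocks:
            raise PartitionError("partition has no blocks")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_bins(self) -> int:
        return self.blocks[-1][1] - self.blocks[0][0]

    def covers(self, matrix: ContactMatrix) -> bool:
        return self.blocks[0][0] == 0 and self.blocks[-1][1] == matrix.n_bins

    def sizes(self) -> list[int]:
        return [b - a for a, b in self.blocks]

    @classmethod
    def from_sizes(cls, sizes) -> "BlockPartition":
        edges = np.concatenate([[0], np.cumsum(sizes)])
        return cls(tuple((int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])))


@dataclass(frozen=True)
class FitSet:
    """The pair set L entering the data fit: (i, j, n) with i < j, n > 0."""

    pairs: tuple[tuple[int, int, float], ...]

    def __post_init__(self):
        seen = set()
        for i, j, n in self.pairs:
            if not i < j:
                raise ValueError(f"fit-set pair ({i}, {j}) must satisfy i < j")
            if not n > 0:
                raise ValueError(f"fit-set count for ({i}, {j}) must be positive")
            if (i, j) in seen:
                raise ValueError(f"duplicate fit-set pair ({i}, {j})")
            seen.add((i, j))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.pairs:
            e = np.empty(0, dtype=int)
            return e, e.copy(), np.empty(0)
        i, j, n = zip(*self.pairs)
        return np.array(i, dtype=int), np.array(j, dtype=int), np.array(n, dtype=float)


# ---------------------------------------------------------------------------
# IO


def read_contact_matrix(path, resolution_bp: int, format: str = "dense") -> ContactMatrix:
    """Read a dense (whitespace N x N grid, '#' comments allowed) or sparse
    ("i j count" rows, 0-based, upper triangle sufficient) text matrix."""
    if format == "dense":
        M = np.loadtxt(path, ndmin=2)
        if M.shape[0] != M.shape[1]:
            raise MatrixFormatError(
                f"dense matrix in {path} is {M.shape[0]}x{M.shape[1]}, not square"
            )
        return ContactMatrix(M, resolution_bp)
    if format == "sparse":
        rows = np.loadtxt(path, ndmin=2)
        if rows.size == 0:
            raise MatrixFormatError(f"sparse matrix file {path} is empty")
        if rows.shape[1] != 3:
            raise MatrixFormatError("sparse format needs rows 'i j count'")
        i = rows[:, 0].astype(int)
        j = rows[:, 1].astype(int)
        c = rows[:, 2]
        if np.any(i < 0) or np.any(j < 0):
            raise MatrixFormatError("sparse indices must be non-negative (0-based)")
        n = int(max(i.max(), j.max())) + 1
        M = np.zeros((n, n))
        for ii, jj, cc in zip(i, j, c):
            lo, hi = (jj, ii) if ii > jj else (ii, jj)
            if M[lo, hi] != 0.0 and M[lo, hi] != cc:
                raise MatrixFormatError(
                    f"conflicting duplicate sparse entries for pair ({lo}, {hi})"
                )
            M[lo, hi] = cc
            M[hi, lo] = cc
        return ContactMatrix(M, resolution_bp)
    raise ValueError(f"unknown matrix format {format!r}")


def write_contact_matrix(matrix: ContactMatrix, path, format: str = "dense") -> None:
    if format == "dense":
        np.savetxt(path, matrix.counts, fmt="%.17g")
    elif format == "sparse":
        iu, ju = np.triu_indices(matrix.n_bins)
        with open(path, "w") as fh:
            for i, j in zip(iu, ju):
                c = matrix.counts[i, j]
                if c != 0.0:
                    fh.write(f"{i}\t{j}\t{c:.17g}\n")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_partition(path, matrix: ContactMatrix, format: str = "bins") -> BlockPartition:
    """Read a block partition as bin ranges ("a b" rows, half-open) or BED
    (chrom start end, 0-based half-open bp; snapped outward to bin edges
    with a warning when unaligned).  The intervals must tile the matrix."""
    ranges: list[tuple[int, int]] = []
    if format == "bins":
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split()[:2]
                ranges.append((int(a), int(b)))
    elif format == "bed":
        res = matrix.resolution_bp
        origin = int(matrix.bins["start_bp"].iloc[0])
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                start, end = int(f[1]), int(f[2])
                if (start - origin) % res or (end - origin) % res:
                    warnings.warn(
                        f"BED interval {f[0]}:{start}-{end} not aligned to the "
                        f"{res} bp grid; snapping outward",
                        stacklevel=2,
                    )
                a = (start - origin) // res
                b = -((-(end - origin)) // res)  # ceil division
                ranges.append((int(a), int(b)))
    else:
        raise ValueError(f"unknown partition format {format!r}")
    ranges.sort()
    try:
        part = BlockPartition(tuple(ranges))
    except PartitionError as exc:
        raise PartitionError(f"partition in {path} does not tile the matrix: {exc}") from exc
    if not part.covers(matrix):
        raise PartitionError(
            f"partition in {path} covers bins [{part.blocks[0][0]}, "
            f"{part.blocks[-1][1]}) but the matrix has {matrix.n_bins} bins"
        )
    return part


def write_partition(partition: BlockPartition, path) -> None:
    with open(path, "w") as fh:
        for a, b in partition.blocks:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# operations


def extract_blocks(matrix: ContactMatrix, partition: BlockPartition) -> list[ContactMatrix]:
    """Square diagonal submatrices counts[a:b, a:b], one per block."""
    if not partition.covers(matrix):
        raise PartitionError("partition does not cover the matrix")
    out = []
    for a, b in partition.blocks:
        out.append(
            ContactMatrix(
                matrix.counts[a:b, a:b].copy(),
                matrix.resolution_bp,
                matrix.bins.iloc[a:b].reset_index(drop=True),
            )
        )
    return out


def bin_matrix(matrix: ContactMatrix, partition: BlockPartition) -> ContactMatrix:
    """Bin by blocks: output (k, l) sums counts over block k x block l.

    Conserves the total count exactly; the output bins span the genomic
    extent of each block (resolution becomes variable).
    """
    if not partition.covers(matrix):
        raise PartitionError("partition does not cover the matrix")
    edges = [a for a, _ in partition.blocks]
    summed_rows = np.add.reduceat(matrix.counts, edges, axis=0)
    binned = np.add.reduceat(summed_rows, edges, axis=1)
    bins = pd.DataFrame(
        {
            "chrom": [matrix.bins["chrom"].iloc[a] for a, _ in partition.blocks],
            "start_bp": [int(matrix.bins["start_bp"].iloc[a]) for a, _ in partition.blocks],
            "end_bp": [int(matrix.bins["end_bp"].iloc[b - 1]) for _, b in partition.blocks],
        }
    )
    return ContactMatrix(binned, matrix.resolution_bp, bins)


def suggest_partition(
    matrix: ContactMatrix,
    *,
    rel_threshold: float = 0.3,
    min_block: int = 2,
) -> BlockPartition:
    """Heuristic diagonal-block finder (a convenience, not a TAD caller).

    Walks the diagonal and closes the current block when the mean count
    linking the next bin to the block falls below `rel_threshold` times
    the running mean within-block count.  Serious analyses should supply
    a partition from a dedicated domain caller; this helper only gives a
    starting point for matrices with pronounced block structure.
    """
    n = matrix.n_bins
    if n == 1:
        return BlockPartition(((0, 1),))
    c = matrix.counts
    edges = [0]
    a = 0
    for j in range(1, n):
        # coupling of bin j to the open block, ignoring the bonded neighbour
        link = float(c[j, a : j - 1].mean()) if j - 1 > a else float(c[j, a:j].mean())
        iu = np.triu_indices(j - a, k=1)
        within = float(c[a:j, a:j][iu].mean()) if j - a >= 2 else float(c[a:j, a:j].mean())
        if j - a >= min_block and within > 0 and link < rel_threshold * within:
            edges.append(j)
            a = j
    edges.append(n)
    return BlockPartition(tuple(zip(edges[:-1], edges[1:])))


def select_fit_set(
    matrix: ContactMatrix, k: int, exclude_adjacent: bool = True
) -> FitSet:
    """The k largest strictly-upper-triangle counts as the data-fit pair set L.

    The main diagonal is never a candidate (d_ii = 0 identically) and, by
    default, genomically adjacent pairs |i - j| = 1 are excluded as well:
    bonds already hold those pairs together, so spending fit-set slots on
    them is uninformative.  Ties are broken by ascending (i, j); if fewer
    than k positive candidates exist, all of them are returned.  A matrix
    with no positive candidate yields an empty fit set with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = matrix.n_bins
    offset = 2 if exclude_adjacent else 1
    iu, ju = np.triu_indices(n, k=offset)
    vals = matrix.counts[iu, ju]
    pos = vals > 0
    iu, ju, vals = iu[pos], ju[pos], vals[pos]
    if len(vals) == 0:
        warnings.warn("no positive off-diagonal candidates; fit set is empty", stacklevel=2)
        return FitSet(())
    order = np.lexsort((ju, iu, -vals))
    take = order[: min(k, len(order))]
    return FitSet(tuple((int(iu[t]), int(ju[t]), float(vals[t])) for t in take))
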