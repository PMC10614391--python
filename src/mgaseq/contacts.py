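"""Sparse chromatin-contact matrices and region contact profiles.

A contact matrix is symmetric by construction; only the upper triangle
(i <= j in global bin indices) is stored, with the diagonal counted once.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import scipy.sparse as sp

from .genome import BinnedGenome, Region


class ContactMatrix:
    """Symmetric binned contact counts, upper triangle stored as CSR."""

    def __init__(self, genome: BinnedGenome, upper: sp.spmatrix) -> None:
        upper = sp.csr_matrix(upper)
        n = genome.n_bins
        if upper.shape != (n, n):
            raise ValueError(f"matrix shape {upper.shape} != ({n}, {n})")
        if (upper.data < 0).any():
            raise ValueError("negative contact count")
        self.genome = genome
        self._upper = upper

    @classmethod
    def from_entries(
        cls,
        genome: BinnedGenome,
        rows: np.ndarray,
        cols: np.ndarray,
        counts: np.ndarray,
    ) -> "ContactMatrix":
        """Build from parallel index/count arrays, folding to the upper triangle.

        Duplicate (i, j) records (after folding) are summed.
        """
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.float64)
        n = genome.n_bins
        if rows.size and (rows.min() < 0 or cols.min() < 0
                          or rows.max() >= n or cols.max() >= n):
            raise ValueError(f"bin index out of range [0, {n})")
        i = np.minimum(rows, cols)
        j = np.maximum(rows, cols)
        m = sp.coo_matrix((counts, (i, j)), shape=(n, n))
        m.sum_duplicates()
        return cls(genome, m.tocsr())

    @property
    def total(self) -> float:
        """Sum of all entries, diagonal counted once."""
        return float(self._upper.sum())

    def value(self, i: int, j: int) -> float:
        """Count for bin pair (i, j); symmetric lookup."""
        a, b = (i, j) if i <= j else (j, i)
        return float(self._upper[a, b])

    @property
    def upper(self) -> sp.csr_matrix:
        return self._upper

    def block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Dense symmetric submatrix M[rows, cols] of the full matrix."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        up = self._upper[np.ix_(rows, cols)].toarray()
        lo = self._upper[np.ix_(cols, rows)].toarray().T
        blk = up + lo
        # entries on the stored diagonal appear in both pulls; subtract once
        common, ri, ci = np.intersect1d(rows, cols, return_indices=True)
        if common.size:
            blk[ri, ci] -= self._upper.diagonal()[common]
        return blk

    def write_coo(self, path) -> None:
        coo = self._upper.tocoo()
        with open(path, "w") as fh:
            fh.write("#bin_i\tbin_j\tcount\n")
            for i, j, c in zip(coo.row, coo.col, coo.data):
                c = int(c) if float(c).is_integer() else c
                fh.write(f"{i}\t{j}\t{c}\n")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ContactMatrix)
            and self.genome == other.genome
            and (self._upper != other._upper).nnz == 0
        )


def read_contacts_coo(path, genome: BinnedGenome) -> ContactMatrix:
    """Read a 3-column COO TSV (bin_i, bin_j, count) into a ContactMatrix.

    Lines starting with '#' and blank lines are skipped; duplicate records
    are summed; malformed lines are reported with their line number.
    """
    rows, cols, counts = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            try:
                i, j = int(fields[0]), int(fields[1])
                c = float(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record {line!r}") from exc
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative count {c}")
            if not (0 <= i < genome.n_bins and 0 <= j < genome.n_bins):
                raise ValueError(
                    f"{path}:{lineno}: bin index out of range [0, {genome.n_bins})"
                )
            rows.append(i)
            cols.append(j)
            counts.append(c)
    return ContactMatrix.from_entries(
        genome, np.array(rows, dtype=np.int64), np.array(cols, dtype=np.int64),
        np.array(counts),
    )


def count_pairs_to_matrix(
    pairs: Iterable[tuple[str, int, str, int]], genome: BinnedGenome
) -> ContactMatrix:
    """Bin a stream of contact pairs (chromA, posA, chromB, posB).

    Each pair increments exactly one upper-triangle entry; positions are
    0-based and must lie within their chromosome.
    """
    rows, cols = [], []
    for chrom_a, pos_a, chrom_b, pos_b in pairs:
        rows.append(genome.bin_index(chrom_a, int(pos_a)))
        cols.append(genome.bin_index(chrom_b, int(pos_b)))
    ones = np.ones(len(rows))
    return ContactMatrix.from_entries(
        genome, np.array(rows, dtype=np.int64), np.array(cols, dtype=np.int64), ones
    )


def read_pairs_file(path) -> Iterator[tuple[str, int, str, int]]:
    """Iterate a 4-column pairs TSV (chromA, posA, chromB, posB)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            yield fields[0], int(fields[1]), fields[2], int(fields[3])


@dataclass
class ContactProfile:
    """Per-bin contact counts between a query region and the whole genome.

    ``values[b]`` is the total contact count between any query bin and
    genome bin b. ``mask[b]`` is True for bins excluded from downstream
    analysis (bins overlapping the query; the whole query chromosome when
    the profile was extracted trans-only).
    """

    genome: BinnedGenome
    query: Region
    values: np.ndarray
    mask: np.ndarray
    trans_only: bool = False

    def unmasked_values(self) -> np.ndarray:
        """Counts of retained bins, in genome order."""
        return self.values[~self.mask]

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#bin\tchrom\tstart\tcount\tmasked\n")
            for b in range(self.genome.n_bins):
                chrom, start = self.genome.bin_location(b)
                fh.write(
                    f"{b}\t{chrom}\t{start}\t{self.values[b]:g}\t"
                    f"{int(self.mask[b])}\n"
                )


def region_profile(
    matrix: ContactMatrix, query: Region, trans_only: bool = False
) -> ContactProfile:
    """Extract the contact profile of a query region against every genome bin.

    Bins overlapping the query are always masked (amplicon self-contacts
    would dominate the cumulative curve); with ``trans_only`` the whole
    query chromosome is masked as well.
    """
    genome = matrix.genome
    if len(query) < genome.bin_size:
        warnings.warn(
            f"query {query.label} is smaller than one bin ({genome.bin_size} bp)",
            stacklevel=2,
        )
    qbins = genome.bins_for_region(query)
    up = matrix.upper
    # M = U + U^T - diag(U); for b outside the query the diagonal term
    # never enters, and query bins are masked anyway.
    vals = np.asarray(up[qbins, :].sum(axis=0)).ravel() + np.asarray(
        up[:, qbins].sum(axis=1)
    ).ravel()
    mask = np.zeros(genome.n_bins, dtype=bool)
    mask[qbins] = True
    if trans_only:
        mask |= genome.chrom_mask(query.chrom)
    return ContactProfile(genome, query, vals, mask, trans_only)
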