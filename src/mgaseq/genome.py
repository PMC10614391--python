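"""Genome binning: chromosomes, fixed-size bins, and region coordinates.

Coordinates are 0-based half-open internally; every human-facing string
(region labels, breakpoint reports) is 1-based inclusive, following the
SAM/VCF display convention.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        """1-based inclusive display string, e.g. 'chr8:127300001-128900000'."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse a 1-based inclusive region string like 'chr8:127,300,001-128,900,000'."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region string {text!r}")
        chrom = m.group(1)
        start1 = int(m.group(2).replace(",", ""))
        end1 = int(m.group(3).replace(",", ""))
        if start1 < 1 or end1 < start1:
            raise ValueError(f"invalid 1-based region {text!r}")
        return cls(chrom, start1 - 1, end1)

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class BinnedGenome:
    """An ordered set of chromosomes partitioned into fixed-size bins.

    Bins are indexed globally: chromosome k's bins occupy the contiguous
    index range [offsets[k], offsets[k] + n_bins_k). Position p on a
    chromosome falls in local bin floor(p / bin_size); the last bin of each
    chromosome may be short (ceil rule).
    """

    def __init__(self, chroms: Sequence[tuple[str, int]], bin_size: int) -> None:
        if bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {bin_size}")
        names = [str(name) for name, _ in chroms]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome name(s): {dup}")
        lengths = [int(length) for _, length in chroms]
        for name, length in zip(names, lengths):
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        self.bin_size = int(bin_size)
        self.names: list[str] = names
        self.lengths: dict[str, int] = dict(zip(names, lengths))
        self._nbins = {
            n: -(-self.lengths[n] // self.bin_size) for n in names
        }  # ceil division
        offs = np.concatenate(([0], np.cumsum([self._nbins[n] for n in names])))
        self.offsets: dict[str, int] = {n: int(offs[i]) for i, n in enumerate(names)}
        self.n_bins: int = int(offs[-1])
        # per-bin chromosome index, for fast masking
        self._bin_chrom_idx = np.repeat(
            np.arange(len(names)), [self._nbins[n] for n in names]
        )

    @property
    def chroms(self) -> list[tuple[str, int]]:
        return [(n, self.lengths[n]) for n in self.names]

    def n_chrom_bins(self, chrom: str) -> int:
        self._check_chrom(chrom)
        return self._nbins[chrom]

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of (chrom, pos); pos is 0-based."""
        self._check_chrom(chrom)
        if not (0 <= pos < self.lengths[chrom]):
            raise ValueError(
                f"position {pos} out of bounds for {chrom} "
                f"(length {self.lengths[chrom]})"
            )
        return self.offsets[chrom] + pos // self.bin_size

    def bin_location(self, gbin: int) -> tuple[str, int]:
        """(chrom, bin start position) of a global bin index."""
        if not (0 <= gbin < self.n_bins):
            raise ValueError(f"bin index {gbin} out of range [0, {self.n_bins})")
        ci = int(self._bin_chrom_idx[gbin])
        chrom = self.names[ci]
        return chrom, (gbin - self.offsets[chrom]) * self.bin_size

    def bin_region(self, gbin: int) -> Region:
        chrom, start = self.bin_location(gbin)
        end = min(start + self.bin_size, self.lengths[chrom])
        return Region(chrom, start, end)

    def chrom_bins(self, chrom: str) -> np.ndarray:
        """Global bin indices of one chromosome."""
        self._check_chrom(chrom)
        off = self.offsets[chrom]
        return np.arange(off, off + self._nbins[chrom])

    def bins_for_region(self, region: Region) -> np.ndarray:
        """Global indices of all bins overlapping the region."""
        self._check_chrom(region.chrom)
        if region.end > self.lengths[region.chrom]:
            raise ValueError(
                f"region {region.label} exceeds chromosome length "
                f"{self.lengths[region.chrom]}"
            )
        off = self.offsets[region.chrom]
        first = region.start // self.bin_size
        last = (region.end - 1) // self.bin_size
        return np.arange(off + first, off + last + 1)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        """Boolean mask (length n_bins) selecting one chromosome's bins."""
        self._check_chrom(chrom)
        return self._bin_chrom_idx == self.names.index(chrom)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinnedGenome)
            and self.bin_size == other.bin_size
            and self.chroms == other.chroms
        )

    def __repr__(self) -> str:
        return (
            f"BinnedGenome({len(self.names)} chroms, bin_size={self.bin_size}, "
            f"n_bins={self.n_bins})"
        )


def read_chrom_sizes(path) -> list[tuple[str, int]]:
    """Read a 2-column chrom.sizes TSV (name, length)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1],
        names=["chrom", "length"], dtype={"chrom": str},
    )
    return list(zip(df["chrom"], df["length"].astype(int)))


def make_binned_genome(
    chrom_sizes: Sequence[tuple[str, int]] | str, bin_size: int
) -> BinnedGenome:
    """Build a BinnedGenome from (name, length) pairs or a chrom.sizes path."""
    if isinstance(chrom_sizes, (str, bytes)) or hasattr(chrom_sizes, "read"):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    return BinnedGenome(chrom_sizes, bin_size)
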