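"""Focal-amplification calling from binned read depth.

A deliberately transparent caller: per-bin log2 copy ratio against a
reference track (or the sample's own genome-wide median), thresholded and
run-length merged. It feeds the same downstream stages (fluctuation
analysis, amplicon assembly, coamplification network) that a full CNV
segmenter would; externally produced segment tables can be substituted via
``read_cnv_segments``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinnedGenome, Region


@dataclass
class DepthTrack:
    """Binned read counts over a genome; optionally per-million normalized."""

    genome: BinnedGenome
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} != genome bins {self.genome.n_bins}"
            )
        if (self.values < 0).any():
            raise ValueError("negative depth value")


@dataclass(frozen=True)
class AmplifiedRegion:
    """A called focal amplification: maximal run of high-ratio bins."""

    region: Region
    mean_log2_ratio: float
    n_bins: int


def normalize_depth(track: DepthTrack, total_mapped: float | None = None) -> DepthTrack:
    """Scale to counts per million mapped reads.

    ``total_mapped`` defaults to the track's own total; it must be positive.
    """
    total = float(track.values.sum()) if total_mapped is None else float(total_mapped)
    if total <= 0:
        raise ValueError(f"total mapped reads must be positive, got {total}")
    return DepthTrack(track.genome, track.values * 1e6 / total, normalized=True)


def log2_ratio(
    sample: DepthTrack,
    reference: DepthTrack | None = None,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Per-bin log2((sample + p) / (reference + p)).

    With no reference track, each bin is compared to the sample's own
    genome-wide median depth (median-self reference). The pseudocount keeps
    empty bins finite.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    if reference is None:
        ref_vals = np.full(sample.genome.n_bins, np.median(sample.values))
    else:
        if reference.genome != sample.genome:
            raise ValueError("sample and reference tracks have mismatched binning")
        ref_vals = reference.values
    return np.log2((sample.values + pseudocount) / (ref_vals + pseudocount))


def call_amplified_regions(
    ratio: np.ndarray,
    genome: BinnedGenome,
    min_log2: float = 1.0,
    min_bins: int = 2,
    merge_gap_bins: int = 1,
) -> list[AmplifiedRegion]:
    """Threshold-and-merge caller over a per-bin log2-ratio vector.

    Maximal runs of bins with ratio >= min_log2 are found per chromosome,
    runs separated by <= merge_gap_bins low bins are merged, and merged runs
    spanning < min_bins bins are dropped. Returned regions are sorted and
    non-overlapping; mean_log2_ratio is averaged over the full region span.
    """
    ratio = np.asarray(ratio, dtype=float)
    if ratio.shape != (genome.n_bins,):
        raise ValueError("ratio vector not aligned to genome bins")
    out: list[AmplifiedRegion] = []
    for chrom in genome.names:
        bins = genome.chrom_bins(chrom)
        hot = np.flatnonzero(ratio[bins] >= min_log2)
        if hot.size == 0:
            continue
        # merge runs separated by small gaps
        runs: list[list[int]] = [[hot[0], hot[0]]]
        for b in hot[1:]:
            if b - runs[-1][1] <= merge_gap_bins + 1:
                runs[-1][1] = b
            else:
                runs.append([b, b])
        for lo, hi in runs:
            if hi - lo + 1 < min_bins:
                continue
            start = lo * genome.bin_size
            end = min((hi + 1) * genome.bin_size, genome.lengths[chrom])
            mean_r = float(ratio[bins[lo] : bins[hi] + 1].mean())
            out.append(
                AmplifiedRegion(Region(chrom, start, end), mean_r, hi - lo + 1)
            )
    return out


# ---------------------------------------------------------------------------
# I/O: bedGraph depth tracks, BED region lists, CNV segment tables


def write_bedgraph(track: DepthTrack, path) -> None:
    with open(path, "w") as fh:
        for b in range(track.genome.n_bins):
            chrom, start = track.genome.bin_location(b)
            end = min(start + track.genome.bin_size, track.genome.lengths[chrom])
            fh.write(f"{chrom}\t{start}\t{end}\t{track.values[b]:g}\n")


def read_bedgraph(path, genome: BinnedGenome) -> DepthTrack:
    """Read a 4-column bedGraph into a binned track.

    Interval values are distributed over overlapping bins proportionally to
    overlap, so non-bin-aligned input is tolerated.
    """
    values = np.zeros(genome.n_bins)
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    for chrom, start, end, value in df.itertuples(index=False):
        start, end = int(start), int(end)
        iv_len = end - start
        if iv_len <= 0:
            raise ValueError(f"empty interval {chrom}:{start}-{end} in {path}")
        for b in genome.bins_for_region(Region(chrom, start, end)):
            breg = genome.bin_region(b)
            overlap = min(end, breg.end) - max(start, breg.start)
            values[b] += float(value) * overlap / iv_len
    return DepthTrack(genome, values)


def write_regions_bed(regions: list[AmplifiedRegion], path) -> None:
    """BED3 + mean log2 ratio + bin count."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.region.chrom}\t{r.region.start}\t{r.region.end}\t"
                f"{r.mean_log2_ratio:.4f}\t{r.n_bins}\n"
            )


def read_regions_bed(path) -> list[Region]:
    regions = []
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    for chrom, start, end in df.itertuples(index=False):
        regions.append(Region(chrom, int(start), int(end)))
    return regions


def read_cnv_segments(path) -> pd.DataFrame:
    """Read a CNV segment table: chrom, start, end, log2 (BED-like TSV)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "log2"], dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["log2"] = df["log2"].astype(float)
    return df
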