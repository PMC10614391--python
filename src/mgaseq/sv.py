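"""Junction-sequence logic and split-read structural-variant typing.

Three layers:

* Restriction-enzyme ligation junctions. Proximity ligation after 5'
  overhang fill-in creates a diagnostic chimeric sequence (HindIII A^AGCTT
  gives AAGCTAGCTT); read pairs carrying it are contact evidence and are
  excluded from small-variant calling.
* Split-read breakpoints. A read whose alignment is divided between a
  primary and a supplementary (SA-tag) record pins a junction at
  single-base resolution; candidates from many reads are clustered into
  consolidated breakpoint calls.
* Translocation typing. A breakpoint is unbalanced when the copy-number
  (log2 ratio) level steps across either end; balanced otherwise.
"""
from __future__ import annotations

import logging
import re
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage

from .contacts import ContactMatrix
from .genome import BinnedGenome, Region

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Ligation junctions


@dataclass(frozen=True)
class EnzymeSpec:
    """A palindromic restriction enzyme leaving a 5' overhang.

    ``site`` is the recognition sequence; ``cut_offset`` the distance from
    the site start to the top-strand cut. The 5' overhang is
    site[cut_offset : len(site) - cut_offset].
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        if not re.fullmatch(r"[ACGT]+", site):
            raise ValueError(f"invalid recognition site {self.site!r}")
        if site != reverse_complement(site):
            raise ValueError(
                f"unsupported enzyme {self.name}: site {site} is not palindromic"
            )
        if not (0 <= self.cut_offset <= len(site) / 2):
            raise ValueError(
                f"unsupported enzyme {self.name}: cut offset {self.cut_offset} "
                "implies a 3' overhang"
            )
        object.__setattr__(self, "site", site)

    @property
    def overhang(self) -> str:
        return self.site[self.cut_offset : len(self.site) - self.cut_offset]


HINDIII = EnzymeSpec("HindIII", "AAGCTT", 1)
MBOI = EnzymeSpec("MboI", "GATC", 0)

ENZYMES = {e.name.lower(): e for e in (HINDIII, MBOI)}


def expected_junction(enzyme: EnzymeSpec) -> str:
    """Ligation-junction sequence after 5' fill-in and blunt ligation.

    Filling in the 5' overhang duplicates it at the joint:
    junction = site[:cut] + overhang + overhang + site[-cut:] (if cut > 0).
    HindIII -> AAGCTAGCTT; MboI -> GATCGATC; a blunt cutter gives site+site.
    """
    cut = enzyme.cut_offset
    over = enzyme.overhang
    head = enzyme.site[:cut]
    tail = enzyme.site[cut + len(over):]
    return head + over + over + tail


def partition_junction_reads(
    read_pairs: Iterable[tuple[str, str, str]], junction: str
) -> tuple[list[str], list[str], float | None]:
    """Split read pairs by presence of the ligation-junction sequence.

    Each pair is (read_id, seq1, seq2); a pair carries the junction when
    either mate contains it as a substring on either strand. Returns
    (ids_with, ids_without, fraction_with); the fraction is None for an
    empty stream.
    """
    if not junction:
        raise ValueError("junction sequence must be non-empty")
    junction = junction.upper()
    rc = reverse_complement(junction)
    with_ids: list[str] = []
    without_ids: list[str] = []
    for read_id, seq1, seq2 in read_pairs:
        s1, s2 = seq1.upper(), seq2.upper()
        if junction in s1 or junction in s2 or rc in s1 or rc in s2:
            with_ids.append(read_id)
        else:
            without_ids.append(read_id)
    total = len(with_ids) + len(without_ids)
    if total == 0:
        warnings.warn("empty read-pair stream: junction fraction undefined",
                      stacklevel=2)
        return with_ids, without_ids, None
    return with_ids, without_ids, len(with_ids) / total


# ---------------------------------------------------------------------------
# Split alignments

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

_REF_OPS = set("MDN=X")
_READ_OPS = set("MIS=X")  # H added separately: part of the original read


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


@dataclass(frozen=True)
class AlignedPart:
    """One aligned block of a split read (primary or supplementary)."""

    chrom: str
    pos: int  # 1-based leftmost aligned reference base
    strand: str  # '+' or '-'
    cigar: str
    mapq: int = 60

    def geometry(self) -> tuple[int, int, int, int]:
        """(ref_len, read_len, leading_clip_readcoords, aligned_read_len)."""
        ops = parse_cigar(self.cigar)
        ref_len = sum(n for n, op in ops if op in _REF_OPS)
        read_len = sum(n for n, op in ops if op in _READ_OPS or op == "H")
        first_clip = 0
        for n, op in ops:
            if op in "SH":
                first_clip += n
            else:
                break
        last_clip = 0
        for n, op in reversed(ops):
            if op in "SH":
                last_clip += n
            else:
                break
        lead = first_clip if self.strand == "+" else last_clip
        return ref_len, read_len, lead, read_len - first_clip - last_clip


@dataclass(frozen=True)
class SplitAlignment:
    read_id: str
    primary: AlignedPart
    supplementary: AlignedPart


@dataclass(frozen=True)
class BreakpointEnd:
    """One side of a junction: 1-based coordinate of the last aligned base.

    ``side`` records where the partner sequence attaches: 'right' means the
    retained segment extends leftward of pos (junction at its right edge),
    'left' the mirror case.
    """

    chrom: str
    pos: int
    side: str  # 'left' | 'right'


@dataclass(frozen=True)
class BreakpointCandidate:
    read_id: str
    end_a: BreakpointEnd
    end_b: BreakpointEnd


@dataclass(frozen=True)
class BreakpointCall:
    end_a: BreakpointEnd
    end_b: BreakpointEnd
    support: int
    resolution: str = "base"


@dataclass(frozen=True)
class TranslocationCall:
    breakpoint: BreakpointCall
    type: str  # 'balanced' | 'unbalanced'
    cnv_step_a: float
    cnv_step_b: float


def parse_sam_splits(lines: Iterable[str]) -> Iterator[SplitAlignment]:
    """Extract split alignments from minimal SAM text.

    Accepts the mandatory 11 fields plus tags; '@' header lines are
    ignored. Only non-supplementary records carrying an SA:Z: tag yield a
    SplitAlignment; when SA lists several supplementary alignments the one
    with the highest mapq is used.
    """
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise ValueError(f"SAM record has {len(fields)} fields, need >= 11")
        qname, flag, rname, pos, mapq, cigar = (
            fields[0], int(fields[1]), fields[2], int(fields[3]),
            int(fields[4]), fields[5],
        )
        if flag & 0x800:  # supplementary record: represented via the SA tag
            continue
        sa = None
        for tag in fields[11:]:
            if tag.startswith("SA:Z:"):
                sa = tag[5:]
                break
        if sa is None:
            continue
        strand = "-" if flag & 0x10 else "+"
        supp = _best_sa_part(sa)
        yield SplitAlignment(
            qname,
            AlignedPart(rname, pos, strand, cigar, mapq),
            supp,
        )


def _best_sa_part(sa: str) -> AlignedPart:
    best: AlignedPart | None = None
    for entry in sa.strip(";").split(";"):
        if not entry:
            continue
        parts = entry.split(",")
        if len(parts) < 6:
            raise ValueError(f"malformed SA entry {entry!r}")
        chrom, pos, strand, cigar, mapq = (
            parts[0], int(parts[1]), parts[2], parts[3], int(parts[4]),
        )
        cand = AlignedPart(chrom, pos, strand, cigar, mapq)
        if best is None or cand.mapq > best.mapq:
            best = cand
    if best is None:
        raise ValueError(f"empty SA tag {sa!r}")
    return best


def read_splits_tsv(path) -> list[SplitAlignment]:
    """Read split alignments from a flat TSV:
    read_id, chrom, pos, strand, cigar, SA-string."""
    out = []
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["read_id", "chrom", "pos", "strand", "cigar", "sa"],
        dtype={"read_id": str, "chrom": str, "strand": str, "cigar": str, "sa": str},
    )
    for row in df.itertuples(index=False):
        out.append(
            SplitAlignment(
                row.read_id,
                AlignedPart(row.chrom, int(row.pos), row.strand, row.cigar),
                _best_sa_part(row.sa),
            )
        )
    return out


def breakpoint_from_split(aln: SplitAlignment) -> BreakpointCandidate:
    """Derive the base-exact junction from one split alignment.

    The two parts are ordered along the read by their leading soft/hard
    clip in read coordinates; the junction is the last aligned reference
    base of the read-upstream part against the first aligned reference base
    of the read-downstream part. Micro-homology (overlapping read coverage)
    is left-aligned: the upstream part keeps the shared bases.
    """
    pa, pb = aln.primary, aln.supplementary
    ga, gb = pa.geometry(), pb.geometry()
    if ga[1] != gb[1]:
        raise ValueError(
            f"read {aln.read_id}: CIGARs disagree on read length "
            f"({pa.cigar} -> {ga[1]} vs {pb.cigar} -> {gb[1]})"
        )
    if ga[2] == gb[2]:
        raise ValueError(
            f"read {aln.read_id}: both parts clipped on the same side "
            f"({pa.cigar}/{pb.cigar})"
        )
    (up, gup), (down, gdown) = sorted(
        [(pa, ga), (pb, gb)], key=lambda t: t[1][2]
    )
    overlap = (gup[2] + gup[3]) - gdown[2]  # shared read bases (micro-homology)
    if overlap >= gdown[3]:
        raise ValueError(
            f"read {aln.read_id}: downstream part fully contained in upstream"
        )
    o = max(0, overlap)
    if up.strand == "+":
        end_a = BreakpointEnd(up.chrom, up.pos + gup[0] - 1, "right")
    else:
        end_a = BreakpointEnd(up.chrom, up.pos, "left")
    if down.strand == "+":
        end_b = BreakpointEnd(down.chrom, down.pos + o, "left")
    else:
        end_b = BreakpointEnd(down.chrom, down.pos + gdown[0] - 1 - o, "right")
    return _canonical(BreakpointCandidate(aln.read_id, end_a, end_b))


def _canonical(cand: BreakpointCandidate) -> BreakpointCandidate:
    a, b = cand.end_a, cand.end_b
    if (b.chrom, b.pos) < (a.chrom, a.pos):
        return BreakpointCandidate(cand.read_id, b, a)
    return cand


def _mode_pos(positions: Sequence[int]) -> int:
    counts = Counter(positions)
    top = max(counts.values())
    return min(p for p, c in counts.items() if c == top)


def cluster_breakpoints(
    candidates: Iterable[BreakpointCandidate], tolerance_bp: int = 5
) -> list[BreakpointCall]:
    """Consolidate per-read candidates into breakpoint calls.

    Candidates sharing (chromA, sideA, chromB, sideB) are single-linkage
    clustered with both ends within tolerance; the reported position is the
    mode of member positions (ties -> smallest) and support the number of
    distinct reads.
    """
    groups: dict[tuple, list[BreakpointCandidate]] = {}
    for cand in candidates:
        cand = _canonical(cand)
        key = (cand.end_a.chrom, cand.end_a.side, cand.end_b.chrom, cand.end_b.side)
        groups.setdefault(key, []).append(cand)
    calls: list[BreakpointCall] = []
    for key, members in groups.items():
        members.sort(key=lambda c: (c.end_a.pos, c.end_b.pos))
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if members[j].end_a.pos - members[i].end_a.pos > tolerance_bp:
                    break
                if abs(members[j].end_b.pos - members[i].end_b.pos) <= tolerance_bp:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[BreakpointCandidate]] = {}
        for i, cand in enumerate(members):
            clusters.setdefault(find(i), []).append(cand)
        for cluster in clusters.values():
            pos_a = _mode_pos([c.end_a.pos for c in cluster])
            pos_b = _mode_pos([c.end_b.pos for c in cluster])
            calls.append(
                BreakpointCall(
                    BreakpointEnd(key[0], pos_a, key[1]),
                    BreakpointEnd(key[2], pos_b, key[3]),
                    support=len({c.read_id for c in cluster}),
                )
            )
    calls.sort(key=lambda c: (c.end_a.chrom, c.end_a.pos, c.end_b.chrom, c.end_b.pos))
    return calls


# ---------------------------------------------------------------------------
# Contact-matrix screening for rearrangement loci


def screen_trans_blocks(
    matrix: ContactMatrix,
    z_threshold: float = 8.0,
    min_bins: int = 3,
) -> list[tuple[Region, Region, int]]:
    """Flag inter-chromosomal blocks of anomalously high contact.

    For each chromosome pair, bin pairs exceeding mean + z_threshold * sd of
    that pair's trans counts are connected-component clustered (8-neighbour)
    and components of >= min_bins cells are returned as candidate
    rearrangement loci (Region on each chromosome, number of hot cells) to
    guide split-read breakpoint searching.
    """
    genome = matrix.genome
    out: list[tuple[Region, Region, int]] = []
    for ai in range(len(genome.names)):
        for bi in range(ai + 1, len(genome.names)):
            ca, cb = genome.names[ai], genome.names[bi]
            bins_a, bins_b = genome.chrom_bins(ca), genome.chrom_bins(cb)
            blk = matrix.block(bins_a, bins_b)
            if blk.sum() == 0:
                continue
            mu, sd = blk.mean(), blk.std()
            hot = blk > mu + z_threshold * sd
            if not hot.any():
                continue
            labels, n_lab = scipy.ndimage.label(hot, structure=np.ones((3, 3)))
            for lab in range(1, n_lab + 1):
                cells = labels == lab
                if cells.sum() < min_bins:
                    continue
                rows = np.flatnonzero(cells.any(axis=1))
                cols = np.flatnonzero(cells.any(axis=0))
                reg_a = Region(
                    ca,
                    rows[0] * genome.bin_size,
                    min((rows[-1] + 1) * genome.bin_size, genome.lengths[ca]),
                )
                reg_b = Region(
                    cb,
                    cols[0] * genome.bin_size,
                    min((cols[-1] + 1) * genome.bin_size, genome.lengths[cb]),
                )
                out.append((reg_a, reg_b, int(cells.sum())))
    return out


# ---------------------------------------------------------------------------
# Balanced / unbalanced typing from CNV steps


def _interval_log2(cnv: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Overlap-weighted mean log2 over [start, end) from a segment table."""
    sel = cnv[cnv["chrom"] == chrom]
    if start >= end:
        return np.nan
    ov = np.minimum(sel["end"].to_numpy(), end) - np.maximum(
        sel["start"].to_numpy(), start
    )
    ov = np.clip(ov, 0, None).astype(float)
    total = ov.sum()
    if total == 0:
        return np.nan
    return float((sel["log2"].to_numpy() * ov).sum() / total)


def classify_translocation(
    bp: BreakpointCall,
    cnv: pd.DataFrame,
    flank_bins: int = 10,
    step_threshold_log2: float = 0.3,
    bin_size: int = 50_000,
    chrom_lengths: dict[str, int] | None = None,
) -> TranslocationCall:
    """Type a breakpoint as balanced or unbalanced from CNV evidence.

    For each end, the copy-number step is the mean log2 ratio over
    ``flank_bins`` bins downstream of the breakpoint minus the mean over the
    same flank upstream; the call is unbalanced when either |step| reaches
    ``step_threshold_log2``. Flanks truncated by a chromosome end are
    reduced with a warning.
    """
    flank = flank_bins * bin_size
    steps = []
    for end in (bp.end_a, bp.end_b):
        pos0 = end.pos  # 1-based; use as the boundary between flanks
        lo = pos0 - flank
        hi = pos0 + flank
        if lo < 0:
            warnings.warn(
                f"breakpoint {end.chrom}:{end.pos} within {flank} bp of "
                "chromosome start; flank reduced", stacklevel=2,
            )
            lo = 0
        if chrom_lengths is not None and hi > chrom_lengths.get(end.chrom, hi):
            warnings.warn(
                f"breakpoint {end.chrom}:{end.pos} within {flank} bp of "
                "chromosome end; flank reduced", stacklevel=2,
            )
            hi = chrom_lengths[end.chrom]
        up = _interval_log2(cnv, end.chrom, lo, pos0)
        down = _interval_log2(cnv, end.chrom, pos0, hi)
        if np.isnan(up) or np.isnan(down):
            raise ValueError(
                f"CNV table does not cover the neighbourhood of "
                f"{end.chrom}:{end.pos}"
            )
        steps.append(down - up)
    step_a, step_b = steps
    kind = (
        "unbalanced"
        if max(abs(step_a), abs(step_b)) >= step_threshold_log2
        else "balanced"
    )
    return TranslocationCall(bp, kind, step_a, step_b)


def write_translocations_tsv(calls: list[TranslocationCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chromA\tposA\tsideA\tchromB\tposB\tsideB\tsupport\ttype\t"
            "cnv_step_A\tcnv_step_B\n"
        )
        for c in calls:
            bp = c.breakpoint
            fh.write(
                f"{bp.end_a.chrom}\t{bp.end_a.pos}\t{bp.end_a.side}\t"
                f"{bp.end_b.chrom}\t{bp.end_b.pos}\t{bp.end_b.side}\t"
                f"{bp.support}\t{c.type}\t{c.cnv_step_a:.4f}\t{c.cnv_step_b:.4f}\n"
            )
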