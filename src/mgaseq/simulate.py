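"""Seeded synthetic-data generators for every input the toolkit consumes.

The simulator encodes the physical picture behind the classifier: a
focally amplified region whose inter-chromosomal contacts are either
dispersed genome-wide (ecDNA, which floats freely through the nucleus) or
concentrated around a single insertion locus (HSR, which is anchored to
one chromosomal territory). Around that, it produces power-law cis contact
decay, uniform trans background, Poisson depth tracks over a planted copy
profile, split reads spanning defined junctions, and read pairs carrying
the proximity-ligation junction sequence — all deterministically from a
seed.

The two amplification modes are matched in expected total contact count by
construction: the amplicon's extra trans budget is identical, only its
placement differs. Classification accuracy on these simulations is
therefore attributable to contact placement, not library size.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .focal_amp import DepthTrack
from .genome import BinnedGenome, Region

DEFAULT_CHROMS: tuple[tuple[str, int], ...] = tuple(
    (f"chr{i}", 20_000_000) for i in range(1, 6)
)


@dataclass(frozen=True)
class TranslocationSpec:
    """A planted junction: last aligned base on A joined to first on B.

    ``cnv_step`` is the log2 copy change downstream of pos_a on chrom_a
    (0 for a balanced translocation).
    """

    chrom_a: str
    pos_a: int  # 1-based
    chrom_b: str
    pos_b: int  # 1-based
    split_support: int = 20
    cnv_step: float = 0.0

    @property
    def balanced(self) -> bool:
        return self.cnv_step == 0.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults describe a toy genome of 5 chromosomes x 20 Mb binned at
    100 kb (1,000 bins), a 1.6 Mb amplicon at 30 copies on a diploid
    background, a trans contact background of 0.05 expected counts per bin
    pair, power-law cis decay with exponent 1, Poisson depth at 100 reads
    per copy per 50 kb bin, and a 1.5% ligation-junction pair fraction.
    """

    seed: int = 0
    chroms: tuple[tuple[str, int], ...] = DEFAULT_CHROMS
    bin_size: int = 100_000
    depth_bin_size: int = 50_000
    cis_decay_exponent: float = 1.0
    cis_rate: float = 5.0
    trans_background_rate: float = 0.05
    amplicon: Region = field(
        default_factory=lambda: Region("chr1", 8_000_000, 9_600_000)
    )
    copy_number: int = 30
    background_copy: int = 2
    mode: str = "none"  # 'ecdna' | 'hsr' | 'none'
    hsr_insertion: Region | None = None
    hsr_spread_bp: int = 1_000_000
    translocations: tuple[TranslocationSpec, ...] = ()
    reads_per_copy_per_bin: float = 100.0
    cnv_noise_sd: float = 0.1
    junction_fraction: float = 0.015
    read_length: int = 100
    min_clip: int = 20

    def __post_init__(self) -> None:
        if self.mode not in ("none", "ecdna", "hsr"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "hsr" and self.hsr_insertion is None:
            raise ValueError("HSR mode requires an hsr_insertion region")
        for rate in (self.cis_rate, self.trans_background_rate,
                     self.reads_per_copy_per_bin):
            if rate < 0:
                raise ValueError("rates must be non-negative")

    def genome(self) -> BinnedGenome:
        return BinnedGenome(self.chroms, self.bin_size)

    def depth_genome(self) -> BinnedGenome:
        return BinnedGenome(self.chroms, self.depth_bin_size)


def default_hsr_insertion() -> Region:
    """A single-bin insertion locus in the middle of chr3."""
    return Region("chr3", 10_000_000, 10_100_000)


def _copy_profile(cfg: SimConfig, genome: BinnedGenome) -> np.ndarray:
    copies = np.full(genome.n_bins, float(cfg.background_copy))
    copies[genome.bins_for_region(cfg.amplicon)] = float(cfg.copy_number)
    for t in cfg.translocations:
        if t.cnv_step != 0.0:
            factor = 2.0 ** t.cnv_step
            off = genome.offsets[t.chrom_a]
            first = (t.pos_a - 1) // genome.bin_size + 1  # bins fully downstream
            copies[off + first : off + genome.n_chrom_bins(t.chrom_a)] *= factor
    return copies


def simulate_contact_matrix(cfg: SimConfig) -> ContactMatrix:
    """Draw a Poisson contact matrix under the configured amplification mode.

    Cis expectation: cis_rate * (copy_i * copy_j / bg^2) / (d + 1)^alpha for
    bins d apart. Trans expectation: a uniform background plus, for the
    amplicon, an extra budget of trans_background_rate * copy_number per
    (amplicon bin, eligible trans bin) pair — spread uniformly over all
    trans bins in ecDNA mode, concentrated with triangular weights around
    the insertion locus (+- hsr_spread_bp) in HSR mode. The expected extra
    total is identical in the two modes.
    """
    genome = cfg.genome()
    rng = np.random.default_rng(cfg.seed)
    n = genome.n_bins
    copies = _copy_profile(cfg, genome)
    rel = copies / cfg.background_copy
    lam = np.full((n, n), cfg.trans_background_rate)
    # cis blocks with power-law decay
    for chrom in genome.names:
        bins = genome.chrom_bins(chrom)
        nb = bins.size
        d = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb)))
        block = cfg.cis_rate / (d + 1.0) ** cfg.cis_decay_exponent
        block *= np.outer(rel[bins], rel[bins])
        lam[np.ix_(bins, bins)] = block
    # amplification-mode trans extras on the amplicon's rows/columns
    amp_bins = genome.bins_for_region(cfg.amplicon)
    trans_mask = ~genome.chrom_mask(cfg.amplicon.chrom)
    elig = np.flatnonzero(trans_mask)
    per_pair_budget = cfg.trans_background_rate * cfg.copy_number
    if cfg.mode == "ecdna":
        extra = np.full(elig.size, per_pair_budget)
    elif cfg.mode == "hsr":
        ins = cfg.hsr_insertion
        center = (ins.start + ins.end) / 2.0
        weights = np.zeros(elig.size)
        for k, b in enumerate(elig):
            chrom, start = genome.bin_location(b)
            if chrom != ins.chrom:
                continue
            mid = start + genome.bin_size / 2.0
            w = 1.0 - abs(mid - center) / cfg.hsr_spread_bp
            weights[k] = max(0.0, w)
        if weights.sum() == 0:
            raise ValueError("hsr_insertion neighbourhood has no eligible bins")
        extra = per_pair_budget * elig.size * weights / weights.sum()
    else:
        extra = None
    if extra is not None:
        for a in amp_bins:
            lam[a, elig] += extra
            lam[elig, a] += extra
    # draw the upper triangle only (symmetric storage, diagonal once)
    iu, ju = np.triu_indices(n)
    counts = rng.poisson(lam[iu, ju])
    nz = counts > 0
    return ContactMatrix.from_entries(genome, iu[nz], ju[nz], counts[nz])


def simulate_depth_track(cfg: SimConfig) -> tuple[DepthTrack, pd.DataFrame]:
    """Poisson read-depth track over the planted copy profile, plus truth.

    value_b ~ Poisson(copy_b * reads_per_copy_per_bin). The truth table
    lists the planted amplicon and each CNV step interval.
    """
    genome = cfg.depth_genome()
    rng = np.random.default_rng(cfg.seed + 1)
    copies = _copy_profile(cfg, genome)
    values = rng.poisson(copies * cfg.reads_per_copy_per_bin).astype(float)
    rows = [
        {
            "kind": "amplicon",
            "chrom": cfg.amplicon.chrom,
            "start": cfg.amplicon.start,
            "end": cfg.amplicon.end,
            "copy": cfg.copy_number,
        }
    ]
    for t in cfg.translocations:
        if t.cnv_step != 0.0:
            rows.append(
                {
                    "kind": "cnv_step",
                    "chrom": t.chrom_a,
                    "start": t.pos_a,
                    "end": genome.lengths[t.chrom_a],
                    "copy": cfg.background_copy * 2.0 ** t.cnv_step,
                }
            )
    return DepthTrack(genome, values), pd.DataFrame(rows)


def simulate_cnv_segments(cfg: SimConfig) -> pd.DataFrame:
    """Per-bin CNV segment table (chrom, start, end, log2) with noise.

    log2 baseline 0 everywhere, stepping by cnv_step downstream of each
    planted unbalanced junction, plus N(0, cnv_noise_sd) per bin.
    """
    genome = cfg.depth_genome()
    rng = np.random.default_rng(cfg.seed + 2)
    log2 = rng.normal(0.0, cfg.cnv_noise_sd, genome.n_bins)
    for t in cfg.translocations:
        if t.cnv_step != 0.0:
            off = genome.offsets[t.chrom_a]
            first = (t.pos_a - 1) // genome.bin_size + 1
            log2[off + first : off + genome.n_chrom_bins(t.chrom_a)] += t.cnv_step
    rows = []
    for b in range(genome.n_bins):
        chrom, start = genome.bin_location(b)
        end = min(start + genome.bin_size, genome.lengths[chrom])
        rows.append({"chrom": chrom, "start": start, "end": end, "log2": log2[b]})
    return pd.DataFrame(rows)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_split_reads(cfg: SimConfig) -> tuple[str, pd.DataFrame]:
    """SAM text of split reads spanning each planted junction, plus truth.

    Each read of length L is split at a random point s in
    [min_clip, L - min_clip]: its first s bases align ending at pos_a on
    chrom_a (primary, sM (L-s)S) and the remainder aligns starting at pos_b
    on chrom_b (supplementary via SA tag, sS (L-s)M). The truth table lists
    the exact planted coordinates and type.
    """
    genome = cfg.genome()
    rng = np.random.default_rng(cfg.seed + 3)
    L = cfg.read_length
    if L < 2 * cfg.min_clip:
        raise ValueError("read length shorter than twice the minimum clip")
    lines = []
    for name, length in cfg.chroms:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    truth_rows = []
    for ti, t in enumerate(cfg.translocations):
        for chrom, pos in ((t.chrom_a, t.pos_a), (t.chrom_b, t.pos_b)):
            if not (L < pos <= genome.lengths[chrom] - L):
                raise ValueError(
                    f"junction end {chrom}:{pos} too close to a chromosome "
                    f"end for {L} bp reads"
                )
        for ri in range(t.split_support):
            s = int(rng.integers(cfg.min_clip, L - cfg.min_clip + 1))
            qname = f"tr{ti}_read{ri}"
            seq = _random_seq(rng, L)
            p_pos = t.pos_a - s + 1
            p_cigar = f"{s}M{L - s}S"
            s_cigar = f"{s}S{L - s}M"
            sa_on_primary = f"SA:Z:{t.chrom_b},{t.pos_b},+,{s_cigar},60,0;"
            sa_on_supp = f"SA:Z:{t.chrom_a},{p_pos},+,{p_cigar},60,0;"
            lines.append(
                f"{qname}\t0\t{t.chrom_a}\t{p_pos}\t60\t{p_cigar}\t*\t0\t0\t"
                f"{seq}\t*\t{sa_on_primary}"
            )
            lines.append(
                f"{qname}\t2048\t{t.chrom_b}\t{t.pos_b}\t60\t{s_cigar}\t*\t0\t0\t"
                f"{seq}\t*\t{sa_on_supp}"
            )
        truth_rows.append(
            {
                "chrom_a": t.chrom_a,
                "pos_a": t.pos_a,
                "chrom_b": t.chrom_b,
                "pos_b": t.pos_b,
                "type": "balanced" if t.balanced else "unbalanced",
                "split_support": t.split_support,
                "cnv_step": t.cnv_step,
            }
        )
    sam_text = "\n".join(lines) + ("\n" if lines else "")
    return sam_text, pd.DataFrame(
        truth_rows,
        columns=["chrom_a", "pos_a", "chrom_b", "pos_b", "type",
                 "split_support", "cnv_step"],
    )


def simulate_read_pairs_with_junction(
    cfg: SimConfig, n_pairs: int, junction: str = "AAGCTAGCTT"
) -> tuple[list[tuple[str, str, str]], set[str]]:
    """Read pairs with the ligation junction planted in an exact fraction.

    Exactly round(n_pairs * junction_fraction) pairs carry the junction as
    a substring of one mate; the rest are guaranteed junction-free on both
    strands. Returns (pairs, truth id set).
    """
    if not (0 <= cfg.junction_fraction <= 1):
        raise ValueError("junction_fraction must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed + 4)
    k = round(n_pairs * cfg.junction_fraction)
    carriers = set(rng.choice(n_pairs, size=k, replace=False).tolist())
    from .sv import reverse_complement

    rc = reverse_complement(junction)
    L = max(cfg.read_length, len(junction))
    pairs = []
    truth = set()
    for i in range(n_pairs):
        rid = f"pair{i}"
        seqs = []
        for _ in range(2):
            seq = _random_seq(rng, L)
            while junction in seq or rc in seq:
                seq = _random_seq(rng, L)
            seqs.append(seq)
        if i in carriers:
            mate = int(rng.integers(0, 2))
            off = int(rng.integers(0, L - len(junction) + 1))
            s = seqs[mate]
            seqs[mate] = s[:off] + junction + s[off + len(junction):]
            truth.add(rid)
        pairs.append((rid, seqs[0], seqs[1]))
    return pairs, truth


def random_translocations(
    n: int,
    seed: int,
    chroms: tuple[tuple[str, int], ...] = DEFAULT_CHROMS,
    split_support: int = 20,
    steps: tuple[float, ...] = (-1.0, 0.0),
    margin: int = 2_000_000,
    min_sep: int = 2_000_000,
) -> tuple[TranslocationSpec, ...]:
    """Plant n well-separated inter-chromosomal junctions.

    Chromosome pairs cycle; breakpoint ends keep ``margin`` bp from
    chromosome ends and ``min_sep`` bp from every other planted end on the
    same chromosome, so split-read clusters and CNV flanks never interfere.
    ``steps`` cycles per junction (log2 step downstream on the A chromosome;
    0 plants a balanced translocation).
    """
    rng = np.random.default_rng(seed)
    names = [c[0] for c in chroms]
    lengths = dict(chroms)
    pairs = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(len(names))
        if i != j
    ]
    used: dict[str, list[int]] = {name: [] for name in names}
    out = []
    k = 0
    for idx in range(n):
        for _ in range(1000):
            ca, cb = pairs[k % len(pairs)]
            k += 1
            pa = int(rng.integers(margin, lengths[ca] - margin))
            pb = int(rng.integers(margin, lengths[cb] - margin))
            if all(abs(pa - p) >= min_sep for p in used[ca]) and all(
                abs(pb - p) >= min_sep for p in used[cb]
            ):
                break
        else:
            raise RuntimeError("could not place translocations with min_sep")
        used[ca].append(pa)
        used[cb].append(pb)
        out.append(
            TranslocationSpec(ca, pa, cb, pb, split_support,
                              steps[idx % len(steps)])
        )
    return tuple(out)


def matched_mode_configs(base: SimConfig) -> tuple[SimConfig, SimConfig]:
    """The ecDNA/HSR pair of configs differing only in contact placement."""
    ins = base.hsr_insertion or default_hsr_insertion()
    return (
        replace(base, mode="ecdna"),
        replace(base, mode="hsr", hsr_insertion=ins),
    )
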