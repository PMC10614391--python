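# Methods

## Problem setting

A single proximity-ligation sequencing library contains two read
populations: pairs carrying the restriction-enzyme ligation junction
(chromatin-contact evidence) and ordinary genomic pairs (depth, SNV/indel
and split-read evidence). This package implements the downstream analyses
that combine both populations: contact-matrix construction and profiling,
ecDNA/HSR discrimination, focal-amplification calling, split-read
breakpoint calling with translocation typing, and amplicon/coamplification
network construction.

## Genome binning and contact matrices

The genome is partitioned into fixed-size bins (`ceil(length / bin_size)`
per chromosome; position `p` belongs to bin `floor(p / bin_size)`).
Contact-analysis defaults to 100 kb bins; depth/CNV analyses to 50 kb.
Coordinates are 0-based half-open internally and 1-based inclusive in all
human-facing output (SAM/VCF display convention).

Contact matrices are symmetric and stored as a scipy.sparse upper triangle
with the diagonal counted once; COO text input is folded to the upper
triangle with duplicate records summed (tolerant dialect). Raw counts are
used throughout — no ICE/balancing — because the fluctuation statistic
below is scale-free, so library-size normalization cannot change its value.

A region's *contact profile* is the per-bin total contact count between any
of its bins and each genome bin. Bins overlapping the query are always
masked (amplicon self-contacts would otherwise dominate the cumulative
curve). By default the whole query chromosome is masked as well
(`trans_only=True`): the discrimination problem is about *inter*-chromosomal
contact placement, and the strong, smooth cis-decay component is common to
both amplification forms, so including it only dilutes the signal. A
genome-wide (cis-included) profile remains available via configuration.

## Genome-wide interaction fluctuation analysis

Over the retained counts `C_1..C_n` (genome order, masked bins removed —
removing them before differencing avoids artificial spikes at mask
boundaries):

* `CII_x = Σ_{i≤x} C_i` (with `CII_0 = 0`);
* `SOBDc_x = (Σ_{i=x−h+1..x} C_i − Σ_{j=x−2h+1..x−h} C_j) / h²` for
  `x ∈ [2h, n]`, equal to `(CII_x − 2·CII_{x−h} + CII_{x−2h}) / h²`;
* `FS = Σ_{i≤k} S_i / Σ_{j≤m} S_j` with `S` the descending-sorted
  `|SOBDc|`, `m` its length and `k = ⌈top_fraction · m⌉` (the ceiling
  guarantees `k ≥ 1` for short profiles);
* call: ecDNA if `FS < T`, HSR if `FS > T`; `FS = T` is reported as
  `ambiguous` with a warning rather than silently resolved.

Parameter defaults: `h = 3` bins (the spacing of the backward difference;
larger `h` smooths noise at the cost of positional resolution),
`top_fraction = 0.1`, `T = 0.5`. `T` is exposed as a tunable decision
threshold; 0.5 sits roughly midway between the FS levels the bundled
simulations produce for dispersed (~0.26) and concentrated (~0.97)
contact placement and is comfortably separated from both.

Numerical properties asserted by the test suite: the two SOBD forms agree
exactly on integer counts; `FS ∈ (0, 1]`; FS is invariant to positive
scaling of all counts and to a constant per-bin offset (a linear CII ramp).
Consequently the optional ordinary-least-squares detrending of CII is
diagnostic output only — it can never change FS or the call — and is kept
because the residual curve is useful for visual inspection of uneven
coverage. An all-zero SOBD vector (a region with no trans contacts) is an
error, not a call: the ratio is 0/0 and the region is unclassifiable.

Degenerate inputs: profiles shorter than `2h` retained bins are rejected;
an all-masked profile is rejected (`empty profile`).

## Focal-amplification calling

Depth tracks are Poisson-like binned read counts, optionally normalized to
counts per million mapped reads. The per-bin log2 copy ratio is
`log2((s_b + p)/(r_b + p))` against a reference track or the sample's own
genome-wide median (`p = 0.5` pseudocount avoids log of zero). The caller
is a transparent threshold-and-merge scan: maximal runs of bins with ratio
≥ `min_log2` (default 1.0), runs separated by ≤ `merge_gap_bins` (default
1) merged, merged runs shorter than `min_bins` (default 2) dropped. A 5×
amplification on a diploid background (log2 ≈ 2.3) is therefore always
called. This deliberately replaces a full CNV segmenter; externally
produced segment tables (chrom, start, end, log2) can be substituted
directly via `read_cnv_segments`.

## Split-read breakpoints and translocation typing

Split alignments are taken from minimal SAM text (mandatory 11 fields plus
`SA:Z:`; headers optional; supplementary records are skipped so each read
is counted once; when the SA tag lists several alignments the highest-mapq
one is used). The two parts are ordered along the read by their leading
clip in read coordinates; the breakpoint is the last aligned reference base
of the read-upstream part joined to the first aligned reference base of the
read-downstream part, computed from the reference-consuming CIGAR length
(M/D/N/=/X). Micro-homology (read bases covered by both parts) is
left-aligned: the upstream part keeps the shared bases. Each end records
the side at which the partner attaches, which downstream boundary matching
uses to orient segments.

Per-read candidates sharing (chromA, sideA, chromB, sideB) are
single-linkage clustered with both ends within `tolerance_bp` (default 5);
the reported coordinate is the mode of member positions (ties resolved to
the smallest), support the number of distinct reads.

Candidate rearrangement loci can also be screened directly from the
contact matrix: per chromosome pair, trans bin pairs exceeding
`mean + z·sd` (default z = 8) are connected-component clustered and blocks
of ≥ 3 cells reported — a guide for where to look for split reads, not a
breakpoint caller.

Typing: for each breakpoint end, the copy-number step is the
overlap-weighted mean log2 ratio over `flank_bins` (default 10) bins
downstream minus upstream; the translocation is *unbalanced* when either
|step| ≥ `step_threshold_log2` (default 0.3, ≈ one copy at tetraploid
baseline — conservative and exposed in config), *balanced* otherwise.
Flanks truncated by a chromosome end are reduced with a warning.

## Amplicon assembly and coamplification network

Called amplified regions become segments with two ends (L/R at the region
boundaries). A breakpoint whose two ends each fall within
`boundary_tol_bp` (default 1 kb) of segment boundaries (side-compatible)
becomes a junction edge; ends landing inside a segment body are excluded
and logged. During path assembly each segment end retains at most one
junction edge (highest support; losing ends are surfaced as an ambiguity
list rather than forced into a path — heterogeneous tumours genuinely
carry conflicting junctions). Walking end-to-end yields maximal paths:
linear, or circular when the walk returns to its start; a circular walk
closed by a junction from the last segment's R end to the first segment's
L end is flagged head-to-tail tandem (a single self-joined segment is the
minimal case; an all-forward multi-segment cycle also satisfies the rule,
which matches how a repeating multi-segment HSR unit presents). Circular
paths are canonicalized over rotation and reflection to start at the
lexicographically smallest segment id, making output deterministic.

The coamplification network keeps *all* junction edges (support ≥
`min_support`): nodes are segments (annotatable with gene labels), and each
edge carries split support plus `contact_strength` = total contacts between
the two regions divided by the number of bin pairs. The bin-pair
denominator is a declared design choice — it makes strength independent of
segment size and symmetric; no canonical formula exists for this weight.

## The simulator: what it emulates

All generators are deterministic functions of a `SimConfig` (seed
included). The default toy genome is 5 chromosomes × 20 Mb at 100 kb bins
(1,000 bins) — large enough for `n ≫ 2h` and a stable FS, small enough for
seconds-scale tests — with a 1.6 Mb amplicon (16 bins) at copy 30 on a
diploid background, mirroring a MYC-amplicon-sized region.

Contact matrices: Poisson counts with cis expectation
`cis_rate · (copy_i·copy_j / bg²) / (d+1)^α` (α = 1, `cis_rate` = 5) and a
uniform trans background (0.05 expected counts per bin pair). The two
amplification modes add an identical expected extra trans budget for the
amplicon — `trans_background_rate · copy_number` per (amplicon bin,
eligible trans bin) pair — differing only in placement: spread uniformly
over all trans bins (ecDNA) or concentrated with triangular weights over
the insertion locus ± 1 Mb (HSR; the linear taper avoids a hard-edge
artifact). The amplicon's *baseline* trans rate is copy-independent: an
HSR occupies a single chromosomal territory, so its per-locus trans
contact rate does not scale with copy number, whereas ecDNA mobility makes
it scale — that asymmetry is precisely the signal being modelled. Matched
expected totals between modes mean classification accuracy measures
contact placement, not library size.

Depth: `Poisson(copy_b · reads_per_copy_per_bin)` at 50 kb bins (default
rate 100 per copy). CNV tables: per-bin log2 with planted steps downstream
of unbalanced junctions plus N(0, 0.1) noise. Split reads: each planted
junction emits reads split at a uniformly random position (≥ 20 bp on each
side of a 100 bp read), with exact primary/supplementary CIGARs — decoding
them is an inverse-function property the tests assert. Junction-carrying
read pairs: exactly `round(n · 0.015)` of n pairs carry the junction
substring (1.5% is the carrier fraction observed in real libraries of this
type); non-carriers are rejection-sampled to be junction-free on both
strands.

What the simulations do **not** show: real Hi-C counts are over-dispersed
(negative binomial) and distance decay is not a clean power law; mapping
artifacts, repeats and copy-number-driven coverage bias are absent; reads
carry random bases, so alignment itself is never exercised; the ecDNA/HSR
separation margin on real tissue (where forms can coexist and purity is
< 1) will be narrower than on these clean simulations. Samples where ecDNA
and HSR coexist are outside the classifier's scope — the statistic assumes
one dominant form per amplicon.

## Problem sizes used in the bundled checks

The acceptance script and test suite use: 1,000 random profiles for the
SOBD identity; 100 simulations per mode for discrimination; 50 seeds × 10
planted translocations (support 20) for breakpoint recovery and typing; 50
trials each for circle and tandem assembly; 10,000 read pairs for junction
partitioning. These sizes give stable percentages while keeping a full run
in the tens of seconds on one CPU.

## Known limitations

* The FA caller is a threshold scan, not a segmentation model; noisy or
  low-amplitude amplifications need an external segmenter, whose output
  the pipeline accepts.
* Translocation typing assumes CNV coverage of both breakpoint
  neighbourhoods and a roughly constant baseline within the flank.
* Assembly retains one junction per segment end; subclonal structures are
  reported as ambiguities, not enumerated as alternative paths.
* The ecDNA/HSR threshold `T = 0.5` was chosen from the bundled
  simulations; cohorts with different contact depth or amplicon size may
  warrant recalibration (the parameter is exposed everywhere).
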