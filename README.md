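# mgaseq

Downstream analysis toolkit for one-library genome-abnormality profiling by
proximity-ligation sequencing. From a single sequencing library that mixes
ordinary genomic reads with ligation-junction (chromatin-contact) reads, the
package:

* **discriminates ecDNA from HSR** — the two physical forms of focal
  oncogene amplification — by genome-wide interaction fluctuation analysis
  of the chromatin-contact matrix;
* **partitions read pairs** by the restriction-enzyme ligation-junction
  sequence (HindIII fill-in junction `AAGCTAGCTT`; MboI `GATCGATC`), so
  junction-free reads can feed small-variant callers;
* **calls focally amplified regions** from binned read depth;
* **calls translocation breakpoints at single-base resolution** from
  split-read (SA-tag) alignments and types them balanced/unbalanced from
  copy-number steps;
* **assembles amplicon structure** (linear / circular / head-to-tail
  tandem) from boundary split reads and builds a **coamplification
  network** of amplified regions weighted by chromatin-contact strength;
* ships a **seeded simulator** for every input, so the whole pipeline runs
  and is testable without any external data.

Intended users: cancer-genomics and clinical-genetics analysts working with
Hi-C-like proximity-ligation libraries.

## The statistic at the core

Extrachromosomal DNA (ecDNA) moves freely through the nucleus and contacts
every chromosome; a homogeneously staining region (HSR) is anchored at one
insertion locus, so its inter-chromosomal contacts concentrate there. Given
the amplicon's per-bin contact counts `C_1..C_n` across the genome (100 kb
bins, amplicon bins masked), the package computes:

* cumulative interaction intensity — `CII_x = Σ_{i≤x} C_i`;
* second-order backward difference with spacing `h` (default 3) —
  `SOBDc_x = (Σ_{i=x−h+1..x} C_i − Σ_{j=x−2h+1..x−h} C_j) / h²`,
  defined for `x ∈ [2h, n]`; algebraically
  `(CII_x − 2·CII_{x−h} + CII_{x−2h}) / h²`;
* fluctuation score — with `S` the descending-sorted `|SOBDc|`,
  `FS = Σ_{i≤⌈n/10⌉} S_i / Σ_{j≤n} S_j`;
* discrimination — **ecDNA if FS < T, HSR if FS > T** (default T = 0.5).

FS is near 1 when fluctuation is concentrated at few loci (HSR) and near
the top fraction (0.1) when spread genome-wide (ecDNA). It is invariant to
library size (positive scaling) and to any constant per-bin offset.

## Worked example

```python
from mgaseq import SimConfig, run_gwifa, simulate_contact_matrix
from mgaseq.simulate import matched_mode_configs

ec, hsr = matched_mode_configs(SimConfig(seed=1))
for cfg in (ec, hsr):
    res = run_gwifa(simulate_contact_matrix(cfg), cfg.amplicon)
    print(f"{cfg.mode:5s}  FS = {res.fs:.3f}  ->  {res.call}  (n = {res.n} trans bins)")
```

prints

```
ecdna  FS = 0.257  ->  ecDNA  (n = 800 trans bins)
hsr    FS = 0.969  ->  HSR  (n = 800 trans bins)
```

The two simulated samples carry the same 1.6 Mb, 30-copy amplicon and the
same expected contact total; they differ only in where the amplicon's
inter-chromosomal contacts land (dispersed genome-wide vs concentrated at
one insertion locus). The fluctuation score separates them by a factor of
~4 around the decision threshold 0.5.

The same analyses are available from a shell:

```sh
mga simulate --mode ecdna --seed 4 -o sim/
mga gwifa --matrix sim/matrix.coo --chrom-sizes sim/chrom.sizes \
    --region chr1:8000001-9600000 -o out/
mga fa-call --depth sim/depth.bedgraph --chrom-sizes sim/chrom.sizes -o fa.bed
mga sv-type --sam sim/splits.sam --cnv sim/cnv.tsv -o calls.tsv
```

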