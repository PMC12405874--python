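# barseqkit

Platform-agnostic analysis of **Bar-seq** pooled fitness screens.

Barcoded mutant collections — most prominently the yeast knockout (YKO)
collection, in which every deletion strain carries two unique 20-bp
barcodes (an *uptag* and a *downtag*) flanked by common priming sites —
let thousands of strains compete in one pooled culture. Sequencing the
amplified barcodes before and after selection turns read counts into
per-strain relative fitness. `barseqkit` implements the full desk side
of such a screen for reads produced by Illumina, MGI, Element/AVITI and
Oxford Nanopore (short- and long-amplicon) library designs:

* **catalog** — load/validate strain↔barcode tables (TSV or FASTA),
  summarize tag presence and minimum pairwise distances.
* **layouts** — declarative read architectures per platform: fixed
  flanks, MGI stagger (0–3 nt) and dark-cycle skips, Element reads that
  begin directly at the tag, and the ~1.6-kb long-Nanopore amplicon
  carrying a 15-mer anchor, a 10-mer sample index and *both* tags in one
  read. Tags are located by anchoring the flanks (mismatch-bounded for
  short reads, edit-distance-bounded for Nanopore, both orientations).
* **matching** — error-tolerant assignment of an observed tag to its
  strain: the nearest catalog tag must be within `max_dist` and beat
  the runner-up by `min_margin` (ties are never broken). This explicit
  distance-margin rule plays the role a mapping-quality cutoff plays in
  an aligner-based pipeline, and is verified against an exhaustive-scan
  oracle.
* **fitness** — reads-per-million normalization with a pseudocount,
  fitness-defect scores
  `FD = log2(mean control) − log2(mean treatment)` (positive =
  drug-sensitive), and the three tag-combination strategies: per-strain
  **best tag** (lowest robust CV, `1.4826·MAD/median`, across control
  samples), **mean** of the two per-tag FDs, or FD of the **summed**
  raw counts.
* **profiles** — profile Pearson correlations, top/bottom-k hit
  correlations, uptag–downtag concordance (uptag-only strains
  excluded), and all-pairs "coinhibition" matrices with optional
  heatmap/scatter plots.
* **assaydesign** — growth arithmetic: generations = log2(OD ratio),
  doubling times, percent inhibition at a generation-anchored time,
  IC20 by piecewise log-linear interpolation, read-budget coverage and
  serial-transfer planning.
* **simulate** — a ground-truth generator: pool growth
  (`abundance ∝ 2^{g(1−s)}`, so a strain with fitness coefficient `s`
  carries a planted FD ≈ `g·s`), lognormal tag-efficiency bias with
  cis/trans linkage, multinomial sequencing depth, and platform-faithful
  read synthesis with substitution/indel errors — everything seeded and
  byte-for-byte reproducible.

## Worked example

Simulate a homozygous-pool screen (1,000 strains, 5 generations, 5% of
strains with a fitness defect, 3 replicates per arm, ~50 reads/tag) and
run the full pipeline on the generated FASTQs:

```bash
barseq simulate --scenario hop_basic --seed 7 --out demo/
barseq run --config demo/run.yaml
```

```
conditions  drug
T1  {'n_reads': 100000, 'assigned': 99716, 'no_hit': 105, 'ambiguous': 0, 'extraction_failed': 179}
T2  {'n_reads': 100000, 'assigned': 99742, 'no_hit': 85, 'ambiguous': 0, 'extraction_failed': 173}
...
```

Per sample, every read is accounted for:
`assigned + no_hit + ambiguous + extraction_failed = n_reads` (the
~0.3% losses here are the simulator's 1% per-base substitution errors
landing in a flank or pushing a tag past the distance cutoff).

```bash
barseq catalog stats demo/catalog.tsv
```

```
n_strains           1000
n_both_tags          970
n_uptag_only          30
min_hamming_uptag      5
```

The FD table written to `demo/results/fd_drug.tsv` holds one row per
strain with per-tag and combined scores plus the chosen best tag:

```
strain_id   fd_uptag    fd_downtag  fd_combined  chosen_tag
STR00000    -0.729667   0.076433    0.076433     downtag
STR00001    0.105106    -0.158259   0.105106     uptag
STR00002    0.000197    -0.110404   -0.110404    downtag
```

Against the simulator's truth table (`demo/truth.tsv`), the estimated
combined FD correlates with the planted FD at Pearson r = 0.936 over
all 1,000 strains at this modest depth; the most sensitive strains
(e.g. STR00159, planted s = 0.76, true FD 3.8) top the estimated
ranking.

Design helpers reproduce the usual screen arithmetic — a 5.5M-read
budget over 5,500 dual-tagged strains yields 500 reads/strain/tag, and
a 20-generation exposure at 5 generations per culture cycle needs 3
serial transfers:

```bash
$ barseq design coverage --total-reads 5500000 --n-strains 5500
reads_per_strain_per_tag  500
$ barseq design transfers --total-generations 20 --per-cycle 5
transfers  3
```

## Library use

```python
import barseqkit as bk

catalog = bk.load_catalog("catalog.tsv")
index = bk.build_index(catalog)
layout = bk.preset_layout("illumina_uptag")
from barseqkit._fastq import read_fastq
col, stats = bk.quantify_sample(read_fastq("sample.fastq.gz"), layout, index)
```

See `docs/methods.md` for the model, parameter defaults, numerical
choices and known limitations.
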