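# Methods

This note documents the models, parameter defaults, numerical choices
and known limitations of `barseqkit`. It is the package's own account
of its science; every number quoted here is recomputed by the test
suite or by `scripts/acceptance.py`, never hard-coded.

## The screen being modelled

A pooled barcode fitness screen grows thousands of barcoded mutant
strains in one culture, with and without a drug, for a set number of
population doublings (generations). Strains whose deleted gene matters
under the drug fall behind; sequencing the PCR-amplified barcodes
before/after gives per-strain relative abundance. Two assay flavours
are built in: **HIP** (heterozygous essential-gene pool, 20
generations, sensitive enough to detect ~3% fitness defects) and
**HOP** (homozygous nonessential pool, 5 generations). Each strain
carries two independent 20-bp barcodes (uptag, downtag) between common
priming sites; roughly 3% of strains in the classic yeast deletion
collection carry only an uptag, and the toolkit keeps such strains
with the downtag marked absent rather than dropping them.

## Read layouts and tag extraction

A layout is an ordered list of segments: `fixed` (known flank sequence,
anchored with a bounded number of errors), `stagger` (0–3 unknown
leading bases, as produced by the MGI staggered primer sets), `skip`
(a fixed-length ignored stretch, or an unbounded gap for the
long-amplicon interior), `tag` (a 20-bp barcode slot) and
`sample_index` (an in-read index, 10 bp in the long-Nanopore design).

Flank sequences in the short-read presets derive from the common
primers of the deletion-collection cassette. Reads are modelled
5'→3' on the top strand, so each **right** flank is the reverse
complement of the printed reverse primer — e.g. the uptag block is
`GATGTCCACGAGGTCTCT · tag20 · CGTACGCTGCAGGTCGAC`. The Element preset
has no left flank at all: its custom sequencing primer ends exactly at
the tag boundary, so the read begins with the tag. The long-Nanopore
preset is `15-mer anchor (GCTAGTACGTGACAT) · 10-bp index · uptag block
· cassette interior (~1.4 kb, unsequenced for analysis purposes) ·
downtag block`, scanned in both orientations.

Anchoring policy:

* substitution-only layouts (Illumina, MGI, Element): each fixed
  segment is placed at the offset (within the stagger-widened window)
  minimising mismatches, requiring ≤ `max_err` (default 2). A trailing
  flank may run off the read end (a 50-bp single-end read truncates the
  uptag right flank to 12 bp); at least 4 overlapping bases are
  required. Tags are then sliced at fixed offsets — exactly 20 bp.
* with-indels layouts (Nanopore): fixed segments are placed by best
  local edit-distance alignment (edlib, infix mode, edit ≤ 3 per flank
  by default). A tag slice is accepted at 18–22 bp because indels move
  the boundaries; the downstream flank re-anchors the right edge.

Extraction is all-or-nothing per read: if any required anchor fails the
read yields no observations and is tallied as an extraction failure,
never an exception. Observed tag sequences are always verbatim slices
of the (possibly reverse-complemented) read.

MGI dark cycles: delivered FASTQs may or may not include the bases
covered by the instrument's initial dark cycles, so the MGI presets
default to `skip = 0` and the skip length is user-configurable.

## Tag-to-strain assignment

An observation is assigned by distance to the catalog tags *of its own
class* (the two tag PCRs are class-specific in every supported
protocol, so cross-class rescue is deliberately not attempted):

1. exact sequence match → assigned, distance 0;
2. otherwise the minimum-distance tag must satisfy
   `d_best ≤ max_dist` **and** `d_second − d_best ≥ min_margin`;
3. ties or insufficient margin → *ambiguous*; beyond `max_dist` →
   *no hit*. Ambiguous reads are never rescued, because a silently
   misassigned read biases FD scores in a way a dropped read does not.

Defaults: Hamming metric with `max_dist = 2, min_margin = 1` for
short reads; Levenshtein with `max_dist = 3` for Nanopore. This
explicit rule is the package's stand-in for the "unique, confident
alignment" semantics of a mapping-quality cutoff in aligner-based
pipelines. `N` bases match nothing (Hamming scans operate on raw
bytes; a query of non-20 length has infinite Hamming distance to every
tag and can only match under Levenshtein).

Implementation: exact lookups are a hash table; Hamming search is a
vectorised numpy scan over the byte-encoded tag matrix; Levenshtein
search uses a pigeonhole seed index (20-mers split into 5 pieces of 4;
any tag within edit distance R ≤ 4 of a query must share one piece
verbatim within an R-base shift) with edlib verifying candidates. Only
tags within `max_dist + min_margin − 1` can influence the decision, so
the candidate radius is bounded by that quantity. The whole assigner is
tested for exact agreement with an independent exhaustive-scan oracle
(full query×tag distance matrix, rule applied by hand) over 20 random
catalogs × 10,000 queries × {hamming, levenshtein} × max_dist 0–3 ×
margin 1–2; the catalogs deliberately contain ~25% near-duplicate tags
so that margin and tie rules are exercised.

Read accounting: per sample,
`assigned + no_hit + ambiguous + extraction_failed = n_reads` at the
read level. A long-Nanopore read carries two tag observations and can
increment both its uptag and downtag cells; such a read counts as
assigned if at least one observation assigned, so cell sums equal the
number of assigned *observations* while the accounting identity holds
over *reads*.

## Normalization and FD scores

Counts are scaled to reads-per-million within each sample column
(denominator: the column's assigned-read total) and offset by a
pseudocount (default 1.0 on the RPM scale). The fitness defect of a
strain's tag for a condition is

    FD = log2( mean over control replicates ) − log2( mean over treatment replicates )

computed on the normalized scale; positive FD = depleted under drug =
sensitive. Replicates are averaged *before* the log ratio by default
(one log ratio per condition); per-replicate log ratios then averaged
are available as `replicate_mode="log_then_mean"`. Controls are
matched to a condition by assay (HIP controls for HIP conditions,
etc.). Two provable consequences, used as invariants: swapping
treatment/control labels negates every FD, and rescaling any raw
column leaves FDs unchanged when the pseudocount is 0.

The RPM+pseudocount scheme is this package's choice of normalization:
it is scale-free, standard for count ratios, and makes depth invariance
exact. The assigned-read total (not the raw read total) is used as the
denominator so that junk reads cannot dilute a sample.

### Combining the two tags

* **best_tag** (default): for every strain, the robust coefficient of
  variation `rCV = 1.4826 · MAD / median` is computed per tag across
  all control samples of the assay; the tag with the lower rCV is
  used. The 1.4826 factor makes the MAD consistent with the standard
  deviation under normality. Ties choose the uptag (deterministic,
  documented); single-tag strains keep their only tag.
* **mean**: arithmetic mean of the two per-tag FDs; single-tag strains
  pass through.
* **sum**: uptag+downtag raw counts are summed per strain first, then
  renormalized and rescored — equivalent to treating the pair as one
  pseudo-tag.

## Profile analyses

Profile correlation is Pearson's r over strains with defined FD in
both profiles (≥ 3 required; n reported). Top/bottom-k correlation
ranks by the **first** profile's combined FD (k = 50 by default), with
rank-boundary ties broken by strain id. Uptag–downtag concordance is
computed on replicate-averaged normalized counts, log2-transformed so
abundance outliers do not dominate (FD-level concordance uses values
as-is); strains lacking either tag are excluded. The coinhibition
matrix is the all-pairs profile correlation — symmetric, unit
diagonal, undefined pairs left as NaN.

## Assay-design arithmetic

Generations grown = `log2(OD_end / OD_start)` (exact value returned;
0.0625 → 1.2 OD600 gives 4.26, commonly rounded to ~5 in practice).
Doubling time is `1/slope` of a least-squares fit of log2(OD) vs time;
non-positive slopes yield "undefined" rather than a negative time.
Percent inhibition is `100·(1 − OD_treated/OD_control)` evaluated at
the time the *control* reaches the stated generation count (linear
interpolation) — generation-anchored because that is how IC values are
defined for growing pools. IC interpolation is piecewise log-linear in
dose (the zero-dose anchor sits at half the smallest nonzero dose on
the log axis), returning the first upward crossing; no 4-parameter
logistic is fitted, because serial halving dilutions are sparse and a
monotone interpolant is the minimal faithful estimator. Read budget:
`reads/(strains × tags)` — a 5–6M-read sample over a ~5,500-strain
dual-tagged pool gives ~500 reads per strain per tag, which is why
outputs are labelled "per strain per tag". Serial transfers:
`ceil(total/per_cycle) − 1` (the first growth cycle is not a
transfer).

## Simulator

Growth: initial abundances `a_i(0) ∝ lognormal(0, σ_init)`
(σ_init = 0.5 by default); a strain with fitness coefficient `s`
(0 = neutral, s > 1 rejected) has treated abundance
`a_i(g) ∝ a_i(0)·2^{g(1−s_i)}`, renormalized; the control arm uses
s = 0. The recorded `true_fd = log2(a_ctrl/a_trt)` therefore equals
`g·s_i + log2 Z` with a renormalization constant Z shared by all
strains — the constant vanishes as the affected fraction → 0, and the
test suite checks both the closed form at 2,000 strains (|error| <
2×10⁻³ for s = 0.03, g = 20) and the exact pairwise identity
`fd_i − fd_j = g(s_i − s_j)`.

Counts: each tag class's expected share is `a_i(g) × e_{i,class}`,
with tag efficiencies lognormal (σ_tag = 0.3 by default) —
multiplicative PCR bias. `cis` linkage copies the uptag efficiency to
the downtag (both tags on one amplicon, as in long-Nanopore); `trans`
draws them independently (separate PCRs, all short protocols). This
single mechanism reproduces the observed ordering of uptag–downtag
concordance: simulated cis correlations (~0.99 median at σ = 0.3)
always exceed trans (~0.73 median), mirroring the direction seen
between long-read and short-read platforms, though the simulated cis
values are higher than real long-read data because template switching
and other chimera-forming processes are not modelled. Depth is one
multinomial draw per tag class per sample, the per-sample total split
evenly between classes (the two PCRs are pooled equally); column sums
are exact. Per-replicate amplification jitter can be switched on per
tag class (`replicate_efficiency_sigma`) to create a noisy-tag
scenario; it is off by default.

Reads: layouts are rendered literally (stagger prefixes drawn
uniformly from the printed primer variants; the long-amplicon interior
is a random stuffer of configurable length, default 1,400 bp, standing
in for the unprinted cassette/marker sequence; orientations are
equiprobable for both-orientation layouts). Substitutions are i.i.d.
per base (default 1%); insertions/deletions (default 0.5%/0.5%) are
injected only for with-indels layouts. Base qualities are constant
placeholders — extraction never reads them, so simulating quality
strings would add no test power. Identical config + seed reproduces
FASTQ files byte-for-byte (gzip mtime is zeroed).

What the simulator does **not** emulate — and what passing tests
therefore cannot show about real data: PCR-cycle-explicit jackpotting,
template switching/chimeras, index hopping, homopolymer-specific
nanopore errors, quality-correlated errors, and real catalog
cross-talk structure (synthetic catalogs are rejection-sampled to a
minimum within-class Hamming distance of 5, which the real deletion
collection only approximately satisfies).

### Scenario fixtures

* `hop_basic`: 1,000 strains, HOP (g = 5), 5% affected with
  s ~ U(0.1, 0.8), 3 replicates/arm, 100,000 reads/sample (~50
  reads/tag) written as Illumina uptag+downtag FASTQs with a run
  config. Depth here is kept moderate because the fixture's role is
  end-to-end plumbing; the FD parameter-recovery measurement uses the
  same pool at 500 reads/tag via count matrices.
* `hip_3pct`: 200 strains, HIP (g = 20), a 40-strain cohort planted at
  exactly s = 0.03 (planted FD ≈ 0.6 before the renormalization
  shift), 500 reads/tag.
* `dose_series`: 300 strains; four conditions sharing one affected set
  with s scaled by 0.4/0.6/0.8/1.0 (a dose ladder), plus one condition
  with an independently drawn affected set (an unrelated compound);
  two treatment replicates each against three shared controls, emitted
  at the count level.
* `platform_panel`: 50 strains, one per-strain count vector rendered
  through all nine layout presets at zero error — quantifying any of
  them must reproduce the identical matrix.

## Validation results the package recomputes

`scripts/acceptance.py --seed N --out results/acceptance.json` runs,
from scratch: the matcher/oracle agreement (3.2M comparisons expected
to agree exactly); per-platform round trips (zero-error = 100%; 1%
substitutions ≥ 99% correct assignment; 0.5%/0.5% indels on
long-Nanopore ≥ 95%, both on a 1,000-strain min-distance-5 catalog);
FD recovery at 500 reads/tag (Pearson r vs planted FD ≈ 0.99, slope
≈ 0.98); the 3%-defect HIP scenario (cohort mean ≈ 0.51 with the
−0.10 renormalization shift of a 20% affected cohort included,
separated from neutrals by ~11 robust z-units); cis-vs-trans
concordance (cis wins 20/20 matched seeds); and the dose-series
coinhibition ordering (every within-series r above every cross-series
r). Problem sizes were fixed once, as the package's study conditions,
and are printed alongside each value in the JSON.

## Numerical and degenerate-input conventions

* Tie-breaks are always deterministic and documented (earliest offset
  for equal-mismatch anchors; uptag for equal rCV; strain id at the
  top-k rank boundary; ambiguity never broken in matching).
* `robust_cv` requires ≥ 2 values and a positive median; inside
  best-tag selection a failing rCV (possible only at pseudocount 0)
  becomes NaN and that tag loses the comparison.
* Zero-depth count columns are a hard error in `normalize`.
* Catalog validation is strict: non-ACGT symbols, wrong lengths,
  duplicate strain ids or duplicate within-class tags all fail the
  load; lowercase is folded to uppercase.
* All stochastic code takes a `numpy.random.Generator` or derives one
  from an integer seed via `default_rng([seed, stream])`; no global
  RNG state is used anywhere.

## Known limitations

* Paired-end input is handled by parsing the tag-bearing read only;
  mate-pair consistency is not checked.
* The MGI dark-cycle convention is configuration, not detection: the
  toolkit cannot tell from a FASTQ whether dark-cycle bases were
  consumed by the instrument.
* Coinhibition is plain profile Pearson correlation; no compound-level
  normalization across a screening campaign is applied.
* The matcher is exact-by-construction but not sublinear for Hamming
  queries; catalogs far beyond 10⁵ tags would want a bit-packed or
  partitioned scan.
* No enrichment analysis: FD tables and rank files are the interface
  to external GSEA/GO tooling.
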