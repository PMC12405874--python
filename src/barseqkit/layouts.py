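"""Declarative read-structure models for Bar-seq sequencing platforms.

A :class:`ReadLayout` describes one platform's amplicon architecture as
an ordered list of segments (fixed flanks, stagger, skip, tag slots,
sample index), and :func:`extract_tags` locates the 20-bp tag(s) in a
read by anchoring the fixed segments.

The short-read presets model the common flanking primers of the yeast
deletion-collection barcodes:

* Illumina: left common primer + 20-bp tag + reverse complement of the
  right common primer (reads run 5'->3' on the top strand; the printed
  primers face each other, so the right flank appears reverse
  complemented in the read).
* MGI: the same structure preceded by a 0-3 nt stagger (the staggered
  primer set offsets otherwise-identical common sequence by one base
  per primer to create base diversity), and an optional leading skip for
  dark cycles.
* Element/AVITI: custom sequencing primers end at the tag boundary, so
  the read begins directly with the tag followed by the right flank.
* Nanopore short: Illumina amplicon structure read on a long-read
  instrument; anchoring is edit-distance based and both orientations
  are scanned.
* Nanopore long: a single-PCR amplicon of the entire deletion cassette;
  one read carries a 15-mer anchor, a 10-mer sample index, the uptag
  block, the unsequenced cassette interior, and the downtag block.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# common flanking primers of the deletion-collection barcodes
UPTAG_LEFT_PRIMER = "GATGTCCACGAGGTCTCT"
UPTAG_RIGHT_PRIMER = "GTCGACCTGCAGCGTACG"
DOWNTAG_LEFT_PRIMER = "GAAAACGAGCTCGAATTCATCG"
DOWNTAG_RIGHT_PRIMER = "CGGTGTCGGTCTCGTAG"
NANOPORE_LONG_ANCHOR = "GCTAGTACGTGACAT"  # 5' common 15-mer before the index
NANOPORE_INDEX_LEN = 10

# stagger variants of the MGI primer sets (offset prefixes between the
# sequencing primer and the common flank), per tag class
MGI_STAGGER_UPTAG = ("", "C", "GA", "TGC")
MGI_STAGGER_DOWNTAG = ("", "A", "TC", "CAC")

TAG_NOMINAL_LEN = 20
TAG_MIN_LEN = 18  # with-indels layouts tolerate 18-22 bp slices
TAG_MAX_LEN = 22

PLATFORMS = (
    "illumina_uptag",
    "illumina_downtag",
    "mgi_uptag",
    "mgi_downtag",
    "element_uptag",
    "element_downtag",
    "nanopore_short_uptag",
    "nanopore_short_downtag",
    "nanopore_long",
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Segment:
    """One element of a read architecture.

    kind:
      fixed        known sequence anchored with up to ``max_err`` errors
      stagger      0..max_len unknown bases (widens the anchor window)
      skip         exactly ``max_len`` ignored bases; -1 = unbounded gap
      tag          a barcode slot of the given ``tag_class``
      sample_index ``index_len`` bases of per-sample index
    """

    kind: str
    sequence: str = ""
    max_len: int = 0
    tag_class: str = ""
    index_len: int = 0
    max_err: int = 2
    variants: tuple[str, ...] = ()  # stagger only: the printed prefix variants

    def __post_init__(self) -> None:
        if self.kind not in {"fixed", "stagger", "skip", "tag", "sample_index"}:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "fixed" and not self.sequence:
            raise ValueError("fixed segment requires a non-empty sequence")
        if self.kind == "tag" and self.tag_class not in {"uptag", "downtag"}:
            raise ValueError("tag segment requires tag_class uptag or downtag")
        if self.max_err < 0:
            raise ValueError("max_err must be non-negative")


@dataclass(frozen=True)
class ReadLayout:
    name: str
    segments: tuple[Segment, ...]
    scan_both_orientations: bool = False
    error_model: str = "substitution_only"  # or "with_indels"

    def __post_init__(self) -> None:
        if self.error_model not in {"substitution_only", "with_indels"}:
            raise ValueError(f"unknown error model {self.error_model!r}")
        n_tags = sum(1 for s in self.segments if s.kind == "tag")
        if n_tags == 0:
            raise ValueError("layout needs at least one tag segment")

    @property
    def tag_classes(self) -> tuple[str, ...]:
        return tuple(s.tag_class for s in self.segments if s.kind == "tag")

    def min_span(self) -> int:
        """Minimal read length that can contain all segments."""
        span = 0
        for seg in self.segments:
            if seg.kind == "fixed":
                span += len(seg.sequence)
            elif seg.kind == "skip" and seg.max_len > 0:
                span += seg.max_len
            elif seg.kind == "tag":
                span += TAG_NOMINAL_LEN
            elif seg.kind == "sample_index":
                span += seg.index_len
        return span


@dataclass(frozen=True)
class TagObservation:
    """A tag sequence sliced verbatim from a read."""

    read_id: str
    tag_class: str
    observed_seq: str
    sample_index_seq: str | None = None
    orientation: str = "forward"


def _short_block(tag_class: str, max_err: int = 2) -> tuple[Segment, ...]:
    if tag_class == "uptag":
        left, right = UPTAG_LEFT_PRIMER, revcomp(UPTAG_RIGHT_PRIMER)
    else:
        left, right = DOWNTAG_LEFT_PRIMER, revcomp(DOWNTAG_RIGHT_PRIMER)
    return (
        Segment("fixed", sequence=left, max_err=max_err),
        Segment("tag", tag_class=tag_class),
        Segment("fixed", sequence=right, max_err=max_err),
    )


def preset_layout(
    platform: str, *, max_err: int | None = None, mgi_skip: int = 0
) -> ReadLayout:
    """Return the read layout for a named platform preset.

    ``max_err`` overrides the per-flank anchoring tolerance (default 2
    mismatches for substitution-only layouts, edit distance 3 for
    with-indels layouts).  ``mgi_skip`` sets the leading dark-cycle skip
    for the MGI presets (default 0: delivered FASTQs usually start after
    the dark cycles).
    """
    if platform not in PLATFORMS:
        raise ValueError(f"unknown platform {platform!r}; choose from {PLATFORMS}")

    if platform.startswith(("illumina_", "mgi_", "element_", "nanopore_short_")):
        tag_class = "uptag" if platform.endswith("uptag") else "downtag"

    if platform.startswith("illumina_"):
        err = 2 if max_err is None else max_err
        return ReadLayout(platform, _short_block(tag_class, err))

    if platform.startswith("mgi_"):
        err = 2 if max_err is None else max_err
        variants = MGI_STAGGER_UPTAG if tag_class == "uptag" else MGI_STAGGER_DOWNTAG
        segments = (
            Segment("skip", max_len=mgi_skip),
            Segment("stagger", max_len=3, variants=variants),
        ) + _short_block(tag_class, err)
        return ReadLayout(platform, segments)

    if platform.startswith("element_"):
        err = 2 if max_err is None else max_err
        right = (
            revcomp(UPTAG_RIGHT_PRIMER)
            if tag_class == "uptag"
            else revcomp(DOWNTAG_RIGHT_PRIMER)
        )
        segments = (
            Segment("tag", tag_class=tag_class),
            Segment("fixed", sequence=right, max_err=err),
        )
        return ReadLayout(platform, segments)

    if platform.startswith("nanopore_short_"):
        err = 3 if max_err is None else max_err
        return ReadLayout(
            platform,
            _short_block(tag_class, err),
            scan_both_orientations=True,
            error_model="with_indels",
        )

    # nanopore_long
    err = 3 if max_err is None else max_err
    segments = (
        Segment("fixed", sequence=NANOPORE_LONG_ANCHOR, max_err=err),
        Segment("sample_index", index_len=NANOPORE_INDEX_LEN),
        Segment("fixed", sequence=UPTAG_LEFT_PRIMER, max_err=err),
        Segment("tag", tag_class="uptag"),
        Segment("fixed", sequence=revcomp(UPTAG_RIGHT_PRIMER), max_err=err),
        Segment("skip", max_len=-1),  # unsequenced cassette interior
        Segment("fixed", sequence=DOWNTAG_LEFT_PRIMER, max_err=err),
        Segment("tag", tag_class="downtag"),
        Segment("fixed", sequence=revcomp(DOWNTAG_RIGHT_PRIMER), max_err=err),
    )
    return ReadLayout(
        "nanopore_long",
        segments,
        scan_both_orientations=True,
        error_model="with_indels",
    )


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


_MIN_FLANK_OVERLAP = 4  # a truncated trailing flank must show this much


def _anchor_fixed(seq: str, ref: str, lo: int, hi: int, max_err: int):
    """Best substitution-only placement of ``ref`` starting in [lo, hi].

    Returns (start, end, mismatches) or None.  The flank may run off the
    read end (short single-end reads truncate the trailing flank); then
    only the overlap is compared, requiring at least
    ``_MIN_FLANK_OVERLAP`` bases.  Ties go to the earliest offset.
    """
    best = None
    for off in range(lo, hi + 1):
        window = seq[off : off + len(ref)]
        if len(window) < _MIN_FLANK_OVERLAP:
            break
        mm = _mismatches(window, ref)
        if mm <= max_err and (best is None or mm < best[2]):
            best = (off, off + len(window), mm)
            if mm == 0:
                break
    return best


def _extract_substitution(read_id: str, seq: str, layout: ReadLayout):
    pos = 0
    window = 0
    sample_index: str | None = None
    found: list[tuple[str, str]] = []
    for seg in layout.segments:
        if seg.kind == "skip":
            pos += max(seg.max_len, 0)
        elif seg.kind == "stagger":
            window += seg.max_len
        elif seg.kind == "fixed":
            hit = _anchor_fixed(seq, seg.sequence, pos, pos + window, seg.max_err)
            if hit is None:
                return []
            pos = hit[1]
            window = 0
        elif seg.kind == "sample_index":
            if window or pos + seg.index_len > len(seq):
                return []
            sample_index = seq[pos : pos + seg.index_len]
            pos += seg.index_len
        elif seg.kind == "tag":
            if window or pos + TAG_NOMINAL_LEN > len(seq):
                return []
            found.append((seg.tag_class, seq[pos : pos + TAG_NOMINAL_LEN]))
            pos += TAG_NOMINAL_LEN
    return [
        TagObservation(read_id, cls, obs, sample_index_seq=sample_index)
        for cls, obs in found
    ]


def _edlib_anchor(ref: str, region: str, max_err: int):
    """Best infix placement of ref in region by edit distance, or None."""
    if not region:
        return None
    res = edlib.align(ref, region, mode="HW", task="locations", k=max_err)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return start, end + 1, res["editDistance"]


def _extract_with_indels(read_id: str, seq: str, layout: ReadLayout):
    pos = 0
    unbounded = False
    pending_tag: tuple[str, int] | None = None  # (tag_class, start)
    sample_index: str | None = None
    found: list[tuple[str, str]] = []
    slack_before = 0
    for seg in layout.segments:
        if seg.kind == "skip":
            if seg.max_len < 0:
                unbounded = True
            else:
                pos += seg.max_len
        elif seg.kind == "stagger":
            slack_before += seg.max_len
        elif seg.kind == "sample_index":
            if pos + seg.index_len > len(seq):
                return []
            sample_index = seq[pos : pos + seg.index_len]
            pos += seg.index_len
        elif seg.kind == "tag":
            pending_tag = (seg.tag_class, pos)
        elif seg.kind == "fixed":
            if pending_tag is not None:
                # the flank closes the preceding tag slot: it must start
                # 18-22 bp after the tag start
                tstart = pending_tag[1]
                lo = tstart + TAG_MIN_LEN
                hi = tstart + TAG_MAX_LEN + len(seg.sequence) + seg.max_err
                hit = _edlib_anchor(seg.sequence, seq[lo:hi], seg.max_err)
                if hit is None:
                    return []
                start = lo + hit[0]
                tag_seq = seq[tstart:start]
                if not TAG_MIN_LEN <= len(tag_seq) <= TAG_MAX_LEN:
                    return []
                found.append((pending_tag[0], tag_seq))
                pending_tag = None
                pos = lo + hit[1]
            else:
                if unbounded:
                    hi = len(seq)
                else:
                    hi = pos + slack_before + len(seg.sequence) + seg.max_err + 2
                hit = _edlib_anchor(seg.sequence, seq[pos:hi], seg.max_err)
                if hit is None:
                    return []
                pos = pos + hit[1]
            unbounded = False
            slack_before = 0
    if pending_tag is not None:
        # tag not closed by a flank (all presets close tags); reject
        return []
    return [
        TagObservation(read_id, cls, obs, sample_index_seq=sample_index)
        for cls, obs in found
    ]


def extract_tags(read, layout: ReadLayout) -> list[TagObservation]:
    """Locate and slice the tag(s) of a read under a layout.

    ``read`` is a ``(read_id, sequence)`` pair.  Returns one observation
    per tag segment, or an empty list when any required anchor fails
    (extraction failure is an accounting event, not an exception).
    With ``scan_both_orientations``, the reverse complement is tried
    when the forward parse fails.
    """
    read_id, seq = read
    seq = seq.upper()
    if layout.error_model == "substitution_only":
        parse = _extract_substitution
    else:
        parse = _extract_with_indels
    obs = parse(read_id, seq, layout)
    if obs:
        return obs
    if layout.scan_both_orientations:
        obs = parse(read_id, revcomp(seq), layout)
        if obs:
            return [replace(o, orientation="reverse") for o in obs]
    return []


def demux_sample_index(
    obs: TagObservation,
    index_table: dict[str, str],
    max_mismatch: int = 1,
) -> str | None:
    """Assign a sample id from the observation's index sequence.

    Nearest index within ``max_mismatch`` and unique at that distance;
    ties and misses return None (unassigned).  ``index_table`` is a
    mapping index sequence -> sample id, or an iterable of such pairs
    (which must not repeat a sequence).
    """
    if obs.sample_index_seq is None:
        raise ValueError("observation carries no sample index")
    pairs = (
        list(index_table.items())
        if isinstance(index_table, dict)
        else list(index_table)
    )
    seqs = [s for s, _ in pairs]
    if len(set(seqs)) != len(seqs):
        raise ValueError("index table has duplicate sequences")
    query = obs.sample_index_seq
    best: tuple[int, str] | None = None
    tied = False
    for seq, sample_id in pairs:
        if len(seq) != len(query):
            continue
        d = _mismatches(seq, query)
        if best is None or d < best[0]:
            best = (d, sample_id)
            tied = False
        elif d == best[0]:
            tied = True
    if best is None or tied or best[0] > max_mismatch:
        return None
    return best[1]
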