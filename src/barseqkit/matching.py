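"""Error-tolerant assignment of observed tags to catalog strains.

A short-tag aligner's mapping quality is, in essence, a proxy for a
unique confident match.  Here that intent is made explicit and
deterministic: an observation is assigned to the catalog tag of its
class at minimal distance, provided the distance is within ``max_dist``
and the runner-up is at least ``min_margin`` further away.  Ties are
never broken — ambiguity yields no assignment, because a silently
misassigned read corrupts downstream fitness scores.  The recommended
analog of a MAPQ >= 30 filter is ``max_dist=2, min_margin=1``.

Hamming distance is evaluated with vectorized numpy scans; Levenshtein
uses a pigeonhole seed index (a tag within edit distance R of the query
must share one of R+1 tag pieces verbatim, up to an R-base shift) with
edlib verifying candidate distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import edlib
import numpy as np
import pandas as pd

from .catalog import TAG_CLASSES, TAG_LENGTH, BarcodeCatalog
from .layouts import ReadLayout, extract_tags

_MAX_PIECE_RADIUS = 4  # pigeonhole index built for edit radius <= 4


@dataclass(frozen=True)
class MatchParams:
    max_dist: int = 2
    min_margin: int = 1
    metric: str = "hamming"  # or "levenshtein"

    def __post_init__(self) -> None:
        if self.max_dist < 0 or self.min_margin < 0:
            raise ValueError("max_dist and min_margin must be non-negative")
        if self.max_dist > 0 and self.min_margin < 1:
            raise ValueError("min_margin must be >= 1 when max_dist > 0")
        if self.metric not in {"hamming", "levenshtein"}:
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass(frozen=True)
class Assignment:
    strain_id: str | None
    tag_class: str
    distance: int | None
    reason: str  # exact, within_dist, no_hit, ambiguous

    @property
    def assigned(self) -> bool:
        return self.reason in {"exact", "within_dist"}


class _ClassIndex:
    """Search structures for one tag class."""

    def __init__(self, tags: dict[str, str]):
        self.exact = dict(tags)  # seq -> strain_id
        self.seqs = list(tags)
        self.strains = [tags[s] for s in self.seqs]
        if self.seqs:
            self.matrix = np.frombuffer(
                "".join(self.seqs).encode("ascii"), dtype=np.uint8
            ).reshape(len(self.seqs), TAG_LENGTH)
        else:
            self.matrix = np.empty((0, TAG_LENGTH), dtype=np.uint8)
        # pigeonhole pieces: TAG_LENGTH split into _MAX_PIECE_RADIUS+1 pieces
        self.n_pieces = _MAX_PIECE_RADIUS + 1
        self.piece_len = TAG_LENGTH // self.n_pieces
        self.piece_map: dict[tuple[int, str], list[int]] = {}
        for ti, seq in enumerate(self.seqs):
            for pi in range(self.n_pieces):
                piece = seq[pi * self.piece_len : (pi + 1) * self.piece_len]
                self.piece_map.setdefault((pi, piece), []).append(ti)


class TagIndex:
    """Exact lookup plus bounded-distance search over a catalog."""

    def __init__(self, catalog: BarcodeCatalog):
        self.by_class = {cls: _ClassIndex(catalog.tags(cls)) for cls in TAG_CLASSES}

    def _best_two_hamming(self, cidx: _ClassIndex, seq: str):
        if len(seq) != TAG_LENGTH or cidx.matrix.shape[0] == 0:
            return None
        q = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        d = (cidx.matrix != q).sum(axis=1)
        i1 = int(d.argmin())
        d1 = int(d[i1])
        d[i1] = TAG_LENGTH + 1
        d2 = int(d.min()) if d.size > 1 else None
        return cidx.strains[i1], d1, d2

    def _candidates_levenshtein(self, cidx: _ClassIndex, seq: str, radius: int):
        cands: set[int] = set()
        plen = cidx.piece_len
        for pi in range(cidx.n_pieces):
            off = pi * plen
            lo = max(0, off - radius)
            hi = min(len(seq) - plen, off + radius)
            for s in range(lo, hi + 1):
                hits = cidx.piece_map.get((pi, seq[s : s + plen]))
                if hits:
                    cands.update(hits)
        return cands

    def _best_two_levenshtein(self, cidx: _ClassIndex, seq: str, radius: int):
        if not cidx.seqs:
            return None
        if radius <= _MAX_PIECE_RADIUS:
            candidates: Iterable[int] = self._candidates_levenshtein(
                cidx, seq, radius
            )
        else:  # fall back to a full scan for unusually wide parameters
            candidates = range(len(cidx.seqs))
        best: tuple[int, int] | None = None  # (distance, tag index)
        second: int | None = None
        for ti in candidates:
            res = edlib.align(seq, cidx.seqs[ti], task="distance", k=radius)
            d = res["editDistance"]
            if d < 0:
                continue
            if best is None or d < best[0]:
                second = best[0] if best is not None else None
                best = (d, ti)
            elif second is None or d < second:
                second = d
        if best is None:
            return None
        return cidx.strains[best[1]], best[0], second


def build_index(catalog: BarcodeCatalog) -> TagIndex:
    return TagIndex(catalog)


def assign_tag(
    obs_seq: str, tag_class: str, index: TagIndex, params: MatchParams
) -> Assignment:
    """Assign one observed tag sequence to a strain, or refuse.

    Exact matches assign immediately.  Otherwise the best catalog tag of
    the same class must be within ``params.max_dist`` and beat the
    runner-up by at least ``params.min_margin``; ties or insufficient
    margin are reported as ambiguous, and distances beyond ``max_dist``
    as no_hit.  N bases never match (they count as errors against every
    catalog base).
    """
    cidx = index.by_class[tag_class]
    strain = cidx.exact.get(obs_seq)
    if strain is not None:
        return Assignment(strain, tag_class, 0, "exact")
    # only tags closer than max_dist + min_margin can influence the outcome
    radius = params.max_dist + max(params.min_margin, 1) - 1
    if params.metric == "hamming":
        hit = index._best_two_hamming(cidx, obs_seq)
    else:
        hit = index._best_two_levenshtein(cidx, obs_seq, radius)
    if hit is None:
        return Assignment(None, tag_class, None, "no_hit")
    strain, d1, d2 = hit
    if d1 > params.max_dist:
        return Assignment(None, tag_class, None, "no_hit")
    if d2 is not None and d2 - d1 < params.min_margin:
        return Assignment(None, tag_class, d1, "ambiguous")
    return Assignment(strain, tag_class, d1, "within_dist")


STAT_FIELDS = ("n_reads", "assigned", "no_hit", "ambiguous", "extraction_failed")


def quantify_sample(
    reads: Iterable[tuple[str, str]],
    layout: ReadLayout,
    index: TagIndex,
    params: MatchParams | None = None,
) -> tuple[pd.Series, dict[str, int]]:
    """Stream reads through extraction and assignment; count per cell.

    Returns a counts Series indexed by ``(strain_id, tag_class)`` and a
    read-accounting dict.  Read status: extraction_failed when no tag
    could be located; otherwise assigned if at least one observation was
    assigned, else ambiguous if any observation tied, else no_hit.
    Counts increment once per assigned observation (a long-read layout
    can contribute to both tag classes from one read), so
    ``assigned + no_hit + ambiguous + extraction_failed == n_reads``
    always holds at the read level.
    """
    if params is None:
        params = MatchParams()
    if params.metric == "hamming" and layout.error_model == "with_indels":
        raise ValueError(
            "with_indels layouts shift tag boundaries; use metric='levenshtein'"
        )
    stats = dict.fromkeys(STAT_FIELDS, 0)
    counts: dict[tuple[str, str], int] = {}
    for read in reads:
        stats["n_reads"] += 1
        observations = extract_tags(read, layout)
        if not observations:
            stats["extraction_failed"] += 1
            continue
        statuses = []
        for obs in observations:
            a = assign_tag(obs.observed_seq, obs.tag_class, index, params)
            statuses.append(a.reason)
            if a.assigned:
                key = (a.strain_id, a.tag_class)
                counts[key] = counts.get(key, 0) + 1
        if any(s in {"exact", "within_dist"} for s in statuses):
            stats["assigned"] += 1
        elif "ambiguous" in statuses:
            stats["ambiguous"] += 1
        else:
            stats["no_hit"] += 1
    series = pd.Series(counts, dtype=np.int64)
    if not series.empty:
        series.index = pd.MultiIndex.from_tuples(
            series.index, names=["strain_id", "tag_class"]
        )
        series = series.sort_index()
    else:
        series.index = pd.MultiIndex.from_arrays(
            [[], []], names=["strain_id", "tag_class"]
        )
    return series, stats


def counts_frame(
    columns: dict[str, pd.Series],
    catalog: BarcodeCatalog | None = None,
) -> pd.DataFrame:
    """Assemble per-sample count Series into one integer matrix.

    Rows are the union of observed (strain, tag_class) cells, or every
    tag present in ``catalog`` when given (so unobserved strains appear
    as zero rows).  Missing cells are zero.
    """
    if catalog is not None:
        rows = [
            (rec.strain_id, cls)
            for rec in catalog
            for cls in TAG_CLASSES
            if rec.tag(cls) is not None
        ]
        idx = pd.MultiIndex.from_tuples(rows, names=["strain_id", "tag_class"])
    else:
        idx = None
    frame = pd.DataFrame(columns).fillna(0).astype(np.int64)
    if idx is not None:
        frame = frame.reindex(idx, fill_value=0)
    frame.index.names = ["strain_id", "tag_class"]
    return frame.sort_index()


def scan_assign_oracle(
    obs_seq: str,
    tag_class: str,
    catalog: BarcodeCatalog,
    params: MatchParams,
) -> Assignment:
    """Exhaustive-scan reference for assign_tag (test oracle).

    Walks every catalog tag of the class, computing the distance
    directly, then applies the same exact/within/no-hit/ambiguous rule.
    Kept independent of :class:`TagIndex` on purpose.
    """
    d1 = d2 = None
    best_strain = None
    for seq, strain in catalog.tags(tag_class).items():
        if seq == obs_seq:
            return Assignment(strain, tag_class, 0, "exact")
        if params.metric == "hamming":
            if len(seq) != len(obs_seq):
                continue
            d = sum(1 for x, y in zip(seq, obs_seq) if x != y)
        else:
            d = edlib.align(obs_seq, seq, task="distance")["editDistance"]
        if d1 is None or d < d1:
            d1, d2, best_strain = d, d1, strain
        elif d2 is None or d < d2:
            d2 = d
    if d1 is None or d1 > params.max_dist:
        return Assignment(None, tag_class, None, "no_hit")
    if d2 is not None and d2 - d1 < params.min_margin:
        return Assignment(None, tag_class, d1, "ambiguous")
    return Assignment(best_strain, tag_class, d1, "within_dist")
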