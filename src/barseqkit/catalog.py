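"""Strain barcode catalogs.

Each strain of a barcoded deletion collection carries up to two unique
20-bp DNA barcodes ("uptag" and "downtag") flanked by common priming
sites.  The catalog maps those tag sequences back to strain identifiers
and is the reference that error-tolerant matching indexes.  Most strains
carry both tags; a minority carry only an uptag, and such records are
kept with the downtag marked absent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

TAG_LENGTH = 20
TAG_CLASSES = ("uptag", "downtag")
_VALID_BASES = frozenset("ACGT")


class CatalogError(ValueError):
    """Raised when a catalog violates its invariants at load time."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One strain with its uptag and/or downtag sequence.

    Absent tags are ``None``, never empty strings.  Present tags are
    exactly 20 bp over {A, C, G, T}; ambiguity codes are rejected because
    a distance-based reference must be unambiguous.
    """

    strain_id: str
    uptag: str | None = None
    downtag: str | None = None

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise CatalogError("empty strain_id")
        if self.uptag is None and self.downtag is None:
            raise CatalogError(f"strain {self.strain_id!r}: no tag present")
        for cls in TAG_CLASSES:
            seq = getattr(self, cls)
            if seq is None:
                continue
            if len(seq) != TAG_LENGTH:
                raise CatalogError(
                    f"strain {self.strain_id!r}: {cls} has length {len(seq)}, "
                    f"expected {TAG_LENGTH}"
                )
            if not _VALID_BASES.issuperset(seq):
                bad = sorted(set(seq) - _VALID_BASES)
                raise CatalogError(
                    f"strain {self.strain_id!r}: {cls} contains non-ACGT "
                    f"symbol(s) {bad}"
                )

    def tag(self, tag_class: str) -> str | None:
        if tag_class not in TAG_CLASSES:
            raise ValueError(f"unknown tag class {tag_class!r}")
        return getattr(self, tag_class)


class BarcodeCatalog:
    """Validated collection of :class:`BarcodeRecord`.

    Enforces unique strain ids and, within each tag class, unique tag
    sequences.  ``index_by_sequence`` maps tag sequence to
    ``(strain_id, tag_class)`` and is built lazily.
    """

    def __init__(self, records: Iterable[BarcodeRecord]):
        self.records: list[BarcodeRecord] = list(records)
        seen_ids: set[str] = set()
        seen_tags: dict[str, dict[str, str]] = {c: {} for c in TAG_CLASSES}
        for rec in self.records:
            if rec.strain_id in seen_ids:
                raise CatalogError(f"duplicate strain_id {rec.strain_id!r}")
            seen_ids.add(rec.strain_id)
            for cls in TAG_CLASSES:
                seq = rec.tag(cls)
                if seq is None:
                    continue
                if seq in seen_tags[cls]:
                    raise CatalogError(
                        f"duplicate {cls} sequence shared by strains "
                        f"{seen_tags[cls][seq]!r} and {rec.strain_id!r}"
                    )
                seen_tags[cls][seq] = rec.strain_id
        self._index: dict[str, tuple[str, str]] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BarcodeRecord]:
        return iter(self.records)

    @property
    def index_by_sequence(self) -> dict[str, tuple[str, str]]:
        if self._index is None:
            idx: dict[str, tuple[str, str]] = {}
            for rec in self.records:
                for cls in TAG_CLASSES:
                    seq = rec.tag(cls)
                    if seq is not None:
                        idx[seq] = (rec.strain_id, cls)
            self._index = idx
        return self._index

    def tags(self, tag_class: str) -> dict[str, str]:
        """Mapping tag sequence -> strain_id for one tag class."""
        if tag_class not in TAG_CLASSES:
            raise ValueError(f"unknown tag class {tag_class!r}")
        return {
            rec.tag(tag_class): rec.strain_id
            for rec in self.records
            if rec.tag(tag_class) is not None
        }

    def strain_ids(self) -> list[str]:
        return [rec.strain_id for rec in self.records]


def _clean_tag(cell: str | None) -> str | None:
    if cell is None:
        return None
    cell = cell.strip().upper()
    return cell or None


def load_catalog(path: str | Path, format: str | None = None) -> BarcodeCatalog:
    """Load a catalog from TSV or FASTA.

    TSV needs a header row with columns ``strain_id``, ``uptag``,
    ``downtag`` (empty cell = tag absent).  FASTA headers are
    ``strain_id|uptag`` / ``strain_id|downtag``, one entry per tag.
    Lowercase input is uppercased; case carries no information here.
    """
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna"} else "tsv"
    if format == "tsv":
        return _load_tsv(path)
    if format == "fasta":
        return _load_fasta(path)
    raise ValueError(f"unknown catalog format {format!r}")


def _load_tsv(path: Path) -> BarcodeCatalog:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"strain_id", "uptag", "downtag"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CatalogError(
                f"{path}: TSV header must contain columns {sorted(required)}"
            )
        records = [
            BarcodeRecord(
                strain_id=row["strain_id"].strip(),
                uptag=_clean_tag(row["uptag"]),
                downtag=_clean_tag(row["downtag"]),
            )
            for row in reader
        ]
    return BarcodeCatalog(records)


def _load_fasta(path: Path) -> BarcodeCatalog:
    from Bio import SeqIO

    by_strain: dict[str, dict[str, str | None]] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        try:
            strain_id, tag_class = entry.id.split("|", 1)
        except ValueError:
            raise CatalogError(
                f"{path}: FASTA header {entry.id!r} is not 'strain_id|tag_class'"
            ) from None
        if tag_class not in TAG_CLASSES:
            raise CatalogError(f"{path}: unknown tag class in header {entry.id!r}")
        slot = by_strain.setdefault(strain_id, {c: None for c in TAG_CLASSES})
        if slot[tag_class] is not None:
            raise CatalogError(
                f"{path}: strain {strain_id!r} has two {tag_class} entries"
            )
        slot[tag_class] = _clean_tag(str(entry.seq))
    records = [
        BarcodeRecord(strain_id=sid, uptag=tags["uptag"], downtag=tags["downtag"])
        for sid, tags in by_strain.items()
    ]
    return BarcodeCatalog(records)


def write_catalog(catalog: BarcodeCatalog, path: str | Path) -> None:
    """Write the catalog as TSV (lossless round-trip with load_catalog)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["strain_id", "uptag", "downtag"])
        for rec in catalog:
            writer.writerow([rec.strain_id, rec.uptag or "", rec.downtag or ""])


def _encode_tags(tags: list[str]) -> np.ndarray:
    return np.frombuffer("".join(tags).encode("ascii"), dtype=np.uint8).reshape(
        len(tags), TAG_LENGTH
    )


def min_pairwise_hamming(tags: list[str], chunk: int = 512) -> int | None:
    """Exact minimum pairwise Hamming distance among equal-length tags.

    All-pairs, computed in chunks to bound memory; intended for catalogs
    of up to ~10,000 tags per class.  Returns None for fewer than 2 tags.
    """
    n = len(tags)
    if n < 2:
        return None
    mat = _encode_tags(tags)
    best = TAG_LENGTH
    for start in range(0, n, chunk):
        block = mat[start : start + chunk]
        # block rows vs all rows at or after the block start; strict upper
        # triangle keeps each unordered pair exactly once
        rest = mat[start:]
        d = (block[:, None, :] != rest[None, :, :]).sum(axis=2)
        offdiag = d[np.triu_indices(block.shape[0], k=1, m=rest.shape[0])]
        if offdiag.size:
            best = min(best, int(offdiag.min()))
    return best


def catalog_stats(catalog: BarcodeCatalog) -> dict:
    """Summary counts and within-class minimum pairwise Hamming distance."""
    n_both = sum(
        1 for r in catalog if r.uptag is not None and r.downtag is not None
    )
    n_up_only = sum(
        1 for r in catalog if r.uptag is not None and r.downtag is None
    )
    n_down_only = sum(
        1 for r in catalog if r.uptag is None and r.downtag is not None
    )
    stats = {
        "n_strains": len(catalog),
        "n_both_tags": n_both,
        "n_uptag_only": n_up_only,
        "n_downtag_only": n_down_only,
    }
    for cls in TAG_CLASSES:
        tags = [r.tag(cls) for r in catalog if r.tag(cls) is not None]
        stats[f"n_{cls}s"] = len(tags)
        stats[f"min_hamming_{cls}"] = min_pairwise_hamming(tags)
    return stats
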