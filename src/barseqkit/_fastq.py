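"""FASTQ reading/writing helpers (plain or gzip, Phred+33).

Extraction never consumes base qualities, so reading yields
``(read_id, sequence)`` pairs; writing emits a constant placeholder
quality.  Gzip members are written with a zeroed mtime so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PLACEHOLDER_QUALITY = "I"  # Q40


def _is_gz(path: Path) -> bool:
    return path.suffix == ".gz"


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ or FASTQ.gz file.

    Truncated or malformed records raise with the offending position
    (via Biopython's parser).
    """
    path = Path(path)
    opener = gzip.open if _is_gz(path) else open
    with opener(path, "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> int:
    """Write (read_id, sequence) pairs as FASTQ; returns records written."""
    path = Path(path)
    if _is_gz(path):
        fh = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
        import io

        out = io.TextIOWrapper(fh)
    else:
        out = open(path, "w")
    n = 0
    with out:
        for read_id, seq in reads:
            out.write(f"@{read_id}\n{seq}\n+\n{PLACEHOLDER_QUALITY * len(seq)}\n")
            n += 1
    return n
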