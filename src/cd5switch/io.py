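"""FASTA/FASTQ input/output helpers.

Sequence files follow the common dereplication convention of carrying the
read abundance in the header as ``;size=N`` (as produced by usearch/vsearch
``-sizeout``), so processed repertoires round-trip through plain FASTA.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PHRED_OFFSET = 33


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(record_id, sequence)`` tuples."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with _open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta-2line")


def parse_size_annotation(record_id: str) -> tuple[str, int]:
    """Split ``seq12;size=42`` into ``("seq12", 42)``; size defaults to 1."""
    size = 1
    parts = [p for p in record_id.split(";") if p]
    name = parts[0] if parts else record_id
    for part in parts[1:]:
        if part.startswith("size="):
            size = int(part[5:])
    return name, size


def read_sized_fasta(path: str | Path) -> list[tuple[str, str, int]]:
    """Read FASTA with ``;size=`` annotations -> ``(name, sequence, size)``."""
    out = []
    for rec_id, seq in read_fasta(path):
        name, size = parse_size_annotation(rec_id)
        out.append((name, seq, size))
    return out


def write_sized_fasta(records: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    write_fasta(((f"{name};size={size}", seq) for name, seq, size in records), path)


def decode_phred(qual: str) -> list[int]:
    scores = [ord(c) - PHRED_OFFSET for c in qual]
    if any(q < 0 or q > 93 for q in scores):
        raise ValueError("quality string is not Phred+33 encodable")
    return scores


def encode_phred(scores: Iterable[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in scores)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, sequence, quality_string)`` from a FASTQ file."""
    with _open_text(path) as fh:
        for title, seq, qual in SeqIO.QualityIO.FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper(), qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
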