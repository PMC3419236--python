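"""FASTQ/FASTA input-output and the read record container.

Reads are carried as :class:`ReadRecord`, a light dataclass holding the
bases, integer Phred qualities and the CASAVA-1.8 pass-filter flag parsed
from the header (``<id> <mate>:<Y|N>:<control>:<index>``; ``Y`` means the
read FAILED the instrument's chastity filter).  Files may be plain or
gzip-compressed; quality strings may use offset 33 (default) or 64.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass
class ReadRecord:
    """One sequenced read."""

    id: str
    mate: int  # 1 or 2
    bases: str
    quals: list[int] = field(repr=False)
    passfilter: bool = True

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if self.quals and not all(0 <= q <= 60 for q in self.quals):
            raise ValueError(f"read {self.id!r}: Phred values outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


def xopen(path: str | Path, mode: str = "rt") -> IO:
    """Open ``path``, transparently handling a ``.gz`` suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_title(title: str) -> tuple[str, int, bool]:
    """Split a FASTQ title into (id, mate, passfilter).

    CASAVA-1.8 style ``name 1:N:0:INDEX`` is recognised; older ``name/1``
    suffixes are accepted as a fallback.  Reads without any mate marker are
    treated as mate 1, pass-filter.
    """
    name, _, desc = title.partition(" ")
    if desc:
        fields = desc.split(":")
        if len(fields) >= 2 and fields[0] in ("1", "2") and fields[1] in ("Y", "N"):
            return name, int(fields[0]), fields[1] == "N"
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        return name[:-2], int(name[-1]), True
    return name, 1, True


def decode_quals(qual_str: str, phred_offset: int = 33) -> list[int]:
    quals = [ord(c) - phred_offset for c in qual_str]
    if any(q < 0 or q > 93 for q in quals):
        raise ValueError(
            f"quality string {qual_str!r} not valid for Phred offset {phred_offset}"
        )
    return quals


def encode_quals(quals: Iterable[int], phred_offset: int = 33) -> str:
    return "".join(chr(q + phred_offset) for q in quals)


def read_fastq(path: str | Path, phred_offset: int = 33) -> Iterator[ReadRecord]:
    """Iterate over one FASTQ file."""
    with xopen(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            name, mate, pf = _parse_title(title)
            try:
                quals = decode_quals(qual, phred_offset)
            except ValueError as exc:
                raise ValueError(f"record {name!r}: {exc}") from exc
            yield ReadRecord(id=name, mate=mate, bases=seq.upper(), quals=quals,
                             passfilter=pf)


def read_fastq_pairs(
    path1: str | Path, path2: str | Path, phred_offset: int = 33
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Iterate over synchronized mate files, checking id agreement."""
    it1, it2 = read_fastq(path1, phred_offset), read_fastq(path2, phred_offset)
    for r1 in it1:
        r2 = next(it2, None)
        if r2 is None:
            raise ValueError(f"mate files desynchronized: {path2} ended early")
        if r1.id != r2.id:
            raise ValueError(
                f"mate files desynchronized: {r1.id!r} paired with {r2.id!r}"
            )
        yield r1, r2
    if next(it2, None) is not None:
        raise ValueError(f"mate files desynchronized: {path1} ended early")


def format_fastq_record(read: ReadRecord, phred_offset: int = 33) -> str:
    pf = "N" if read.passfilter else "Y"
    return (
        f"@{read.id} {read.mate}:{pf}:0:ACGTACGT\n{read.bases}\n+\n"
        f"{encode_quals(read.quals, phred_offset)}\n"
    )


def write_fastq(
    reads: Iterable[ReadRecord], path: str | Path, phred_offset: int = 33
) -> int:
    """Write reads to a FASTQ file; returns the number written."""
    n = 0
    with xopen(path, "wt") as handle:
        for read in reads:
            handle.write(format_fastq_record(read, phred_offset))
            n += 1
    return n


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write (id, sequence) pairs as FASTA, 70 columns per line."""
    n = 0
    with xopen(path, "wt") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as a list of (id, sequence) pairs."""
    from Bio import SeqIO

    with xopen(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
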