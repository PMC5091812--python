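"""FASTQ records and paired-file IO.

Reads are Illumina-style: the header comment carries the CASAVA >= 1.8
control fields ``<mate>:<Y|N>:<control>:<index>`` where ``Y`` in the second
field means the read *failed* the chastity filter. A missing comment is
treated as a pass, since pre-CASAVA-1.8 files carry no flag at all.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


class FastqFormatError(ValueError):
    """Malformed FASTQ input, annotated with the 1-based record number."""


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    mate: int
    sequence: str
    quality: tuple[int, ...]
    chastity_pass: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )
        if self.mate not in (1, 2):
            raise ValueError(f"{self.read_id}: mate must be 1 or 2")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    mate1: ReadRecord
    mate2: ReadRecord

    def __post_init__(self) -> None:
        if self.mate1.read_id != self.mate2.read_id:
            raise ValueError(
                f"unmatched mates: {self.mate1.read_id!r} vs {self.mate2.read_id!r}"
            )

    @property
    def read_id(self) -> str:
        return self.mate1.read_id


def decode_quality(qual: str) -> tuple[int, ...]:
    return tuple(ord(c) - PHRED_OFFSET for c in qual)


def encode_quality(quality: Iterable[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in quality)


def _parse_title(title: str, default_mate: int) -> tuple[str, int, bool]:
    """Split a FASTQ title into (read_id, mate, chastity_pass)."""
    parts = title.split(None, 1)
    read_id = parts[0]
    mate, chastity_pass = default_mate, True
    if len(parts) == 2:
        fields = parts[1].split(":")
        if fields and fields[0].isdigit():
            mate = int(fields[0])
        if len(fields) >= 2 and fields[1] in ("Y", "N"):
            chastity_pass = fields[1] == "N"
    return read_id, mate, chastity_pass


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # mtime=0 keeps gzip output byte-identical across reruns.
            raw = gzip.GzipFile(path, "wb", mtime=0)
            return io.TextIOWrapper(raw)
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path: str | Path, mate: int) -> Iterator[ReadRecord]:
    """Yield ReadRecords; malformed records raise with their record number."""
    with _open_text(path) as handle:
        parsed = FastqGeneralIterator(handle)
        n = 0
        while True:
            try:
                title, seq, qual = next(parsed)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"{path}: malformed FASTQ at record {n + 1}: {exc}"
                ) from exc
            n += 1
            read_id, hdr_mate, chastity = _parse_title(title, mate)
            yield ReadRecord(read_id, hdr_mate, seq.upper(), decode_quality(qual), chastity)


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    mates1 = list(iter_fastq(path1, 1))
    mates2 = list(iter_fastq(path2, 2))
    if len(mates1) != len(mates2):
        raise FastqFormatError(
            f"mate files differ in length: {len(mates1)} vs {len(mates2)}"
        )
    return [ReadPair(m1, m2) for m1, m2 in zip(mates1, mates2)]


def format_record(read: ReadRecord) -> str:
    flag = "N" if read.chastity_pass else "Y"
    return (
        f"@{read.read_id} {read.mate}:{flag}:0:1\n"
        f"{read.sequence}\n+\n{encode_quality(read.quality)}\n"
    )


def write_fastq(path: str | Path, reads: Iterable[ReadRecord]) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            handle.write(format_record(read))


def write_fastq_pairs(
    path1: str | Path, path2: str | Path, pairs: Iterable[ReadPair]
) -> None:
    pairs = list(pairs)
    write_fastq(path1, (p.mate1 for p in pairs))
    write_fastq(path2, (p.mate2 for p in pairs))


__all__ = [
    "FastqFormatError",
    "ReadRecord",
    "ReadPair",
    "decode_quality",
    "encode_quality",
    "iter_fastq",
    "read_fastq_pairs",
    "write_fastq",
    "write_fastq_pairs",
    "format_record",
]
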