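"""Light FASTQ record container and paired read/write helpers.

Parsing goes through Biopython; writing is done directly so repeated runs
with the same seed produce byte-identical files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

from Bio import SeqIO


@dataclass
class FastqRecord:
    id: str
    seq: str
    qual: str  # Phred+33 string, same length as seq

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id!r}: sequence/quality length mismatch")


@dataclass
class ReadPair:
    read1: FastqRecord
    read2: FastqRecord


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> list[FastqRecord]:
    out = []
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append(FastqRecord(rec.description, str(rec.seq), qual))
    return out


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    r1, r2 = read_fastq(path1), read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError(f"mate files differ in length: {len(r1)} vs {len(r2)} records")
    return [ReadPair(a, b) for a, b in zip(r1, r2)]


def write_fastq(records, path) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")


def write_fastq_pairs(pairs, path1, path2) -> None:
    write_fastq((p.read1 for p in pairs), path1)
    write_fastq((p.read2 for p in pairs), path2)
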