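"""UMI extraction and read trimming.

The library design places an 8-base random barcode (UMI) at the very start of
read 2. Before anything else, that barcode is clipped off and appended to
both read IDs (after a ':' separator) so it survives alignment and can key
deduplication. Trimming is a deliberately small re-implementation of the
usual adapter/quality trimming step: 3' Phred cutoff, single 3' adapter per
mate with partial-overlap matching, minimum-length filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fastqio import FastqRecord, ReadPair
from .panel import FWD_TAIL, REV_TAIL, UMI_LEN


@dataclass
class TaggedReadPair:
    """A read pair after UMI extraction; both IDs end in ':<UMI>'."""

    read1: FastqRecord
    read2: FastqRecord
    umi: str


@dataclass
class PreprocessStats:
    input_pairs: int = 0
    rejected_umi: int = 0
    discarded_trim: int = 0
    output_pairs: int = 0
    messages: list[str] = field(default_factory=list)


def extract_umi(pair: ReadPair, umi_len: int = UMI_LEN) -> TaggedReadPair | None:
    """Move the first umi_len bases of read 2 into both read IDs.

    Returns None for pairs whose read 2 is too short to contain both the UMI
    and at least one template base (the caller counts these as rejected).
    """
    if len(pair.read2.seq) <= umi_len:
        return None
    umi = pair.read2.seq[:umi_len]
    r1 = FastqRecord(f"{pair.read1.id}:{umi}", pair.read1.seq, pair.read1.qual)
    r2 = FastqRecord(f"{pair.read2.id}:{umi}",
                     pair.read2.seq[umi_len:], pair.read2.qual[umi_len:])
    return TaggedReadPair(r1, r2, umi)


def _quality_trim_3p(seq: str, qual: str, cutoff: int) -> tuple[str, str]:
    end = len(seq)
    while end > 0 and ord(qual[end - 1]) - 33 < cutoff:
        end -= 1
    return seq[:end], qual[:end]


def _adapter_trim_3p(seq: str, qual: str, adapter: str,
                     min_overlap: int = 3, max_error: float = 0.1) -> tuple[str, str]:
    """Remove a 3' adapter allowing a partial match at the read end.

    Scans candidate start positions left to right; the first position where
    the read suffix matches an adapter prefix of length >= min_overlap with
    at most max_error mismatch fraction wins.
    """
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, len(adapter))
        if overlap < min_overlap:
            break
        mism = sum(a != b for a, b in zip(seq[i:i + overlap], adapter[:overlap]))
        if mism <= max_error * overlap:
            return seq[:i], qual[:i]
    return seq, qual


def trim_pair(tagged: TaggedReadPair, quality_cutoff: int = 20,
              adapter_seqs: tuple[str, str] = (FWD_TAIL, REV_TAIL),
              min_len: int = 20) -> TaggedReadPair | None:
    """Quality- and adapter-trim a tagged pair; None if either mate ends < min_len."""
    out = []
    for rec, adapter in ((tagged.read1, adapter_seqs[0]), (tagged.read2, adapter_seqs[1])):
        seq, qual = _quality_trim_3p(rec.seq, rec.qual, quality_cutoff)
        seq, qual = _adapter_trim_3p(seq, qual, adapter)
        if len(seq) < min_len:
            return None
        out.append(FastqRecord(rec.id, seq, qual))
    return TaggedReadPair(out[0], out[1], tagged.umi)


def preprocess_pairs(pairs, umi_len: int = UMI_LEN, quality_cutoff: int = 20,
                     adapter_seqs: tuple[str, str] = (FWD_TAIL, REV_TAIL),
                     min_len: int = 20) -> tuple[list[TaggedReadPair], PreprocessStats]:
    """Run UMI extraction + trimming over a collection of pairs, with accounting.

    Invariant: input_pairs == output_pairs + rejected_umi + discarded_trim.
    """
    stats = PreprocessStats()
    kept = []
    for pair in pairs:
        stats.input_pairs += 1
        tagged = extract_umi(pair, umi_len)
        if tagged is None:
            stats.rejected_umi += 1
            continue
        trimmed = trim_pair(tagged, quality_cutoff, adapter_seqs, min_len)
        if trimmed is None:
            stats.discarded_trim += 1
            continue
        kept.append(trimmed)
    stats.output_pairs = len(kept)
    return kept, stats


def umi_from_read_id(read_id: str) -> str:
    """The UMI is the final colon-delimited field of a tagged read ID."""
    _, sep, umi = read_id.rpartition(":")
    if not sep or not umi or set(umi) - set("ACGTN"):
        raise ValueError(f"read {read_id!r} carries no UMI suffix")
    return umi
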