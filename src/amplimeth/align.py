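"""Amplicon assignment and bisulfite-space CpG/SNP calling.

Reads are never aligned to a genome: amplicons are primer-defined, so read 1
always starts at a known end of a known reference. Assignment therefore
reduces to comparing the read-1 prefix against each amplicon's converted
reference in three-letter space (C and T collapsed in the read orientation,
since bisulfite conversion makes C/T uninformative on the sequenced strand),
and calling reduces to ungapped placement. Methylation at each CpG is read as
C (methylated) vs T (unmethylated) on the targeted strand, reported at the
canonical top-strand offset; bottom-strand amplicons observe the mirrored
G/A states in top coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .panel import Amplicon, AmpliconPanel, ANCHOR_LEN, ANCHOR_TIE_MARGIN, revcomp
from .preprocess import TaggedReadPair, umi_from_read_id

#: Per-read call codes: methylated / unmethylated / unknown.
METH, UNMETH, UNKNOWN = "M", "U", "."

#: Reads with at least this many retained non-CpG cytosines are flagged
#: conversion-suspect (they are retained; controls handle conversion QC).
CONVERSION_SUSPECT_MIN = 3


@dataclass
class AlignedRead:
    """A read pair placed on its amplicon with per-CpG and SNP observations."""

    read_id: str
    umi: str
    amplicon: str
    start: int
    cpg_calls: list[str]                 # aligned with the amplicon's cpg_offsets
    snp_obs: dict[int, str] = field(default_factory=dict)  # top offset -> base
    mismatches: int = 0
    unconverted_noncpg: int = 0
    converted_noncpg: int = 0
    obs_seq: str = ""                    # targeted-strand observation, '.' = uncovered

    @property
    def conversion_suspect(self) -> bool:
        return self.unconverted_noncpg >= CONVERSION_SUSPECT_MIN

    @property
    def n_called(self) -> int:
        return sum(c != UNKNOWN for c in self.cpg_calls)

    @property
    def n_methylated(self) -> int:
        return sum(c == METH for c in self.cpg_calls)


def _three_letter(seq: str) -> str:
    return seq.replace("C", "T")


def assign_amplicon(pair: TaggedReadPair, panel: AmpliconPanel,
                    max_mismatch_frac: float = 0.1,
                    anchor_len: int = ANCHOR_LEN,
                    tie_margin: int = ANCHOR_TIE_MARGIN) -> str | None:
    """Demultiplex a pair to an amplicon by its read-1 prefix, or None.

    The best amplicon wins only if its three-letter mismatch fraction over
    the anchor is <= max_mismatch_frac and it beats the runner-up by at
    least tie_margin mismatches.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    prefix = _three_letter(pair.read1.seq[:anchor_len])
    scored = []
    for amp in panel:
        anchor = amp.anchor(anchor_len)
        n = min(len(prefix), len(anchor))
        if n == 0:
            continue
        mism = sum(a != b for a, b in zip(prefix[:n], anchor[:n]))
        # an anchor truncated by a short read counts missing bases as mismatches
        mism += max(len(anchor) - n, 0)
        scored.append((mism, amp.name))
    if not scored:
        return None
    scored.sort()
    best_mism, best_name = scored[0]
    if best_mism > max_mismatch_frac * anchor_len:
        return None
    if len(scored) > 1 and scored[1][0] - best_mism < tie_margin:
        return None
    return best_name


def _observed_targeted(pair: TaggedReadPair, L: int) -> list[str | None]:
    """Reconstruct the targeted-strand observation from both mates.

    Read 1 is the targeted-strand sequence from position 0; the reverse
    complement of read 2 is its tail. Read 1 wins where the mates overlap.
    """
    obs: list[str | None] = [None] * L
    for i, b in enumerate(pair.read1.seq[:L]):
        obs[i] = b
    rc2 = revcomp(pair.read2.seq)
    n2 = min(len(rc2), L)
    tail = rc2[len(rc2) - n2:]
    for j, b in enumerate(tail):
        pos = L - n2 + j
        if obs[pos] is None:
            obs[pos] = b
    return obs


def call_cpgs(pair: TaggedReadPair, amplicon: Amplicon) -> AlignedRead:
    """Call per-CpG methylation and conversion QC for an assigned pair.

    At each CpG position on the targeted strand: observed C -> methylated,
    T -> unmethylated, anything else (or no coverage) -> unknown. Non-CpG
    reference cytosines observed as C count as conversion failures.
    Mismatches are counted in three-letter space against the reference
    (SNP-carrying reads will show a small constant excess).
    """
    L = len(amplicon.ref_seq)
    obs = _observed_targeted(pair, L)
    tref = amplicon.targeted_ref()
    cpg_pos = set(amplicon.cpg_targeted_positions())
    snp_pos = {amplicon.targeted_pos(s.offset) for s in amplicon.snps}

    calls = []
    for tpos in amplicon.cpg_targeted_positions():
        b = obs[tpos]
        if tref[tpos] != "C" or b is None:
            calls.append(UNKNOWN)
        elif b == "C":
            calls.append(METH)
        elif b == "T":
            calls.append(UNMETH)
        else:
            calls.append(UNKNOWN)

    unconv = conv = mism = 0
    for i, b in enumerate(obs):
        if b is None:
            continue
        if tref[i] == "C" and i not in cpg_pos and i not in snp_pos:
            if b == "C":
                unconv += 1
            elif b == "T":
                conv += 1
        if _three_letter(b) != _three_letter(tref[i]):
            mism += 1

    return AlignedRead(
        read_id=pair.read1.id, umi=umi_from_read_id(pair.read1.id),
        amplicon=amplicon.name, start=0, cpg_calls=calls,
        mismatches=mism, unconverted_noncpg=unconv, converted_noncpg=conv,
        obs_seq="".join(b if b is not None else "." for b in obs))


def observe_snps(aligned: AlignedRead, amplicon: Amplicon) -> AlignedRead:
    """Record the observed base (top-strand space) at each usable SNP.

    Bases are recorded as-is; conversion-aware comparison against the two
    alleles happens at allele-splitting time.
    """
    if aligned.amplicon != amplicon.name:
        raise ValueError("aligned read does not belong to this amplicon")
    L = len(amplicon.ref_seq)
    for snp in amplicon.usable_snps:
        tpos = amplicon.targeted_pos(snp.offset)
        b = aligned.obs_seq[tpos]
        if b == ".":
            continue
        if amplicon.targeted_strand == "bottom":
            b = revcomp(b)
        aligned.snp_obs[snp.offset] = b
    return aligned


def align_pairs(pairs, panel: AmpliconPanel,
                max_mismatch_frac: float = 0.1) -> tuple[list[AlignedRead], int]:
    """Assign, call and SNP-observe a batch of pairs.

    Returns the aligned reads and the count of unassigned pairs.
    """
    aligned, unassigned = [], 0
    for pair in pairs:
        name = assign_amplicon(pair, panel, max_mismatch_frac)
        if name is None:
            unassigned += 1
            continue
        amp = panel[name]
        aligned.append(observe_snps(call_cpgs(pair, amp), amp))
    return aligned, unassigned


def write_alignment_dump(reads: list[AlignedRead], path) -> None:
    """SAM-like TSV dump of aligned reads for debugging."""
    with open(path, "w") as fh:
        fh.write("read_id\tamplicon\tstart\tcigar\tcpg_calls\tumi\tmismatches\tunconverted_noncpg\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.amplicon}\t{r.start}\t"
                     f"{len(r.obs_seq.strip('.'))}M\t{''.join(r.cpg_calls)}\t"
                     f"{r.umi}\t{r.mismatches}\t{r.unconverted_noncpg}\n")
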