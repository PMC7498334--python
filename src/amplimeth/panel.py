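"""Amplicon panel model: regions, primers, CpG/SNP annotation and bisulfite space.

A panel is a small set of PCR amplicons targeting CpG-rich regulatory regions
(imprinting control regions plus methylated/unmethylated control loci). Each
amplicon carries its genomic reference sequence, the bisulfite strand the
primers amplify, primer sequences, the CpG positions, and any strain SNPs used
for allele splitting. Everything downstream (simulation, alignment, calling)
works in the coordinates defined here: 0-based half-open, with CpGs keyed by
the top-strand 'C' position regardless of which strand is targeted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO

VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Constant 5' tails added to panel primers during library construction.
#: The reverse tail is followed by 8 random bases forming the UMI.
FWD_TAIL = "CTACACGACGCTCTTCCGATCT"
REV_TAIL = "TGCTGAACCGCTCTTCCGATCT"
UMI_LEN = 8

REGION_CLASSES = ("imprinted_icr", "control_unmethylated", "control_methylated", "other")

#: Bases read 1 is anchored on when demultiplexing read pairs to amplicons,
#: and the mismatch margin the best hit must beat the runner-up by.
ANCHOR_LEN = 30
ANCHOR_TIE_MARGIN = 2


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)}")


def find_cpg_sites(seq: str) -> list[int]:
    """Offsets i with seq[i:i+2] == 'CG' (the top-strand C of each CpG)."""
    _validate_dna(seq)
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


@dataclass
class SnpSite:
    """A strain-discriminating SNP inside an amplicon (top-strand alleles)."""

    offset: int
    allele_a: str
    allele_b: str
    label_a: str
    label_b: str
    usable: bool = True

    def __post_init__(self) -> None:
        self.allele_a = self.allele_a.upper()
        self.allele_b = self.allele_b.upper()
        if self.allele_a == self.allele_b:
            raise ValueError("SNP alleles must differ")
        if not self.label_a or not self.label_b or self.label_a == self.label_b:
            raise ValueError("SNP labels must be non-empty and distinct")

    def allele_for(self, label: str) -> str | None:
        if label == self.label_a:
            return self.allele_a
        if label == self.label_b:
            return self.allele_b
        return None


def filter_snps(snps: list[SnpSite], targeted_strand: str) -> list[SnpSite]:
    """Mark SNPs masked by bisulfite conversion as unusable.

    On the targeted strand a C can be read as either C or T depending on its
    methylation state, so a C/T pair (top strand) or the strand-mirrored G/A
    pair (bottom strand) cannot be distinguished after conversion. An 'N'
    allele is never usable.
    """
    if targeted_strand not in ("top", "bottom"):
        raise ValueError(f"unknown strand {targeted_strand!r}")
    masked = {"C", "T"} if targeted_strand == "top" else {"G", "A"}
    out = []
    for snp in snps:
        pair = {snp.allele_a, snp.allele_b}
        usable = pair != masked and "N" not in pair
        out.append(replace(snp, usable=usable))
    return out


def observed_alleles(allele: str, targeted_strand: str) -> set[str]:
    """Bases (top-strand space) an allele can appear as after conversion.

    A C on the targeted strand reads as C (methylated / conversion failure)
    or T (converted); in top coordinates that is C/T for top-strand amplicons
    and G/A for bottom-strand ones. All other bases are read faithfully.
    """
    if targeted_strand == "top" and allele == "C":
        return {"C", "T"}
    if targeted_strand == "bottom" and allele == "G":
        return {"G", "A"}
    return {allele}


def bisulfite_reference(seq: str, mode: str, strand: str) -> str:
    """Bisulfite-convert a reference in silico, returned in top coordinates.

    mode 'all_unmethylated' converts every targeted-strand C to T;
    'cpg_methylated' protects CpG cytosines (the fully methylated reference).
    Bottom-strand conversion is applied to the reverse complement and the
    result re-complemented, so it shows up as G->A changes in top coordinates.
    """
    _validate_dna(seq)
    if mode not in ("all_unmethylated", "cpg_methylated"):
        raise ValueError(f"unknown mode {mode!r}")
    if strand == "bottom":
        return revcomp(bisulfite_reference(revcomp(seq), mode, "top"))
    if strand != "top":
        raise ValueError(f"unknown strand {strand!r}")
    cpg = set(find_cpg_sites(seq))
    out = []
    for i, b in enumerate(seq):
        if b == "C" and (mode == "all_unmethylated" or i not in cpg):
            out.append("T")
        else:
            out.append(b)
    return "".join(out)


@dataclass
class RuleVerdict:
    """Outcome of the amplicon primer-design rule check."""

    size_rule: bool
    min_cpg_rule: bool
    primer_cpg_rule: bool
    optimal: bool
    messages: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.size_rule and self.min_cpg_rule and self.primer_cpg_rule


def check_primer_pair(fwd: str, rev: str, product_seq: str,
                      max_size: int = 430, optimal_size: int = 300,
                      min_cpgs: int = 5) -> RuleVerdict:
    """Check a bisulfite PCR design against the panel rules.

    The product must be at most 430 bp (ideally <=300 bp, to limit dropout of
    fragmented bisulfite-treated templates), contain at least five CpGs, and
    neither primer may contain a CpG (a CpG in a primer would bias
    amplification toward one methylation state).
    """
    if not fwd or not rev:
        raise ValueError("empty primer sequence")
    for name, p in (("fwd", fwd), ("rev", rev)):
        _validate_dna(p, f"{name} primer")
    _validate_dna(product_seq, "product")
    msgs = []
    size_ok = len(product_seq) <= max_size
    if not size_ok:
        msgs.append(f"product {len(product_seq)} bp exceeds {max_size} bp")
    n_cpg = len(find_cpg_sites(product_seq))
    cpg_ok = n_cpg >= min_cpgs
    if not cpg_ok:
        msgs.append(f"only {n_cpg} CpGs in product (minimum {min_cpgs})")
    primer_ok = "CG" not in fwd and "CG" not in rev
    if not primer_ok:
        msgs.append("CpG within a primer sequence")
    return RuleVerdict(size_ok, cpg_ok, primer_ok,
                       optimal=len(product_seq) <= optimal_size, messages=msgs)


@dataclass
class Amplicon:
    """One panel region with reference, primers, CpG and SNP annotation."""

    name: str
    chrom: str
    start: int
    end: int
    targeted_strand: str
    ref_seq: str
    fwd_primer: str
    rev_primer: str
    region_class: str = "other"
    snps: list[SnpSite] = field(default_factory=list)
    cpg_offsets: list[int] = field(init=False)

    def __post_init__(self) -> None:
        self.ref_seq = self.ref_seq.upper()
        _validate_dna(self.ref_seq, f"amplicon {self.name!r}")
        if self.targeted_strand not in ("top", "bottom"):
            raise ValueError(f"amplicon {self.name!r}: bad strand {self.targeted_strand!r}")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"amplicon {self.name!r}: bad class {self.region_class!r}")
        if self.end - self.start != len(self.ref_seq):
            raise ValueError(f"amplicon {self.name!r}: coordinates span "
                             f"{self.end - self.start} bp but sequence is {len(self.ref_seq)} bp")
        self.cpg_offsets = find_cpg_sites(self.ref_seq)
        if not self.cpg_offsets:
            raise ValueError(f"amplicon {self.name!r} contains no CpG")
        for snp in self.snps:
            if not 0 <= snp.offset < len(self.ref_seq):
                raise ValueError(f"amplicon {self.name!r}: SNP offset {snp.offset} out of bounds")
        self.snps = filter_snps(self.snps, self.targeted_strand)

    def __len__(self) -> int:
        return len(self.ref_seq)

    @property
    def usable_snps(self) -> list[SnpSite]:
        return [s for s in self.snps if s.usable]

    def targeted_ref(self) -> str:
        """Reference in targeted-strand orientation (read-1 direction)."""
        return self.ref_seq if self.targeted_strand == "top" else revcomp(self.ref_seq)

    def targeted_pos(self, top_offset: int) -> int:
        """Map a top-strand offset to targeted-strand orientation."""
        if self.targeted_strand == "top":
            return top_offset
        return len(self.ref_seq) - 1 - top_offset

    def cpg_targeted_positions(self) -> list[int]:
        """Positions of CpG cytosines in targeted-strand orientation.

        On the bottom strand the complementary CpG cytosine sits opposite the
        top-strand G, i.e. at orientation position L-2-offset.
        """
        if self.targeted_strand == "top":
            return list(self.cpg_offsets)
        L = len(self.ref_seq)
        return [L - 2 - o for o in self.cpg_offsets]

    def anchor(self, length: int = ANCHOR_LEN) -> str:
        """Three-letter (C->T collapsed) read-1 prefix used for demultiplexing."""
        return self.targeted_ref()[:length].replace("C", "T")


class AmpliconPanel:
    """Ordered collection of amplicons with name lookup."""

    def __init__(self, amplicons: list[Amplicon]):
        names = [a.name for a in amplicons]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate amplicon names: {sorted(dup)}")
        self.amplicons = list(amplicons)
        self._by_name = {a.name: a for a in amplicons}
        self._warn_anchor_collisions()

    def _warn_anchor_collisions(self) -> None:
        seen: dict[str, str] = {}
        for a in self.amplicons:
            key = a.anchor()
            if key in seen:
                warnings.warn(
                    f"amplicons {seen[key]!r} and {a.name!r} share an identical "
                    f"{ANCHOR_LEN}-base converted anchor; their reads cannot be "
                    "demultiplexed and will be reported unassigned",
                    stacklevel=3,
                )
            else:
                seen[key] = a.name
        self._colliding = len(seen) < len(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons)

    def __getitem__(self, name: str) -> Amplicon:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.amplicons]


PANEL_COLUMNS = ["name", "chrom", "start", "end", "strand", "class",
                 "fwd_primer", "rev_primer"]
SNP_COLUMNS = ["chrom", "start", "end", "amplicon", "alleles", "labels"]


def load_panel(fasta_path, annotation_path, snp_path=None) -> AmpliconPanel:
    """Load and validate a panel from FASTA + TSV annotation (+ optional SNP file).

    FASTA record ids must match the `name` column of the annotation TSV
    one-to-one. CpG offsets are always recomputed from the sequence and SNP
    usability flags are set from the targeted strand. The SNP file is
    BED-like: chrom, start, end, amplicon, alleles "A/G", labels "BL6/CAST",
    with genomic coordinates converted to amplicon offsets.
    """
    seqs = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    missing_cols = set(PANEL_COLUMNS) - set(ann.columns)
    if missing_cols:
        raise ValueError(f"panel annotation missing columns: {sorted(missing_cols)}")

    snps_by_amp: dict[str, list[tuple[int, SnpSite]]] = {}
    if snp_path is not None:
        snp_df = pd.read_csv(snp_path, sep="\t", dtype=str)
        missing_cols = set(SNP_COLUMNS) - set(snp_df.columns)
        if missing_cols:
            raise ValueError(f"SNP file missing columns: {sorted(missing_cols)}")
        for _, row in snp_df.iterrows():
            a1, _, a2 = row["alleles"].partition("/")
            l1, _, l2 = row["labels"].partition("/")
            snps_by_amp.setdefault(row["amplicon"], []).append(
                (int(row["start"]),
                 SnpSite(offset=0, allele_a=a1, allele_b=a2, label_a=l1, label_b=l2)))

    amplicons = []
    for _, row in ann.iterrows():
        name = row["name"]
        if name not in seqs:
            raise ValueError(f"annotation row {name!r} has no FASTA record")
        start, end = int(row["start"]), int(row["end"])
        snps = []
        for gstart, proto in snps_by_amp.get(name, []):
            off = gstart - start
            if not 0 <= off < end - start:
                raise ValueError(f"SNP at {row['chrom']}:{gstart} outside amplicon {name!r}")
            snps.append(replace(proto, offset=off))
        amplicons.append(Amplicon(
            name=name, chrom=row["chrom"], start=start, end=end,
            targeted_strand=row["strand"], ref_seq=seqs[name],
            fwd_primer=row["fwd_primer"], rev_primer=row["rev_primer"],
            region_class=row["class"], snps=snps))

    extra = set(seqs) - {a.name for a in amplicons}
    if extra:
        raise ValueError(f"FASTA records without annotation rows: {sorted(extra)}")
    return AmpliconPanel(amplicons)


def write_panel(panel: AmpliconPanel, fasta_path, annotation_path, snp_path=None) -> None:
    """Write a panel back to FASTA + TSV (+ SNP file); inverse of load_panel."""
    with open(fasta_path, "w") as fh:
        for a in panel:
            fh.write(f">{a.name}\n{a.ref_seq}\n")
    rows = [{"name": a.name, "chrom": a.chrom, "start": a.start, "end": a.end,
             "strand": a.targeted_strand, "class": a.region_class,
             "fwd_primer": a.fwd_primer, "rev_primer": a.rev_primer}
            for a in panel]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(annotation_path, sep="\t", index=False)
    if snp_path is not None:
        srows = []
        for a in panel:
            for s in a.snps:
                srows.append({"chrom": a.chrom, "start": a.start + s.offset,
                              "end": a.start + s.offset + 1, "amplicon": a.name,
                              "alleles": f"{s.allele_a}/{s.allele_b}",
                              "labels": f"{s.label_a}/{s.label_b}"})
        pd.DataFrame(srows, columns=SNP_COLUMNS).to_csv(snp_path, sep="\t", index=False)
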