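"""Parental-allele assignment of reads via strain SNPs.

Each usable SNP covered by a read votes for the strain whose allele matches
the observed base under conversion-aware comparison (an allele that is a
cytosine on the sequenced strand may legitimately be read as T). A read is
assigned only when every informative vote agrees; conflicting votes leave
the read unassigned with the conflict flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AlignedRead
from .panel import Amplicon, observed_alleles

UNASSIGNED = "unassigned"


@dataclass
class AlleleAssignment:
    read_id: str
    label: str          # strain label or UNASSIGNED
    n_informative: int
    conflict: bool = False


def genotype_read(read: AlignedRead, amplicon: Amplicon) -> AlleleAssignment:
    """Assign a read to a strain by unanimous SNP votes.

    A single informative SNP suffices. Observed bases matching neither
    allele (sequencing errors) are ignored; bases compatible with both
    alleles cannot occur at usable SNPs since their post-conversion
    observation sets are disjoint.
    """
    votes = []
    for snp in amplicon.usable_snps:
        base = read.snp_obs.get(snp.offset)
        if base is None:
            continue
        hits = [label for allele, label in
                ((snp.allele_a, snp.label_a), (snp.allele_b, snp.label_b))
                if base in observed_alleles(allele, amplicon.targeted_strand)]
        if len(hits) == 1:
            votes.append(hits[0])
    if not votes:
        return AlleleAssignment(read.read_id, UNASSIGNED, 0)
    if len(set(votes)) > 1:
        return AlleleAssignment(read.read_id, UNASSIGNED, len(votes), conflict=True)
    return AlleleAssignment(read.read_id, votes[0], len(votes))


def split_counts(assignments: list[AlleleAssignment],
                 label_a: str, label_b: str) -> dict[str, float]:
    """Percentages of reads per strain label and unassigned (sum to 100)."""
    if not assignments:
        raise ValueError("no assignments to summarize")
    n = len(assignments)
    na = sum(a.label == label_a for a in assignments)
    nb = sum(a.label == label_b for a in assignments)
    return {label_a: 100.0 * na / n,
            label_b: 100.0 * nb / n,
            UNASSIGNED: 100.0 * (n - na - nb) / n}


def genotype_reads(reads: list[AlignedRead],
                   panel) -> dict[str, AlleleAssignment]:
    """Genotype a batch of reads; keyed by read id."""
    out = {}
    for r in reads:
        out[r.read_id] = genotype_read(r, panel[r.amplicon])
    return out


def write_split_report(reads: list[AlignedRead], assignments: dict[str, "AlleleAssignment"],
                       panel, path) -> None:
    with open(path, "w") as fh:
        fh.write("amplicon\tlabel_a\tlabel_b\tpct_a\tpct_b\tpct_unassigned\tn_reads\n")
        for amp in panel:
            sub = [assignments[r.read_id] for r in reads if r.amplicon == amp.name]
            if not sub:
                continue
            if amp.usable_snps:
                la, lb = amp.usable_snps[0].label_a, amp.usable_snps[0].label_b
            else:
                la, lb = "a", "b"
            pct = split_counts(sub, la, lb)
            fh.write(f"{amp.name}\t{la}\t{lb}\t{pct[la]:.2f}\t{pct[lb]:.2f}\t"
                     f"{pct[UNASSIGNED]:.2f}\t{len(sub)}\n")
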