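"""Ground-truthed read simulation for amplicon bisulfite sequencing.

The simulator emulates the library at molecule resolution: each template
molecule has a parental origin (maternal/paternal), a strain label that fixes
its SNP alleles, and a per-CpG methylation bit vector drawn from the allele's
methylation probabilities. Bisulfite chemistry is applied per cytosine
(conversion of unmethylated Cs with a tunable failure rate, inappropriate
conversion of methylated Cs), the molecule is PCR-amplified with all copies
sharing one 8-bp UMI, and paired 250-bp reads with substitution errors are
emitted. A truth table records every molecule so the pipeline's output can be
checked against what was actually simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fastqio import FastqRecord, ReadPair
from .panel import Amplicon, AmpliconPanel, SnpSite, revcomp, find_cpg_sites

_BASES = np.array(list("ACGT"))


@dataclass
class ChemistryParams:
    """Bisulfite chemistry, sequencing and PCR parameters.

    conversion_rate: probability an unmethylated C reads as T.
    inappropriate_conversion: probability a methylated C reads as T.
    seq_error_rate: per-base substitution probability, per sequenced copy.
    mean_pcr_copies: mean reads per molecule; copies ~ 1 + Poisson(mean-1).
    maternal_amp_bias: multiplies the PCR copy mean for maternal molecules
        (models allele-specific amplification bias; 1.0 = unbiased).
    low_quality_tail: if >0, the last N bases of every read are replaced with
        random bases at Q2, to exercise quality trimming.
    """

    conversion_rate: float = 0.995
    inappropriate_conversion: float = 0.005
    seq_error_rate: float = 0.001
    read_len: int = 250
    umi_len: int = 8
    mean_pcr_copies: float = 1.2
    maternal_amp_bias: float = 1.0
    low_quality_tail: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "inappropriate_conversion", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.umi_len != 8:
            raise ValueError("UMI length is fixed at 8")
        if self.mean_pcr_copies < 1:
            raise ValueError("mean_pcr_copies must be >= 1")


@dataclass
class AlleleSpec:
    """Per-amplicon parental-allele composition of the simulated sample.

    Methylation probabilities may be scalars (applied to every CpG) or
    per-CpG sequences. maternal_fraction is the proportion of template
    molecules of maternal origin; a deleted allele must have fraction 0.
    """

    maternal_meth_p: float | list[float] = 1.0
    paternal_meth_p: float | list[float] = 0.0
    maternal_label: str = "BL6"
    paternal_label: str = "CAST"
    maternal_fraction: float = 0.5
    allele_deleted: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maternal_fraction <= 1.0:
            raise ValueError("maternal_fraction must be in [0,1]")
        if self.allele_deleted not in ("none", "maternal", "paternal"):
            raise ValueError(f"bad allele_deleted {self.allele_deleted!r}")
        if self.allele_deleted == "maternal" and self.maternal_fraction != 0.0:
            raise ValueError("maternal allele deleted but maternal_fraction != 0")
        if self.allele_deleted == "paternal" and self.maternal_fraction != 1.0:
            raise ValueError("paternal allele deleted but paternal fraction != 0")

    def meth_p(self, parent: str, n_cpgs: int) -> np.ndarray:
        p = self.maternal_meth_p if parent == "maternal" else self.paternal_meth_p
        arr = np.broadcast_to(np.asarray(p, dtype=float), (n_cpgs,))
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("methylation probabilities must be in [0,1]")
        return arr

    def label(self, parent: str) -> str:
        return self.maternal_label if parent == "maternal" else self.paternal_label


@dataclass
class Molecule:
    """One simulated template molecule (pre-PCR)."""

    molecule_id: str
    amplicon: str
    parent: str
    strain: str
    meth_vector: tuple[int, ...]
    umi: str | None = None
    copies: int = 1


def draw_molecules(amplicon: Amplicon, spec: AlleleSpec, n: int,
                   rng: np.random.Generator) -> list[Molecule]:
    """Draw n template molecules for one amplicon.

    Parental origin is Bernoulli(maternal_fraction); each CpG's methylation
    bit is drawn independently from that parent's probability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ncpg = len(amplicon.cpg_offsets)
    mols = []
    for i in range(n):
        parent = "maternal" if rng.random() < spec.maternal_fraction else "paternal"
        bits = (rng.random(ncpg) < spec.meth_p(parent, ncpg)).astype(int)
        mols.append(Molecule(
            molecule_id=f"{amplicon.name}:{i}", amplicon=amplicon.name,
            parent=parent, strain=spec.label(parent),
            meth_vector=tuple(int(b) for b in bits)))
    return mols


def random_umi(rng: np.random.Generator, length: int = 8) -> str:
    return "".join(rng.choice(_BASES, size=length))


def pcr_amplify(molecules: list[Molecule], mean_pcr_copies: float,
                rng: np.random.Generator, maternal_amp_bias: float = 1.0) -> list[Molecule]:
    """Assign each molecule a UMI and a PCR copy count.

    Copy counts follow 1 + Poisson(mean - 1): every molecule is sequenced at
    least once and the distribution has a single mean parameter. All copies
    of a molecule share its UMI. Returns the same molecules, mutated.
    """
    if mean_pcr_copies < 1:
        raise ValueError("mean_pcr_copies must be >= 1")
    for mol in molecules:
        mean = mean_pcr_copies
        if mol.parent == "maternal":
            mean = max(1.0, mean * maternal_amp_bias)
        mol.umi = random_umi(rng)
        mol.copies = 1 + int(rng.poisson(mean - 1.0))
    return molecules


def _template_with_snps(amplicon: Amplicon, strain: str) -> str:
    seq = list(amplicon.ref_seq)
    for snp in amplicon.snps:
        allele = snp.allele_for(strain)
        if allele is not None:
            seq[snp.offset] = allele
    return "".join(seq)


def _converted_template(molecule: Molecule, amplicon: Amplicon,
                        chem: ChemistryParams, rng: np.random.Generator) -> str:
    """Bisulfite-converted targeted-strand sequence for one molecule."""
    top = _template_with_snps(amplicon, molecule.strain)
    tseq = top if amplicon.targeted_strand == "top" else revcomp(top)
    meth_at = dict(zip(amplicon.cpg_targeted_positions(), molecule.meth_vector))
    out = []
    L = len(tseq)
    for i, b in enumerate(tseq):
        if b != "C":
            out.append(b)
            continue
        # a SNP can disrupt a panel CpG; such a C converts as non-CpG
        is_cpg = i in meth_at and i + 1 < L and tseq[i + 1] == "G"
        if is_cpg and meth_at[i]:
            reads_c = rng.random() >= chem.inappropriate_conversion
        elif is_cpg:
            reads_c = rng.random() >= chem.conversion_rate
        else:
            reads_c = rng.random() >= chem.conversion_rate
        out.append("C" if reads_c else "T")
    return "".join(out)


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def synthesize_read_pair(molecule: Molecule, amplicon: Amplicon,
                         chem: ChemistryParams, umi: str,
                         rng: np.random.Generator,
                         read_id: str | None = None) -> ReadPair:
    """Emit one paired read from a molecule.

    Read 1 starts at the forward-primer end of the targeted strand; read 2 is
    the mate from the reverse end and begins with the 8-base UMI. Conversion
    is applied before error injection; base qualities are constant Q37.
    """
    if len(umi) != chem.umi_len:
        raise ValueError(f"UMI must be {chem.umi_len} bases")
    if chem.read_len <= chem.umi_len:
        raise ValueError("read_len must exceed the UMI length")
    conv = _converted_template(molecule, amplicon, chem, rng)
    r1 = conv[:chem.read_len]
    r2 = umi + revcomp(conv)[:chem.read_len - chem.umi_len]
    r1 = _inject_errors(r1, chem.seq_error_rate, rng)
    r2 = _inject_errors(r2, chem.seq_error_rate, rng)
    q1, q2 = "F" * len(r1), "F" * len(r2)
    if chem.low_quality_tail > 0:
        k = chem.low_quality_tail
        r1 = r1[:-k] + "".join(rng.choice(_BASES, size=min(k, len(r1))))
        r2 = r2[:-k] + "".join(rng.choice(_BASES, size=min(k, len(r2))))
        q1 = q1[:-k] + "#" * min(k, len(q1))
        q2 = q2[:-k] + "#" * min(k, len(q2))
    rid = read_id or f"SIM:{molecule.molecule_id}:0"
    return ReadPair(FastqRecord(rid, r1, q1), FastqRecord(rid, r2, q2))


def simulate_sample(panel: AmpliconPanel | list[Amplicon],
                    specs: dict[str, AlleleSpec] | AlleleSpec,
                    n_molecules: int | dict[str, int],
                    chem: ChemistryParams | None = None,
                    seed: int = 0) -> tuple[list[ReadPair], list[Molecule]]:
    """Simulate a full sample: molecules -> PCR copies -> read pairs.

    Returns the read pairs (in molecule order) and the truth molecule list.
    Byte-identical output for identical seed and configuration.
    """
    chem = chem or ChemistryParams()
    rng = np.random.default_rng(seed)
    amplicons = list(panel)
    if isinstance(specs, AlleleSpec):
        specs = {a.name: specs for a in amplicons}
    molecules: list[Molecule] = []
    for amp in amplicons:
        n = n_molecules[amp.name] if isinstance(n_molecules, dict) else n_molecules
        molecules.extend(draw_molecules(amp, specs[amp.name], n, rng))
    pcr_amplify(molecules, chem.mean_pcr_copies, rng, chem.maternal_amp_bias)
    by_name = {a.name: a for a in amplicons}
    pairs = []
    for mol in molecules:
        amp = by_name[mol.amplicon]
        for copy in range(mol.copies):
            rid = f"SIM:{mol.molecule_id}:{copy}"
            pairs.append(synthesize_read_pair(mol, amp, chem, mol.umi, rng, read_id=rid))
    return pairs, molecules


TRUTH_COLUMNS = ["molecule_id", "amplicon", "parent", "strain",
                 "meth_vector", "umi", "copies"]


def write_truth(molecules: list[Molecule], path) -> None:
    """Write the molecule truth table as TSV (one row per molecule)."""
    ids = [m.molecule_id for m in molecules]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate molecule ids in truth table")
    rows = [{"molecule_id": m.molecule_id, "amplicon": m.amplicon,
             "parent": m.parent, "strain": m.strain,
             "meth_vector": "".join(str(b) for b in m.meth_vector),
             "umi": m.umi or "", "copies": m.copies} for m in molecules]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"meth_vector": str})


# ---------------------------------------------------------------------------
# Synthetic panel construction (fixtures are generated, never shipped)

def random_cpg_free_seq(length: int, rng: np.random.Generator) -> str:
    """Random DNA of the given length containing no CpG dinucleotide."""
    out: list[str] = []
    for _ in range(length):
        if out and out[-1] == "C":
            out.append("ACT"[rng.integers(3)])
        else:
            out.append("ACGT"[rng.integers(4)])
    return "".join(out)


def synthetic_amplicon(name: str, *, n_cpgs: int = 12, length: int = 300,
                       rng: np.random.Generator | int = 0,
                       targeted_strand: str = "top",
                       region_class: str = "imprinted_icr",
                       snp_labels: tuple[str, str] | None = None,
                       chrom: str = "chrS", start: int = 10_000,
                       primer_len: int = 20) -> Amplicon:
    """Build a random amplicon with an exact CpG count and CpG-free primers.

    The sequence is a CpG-free backbone with `n_cpgs` CG dinucleotides
    inserted at interior positions (never inside the primer-binding ends).
    If snp_labels is given, one usable A/C SNP is placed mid-amplicon with
    the reference 'A' as the first strain's allele.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    backbone_len = length - 2 * n_cpgs
    if backbone_len < 2 * primer_len + n_cpgs:
        raise ValueError("amplicon too short for requested CpG count")
    backbone = random_cpg_free_seq(backbone_len, rng)
    lo, hi = primer_len, backbone_len - primer_len - 1
    points = sorted(rng.choice(np.arange(lo, hi), size=n_cpgs, replace=False))
    seq, prev = [], 0
    for p in points:
        seq.append(backbone[prev:p])
        seq.append("CG")
        prev = p
    seq.append(backbone[prev:])
    ref = "".join(seq)
    assert len(find_cpg_sites(ref)) == n_cpgs

    snps = []
    if snp_labels is not None:
        for pos in range(primer_len + 5, len(ref) - primer_len - 5):
            if ref[pos] == "A" and ref[pos + 1] != "G":
                snps.append(SnpSite(offset=pos, allele_a="A", allele_b="C",
                                    label_a=snp_labels[0], label_b=snp_labels[1]))
                break
        else:
            raise ValueError("no SNP-compatible position found; try another seed")

    return Amplicon(
        name=name, chrom=chrom, start=start, end=start + len(ref),
        targeted_strand=targeted_strand, ref_seq=ref,
        fwd_primer=ref[:primer_len], rev_primer=revcomp(ref[-primer_len:]),
        region_class=region_class, snps=snps)


def synthetic_panel(seed: int = 0, *, n_cpgs: int = 12, length: int = 300,
                    snp_labels: tuple[str, str] | None = ("BL6", "CAST")) -> AmpliconPanel:
    """A three-amplicon demonstration panel: ICR + both conversion controls."""
    rng = np.random.default_rng(seed)
    return AmpliconPanel([
        synthetic_amplicon("icr1", n_cpgs=n_cpgs, length=length, rng=rng,
                           region_class="imprinted_icr", snp_labels=snp_labels,
                           chrom="chr1", start=10_000),
        synthetic_amplicon("ctrl_unmeth", n_cpgs=n_cpgs, length=length, rng=rng,
                           region_class="control_unmethylated",
                           chrom="chr2", start=20_000),
        synthetic_amplicon("ctrl_meth", n_cpgs=n_cpgs, length=length, rng=rng,
                           region_class="control_methylated",
                           chrom="chr3", start=30_000),
    ])
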