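"""Amplicon assignment and bisulfite-space calling against simulator truth."""

import pytest

from amplimeth.align import (METH, UNKNOWN, UNMETH, align_pairs,
                             assign_amplicon, call_cpgs, observe_snps)
from amplimeth.fastqio import FastqRecord, ReadPair
from amplimeth.panel import Amplicon, AmpliconPanel
from amplimeth.preprocess import extract_umi, preprocess_pairs
from amplimeth.simulate import (AlleleSpec, ChemistryParams, Molecule,
                                simulate_sample, synthesize_read_pair,
                                synthetic_amplicon)
from conftest import molecule_id_of


def tag(pair):
    return extract_umi(pair)


class TestAssignAmplicon:
    def test_error_free_reads_recover_true_amplicon(self, panel, perfect_chem):
        pairs, mols = simulate_sample(panel, AlleleSpec(), 30, perfect_chem, seed=3)
        truth = {m.molecule_id: m.amplicon for m in mols}
        for pair in pairs:
            t = tag(pair)
            expected = truth[molecule_id_of(t.read1.id)]
            assert assign_amplicon(t, panel) == expected

    def test_random_sequence_unassigned(self, panel, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100))
        pair = tag(ReadPair(FastqRecord("r", seq, "F" * 100),
                            FastqRecord("r", "ACGTACGT" + seq, "F" * 108)))
        assert assign_amplicon(pair, panel) is None

    def test_identical_anchors_tie_to_unassigned(self, perfect_chem, rng):
        a = synthetic_amplicon("a", rng=5)
        with pytest.warns(UserWarning):
            twin = AmpliconPanel([a, Amplicon(
                name="b", chrom=a.chrom, start=a.start, end=a.end,
                targeted_strand=a.targeted_strand, ref_seq=a.ref_seq,
                fwd_primer=a.fwd_primer, rev_primer=a.rev_primer)])
        mol = Molecule("a:0", "a", "maternal", "BL6", (1,) * len(a.cpg_offsets))
        pair = tag(synthesize_read_pair(mol, a, perfect_chem, "ACGTACGT", rng))
        assert assign_amplicon(pair, twin) is None


class TestCallCpgs:
    def _perfect_pair(self, amp, bits, chem, rng):
        mol = Molecule(f"{amp.name}:0", amp.name, "maternal", "BL6", bits)
        return tag(synthesize_read_pair(mol, amp, chem, "ACGTACGT", rng))

    def test_unmethylated_read_calls_all_unmethylated(self, icr, perfect_chem, rng):
        n = len(icr.cpg_offsets)
        pair = self._perfect_pair(icr, (0,) * n, perfect_chem, rng)
        read = call_cpgs(pair, icr)
        assert read.cpg_calls == [UNMETH] * n

    def test_methylated_read_calls_all_methylated_no_unconverted(self, icr, perfect_chem, rng):
        n = len(icr.cpg_offsets)
        pair = self._perfect_pair(icr, (1,) * n, perfect_chem, rng)
        read = call_cpgs(pair, icr)
        assert read.cpg_calls == [METH] * n
        assert read.unconverted_noncpg == 0
        assert not read.conversion_suspect

    def test_non_ct_base_at_cpg_is_unknown(self, icr, perfect_chem, rng):
        n = len(icr.cpg_offsets)
        pair = self._perfect_pair(icr, (1,) * n, perfect_chem, rng)
        pos = icr.cpg_targeted_positions()[0]
        r1 = pair.read1
        seq = r1.seq[:pos] + "A" + r1.seq[pos + 1:]
        pair.read1 = FastqRecord(r1.id, seq, r1.qual)
        read = call_cpgs(pair, icr)
        assert read.cpg_calls[0] == UNKNOWN
        assert read.cpg_calls[1:] == [METH] * (n - 1)

    def test_conversion_failures_counted_and_flagged(self, icr, rng):
        chem = ChemistryParams(conversion_rate=0.0, inappropriate_conversion=0.0,
                               seq_error_rate=0.0)  # nothing converts
        n = len(icr.cpg_offsets)
        pair = self._perfect_pair(icr, (1,) * n, chem, rng)
        read = call_cpgs(pair, icr)
        assert read.unconverted_noncpg > 0
        assert read.converted_noncpg == 0
        assert read.conversion_suspect

    def test_calls_match_truth_exactly_at_zero_error(self, perfect_run, panel):
        _, molecules, result = perfect_run
        truth = {m.molecule_id: m.meth_vector for m in molecules}
        code = {1: METH, 0: UNMETH}
        assert result.unassigned == 0
        for read in result.unique_reads:
            bits = truth[molecule_id_of(read.read_id)]
            assert read.cpg_calls == [code[b] for b in bits]


class TestStrandSymmetry:
    def test_bottom_strand_amplicon_yields_identical_call_counts(self, perfect_chem):
        top = synthetic_amplicon("amp", rng=9, targeted_strand="top")
        bottom = Amplicon(name="amp", chrom=top.chrom, start=top.start,
                          end=top.end, targeted_strand="bottom",
                          ref_seq=top.ref_seq, fwd_primer=top.rev_primer,
                          rev_primer=top.fwd_primer)
        assert bottom.cpg_offsets == top.cpg_offsets
        spec = AlleleSpec(maternal_meth_p=0.7, paternal_meth_p=0.1)
        results = {}
        for amp in (top, bottom):
            pairs, mols = simulate_sample([amp], spec, 80, perfect_chem, seed=21)
            tagged, _ = preprocess_pairs(pairs)
            reads = [call_cpgs(t, amp) for t in tagged]
            truth = {m.molecule_id: m.meth_vector for m in mols}
            code = {1: METH, 0: UNMETH}
            for r in reads:
                assert r.cpg_calls == [code[b] for b in truth[molecule_id_of(r.read_id)]]
            results[amp.targeted_strand] = [r.cpg_calls for r in reads]
        assert results["top"] == results["bottom"]


class TestObserveSnps:
    def test_alt_strain_base_recorded(self, icr, perfect_chem, rng):
        snp = icr.usable_snps[0]
        mol = Molecule("icr1:0", "icr1", "paternal", snp.label_a,
                       (1,) * len(icr.cpg_offsets))
        pair = tag(synthesize_read_pair(mol, icr, perfect_chem, "ACGTACGT", rng))
        read = observe_snps(call_cpgs(pair, icr), icr)
        assert read.snp_obs[snp.offset] == snp.allele_a

    def test_snp_outside_coverage_missing(self, icr, perfect_chem, rng):
        snp = icr.usable_snps[0]
        chem = ChemistryParams(conversion_rate=1.0, inappropriate_conversion=0.0,
                               seq_error_rate=0.0, read_len=30)
        mol = Molecule("icr1:0", "icr1", "paternal", snp.label_a,
                       (1,) * len(icr.cpg_offsets))
        pair = tag(synthesize_read_pair(mol, icr, chem, "ACGTACGT", rng))
        read = observe_snps(call_cpgs(pair, icr), icr)
        # read1 covers 30 bases, read2 covers 22 from the far end; the SNP
        # at offset 29 is covered by read1 here, so shrink further via slicing
        if snp.offset < 30:
            pair.read1 = FastqRecord(pair.read1.id, pair.read1.seq[:snp.offset],
                                     pair.read1.qual[:snp.offset])
            read = observe_snps(call_cpgs(pair, icr), icr)
        assert snp.offset not in read.snp_obs

    def test_error_base_recorded_as_is(self, icr, perfect_chem, rng):
        snp = icr.usable_snps[0]
        mol = Molecule("icr1:0", "icr1", "paternal", snp.label_a,
                       (1,) * len(icr.cpg_offsets))
        pair = tag(synthesize_read_pair(mol, icr, perfect_chem, "ACGTACGT", rng))
        r1 = pair.read1
        seq = r1.seq[:snp.offset] + "G" + r1.seq[snp.offset + 1:]
        pair.read1 = FastqRecord(r1.id, seq, r1.qual)
        read = observe_snps(call_cpgs(pair, icr), icr)
        assert read.snp_obs[snp.offset] == "G"


def test_align_pairs_accounts_for_unassigned(panel, perfect_chem, rng):
    pairs, _ = simulate_sample(panel, AlleleSpec(), 10, perfect_chem, seed=4)
    junk = "".join(rng.choice(list("ACGT"), size=120))
    pairs.append(ReadPair(FastqRecord("junk", junk, "F" * 120),
                          FastqRecord("junk", "ACGTACGT" + junk, "F" * 128)))
    tagged, _ = preprocess_pairs(pairs)
    aligned, unassigned = align_pairs(tagged, panel)
    assert unassigned == 1
    assert len(aligned) == len(pairs) - 1
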