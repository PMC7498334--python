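"""Methylation tables, epiallele classification, region status and QC."""

import math

import pytest
from scipy.stats import binom

from amplimeth.align import METH, UNKNOWN, UNMETH, AlignedRead
from amplimeth.panel import AmpliconPanel
from amplimeth.pipeline import run_pipeline
from amplimeth.quantify import (CONTROL_FAIL, CONTROL_PASS, HYPER, HYPO,
                                INTERMEDIATE, LOW_COVERAGE, METHYLATED,
                                NORMAL_IMPRINT, NOT_EVALUATED, UNCALLABLE,
                                UNMETHYLATED, ConfigThresholds, RegionReport,
                                apply_coverage_filter, build_table,
                                call_region_status, classify_read,
                                conversion_efficiency)
from amplimeth.simulate import (AlleleSpec, ChemistryParams, simulate_sample,
                                synthetic_amplicon)


def read_with_calls(calls, rid="r:AAAAAAAA", amplicon="amp",
                    conv=0, unconv=0):
    return AlignedRead(read_id=rid, umi="AAAAAAAA", amplicon=amplicon, start=0,
                       cpg_calls=list(calls), converted_noncpg=conv,
                       unconverted_noncpg=unconv)


@pytest.fixture
def tiny_panel():
    return AmpliconPanel([synthetic_amplicon("amp", n_cpgs=5, length=150,
                                             rng=1, region_class="imprinted_icr")])


class TestBuildTable:
    def test_counts_aggregate_to_percentage(self, tiny_panel):
        reads = [read_with_calls([METH] + [UNKNOWN] * 4, rid=f"m{i}:AAAAAAAA")
                 for i in range(7)]
        reads += [read_with_calls([UNMETH] + [UNKNOWN] * 4, rid=f"u{i}:AAAAAAAA")
                  for i in range(3)]
        table = build_table(reads, tiny_panel)
        off = tiny_panel["amp"].cpg_offsets[0]
        assert table.cpg_pct("amp", off) == pytest.approx(70.0)

    def test_unknown_only_cpg_reported_missing(self, tiny_panel):
        reads = [read_with_calls([UNKNOWN] * 5)]
        table = build_table(reads, tiny_panel)
        assert table.df.methylation_pct.isna().all()
        assert math.isnan(table.region_mean("amp"))

    def test_zero_error_even_split_gives_exact_50(self, tiny_panel):
        amp = tiny_panel["amp"]
        spec = AlleleSpec(maternal_meth_p=1.0, paternal_meth_p=0.0)
        chem = ChemistryParams(conversion_rate=1.0, inappropriate_conversion=0.0,
                               seq_error_rate=0.0, mean_pcr_copies=1.0)
        pairs, mols = simulate_sample([amp], spec, 300, chem, seed=41)
        result = run_pipeline(pairs, tiny_panel)
        n_mat = sum(m.parent == "maternal" for m in mols)
        expected = 100.0 * n_mat / len(mols)
        # truth cross-check: every CpG's pct equals the realized maternal share
        for off in amp.cpg_offsets:
            assert result.table.cpg_pct("amp", off) == pytest.approx(expected)


class TestClassifyRead:
    t = ConfigThresholds()

    @pytest.mark.parametrize("n_meth,n_total,expected", [
        (10, 10, METHYLATED),
        (0, 10, UNMETHYLATED),
        (9, 10, INTERMEDIATE),   # exactly 90.0%: strictly-above rule
        (1, 10, INTERMEDIATE),   # exactly 10.0%: strictly-below rule
        (19, 20, METHYLATED),    # 95% > 90
    ])
    def test_threshold_boundaries(self, n_meth, n_total, expected):
        calls = [METH] * n_meth + [UNMETH] * (n_total - n_meth)
        assert classify_read(read_with_calls(calls), self.t) == expected

    def test_too_few_called_cpgs_uncallable(self):
        calls = [METH, METH] + [UNKNOWN] * 8
        assert classify_read(read_with_calls(calls), self.t) == UNCALLABLE


class TestCoverageFilter:
    def _report(self, n):
        return RegionReport(amplicon="amp", region_class="imprinted_icr",
                            n_reads=n, mean_pct=50.0)

    @pytest.mark.parametrize("n,low", [(100, True), (101, False), (0, True)])
    def test_strictly_greater_than_100(self, n, low):
        rep = apply_coverage_filter(self._report(n), ConfigThresholds())
        assert (rep.status == LOW_COVERAGE) is low


class TestRegionStatus:
    def _report(self, mean, cls="imprinted_icr"):
        return RegionReport(amplicon="amp", region_class=cls, n_reads=500,
                            mean_pct=mean)

    @pytest.mark.parametrize("mean,cls,expected", [
        (50.0, "imprinted_icr", NORMAL_IMPRINT),
        (0.0, "imprinted_icr", HYPO),
        (39.9, "imprinted_icr", HYPO),
        (60.1, "imprinted_icr", HYPER),
        (95.0, "control_methylated", CONTROL_PASS),
        (85.0, "control_methylated", CONTROL_FAIL),
        (5.0, "control_unmethylated", CONTROL_PASS),
        (15.0, "control_unmethylated", CONTROL_FAIL),
        (42.0, "other", NOT_EVALUATED),
    ])
    def test_status_calls(self, mean, cls, expected):
        assert call_region_status(self._report(mean, cls)) == expected

    def test_unknown_class_is_error(self):
        with pytest.raises(ValueError):
            call_region_status(self._report(50.0, "no_such_class"))


class TestConversionEfficiency:
    def test_perfect_conversion_reads_100(self):
        reads = [read_with_calls([METH] * 3, conv=10, unconv=0)]
        assert conversion_efficiency(reads)["global"] == 100.0

    def test_no_noncpg_coverage_missing(self):
        reads = [read_with_calls([METH] * 3, conv=0, unconv=0)]
        eff = conversion_efficiency(reads)
        assert eff["amp"] is None and eff["global"] is None

    def test_rate_recovered_within_binomial_ci(self, tiny_panel):
        chem = ChemistryParams(conversion_rate=0.99, inappropriate_conversion=0.0,
                               seq_error_rate=0.0, mean_pcr_copies=1.0)
        pairs, _ = simulate_sample(tiny_panel, AlleleSpec(), 300, chem, seed=43)
        result = run_pipeline(pairs, tiny_panel)
        eff = conversion_efficiency(result.unique_reads)["global"]
        n = sum(r.converted_noncpg + r.unconverted_noncpg
                for r in result.unique_reads)
        lo, hi = binom.interval(0.999, n, 0.99)
        assert 100.0 * lo / n <= eff <= 100.0 * hi / n


class TestParameterRecovery:
    def test_recovered_pct_tracks_realized_truth(self, tiny_panel):
        # per-CpG truth probability p: the pipeline's recovered percentage
        # must sit inside the exact 99% binomial interval around the
        # chemistry-adjusted expectation given the realized truth bits
        p = 0.3
        spec = AlleleSpec(maternal_meth_p=p, paternal_meth_p=p)
        chem = ChemistryParams(conversion_rate=0.995,
                               inappropriate_conversion=0.005,
                               seq_error_rate=0.0, mean_pcr_copies=1.0)
        pairs, mols = simulate_sample(tiny_panel, spec, 1000, chem, seed=47)
        result = run_pipeline(pairs, tiny_panel)
        bits = [b for m in mols for b in m.meth_vector]
        f = sum(bits) / len(bits)
        expect = f * (1 - chem.inappropriate_conversion) + \
            (1 - f) * (1 - chem.conversion_rate)
        sub = result.table.df
        n_calls = int(sub.meth.sum() + sub.unmeth.sum())
        lo, hi = binom.interval(0.99, n_calls, expect)
        recovered = 100.0 * sub.meth.sum() / n_calls
        assert 100.0 * lo / n_calls <= recovered <= 100.0 * hi / n_calls

    def test_imprint_mix_region_mean_and_classes(self, panel):
        # 12 CpGs per read: an 11/12 read still clears the 90% bound, so the
        # intermediate class stays near zero for homogeneous epialleles
        spec = AlleleSpec(maternal_meth_p=0.98, paternal_meth_p=0.02)
        pairs, _ = simulate_sample([panel["icr1"]], {"icr1": spec}, 1000,
                                   ChemistryParams(seq_error_rate=0.0), seed=53)
        result = run_pipeline(pairs, panel)
        rep = result.reports[0]
        assert 45.0 <= rep.mean_pct <= 55.0
        fr = rep.read_class_fractions
        assert 0.4 <= fr[METHYLATED] <= 0.6
        assert 0.4 <= fr[UNMETHYLATED] <= 0.6
        assert fr[INTERMEDIATE] < 0.1
        assert sum(fr.values()) == pytest.approx(1.0)
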