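"""End-to-end orchestration: FASTQ pair -> reports.

Single entry point used by both the command line and programmatic callers
(including the simulation round-trip tests): UMI extraction, trimming,
amplicon assignment, CpG/SNP calling, deduplication, allele splitting and
quantification, with complete read accounting at every stage.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import align, allelesplit, dedup, preprocess, quantify
from .fastqio import ReadPair, read_fastq_pairs
from .panel import AmpliconPanel
from .quantify import ConfigThresholds, MethylationTable, RegionReport


@dataclass
class PipelineResult:
    stats: preprocess.PreprocessStats
    unassigned: int
    dup_stats: dedup.DuplicationStats
    unique_reads: list
    assignments: dict
    table: MethylationTable
    allele_table: MethylationTable | None
    reports: list[RegionReport]
    meth_shift: dict[str, float] = field(default_factory=dict)

    def accounting(self) -> dict[str, int]:
        """Every input pair lands in exactly one of these buckets."""
        duplicates = self.dup_stats.total - self.dup_stats.unique
        return {
            "input_pairs": self.stats.input_pairs,
            "rejected_umi": self.stats.rejected_umi,
            "discarded_trim": self.stats.discarded_trim,
            "unassigned": self.unassigned,
            "duplicate": duplicates,
            "unique": self.dup_stats.unique,
        }


def run_pipeline(pairs: list[ReadPair], panel: AmpliconPanel,
                 thresholds: ConfigThresholds | None = None,
                 by_allele: bool = True,
                 collapse_1mm: bool = False,
                 log=None) -> PipelineResult:
    thresholds = thresholds or ConfigThresholds()

    def say(msg):
        if log is not None:
            print(msg, file=log)

    tagged, stats = preprocess.preprocess_pairs(pairs)
    say(f"[preprocess] {stats.input_pairs} pairs in, {stats.output_pairs} kept, "
        f"{stats.rejected_umi} rejected at UMI, {stats.discarded_trim} discarded at trim")

    aligned, unassigned = align.align_pairs(tagged, panel)
    say(f"[align] {len(aligned)} assigned, {unassigned} unassigned")

    unique, dup_stats = dedup.deduplicate(aligned, collapse_1mm=collapse_1mm)
    say(f"[dedup] {dup_stats.unique} unique of {dup_stats.total} "
        f"({dup_stats.duplication_pct:.1f}% duplication)")
    shift = dedup.methylation_shift_check(aligned, unique) if aligned else {}

    assignments = allelesplit.genotype_reads(unique, panel)
    n_assigned = sum(a.label != allelesplit.UNASSIGNED for a in assignments.values())
    say(f"[allelesplit] {n_assigned} of {len(assignments)} reads allele-assigned")

    table = quantify.build_table(unique, panel)
    allele_table = (quantify.build_table(unique, panel, by_allele=True,
                                         assignments=assignments)
                    if by_allele else None)
    reports = quantify.build_region_reports(unique, panel, table, dup_stats, thresholds)
    for rep in reports:
        say(f"[region] {rep.amplicon}: n={rep.n_reads} mean={rep.mean_pct:.2f}% "
            f"status={rep.status}")

    return PipelineResult(stats=stats, unassigned=unassigned, dup_stats=dup_stats,
                          unique_reads=unique, assignments=assignments,
                          table=table, allele_table=allele_table,
                          reports=reports, meth_shift=shift)


def run_pipeline_files(fastq1, fastq2, panel: AmpliconPanel, outdir,
                       thresholds: ConfigThresholds | None = None,
                       by_allele: bool = True, log=sys.stderr) -> PipelineResult:
    """File-level wrapper: read the pair of FASTQs, run, write all reports."""
    pairs = read_fastq_pairs(fastq1, fastq2)
    result = run_pipeline(pairs, panel, thresholds, by_allele=by_allele, log=log)
    write_reports(result, panel, outdir)
    return result


REPORT_FILES = ("trim_report.tsv", "dedup_report.tsv", "allele_split.tsv",
                "cpg_methylation.tsv", "methylation.bedGraph", "region_summary.json")


def write_reports(result: PipelineResult, panel: AmpliconPanel, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    acct = result.accounting()
    with open(outdir / "trim_report.tsv", "w") as fh:
        fh.write("category\tcount\n")
        for k, v in acct.items():
            fh.write(f"{k}\t{v}\n")
    dedup.write_dedup_report(result.dup_stats, outdir / "dedup_report.tsv")
    allelesplit.write_split_report(result.unique_reads, result.assignments,
                                   panel, outdir / "allele_split.tsv")
    quantify.write_cpg_table(result.allele_table or result.table, panel,
                             outdir / "cpg_methylation.tsv")
    quantify.write_bedgraph(result.table, panel, outdir / "methylation.bedGraph")
    quantify.write_region_summary(result.reports, outdir / "region_summary.json",
                                  outdir / "region_summary.tsv")
    for amp in panel:
        quantify.write_read_matrix(result.unique_reads, panel, amp.name,
                                   outdir / f"read_matrix_{amp.name}.tsv")
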