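"""Methylation quantification, read classification and region status calls.

Per-CpG counts are aggregated from deduplicated reads (overall and per
parental allele), each read is classified by its own methylation fraction
(fully methylated / fully unmethylated / intermediate epialleles), and each
region receives a status call: imprinted regions are expected in the 40-60%
band (each parental allele contributing an opposite homogeneous epiallele
population), controls near 0% or 100%, and regions at or below the coverage
threshold are excluded outright.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd

from .align import AlignedRead, METH, UNMETH
from .allelesplit import AlleleAssignment, UNASSIGNED
from .dedup import DuplicationStats
from .panel import AmpliconPanel

OVERALL = "all"


@dataclass
class ConfigThresholds:
    """Filtering and classification thresholds.

    min_region_reads: a region needs strictly more deduplicated reads than
        this to be evaluated (<=100 reads -> low_coverage).
    read_meth_hi / read_meth_lo: per-read % bounds for the fully methylated
        (> hi) and fully unmethylated (< lo) epiallele classes.
    normal_band: region-mean % band considered a maintained imprint.
    min_cpgs_called_per_read: reads calling fewer CpGs are uncallable.
    """

    min_region_reads: int = 100
    read_meth_hi: float = 90.0
    read_meth_lo: float = 10.0
    normal_band: tuple[float, float] = (40.0, 60.0)
    min_cpgs_called_per_read: int = 3

    def __post_init__(self) -> None:
        if not self.read_meth_lo < self.read_meth_hi:
            raise ValueError("read_meth_lo must be below read_meth_hi")
        lo, hi = self.normal_band
        if not (0 <= lo < hi <= 100):
            raise ValueError("normal_band must be an ascending range within [0,100]")


class MethylationTable:
    """Per-CpG methylated/unmethylated counts, overall and per allele.

    Backed by a DataFrame with columns amplicon, offset (top-strand, 0-based
    within the amplicon), allele ('all' or a strain label), meth, unmeth,
    methylation_pct (NaN when a CpG has no called coverage).
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df

    def region_mean(self, amplicon: str, allele: str = OVERALL) -> float:
        """Unweighted mean over per-CpG methylation percentages (NaN-free)."""
        sub = self.df[(self.df.amplicon == amplicon) & (self.df.allele == allele)]
        vals = sub.methylation_pct.dropna()
        return float(vals.mean()) if len(vals) else float("nan")

    def cpg_pct(self, amplicon: str, offset: int, allele: str = OVERALL) -> float:
        sub = self.df[(self.df.amplicon == amplicon) & (self.df.offset == offset)
                      & (self.df.allele == allele)]
        return float(sub.methylation_pct.iloc[0])


def build_table(unique_reads: list[AlignedRead], panel: AmpliconPanel,
                by_allele: bool = False,
                assignments: dict[str, AlleleAssignment] | None = None) -> MethylationTable:
    """Aggregate per-CpG counts from deduplicated reads.

    With by_allele, additional rows are built per strain label using only
    reads with an unambiguous allele assignment (conflicting or unassigned
    reads still contribute to the overall rows).
    """
    if by_allele and assignments is None:
        raise ValueError("by_allele requires allele assignments")
    counts: dict[tuple[str, int, str], list[int]] = {}

    def bump(amp, off, allele, call):
        key = (amp, off, allele)
        mu = counts.setdefault(key, [0, 0])
        if call == METH:
            mu[0] += 1
        elif call == UNMETH:
            mu[1] += 1

    for read in unique_reads:
        amp = panel[read.amplicon]
        alleles = [OVERALL]
        if by_allele:
            a = assignments.get(read.read_id)
            if a is not None and a.label != UNASSIGNED:
                alleles.append(a.label)
        for off, call in zip(amp.cpg_offsets, read.cpg_calls):
            for allele in alleles:
                bump(read.amplicon, off, allele, call)

    # ensure every panel CpG appears even with zero coverage
    for amp in panel:
        for off in amp.cpg_offsets:
            counts.setdefault((amp.name, off, OVERALL), [0, 0])

    rows = []
    for (amp, off, allele), (m, u) in sorted(counts.items()):
        pct = 100.0 * m / (m + u) if m + u else float("nan")
        rows.append({"amplicon": amp, "offset": off, "allele": allele,
                     "meth": m, "unmeth": u, "methylation_pct": pct})
    return MethylationTable(pd.DataFrame(
        rows, columns=["amplicon", "offset", "allele", "meth", "unmeth", "methylation_pct"]))


METHYLATED, UNMETHYLATED, INTERMEDIATE, UNCALLABLE = (
    "methylated", "unmethylated", "intermediate", "uncallable")


def classify_read(read: AlignedRead,
                  thresholds: ConfigThresholds | None = None) -> str:
    """Classify a read's epiallele by its methylation % over called CpGs.

    Strictly above the high threshold -> methylated; strictly below the low
    threshold -> unmethylated; otherwise intermediate. Reads calling fewer
    than min_cpgs_called_per_read CpGs are uncallable.
    """
    t = thresholds or ConfigThresholds()
    called = read.n_called
    if called < t.min_cpgs_called_per_read:
        return UNCALLABLE
    pct = 100.0 * read.n_methylated / called
    if pct > t.read_meth_hi:
        return METHYLATED
    if pct < t.read_meth_lo:
        return UNMETHYLATED
    return INTERMEDIATE


NORMAL_IMPRINT, HYPO, HYPER = "normal_imprint", "hypomethylated", "hypermethylated"
CONTROL_PASS, CONTROL_FAIL, LOW_COVERAGE = "control_pass", "control_fail", "low_coverage"
NOT_EVALUATED = "not_evaluated"


@dataclass
class RegionReport:
    """Per-amplicon summary: coverage, mean methylation, epiallele mix, status."""

    amplicon: str
    region_class: str
    n_reads: int
    mean_pct: float
    read_class_fractions: dict[str, float] = field(default_factory=dict)
    duplication_pct: float = 0.0
    conversion_efficiency_pct: float | None = None
    status: str | None = None


def apply_coverage_filter(report: RegionReport,
                          thresholds: ConfigThresholds | None = None) -> RegionReport:
    """Mark regions at or below the read threshold low_coverage (strictly >100 kept)."""
    t = thresholds or ConfigThresholds()
    if report.n_reads <= t.min_region_reads:
        report.status = LOW_COVERAGE
    return report


def call_region_status(report: RegionReport, region_class: str | None = None,
                       thresholds: ConfigThresholds | None = None) -> str:
    """Status call for a region that passed the coverage filter.

    Imprinted regions: mean within the normal band -> normal_imprint, below
    -> hypomethylated, above -> hypermethylated. Unmethylated controls pass
    below the low read threshold; methylated controls pass above the high
    one. Regions of class 'other' are summarized but not judged.
    """
    t = thresholds or ConfigThresholds()
    cls = region_class or report.region_class
    mean = report.mean_pct
    if cls == "imprinted_icr":
        lo, hi = t.normal_band
        if mean < lo:
            return HYPO
        if mean > hi:
            return HYPER
        return NORMAL_IMPRINT
    if cls == "control_unmethylated":
        return CONTROL_PASS if mean < t.read_meth_lo else CONTROL_FAIL
    if cls == "control_methylated":
        return CONTROL_PASS if mean > t.read_meth_hi else CONTROL_FAIL
    if cls == "other":
        return NOT_EVALUATED
    raise ValueError(f"unknown region class {cls!r}")


def conversion_efficiency(unique_reads: list[AlignedRead]) -> dict[str, float | None]:
    """Percent of non-CpG cytosine observations that were converted.

    Keyed per amplicon plus 'global'; None where an amplicon exposes no
    non-CpG cytosines.
    """
    acc: dict[str, list[int]] = {}
    for r in unique_reads:
        cu = acc.setdefault(r.amplicon, [0, 0])
        cu[0] += r.converted_noncpg
        cu[1] += r.unconverted_noncpg
    out: dict[str, float | None] = {}
    gc = gu = 0
    for amp, (c, u) in acc.items():
        gc, gu = gc + c, gu + u
        out[amp] = 100.0 * c / (c + u) if c + u else None
    out["global"] = 100.0 * gc / (gc + gu) if gc + gu else None
    return out


def build_region_reports(unique_reads: list[AlignedRead], panel: AmpliconPanel,
                         table: MethylationTable,
                         dup_stats: DuplicationStats | None = None,
                         thresholds: ConfigThresholds | None = None) -> list[RegionReport]:
    """Assemble the full per-region summary with classes and status calls."""
    t = thresholds or ConfigThresholds()
    eff = conversion_efficiency(unique_reads)
    reports = []
    for amp in panel:
        sub = [r for r in unique_reads if r.amplicon == amp.name]
        classes = [classify_read(r, t) for r in sub]
        classified = [c for c in classes if c != UNCALLABLE]
        n_cls = len(classified)
        fractions = {k: (classified.count(k) / n_cls if n_cls else 0.0)
                     for k in (METHYLATED, UNMETHYLATED, INTERMEDIATE)}
        rep = RegionReport(
            amplicon=amp.name, region_class=amp.region_class, n_reads=len(sub),
            mean_pct=table.region_mean(amp.name),
            read_class_fractions=fractions,
            duplication_pct=(dup_stats.amplicon_duplication_pct(amp.name)
                             if dup_stats else 0.0),
            conversion_efficiency_pct=eff.get(amp.name))
        apply_coverage_filter(rep, t)
        if rep.status != LOW_COVERAGE:
            rep.status = call_region_status(rep, amp.region_class, t)
        reports.append(rep)
    return reports


# ---------------------------------------------------------------------------
# Writers

def write_cpg_table(table: MethylationTable, panel: AmpliconPanel, path) -> None:
    """Per-CpG TSV with 1-based genomic positions (human-readable report)."""
    df = table.df.copy()
    df["chrom"] = [panel[a].chrom for a in df.amplicon]
    df["pos_1based"] = [panel[a].start + o + 1 for a, o in zip(df.amplicon, df.offset)]
    cols = ["amplicon", "chrom", "pos_1based", "allele", "meth", "unmeth", "methylation_pct"]
    out = df[cols].copy()
    out["methylation_pct"] = out.methylation_pct.round(4)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_bedgraph(table: MethylationTable, panel: AmpliconPanel, path,
                   allele: str = OVERALL) -> None:
    """bedGraph (0-based half-open) of per-CpG methylation % for one allele."""
    sub = table.df[table.df.allele == allele]
    with open(path, "w") as fh:
        for _, row in sub.iterrows():
            if math.isnan(row.methylation_pct):
                continue
            amp = panel[row.amplicon]
            start = amp.start + int(row.offset)
            fh.write(f"{amp.chrom}\t{start}\t{start + 1}\t{row.methylation_pct:.4f}\n")


def write_read_matrix(unique_reads: list[AlignedRead], panel: AmpliconPanel,
                      amplicon: str, path) -> None:
    """Per-read call matrix (rows = reads, columns = CpGs; 1/0/. codes),
    the data behind read-level lollipop plots."""
    amp = panel[amplicon]
    code = {METH: "1", UNMETH: "0"}
    with open(path, "w") as fh:
        header = "\t".join(["read_id"] + [f"cpg_{o}" for o in amp.cpg_offsets])
        fh.write(header + "\n")
        for r in unique_reads:
            if r.amplicon != amplicon:
                continue
            fh.write("\t".join([r.read_id] + [code.get(c, ".") for c in r.cpg_calls]) + "\n")


def write_region_summary(reports: list[RegionReport], path_json, path_tsv=None) -> None:
    payload = []
    for r in reports:
        payload.append({
            "amplicon": r.amplicon, "region_class": r.region_class,
            "n_reads": r.n_reads,
            "mean_pct": None if math.isnan(r.mean_pct) else round(r.mean_pct, 4),
            "read_class_fractions": {k: round(v, 6) for k, v in r.read_class_fractions.items()},
            "duplication_pct": round(r.duplication_pct, 4),
            "conversion_efficiency_pct": (None if r.conversion_efficiency_pct is None
                                          else round(r.conversion_efficiency_pct, 4)),
            "status": r.status})
    with open(path_json, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if path_tsv is not None:
        rows = [{k: v for k, v in item.items() if k != "read_class_fractions"}
                | {f"frac_{k}": v for k, v in item["read_class_fractions"].items()}
                for item in payload]
        pd.DataFrame(rows).to_csv(path_tsv, sep="\t", index=False, na_rep="NA")
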