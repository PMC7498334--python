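"""UMI-aware PCR-duplicate collapsing.

Reads sharing (amplicon, read-1 start, UMI) are PCR copies of one template
molecule; exactly one representative per group is kept. Matching is exact by
default; an optional single-mismatch UMI merge is available for real data
where sequencing errors fracture UMI groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignedRead
from .preprocess import umi_from_read_id


@dataclass
class DuplicationStats:
    total: int
    unique: int
    per_amplicon: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def duplication_pct(self) -> float:
        if self.total == 0:
            return 0.0
        return 100.0 * (1.0 - self.unique / self.total)

    def amplicon_duplication_pct(self, name: str) -> float:
        total, unique = self.per_amplicon.get(name, (0, 0))
        return 0.0 if total == 0 else 100.0 * (1.0 - unique / total)


def _dedup_key(read: AlignedRead) -> tuple[str, int, str]:
    if not read.umi:
        # recover from the ID; raises with the read named if absent
        read.umi = umi_from_read_id(read.read_id)
    return (read.amplicon, read.start, read.umi)


def _merge_umi_groups(keys: list[tuple[str, int, str]]) -> dict[tuple, tuple]:
    """Map each (amplicon, start, umi) key to a canonical key, collapsing
    UMIs within one position that differ by a single mismatch (larger group
    absorbs smaller; ties broken lexicographically)."""
    from collections import Counter

    counts = Counter(keys)
    canon = {}
    by_pos: dict[tuple, list[str]] = {}
    for amp, start, umi in counts:
        by_pos.setdefault((amp, start), []).append(umi)
    for (amp, start), umis in by_pos.items():
        # biggest groups claim neighbours first
        umis.sort(key=lambda u: (-counts[(amp, start, u)], u))
        assigned: dict[str, str] = {}
        for u in umis:
            target = u
            for v in umis:
                if v == u or v not in assigned or assigned[v] != v:
                    continue
                if counts[(amp, start, v)] < counts[(amp, start, u)]:
                    continue
                if sum(a != b for a, b in zip(u, v)) == 1:
                    target = assigned[v]
                    break
            assigned[u] = target
        for u, t in assigned.items():
            canon[(amp, start, u)] = (amp, start, t)
    return canon


def deduplicate(reads: list[AlignedRead],
                collapse_1mm: bool = False) -> tuple[list[AlignedRead], DuplicationStats]:
    """Collapse PCR duplicates by (amplicon, start, UMI).

    One representative per group is kept: the first after a stable sort by
    read id, which is deterministic across runs and platforms. Set
    collapse_1mm to additionally merge UMIs one mismatch apart.
    """
    keys = [_dedup_key(r) for r in reads]
    if collapse_1mm:
        canon = _merge_umi_groups(keys)
        keys = [canon[k] for k in keys]

    order = sorted(range(len(reads)), key=lambda i: (keys[i], reads[i].read_id))
    unique, seen = [], set()
    per_amp: dict[str, list[int]] = {}
    for i in order:
        key = keys[i]
        amp = key[0]
        tot_uni = per_amp.setdefault(amp, [0, 0])
        tot_uni[0] += 1
        if key not in seen:
            seen.add(key)
            tot_uni[1] += 1
            unique.append(reads[i])
    unique.sort(key=lambda r: r.read_id)
    stats = DuplicationStats(
        total=len(reads), unique=len(unique),
        per_amplicon={a: (t, u) for a, (t, u) in per_amp.items()})
    return unique, stats


def methylation_shift_check(before: list[AlignedRead],
                            after: list[AlignedRead]) -> dict[str, float]:
    """Per-amplicon change in mean methylation % across deduplication.

    A QC metric only: amplification bias toward one methylation state shows
    up as a nonzero shift that deduplication removes. Reported as
    (after - before) percentage points per amplicon.
    """
    def region_means(reads):
        acc: dict[str, list[int]] = {}
        for r in reads:
            m_u = acc.setdefault(r.amplicon, [0, 0])
            m_u[0] += r.n_methylated
            m_u[1] += r.n_called - r.n_methylated
        return {a: (100.0 * m / (m + u) if m + u else float("nan"))
                for a, (m, u) in acc.items()}

    mb, ma = region_means(before), region_means(after)
    if set(mb) != set(ma):
        raise ValueError("amplicon sets differ between before and after")
    return {a: ma[a] - mb[a] for a in mb}


def write_dedup_report(stats: DuplicationStats, path) -> None:
    with open(path, "w") as fh:
        fh.write("amplicon\ttotal\tunique\tduplication_pct\n")
        for amp in sorted(stats.per_amplicon):
            t, u = stats.per_amplicon[amp]
            fh.write(f"{amp}\t{t}\t{u}\t{stats.amplicon_duplication_pct(amp):.2f}\n")
        fh.write(f"ALL\t{stats.total}\t{stats.unique}\t{stats.duplication_pct:.2f}\n")
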