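# Methods

## Scope and model

`amplimeth` models a targeted bisulfite assay at molecule resolution. The
unit of truth is the template **molecule**: an amplicon, a parental origin
(maternal/paternal), a strain label, and one methylation bit per CpG. The
pipeline's claim is that, after UMI deduplication, each surviving read
corresponds to one original molecule, so per-CpG counts, per-read epiallele
classes and per-region means are all statements about the template
population rather than the PCR product.

Coordinates are 0-based half-open throughout the library; only the
human-readable per-CpG TSV uses 1-based positions, and bedGraph output is
0-based half-open as the format requires. A CpG is always keyed by its
top-strand C position, whichever strand an amplicon targets; bottom-strand
amplicons observe the complementary cytosine (top-strand G position read as
G/A) and their calls are mapped back to the canonical key. Reference
positions containing N carry no CpG and no SNP; observations over them are
called unknown.

## Simulator

`draw_molecules` draws parental origin Bernoulli(maternal_fraction) and each
CpG bit independently from the parent's methylation probability (scalar or
per-CpG vector). Defaults describe a well-powered targeted run:

| parameter | default | meaning |
|---|---|---|
| conversion_rate | 0.995 | P(unmethylated C reads T); ~99.5 % conversion efficiency is typical of kit-based treatment |
| inappropriate_conversion | 0.005 | P(methylated C reads T) |
| seq_error_rate | 0.001 | per-base substitution probability per sequenced copy |
| read_len / umi_len | 250 / 8 | 2×250 bp paired reads; 8-base in-line UMI at the start of read 2 |
| mean_pcr_copies | 1.2 | reads per molecule, copies ~ 1 + Poisson(mean−1); 1.2 gives ~17 % duplication, in the middle of what targeted runs show |
| maternal_amp_bias | 1.0 | optional multiplier on the maternal copy mean, to model allele-specific amplification bias; off by default |

Design choices: base qualities are constant Q37 (the error model is
substitution-driven; an optional `low_quality_tail` mode randomizes read
tails at Q2 so that quality trimming is exercised); the shifted-Poisson copy
law was chosen for having a single parameter with copies ≥ 1; UMIs are drawn
uniformly over 4^8 and collisions are left for deduplication to encounter,
exactly as in real data; read pairs always span the full amplicon because
2×250 bp covers any rule-conforming (≤430 bp) product, so no insert-size
model is needed. Sequencing error is applied to the whole of read 2
including the UMI bases — a UMI error fractures a duplicate group, which is
the real failure mode exact-match deduplication has.

SNP alleles are substituted into the template before conversion, so an
allele that is a cytosine on the targeted strand converts like any non-CpG
cytosine; a SNP that disrupts a panel CpG demotes that cytosine to non-CpG
conversion behaviour.

What the simulator deliberately omits: indels, per-cycle quality decay,
chimeric/primer-dimer artifacts, off-target amplification. Passing tests
therefore demonstrate correctness of the bookkeeping and statistics under
substitution-type noise, not robustness to alignment-breaking artifacts —
real indel-bearing reads simply become unassigned.

## Pipeline stages and numerical choices

**UMI extraction** moves the first 8 bases of read 2 into both read IDs
after a final ':' (any downstream parser takes the last colon-delimited
field). Pairs whose read 2 is not longer than the UMI are rejected and
counted.

**Trimming** is a minimal re-implementation: 3' Phred-20 quality trim,
single 3' adapter per mate removed on a ≥3-base overlap with ≤10 % mismatch
(first qualifying position wins), pairs with a mate under 20 bases
discarded and counted. Simulated reads are clean; trimming exists so real
FASTQs behave plausibly. Exact parity with production trimmers is a
non-goal.

**Amplicon assignment** compares the first 30 bases of read 1 against each
amplicon's converted reference in three-letter space (C collapsed to T in
read orientation, which is the C/T collapse for top-strand amplicons and
the G/A collapse, seen from the other strand, for bottom-strand ones). The
best amplicon wins if its mismatch fraction is ≤ 0.1 and it beats the
runner-up by ≥ 2 mismatches; ties and poor matches are explicit
"unassigned". Panels whose anchors collide draw a warning at load time. The
30-base anchor and 2-mismatch margin keep assignment unambiguous at ≤10 %
per-base error on any rule-conforming panel; both are configurable.

**CpG calling** places reads ungapped (read 1 from position 0, the reverse
complement of read 2 from the amplicon end; read 1 wins in the overlap, so
no observation is double-counted). Observed C ⇒ methylated, T ⇒
unmethylated, anything else or no coverage ⇒ unknown. Non-CpG reference
cytosines observed as C count toward a per-read retention tally; reads with
≥ 3 retained non-CpG cytosines are flagged conversion-suspect but retained
— conversion QC is the job of the control amplicons, not a read filter.
SNP positions are excluded from the conversion tally since the non-reference
strain's base there is not informative about conversion.

**Deduplication** groups by (amplicon, read-1 start, UMI) and keeps the
first read per group after a stable sort by read id — deterministic across
platforms, unlike first-seen-in-input-order. UMI matching is exact by
default; an optional single-mismatch merge (larger group absorbs smaller)
exists for real data. A before/after methylation-shift check reports the
per-amplicon change in mean methylation across deduplication as a QC
metric, with no automatic filtering.

**Allele splitting** lets every covered usable SNP vote; all votes must
agree (conflicts ⇒ unassigned, flagged), one informative SNP suffices.
Conflicted reads stay in the allele-agnostic tables but never enter
per-allele tables. Comparison is conversion-aware via per-allele observation
sets ({C,T} for a targeted-strand C, {G,A} for a bottom-strand G in top
coordinates, singleton otherwise); usable SNPs have disjoint sets by
construction, so a base is informative for at most one allele.

**Quantification.** Per-CpG percentage is 100·meth/(meth+unmeth); unknown
calls contribute to neither count, and a CpG with no called coverage
reports a missing value. The region mean is the **unweighted mean over
per-CpG percentages** (matching how per-CpG summaries are usually plotted),
not a read-weighted pooled rate. Read classification uses strict
inequalities — > 90 % methylated, < 10 % unmethylated, otherwise
intermediate — and requires ≥ 3 called CpGs (prevents 1-CpG fragments from
polarizing the class fractions; values on a boundary are intermediate).
Coverage filtering keeps a region only with strictly more than 100
deduplicated reads. Status calls: imprinted regions are normal in [40, 60] %,
hypo- below, hyper- above; unmethylated controls pass < 10 %, methylated
controls > 90 %; regions of class "other" are summarized but receive a
`not_evaluated` status rather than a judgement, since no expectation is
defined for them. All thresholds live in `ConfigThresholds` and are
overridable; the published rules use approximate ("~") bounds, hardened here
to the strict numeric forms just stated.

Amplification-bias exclusion ("clear sequencing bias toward one methylation
state or one SNP") has no quantitative definition in the assay literature;
the package reports the diagnostics (allele-ratio, class fractions,
methylation shift across dedup) and performs no automatic exclusion.

## Problem sizes used by the test and acceptance runs

Simulation-backed checks use 1000 molecules per amplicon for distributional
assertions (region means, class fractions, parameter recovery) and 80–400
molecules for exactness and reproducibility checks, with fixed seeds; at
1000 molecules × 12 CpGs the Monte-Carlo standard error of a region mean is
well under one percentage point, so the 45–55 % acceptance band is
conservative. Statistical assertions use exact binomial intervals (99–99.9 %)
around expectations computed from the realized truth table, never around
nominal parameters, so they cannot fail on an unlucky but correctly
processed draw.

## Known limitations

* Ungapped, anchor-based assignment: indel-bearing reads are unassigned
  rather than rescued.
* Exact-match UMI grouping slightly overcounts molecules at nonzero
  sequencing error (≈0.8 % of reads carry a UMI error at the default rate);
  the optional 1-mismatch merge trades this against collision risk.
* UMI collisions (two molecules of one amplicon drawing the same 8-mer)
  merge molecules at a rate n²/2·4⁻⁸; the simulator's truth table makes the
  effect measurable, and tests account for it exactly.
* The "other" region class is reported but not judged.
* No inter-sample statistics (differential methylation, group tests) — the
  unit of analysis is one library.
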