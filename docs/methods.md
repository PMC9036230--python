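# Methods

## Problem and scope

Small-RNA sequencing of tissues such as brain captures, besides mature
miRNAs, short RNAs derived from the processing of longer non-coding RNAs:
tRNA-derived fragments (tRFs), and fragments of rRNA (rRFs), snRNA (snRFs)
and snoRNA (snoRFs), collectively ncRFs. This package implements the full
descriptive analysis of such libraries: mapping reads to an ncRNA catalog,
classifying them by precursor class, calling end-anchored fragments,
profiling fragment positions and sizes, quantifying fragment enrichment
relative to precursor abundance, and comparing prorated counts across
samples (brain regions and sexes). A synthetic-data module generates
libraries with the same statistical structure so every stage is testable
without sequencing data.

## Read model and trimming

Reads are 36 nt: a 7-nt adapter, then an insert of 15–29 nt, then
read-through padding that continues the adapter sequence from its first
base. Trimming removes the leading adapter (tolerating one substitution)
and then the longest trailing run exactly matching the adapter-continuation
pattern, keeping at least a 15-nt insert; shorter reads are rejected.

Trailing-pad removal is inherently ambiguous when the insert's own 3' end
spells a prefix of the adapter pattern. For padded inserts (≤ 27 nt) the
chosen adapter (`TGGAATT`, non-periodic) makes spurious matches impossible
unless the insert actually contains the adapter; for pad-free 29-nt inserts
the ambiguity is irreducible at the trimmer. The simulator therefore
screens surrogate reference sequences for adapter contamination (no adapter
substring anywhere, and no adapter-pattern prefix at the end of the 29-nt
leader), which makes trimming exactly invertible on simulated data. Real
references are not screened; on real data occasional one-base over-trims of
precursor-length reads are possible, as with any adapter trimmer.

## Mapping

Alignment is ungapped and end-to-end with at most two substitutions,
reporting a single best-stratum hit (minimum achievable mismatch count).
Rather than seed-and-extend, the mapper scores every placement of the
insert on every reference with vectorized mismatch counting; at catalog
scale (tens to hundreds of short references) this is fast, and it is exact
for any insert length — a k-mer seed index cannot guarantee exactness for
15-nt inserts carrying two mismatches. A per-insert memo exploits the heavy
insert duplication typical of small-RNA libraries.

Ties between equally good placements break deterministically: catalog
record order first, then smallest offset. Short-read aligners in this
mode pick pseudo-randomly among equals; the deterministic rule is a
deliberate divergence chosen for reproducibility, and it makes catalog
ordering significant when references share sequence. `N` never matches
anything (including another `N`); inserts that are mostly `N` are dropped.
Only the sense strand is scanned by default, since the catalog carries
sense ncRNA sequences and antisense transcripts are their own reference
class; a `both_strands` option exists.

## Classification summaries

Class fractions are computed over mapped reads. Size distributions use
linear-interpolation quartiles with 1.5·IQR whisker outliers (the standard
boxplot convention; the method is pinned so values are testable). GC
content is pooled — total G+C over total bases within a class, with `N`
counting in the denominator only — not a mean of per-read fractions; the
two differ when read lengths vary, and the pooled reading matches a
"counts over total nucleotides" definition. Biological replicates are
pooled before summarization. Insert sequences are taken from the aligned
reference slice, which equals the read up to the counted mismatches.

## Fragment calling

A hit becomes a fragment call when: insert ≤ 27 nt (reads ≥ 29 nt are
precursor-length signal; the 28-nt band belongs to neither count and the
simulator never plants it, so the exclusion is observable); the precursor
class is fragment-bearing (tRNA, rRNA, snRNA, snoRNA, repeat, lincRNA,
antisense — mature miRNAs are not processed into fragments); and the
precursor carries at least five reads of any length (support counts
fragments and precursor-length reads alike, reading the support rule as a
property of the ncRNA, not of its fragments). The boundary is inclusive
(≤ 27) and configurable.

End typing is literal with default tolerance 0: offset 0 is a 5' fragment,
offset + length = reference length a 3' fragment; anything else is kept as
`internal` — internal calls still count in positional profiles but are
excluded from 5'/3' tables. The tolerance is configurable (1–2 for noisy
data). tRFs are further subtyped by length: < 23 nt are tRF-5/tRF-3,
23–27 nt halves (tRH-5/tRH-3); the literature uses both vocabularies
without a fixed mapping, so the cutoff is a parameter.

Positional profiles assign each fragment-length read to one of 10
equal-width bins by its 5'-most base, `bin = floor(10·offset/L_ref)`, so
bin counts sum to the read count and fractions normalize to 1. A
3'-anchored read starts at `L_ref − L_insert`, which lands in a late — not
necessarily the last — bin; 3' bias therefore shows as mass concentrated in
the last few bins.

## Enrichment

Per precursor or family, the enrichment ratio is fragment reads (≤ 27 nt)
over precursor reads (≥ 29 nt); 1 means one fragment per precursor read.
Family ratios are ratios of summed counts (robust to low-count members).
Because judging enrichment from a raw ratio needs a rule, a symmetric band
is imposed: enriched above 1 + δ, underrepresented below 1 − δ, with
δ = 0.25 by default; an optional two-proportion test can additionally be
required. The ratio is undefined (NaN, never a division error) without
precursor reads.

## Cross-sample comparison

Counts are prorated to a reference sample by total mapped library size
(`prorated = raw · lib_ref / lib_sample`), the basis being configurable;
class-total scaling would distort cross-class percentages. The comparison
table reports, per fragment class: percent of the per-sample class total,
ratio to the same-sex reference region (reference ≡ 1), and the
male:female ratio per region (undefined when the female count is zero).
Display rounding is half-away-from-zero — two decimals for ratios, one for
percentages — matching how such tables are printed; returned values are
unrounded. A worked example ships with the package
(`ncrf.compare.load_example_prorated_counts`): prorated fragment counts
for six rat brain samples whose published shares, region ratios and
male:female ratios the table reproduces cell by cell.

Significance between two samples' class proportions uses a two-sided
two-proportion z-test with continuity correction on raw counts (chosen
here; equivalent to the Yates-corrected chi-square, which the tests verify
numerically). External target-prediction tables are filtered at score
strictly greater than 80 (the "likely real" threshold of miRNA-style
target predictors, whose scores live on a 50–100 scale) and pathway tables
at adjusted (Benjamini–Hochberg) p strictly less than 0.05; both
thresholds are read strictly as worded. Overlaps of 2–3 filtered sets are
reported as exclusive Venn partition counts via set arithmetic.

## Synthetic data: what it emulates and what it does not

Defaults plant the study conditions the pipeline targets: a
miRNA-dominated mixture (miRNA 0.77, repeats 0.12, tRNA 0.025, snoRNA
0.02, lincRNA 0.02, rRNA/snRNA/antisense 0.015 each); tRF insert modes
18 nt (0.65) and 26 nt (0.25); 5' origin bias 0.9 for tRNA and 0.8 for
repeats, 3' bias for snoRNA (5' probability 0.125, i.e. 3':5' ≈ 7:1),
snRNA and rRNA (0.2); tRNA family weights Gly-GCC 0.84, Glu-CTC 0.07,
Lys-CTT 0.055, Val-CAC 0.035, which combined with per-family
fragment:precursor odds (Gly-GCC 0.75 → planted enrichment ratio 3;
Val-CAC 1/6 → ratio 0.2; others 0.5 → ratio 1) put the glycine share of
tRF reads near 90%. Reference sequences are uniform-random surrogates at
class-typical lengths (tRNA 70–90 nt, snoRNA 60–250, snRNA 100–200, rRNA
120–160, others 60–300).

Consequently the simulation exercises the pipeline's arithmetic and
decision rules, not biological sequence realism: surrogates carry no tRNA
cloverleaf structure or sequence conservation, no multi-mapping between
related isodecoders, no expression correlation structure, and errors are
uniform substitutions without indels or quality variation. Passing
recovery tests shows the pipeline measures what was planted at the planted
rates; it does not validate mapping behavior on homologous real
references.

Determinism: one seeded generator stream per operation (catalog and reads
derive independent streams from the config seed), so identical configs
give byte-identical FASTQ/FASTA/manifest output.

## Numerical and testing choices

Recovery tests use three-sigma binomial tolerances at their realized
sample sizes; ratio checks derive their interval from the underlying
binomial count. Test and acceptance problem sizes — one 50,000-read
sample for recovery and caller-exactness checks, twenty catalogs × 5,000
reads for mapper/oracle equivalence, 30,000-read samples in the analysis
scripts — are desk-scale choices that keep the whole suite under a minute
of compute while leaving every tolerance comfortably tight. The mapper is
verified against an independently written exhaustive character-scan
oracle; filters and Venn partitions against brute-force enumerations.

## Known limitations

* One best hit per read: multi-mapping reads resolve to the first-listed
  record rather than being fractionally distributed.
* Enrichment status is a descriptive band, not an inference procedure;
  the optional two-proportion check treats reads as independent.
* Cross-region significance testing of size distributions is out of
  scope: replicate pooling removes the unit of replication such tests
  need.
* The comparison table's proration basis (total mapped reads) is a
  convention; tables prorated on another basis reproduce their internal
  arithmetic but not necessarily each other's counts.
* Gapped alignment, base-quality-aware mapping and genome-wide annotation
  are out of scope.
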