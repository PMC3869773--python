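# Methods

## Inputs and conventions

The classifier consumes one record per gene: average RNA Pol II
(phospho-Ser2) ChIP-seq peak values for `WT`, `KO` (*Parp14*−/−),
`WT+PJ34`, `KO+PJ34` and `INPUT`, plus a per-sample boolean saying whether
SICER called the gene significant. Peak values are dimensionless normalized
tag densities and are assumed already normalized upstream (equal alignment
depth across samples); the package performs no read-level processing.

Genomic intervals are 0-based half-open (BED) throughout; 1-based inputs
are converted at the reader boundary (`one_based=True`). The TSS is
`start` on the + strand and `end − 1` on the − strand. SICER output is
consumed as gene-level booleans; a helper maps island BED files to genes by
a ≥1 bp gene-body overlap. That overlap rule is a declared package default —
upstream reports gene-level significance without stating a convention —
and promoter- or summit-based alternatives would change borderline genes.

## The pool decision tree

Thresholds (all configurable in `ClassifierConfig`, defaults in
parentheses): activity floor on the best sample (0.500, strict `>`),
up-regulation ratio (1.4), down-regulation ratio (0.7), rescue bands
(1.2–1.4 and 0.7–0.83) gated on the stronger sample's peak exceeding 2,
and the no-change band (0.83–1.2) used for every PJ34 comparison.

Band endpoint semantics are not derivable from prose alone; the package
fixes them as: the no-change band is closed and takes precedence, so a
WT/KO ratio of exactly 1.2 or 0.83 is "no change" and the rescue bands are
effectively open at those shared endpoints. Only exact ties are affected.
The "stronger sample" for both the peak-above-2 gate and the SICER
verification is `argmax(p(WT), p(KO))`, i.e. the numerator of the
favourable ratio; the SICER verification is applied after band rescue,
mirroring the order in which the rules are stated.

Zero denominators get a pseudocount (0.01) added to both numerator and
denominator rather than producing infinite ratios; peaks are tag densities,
so an exact zero reflects sampling depth, not biology. The value only
matters for genes with a truly empty condition.

Classification is scale-free in the ratios but not in the absolute gates
(0.500 activity floor, peak-above-2 rescue): multiplying a gene's peaks by
c > 0 preserves its pools only once every gate stays on the same side, a
property the tests exercise away from those boundaries.

## Enrichment statistics

The hypergeometric upper tail P[X ≥ k] is accumulated in log space
(`logpmf` + log-sum-exp) for stability at extreme tails; the test suite
checks it against rational-arithmetic enumeration to 1e-10 relative over
the full N ≤ 30 grid. The urn for both gene-set and motif enrichment is
population = target ∪ background, sample = target (the ZOOPS enrichment
convention); target and background must be disjoint, with the background
being the unregulated genes. A binomial alternative (background hit rate as
success probability) sits behind `method="binomial"`. Multiple testing uses
Benjamini–Hochberg step-up exclusively. Fold enrichment
`(k_t/n_t)/(k_b/n_b)` returns an infinite-fold sentinel when the background
has no hits and a degenerate flag when neither list does. Because report
conventions disagree on the "percent" denominator, the pathway report emits
both percent-of-target and percent-of-set columns.

## Motif machinery

Scanning is plain Hamming distance over fixed-length words: every offset
(both strands unless disabled) within the motif's mismatch budget is a hit;
`N` matches nothing; budgets default to length // 6 (1 for 10-mers, 2 for
12-mers). Promoter windows are −1000/+100 around the TSS, strand-aware and
clipped with a warning at contig edges; locus scans cover the gene body
±10 kb and report genomic coordinates.

De novo discovery enumerates every k-mer present in the target promoters,
computes mismatch-tolerant ZOOPS counts in both collections via vectorized
Hamming-ball expansion of per-sequence k-mer sets (windows containing `N`
are skipped at this stage), and scores each candidate hypergeometrically.
Reporting requires fold ≥ 3.5 **and** BH q ≤ 0.05 across all enumerated
candidates. The q-gate is a deliberate design choice: with ~2·10⁵
candidates per run, fold alone would promote chance singletons (infinite
fold on an empty background), whereas BH control bounds the probability of
any discovery under a complete null by ~α, which the null-simulation test
(≥19/20 clean seeds) exploits.

Mismatch-tolerant counting makes a planted word's shifted variants score
almost as well as the word itself (a one-base shift behaves like a (k−1)-mer
with a free end, so it collects slightly more chance hits). Reported
motifs are therefore redundancy-collapsed: candidates are clustered by a
shift-aware distance (mismatches minimized over small relative shifts, each
shift costing one) and each cluster is represented by the member with the
strongest *exact* target support — the orientation and phase actually
planted or bound. Low-complexity words (tandem repeats of unit ≤ 3
covering ≥ 80%, or mononucleotide entropy < 1 bit) are rejected, which is
what removes poly-A-type false positives while keeping both validated
candidate motifs.

This is an exhaustive k-mer search, not a PWM-optimizing one: degenerate
motifs whose instances differ from any single k-mer by more than the budget
will be fragmented or missed, and p-values are not comparable to
PWM-based tools.

## Synthetic data

`simulate_peak_table` emulates the structure the classifier assumes:
per-gene log-normal baseline peaks (ln-mean 0.4, ln-sd 0.6 — median ~1.5
tag density, right-skewed like real per-gene Pol II densities), an input
level of 0.3, and planted classes whose decision ratios clear every
threshold by a multiplicative margin (default 1.2; e.g. a positive gene's
WT/KO ratio is planted at 1.4 × 1.2). Per-condition log-normal noise
(sd 0.05) is truncated at 0.49·ln(margin), so any two-condition ratio moves
by strictly less than the margin and recovery of planted labels is exact by
construction — the recovery test is constructive, not statistical. Setting
`clip_noise=False` removes the truncation and lets recovery degrade as the
margin shrinks, which the margin-sweep test demonstrates. Active baselines
are floored at 0.75 so the strongest condition stays above the 0.500
activity gate after noise; inactive genes sit below
min(0.500, input)/margin² with all SICER flags cleared.

Default class counts equal the study-scale composition (25,677 genes;
8,062 active; 2,744 dependent split 2,314/430; 1,647/756/341 across pools
4/5/6), apportioned by largest remainder at other sizes, with the
positive/negative split distributed proportionally within each pool (the
per-pool split is not published). `exact_counts=True` (default) plants
those counts deterministically and shuffles gene order by seed; set it to
False for a multinomial draw.

`simulate_genome_with_motifs` writes one uniform-ACGT contig per gene,
sized so ±10 kb locus scans never clip, and plants one motif copy per
selected gene at a uniform promoter offset (rates 0.4 target / 0.05
background by default, strand configurable and recorded). What the
generator does **not** model: GC/CpG composition, repeats, nucleosome or
mappability structure, replicate variability, correlated conditions, and
degenerate motif instances. Passing tests therefore demonstrate
correctness of the decision logic and counting machinery, not robustness
to the compositional biases of real mammalian promoters.

## Problem sizes and determinism

Test and acceptance runs use: the full 25,677-gene table for
classification; 1,000 genes for recovery; 600 promoters (200 target / 400
background, 1,100 bp) for de novo discovery with 20 null repetitions; the
four printed 50-mer pull-down probes for scanning. A single integer seed
drives every generator through `numpy.random.default_rng`; identical seeds
give byte-identical artifacts.

## Limitations

Reproducing the published pool counts from the authors' own supplementary
tables requires those tables (journal/GEO downloads); the package supports
the path via its Excel→TSV converter, and validates it end-to-end on a
generated workbook with the same composition. Three-set overlap counts
against external STAT6 lists and DAVID/KEGG pathway p-values depend on
third-party data and databases and are supported as generic operations
(`venn3`, `gene_set_enrichment`) rather than replicated numbers. Exact
reproduction of printed counts on real data may differ at threshold ties
depending on upstream rounding.
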