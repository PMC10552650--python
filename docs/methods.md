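# Methods

This note documents the models and procedures implemented in `paleotx`, the
parameter defaults and why they were chosen, the numerical decisions made
where the design was genuinely open, and the limits of what the synthetic
benchmarks demonstrate.

## The analysis problem

Small-RNA libraries from historical specimens differ from modern RNA-seq in
four ways that drive every design decision here: the molecules are short
(most inserts below 30 nt), chemically damaged at their ends (cytidine
deamination, sequenced as C→T), amplified through many PCR cycles (10–20
copies per molecule is typical), and mixed with residual genomic DNA and
exogenous contamination. The package therefore couples quantification with
*authentication* statistics: measurements that behave differently for
genuine historical RNA than for DNA or modern contaminants.

Coordinate conventions: every genomic interval is 0-based, half-open (GFF3's
1-based closed coordinates are converted on read). Mismatch positions are
stored in original-read orientation — 5′→3′ of the sequenced molecule — so
end-biased chemistry stays anchored to the molecule's termini regardless of
mapping strand. Soft-clipped bases are excluded from blocks and mismatch
accounting: they are unaligned.

## Preprocessing

**Adapter trimming.** Matching is suffix-anchored: candidate start `i`
compares the read window `seq[i:i+m]` against the adapter prefix of length
`m = min(|adapter|, |read|−i)` under unit-cost Levenshtein distance
(computed with edlib), accepting `floor(max_error_rate·m)` edits
(`max_error_rate` = 0.10). Adapter prefixes of at least 3 nt are accepted at
the read end. Among qualifying candidates the *fewest edits* win, with ties
broken to the leftmost position. A pure leftmost-qualifying rule is not
usable: the window one base left of a true adapter start is always reachable
with one insertion plus one deletion (cost 2 ≤ floor(0.10·21)), so it would
systematically trim one extra payload base and discard every 18-nt insert.
Inserts whose payload after UMI removal is shorter than 18 nt are discarded;
reads without an adapter hit are kept untrimmed.

**UMIs.** Trimmed inserts carry 4-nt UMIs on both ends, joined into an 8-mer
(5′ then 3′); untrimmed reads keep a 4-mer UMI from their first 4 nt while
their last 4 nt are removed without joining the UMI (they may be mid-molecule
bases of a long RNA, not a UMI).

**Deduplication** is two-stage, mirroring practice for UMI protocols: exact
collapsing of identical (payload, UMI) pairs before mapping (the reported PCR
duplication rate is input reads / unique pairs), then directional UMI
clustering at each mapping locus (reference, leftmost aligned base, strand):
a directed edge a→b exists when Hamming(a,b) = 1 and
count(a) ≥ 2·count(b) − 1; processing nodes by count (descending, then
lexicographic), each yet-unclaimed node claims everything reachable from it
and becomes a representative. The 2n−1 threshold is the published directional
criterion for separating true molecules from PCR/sequencing-error UMI
derivatives; the tie-break is fixed here for determinism.

**Length classes** follow the conventional split for degraded RNA: short
(18–25 nt, the miRNA window), medium (26–30 nt), long (> 30 nt); the 42-nt
count is tracked separately because libraries can show an anomalous spike
there whose damage profile distinguishes endogenous from modern material.

## Damage profiling

For each aligned base, the reference base is recovered from the mismatch
record (or equals the read base at matching positions), and the base is
tallied at its 1-based distance from the *nearer* read end (middle base of
odd-length reads to the 5′ tally) — so short reads contribute to both ends
without any base counted twice. Within a window of K = 10 positions per end
(the conventional damage-plot window), all 12 substitution rates are
reported as mismatches / opportunities, with denominators stored so rates are
re-derivable. Indels are excluded: deamination is a substitution process.
Profiles are cohort-level; no per-read damage score or decontamination
filtering is attempted, and the module reports A→G rates without attributing
them to genuine adenosine deamination versus technical misincorporation
(the two are not separable from rates alone).

Profile comparison (e.g. reads mapping to two references, or a suspect
42-nt class against the rest) reports per-position rate differences with
95% intervals obtained by combining the two Wilson score intervals
(Newcombe's method); positions whose interval excludes zero are flagged.

## Quantification and authentication

**Read→gene assignment.** Annotation is reduced to one isoform per gene (the
largest summed exon length; ties to the lexicographically smallest transcript
id). A read is assigned to the gene whose exons overlap the largest share of
its aligned bases, preferring same-strand genes; with no exonic overlap
anywhere, to the containing gene (intronic); otherwise it is intergenic.
"Exonic" requires a strict majority (> 50 %) of aligned bases in exons — the
contrast itself is standard, the per-read majority rule is this package's
choice. Ties break to larger overlap, then smaller gene id.

**Breadth rule.** Per gene, breadth = fraction of the retained isoform's
exonic bases covered ≥ 1×; genes with breadth ≥ 10 % count as reliably
detected. Enrichment statistics are computed over reads (not averaged over
genes) and, by default, restricted to reliably detected genes.

**Exonic enrichment vs DNA.** Mature mRNA concentrates on exons; genomic DNA
covers exons and introns in proportion to length. The module reports exonic
and intronic read fractions for the RNA library and a DNA background over the
same gene set, the enrichment fold (exonic RNA fraction / exonic DNA
fraction) and the intron depletion fold. This contrast is meaningful for
multi-exon protein-coding genes; over single-exon noncoding loci every
overlapping DNA read is trivially "exonic", so the acceptance script computes
it over protein-coding genes.

**Junction spanning.** A read spans an exon–exon junction when it covers the
last base of one exon and the first base of the next (≥ 1 nt on each side; no
larger overhang is required). Exon–intron junctions are the analogous
boundaries in genome space for intron-assigned reads. Single-exon genes are
excluded from the denominator. For uniform fragments of length r on a
transcript of length T with J junctions the expected spanning fraction is
J·(r−1)/(T−r+1), which the test suite checks against simulation.

## Genome windows

Scaffolds are tiled into fixed non-overlapping windows (250 kb default;
scaled-down simulations use 25 kb on a 2-Mb genome, preserving the
windows-per-genome ratio). Each read is counted once in the window containing
its leftmost aligned base — reads straddling a boundary stay in their start
window; for minus-strand reads the leftmost base is the 3′ end, a convention
chosen for determinism since either end changes no window statistic
materially. Hotspots are the top-k windows by read count (ties by chromosome
then start); sharing between libraries is the intersection of their top-k
sets.

**DNA-likeness heuristic.** Windows whose *intergenic* read distribution
resembles uniform DNA are candidate DNA-contamination territory. The DNA
background track is rescaled to the intergenic read total
(scale = intergenic reads / DNA reads); depth rescales linearly and breadth
through the uniform-coverage (Lander–Waterman) relation
b′ = 1 − (1 − b)^scale. A window is flagged when the intergenic breadth
*and* depth both lie within a twofold band of the rescaled DNA values
(conjunction is the conservative reading of "similar breadth and depth";
disjunction is available via `require_both=False`). Windows with zero DNA
coverage are unflaggable and excluded. Two design points deserve emphasis:

* the band is evaluated on the track of the intergenic reads themselves, not
  the whole library — genuine expression in a window would otherwise mask
  the uniform component, and a contamination fraction of a few percent could
  never match a whole-library rescaled track (it sits ~30-fold below it);
* the fraction of intergenic reads inside flagged windows is reported both
  relative to the intergenic population and to the whole library; the latter
  is the per-library DNA-contamination estimate, and recovers a planted 3 %
  uniform spike to within ~0.4 percentage points (the residual is
  contamination falling inside gene spans, which is assigned genic and is
  invisible to an intergenic-read statistic).

Genome-wide breadth and mean depth are reported alongside; for uniform DNA
they obey breadth ≈ 1 − e^(−depth).

## miRNA annotation and arm quantification

Precursor hairpins extended by 30 nt per side form the pri-hairpin used for
mapping; minus-strand hairpins are reverse-complemented so the 5p arm is
always 5′-most, and precursors clipped at scaffold edges are flagged. A
candidate hairpin is annotated as a novel miRNA when all four criteria hold:

1. ≥ 2 reads of 18–25 nt expressed from each arm;
2. consistent 5′-end homogeneity on both arms — operationalized as the modal
   5′-start fraction ≥ 0.5, a threshold this package fixes because read-end
   precision is the biogenesis hallmark but no standard number exists;
3. ≥ 16 matched Watson–Crick positions between the 5p arm and the
   reverse-complemented 3p arm, maximized over ungapped offsets of ±4 nt
   (total matches, not necessarily contiguous; G:U wobble pairs are
   accepted only when explicitly enabled);
4. loop length between 8 and 40 nt inclusive.

Arm quantification discards reads mapping within the stem but outside both
mature arms, reads whose offset bases exceed 25 % of their length (the 25 %
boundary itself is kept), and reads overlapping both arms equally. The 5p/3p
ratio is reported with the dominant arm; a zero 3p count yields a missing
ratio rather than an infinity.

## Taxonomic tally

For reads too short for k-mer classifiers (18–30 nt), origin is estimated
from alignments against a concatenated multi-species reference: MAPQ ≥ 1 is
the uniqueness proxy (best-hit aligners assign MAPQ 0 to multi-hit reads),
sub-threshold reads count as ambiguous, reads on references missing from the
seqid→taxon map as unassigned, and percentages are over uniquely assigned
reads only. An optional minimum-support filter suppresses low-count taxa
from reports. The k-mer classification stage for longer reads is outside
this package's scope.

## Tissue-identity embedding

Counts are converted to CPM against the total of genome-wide mapped
deduplicated reads (not the feature-set sum — the features under study are a
small, biased subset of the library). Cross-species comparison keeps only
homolog groups mapped one-to-one in every species. mRNA profiles are
log2(x+1)-transformed; miRNA profiles stay on the CPM scale, where a handful
of dominant species carry the tissue signal. The reference atlas alone is
embedded in 2-D with UMAP (n_neighbors = 5, metric = correlation distance
1 − r, spread = 10, min_dist = 0.1, random_state = 30); query samples are
projected afterwards and labeled with the tissue of the nearest reference
sample in embedding space (Euclidean; top-3 neighbors reported). A
quantitative nearest-neighbor readout replaces visual cluster inspection so
the contract is testable; with a fixed random_state the embedding is
reproducible on one machine, but across platforms the stable contract is the
label, not the coordinates.

## Synthetic data: what it emulates

The generator builds a two-scaffold toy genome (2 Mb by default) carrying
multi-exon protein-coding genes (2–6 exons), rRNA/tRNA loci, miRNA hairpins
(reverse-complementary arms for true hairpins, shuffled sub-threshold arms
for planted decoys), and hotspot genes placed one per designated window — 16
windows shared between the two tissue programs and 4 private to each, so
top-20 hotspot overlap has a known truth of 16/20. Expression programs give
rRNA dominance (~70 % of gene-derived reads), tissue-specific protein-coding
markers (20-fold boosted disjoint subsets), and per-hairpin 5p/3p arm biases
(0.8/0.2 alternating).

Libraries are drawn as molecules: mature-mRNA fragments are cut in
transcript space (so they span exon–exon junctions) and mapped back to
genomic blocks; a small nascent fraction (5 %) is cut from the unspliced
span; DNA contamination (3 %) is uniform genome-wide; a long-RNA fraction
(5 %) produces inserts longer than the sequencing window, yielding untrimmed
reads. Fragment lengths are 18 + Gamma(2.2, 4.0), clipped to [18, 60] —
short-biased with ~80 % below 30 nt. Damage is applied per base before PCR
with probability p(d) = p₀·e^(−(d−1)/λ) of C→T, where d is the distance to
the *nearer* end (p₀ = 0.20, λ = 3.9, giving ~0.2 terminally decaying to
~0.02 by position 10; optional 3′ A→G available), so the measured per-end
profile has expectation exactly p(d). Each molecule receives random 4+4
UMIs and 1 + Poisson(d−1) PCR copies (library defaults 21.3× for muscle,
11× for skin); raw reads are UMI5+payload+UMI3+adapter truncated to 75
cycles. Every read has one ground-truth row.

The multi-species simulator mutates a common ancestor sequence at a
configurable divergence (8 % default) and determines mapping uniqueness by
exact substring search of each read against every reference — a real, if
naive, uniqueness check, so ambiguity rates follow divergence rather than
being scripted. The tissue-atlas simulator plants per-tissue marker sets
boosted 50-fold over a log-normal baseline (tissue-defining miRNAs such as
the myomirs are enriched by orders of magnitude in real atlases, so this is
conservative) and degrades queries by multinomial downsampling to 8,000
feature-mapped reads, 15 % feature dropout and log-normal distortion.

**What passing tests do and do not show.** The simulations demonstrate
correctness of the algorithms and recoverability of planted parameters under
the stated noise models. They do not model alignment error or multi-mapping
(alignments derive from ground truth; alignment itself is delegated to an
external aligner), sequencing quality-score structure, platform-specific
error profiles, reference/annotation incompleteness, or biological
expression variability beyond the planted programs — so they validate the
measurement machinery, not the field behavior of any particular dataset.

## Numerical choices and degenerate inputs

* Adapter candidates shorter than 3 nt are never matched; adapters shorter
  than 3 nt are a configuration error.
* Empty damage-profile classes return an empty profile flagged via
  `is_empty`, not an exception; zero-denominator positions yield NaN rates
  and are reported as undefined in comparisons.
* Enrichment folds with an empty DNA background are `None`, not raised.
* Hotspot ranking is invariant to input order (ties resolved by coordinates).
* Both-zero arm counts are an error for the arm ratio; a zero 3p count is a
  missing ratio with 5p dominance.
* UMI groups with mixed UMI lengths are rejected.
* CPM with a zero library size is an error; log2 uses x+1.
* Problem sizes in the test and acceptance runs (10,000-read damage
  libraries, 50,000-read assignment libraries, 20,000-read DNA backgrounds,
  1,000-trial oracle sweeps, 100 projection seeds) are the package's chosen
  desk-scale study conditions; all are seeded and deterministic.

## Known limitations

* The directional-deduplication locus key uses the recorded alignment start;
  soft-clip-adjusted positions are not implemented.
* Positional deduplication of untrimmed reads is exposed through the same
  machinery but no dedicated policy is taken on whether to apply it.
* The DNA-likeness heuristic estimates only the *intergenic-visible* part of
  DNA contamination; contamination inside gene spans is counted as genic.
* Criterion 3 counts total matched positions, not a contiguous run; hairpins
  with many scattered matches could pass where a folding-based assessment
  would not. Thermodynamic folding is deliberately out of scope.
* UMAP coordinates are not portable across platforms or library versions;
  only nearest-tissue labels are contractual.
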