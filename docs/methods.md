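# Methods

## The quantities

For one intron in one sequencing library, retention is summarised by the
relative IR score

    r = (mean per-base read depth over the intron) / (reads supporting the intron's spliced junction)

Depth counts reads that kept the intron; junction reads count reads that
spliced it out, so `r` is a retention:splicing odds. If reads retain the
intron with probability ψ (the inclusion level) at gene read intensity
`E·D`, the expectations are `ψ·E·D` and `(1−ψ)·E·D` and `r → ψ/(1−ψ)` as
depth grows — the identity the validation suite checks. When an intron has
coverage but its junction has zero reads, `r` uses a pseudo-denominator of
1 and the measurement is flagged `no_splice_support` (a fully retained
intron is evidence, not an error); with neither coverage nor junction
reads the intron is unscored. The splicing-ratio difference of a
comparison is `Δr = r_control − r_treatment` (negative when the treatment
retains more).

## DIR calling

A comparison is one (tissue, stress, phase) treatment group against its
tissue-matched control, each with replicate libraries. Depths are scaled
to counts per million aligned bases before comparison, so library size
cancels.

**Effect size.** The adjusted log-fold change of intron coverage is

    aLFC(c) = log2((m_t + c) / (m_c + c)) / SE(c)

with `m` the replicate-mean normalised intron depths, `c` a pseudo-count
from the grid {1, 2, 4, 8, 16, 32}, and `SE(c)` the pooled standard error
of per-replicate `log2(depth + c)` floored at ε = 0.05 so the statistic
stays finite with tied replicates. The pair minimising `|aLFC|` over the
grid is reported — larger pseudo-counts can only shrink the raw log-fold
change, so this is the conservative choice among the candidates, and the
floor keeps near-zero-variance introns from dominating.

**Test.** The per-replicate statistic is
`x = log2((intron depth + 1)/(gene expression + 1))` with gene expression
the mean normalised depth over the gene's exonic union; normalising by
expression separates a retention change from a plain expression change.
With ≥ 2 replicates per side, a two-sided Welch t-test on `x`; with one
single-replicate side but ≥ 6 exchangeable libraries, an exact label
permutation on the difference of means; otherwise the p-value is NA.
Identical values on both sides short-circuit to p = 1. P-values are
BH-adjusted within each comparison and calls use `P_adj < 0.05`.

**Expression filter.** Genes whose mean normalised expression changes more
than fivefold in either direction between the two conditions are excluded
before testing. Note the interaction with library scaling: if a large
fraction of the transcriptome shifts strongly in one direction, the
library total moves with it and measured folds compress toward 1, so the
filter is exact only when strongly changed genes are a modest minority —
which is also the regime in which per-library normalisation is meaningful.

**Bookkeeping.** Per comparison the summary counts unique DIR events,
non-redundant associated loci, and loci carrying ≥ 2 DIRs; gene sets per
stress feed an exclusive-intersection (Venn-region) report. Both
per-comparison and pooled unique-gene tallies are emitted, since an event
count and a gene count differ whenever genes harbour several DIRs.

## AS event classification

Observed transcript models (e.g. aligned long reads) are first collapsed:
multi-exon models with identical (chrom, strand, junction chain) merge
into one isoform taking the outermost observed ends, single-exon models
merge by same-strand overlap; support counts merged models, and the
operation is idempotent. Each isoform is classified against the reference
transcript sharing the most junctions (ties: longer exonic length, then
lexicographic id):

* **IR** — a reference intron fully contained in one isoform exon;
* **Alt5 / Alt3** — an isoform junction sharing the acceptor but not the
  donor (respectively donor but not acceptor) with a reference junction,
  donor/acceptor taken in transcript orientation, so the roles flip on
  the minus strand;
* **ES** — one or more complete internal reference exons inside a single
  isoform junction;
* **MXE** — an ES skipping exactly one exon, upgraded when the isoform
  retains an adjacent reference exon and another annotated transcript of
  the gene shows the complementary inclusion pattern. Summaries fold MXE
  into ES.

Terminal-exon differences (alternative starts/ends, 5′ truncation) are
not events. A compound isoform yields one event per local difference;
both event-level and isoform-level (once per class per isoform) tallies
are available because the two denominators genuinely differ. Intergenic
isoforms are grouped into strand-aware overlap clusters; a cluster is
alternatively spliced when members differ in junction chain, and coding
capacity uses a longest-ORF rule (default ≥ 100 codons).

## Junction triage

Junctions are keyed by intron coordinates (0-based half-open). From BAM,
only primary, uniquely aligned reads (NH = 1) contribute; counts sum per
distinct junction and the maximum anchor overhang is tracked. Motif
classes come from the first/last two intronic bases read strand-aware;
unstranded junctions try both orientations and adopt the strand giving a
whitelisted motif, staying "other" on ties. The false-positive filter is
a transparent rule set — motif ∈ {GT/AG, GC/AG, AT/AC}, read count ≥ 2,
overhang ≥ 8 nt, all configurable — standing in for trained junction
classifiers; novelty is exact non-membership in the annotation's
distinct-intron set, enumerated per gene as the union of exon gaps over
isoforms (≥ 20 nt by default; shorter gaps are treated as alignment
artifacts).

## Co-regulation

The DIR × condition matrix holds Δr values; rows present in fewer than
half the conditions are dropped. Rows are z-scored, missing entries sit
at the row mean, and hierarchical clustering uses correlation distance
(1 − Pearson) with average linkage, cut at 0.3; singletons and constant
rows are discarded. Cluster coherence is the mean pairwise Pearson
correlation of member rows, tested by independently permuting each
member's condition labels: `p = (1 + #{null ≥ observed})/(1 + N)`, which
is valid (never anti-conservative beyond Monte-Carlo noise) by
construction. Algorithm and cut are stated stand-ins — reproducibility
was preferred over fidelity to any particular unpublished choice — and
all knobs are exposed.

## ddPCR

Droplets partition template molecules independently, so occupancy is
Poisson: `λ = −ln(1 − positive/total)` copies per droplet, concentration
`λ/volume × dilution` (droplet volume default 0.85 nL, QX200-class).
Replicate wells pool droplet counts before correction, preserving the
likelihood. The retained:spliced percentage is
`100 × retained copies / spliced copies` (NA at zero spliced), and a
ratio switch flags a target whose spliced fold change and ratio fold
change versus baseline lie on opposite sides of 1. Normal-approximation
CIs for λ are reported but never used for gating.

## Synthetic data

The generator emulates the study design at toy scale — default 3 tissues
× 4 stresses × 2 phases × 3 replicates plus per-tissue controls, 20
genes — with one RNG stream per (purpose, condition, replicate) derived
from the seed, so outputs are byte-identical across reruns. Genes have
3–8 exons (80–300 nt) and introns 60–200 nt whose boundary dinucleotides
follow configurable motif fractions (default 90% GT/AG, 8% GC/AG, 2%
AT/AC), strand-aware. Exonic depth is negative binomial
(variance = μ + μ²·φ, default φ = 0.1, base depth 50×, 100× in
calibration runs) around the gene's expression fold; intronic depth is NB
around ψ·μ with exact zeros at ψ = 0; junction counts are Binomial over
the spliced fraction of a Poisson read total. Baseline inclusion is
ψ = 0.1; seeded DIR introns (default 20%) shift by ±0.3 in a random
non-empty subset of stresses. Long reads carry seeded single events of
all five classes with 5′ truncation that never removes an internal
junction; droplet counts are Binomial with success `1 − e^{−λ}`.

What the generator does **not** model: read-level errors and mappability,
positional coverage autocorrelation (per-base depths are independent
given the mean), fragment-length effects, overlapping genes, partial or
multi-isoform expression mixtures, and batch structure. Passing
calibrations therefore demonstrate the statistical machinery is correct
under its stated model, not that real-library biases are absent.

## Validation scale and numerical choices

Calibration experiments (in `dirseq.benchmarks`) use a few hundred genes:
~1,000 introns × 20 seeds for null calibration, ~500 introns for power
(Δψ = 0.3, depth 100, 3 vs 3), 500 seeded isoforms for the classifier,
200 permutation clusters, 100 ddPCR wells — sizes chosen to give stable
Monte-Carlo estimates while a full run stays around a minute on one CPU.
Welch's test with three replicates per side is slightly conservative
(observed null rejection ≈ 0.035 at α = 0.05), which the calibration
bands accommodate.

Degenerate inputs are handled explicitly rather than silently: saturated
ddPCR wells, all-positive or empty replicate sets, zero-variance cluster
rows, single-exon genes, annotation features with overlapping exons, and
unsorted alignments all raise named errors or produce flagged/NA values
as documented on each function.

## Known limitations

* The DIR test models replicate variability on the log scale with a
  t-approximation; counts are not modelled as NB likelihoods, so very low
  depths rely on the +1 stabilisers.
* Junction novelty is exact-coordinate; near-miss junctions (wobble from
  alignment) count as novel.
* MXE detection requires the complementary pattern to exist among
  annotated transcripts; unannotated mutually exclusive pairs are
  reported as plain ES.
* The expression filter's exactness degrades when a large transcriptome
  fraction shifts in one direction (see above).
* Clustering results depend on the stated distance/linkage/cut; they are
  deterministic and configurable but not claimed optimal.
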