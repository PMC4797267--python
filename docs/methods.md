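# Methods

## Scope and data model

The package analyses a two-condition ChIP-seq comparison: condition A
(untreated) and condition B (treated, e.g. oxidative stress). Its inputs
are peak calls (BED), aligned-read intervals (BED, or SAM/BAM through a
thin adapter that keeps only primary mapped records' reference
intervals), a chromosome-size table or genome FASTA, a refGene-flat
transcript table, and a JASPAR-like position count matrix. All
coordinates are 0-based half-open throughout; parsers reject, and never
silently repair, coordinate-order violations. One transcript is one gene
model — isoforms are not collapsed, because overlap between transcripts
is resolved by annotation priority, not by merging.

## Differential occupancy

**Evaluation sites.** The union of peak centers from both conditions is
deduplicated greedily: centers closer than half the window width are
merged, keeping the center whose summed two-condition window count is
larger (ties break lexicographically, so the evaluation set is
deterministic and condition-symmetric). A peak's center is the floor of
its interval midpoint — a deterministic tie-break for even-length peaks.

**Counting.** A read belongs to a window when its midpoint lies in
`[center − w/2, center + w/2)` with w = 200 bp by default. Midpoint
containment counts each read at most once per window and avoids
double-counting at window edges.

**Signal and fold.** Counts are normalised to reads-per-ten-million
(`10^7 · c / depth`); the fold change is the ratio of pseudocounted
normalised signals, treated over untreated. The pseudocount (default 1.0
in normalised units) makes the fold total and bounded when a window is
empty in one condition; it is a disclosed parameter, not a constant.

**Test.** The per-site significance test is the conditional exact
binomial: given n = c_A + c_B window reads, c_B ~ Binomial(n,
d_B/(d_A+d_B)) under the null of equal per-depth occupancy. This is the
standard exact test for comparing two Poisson counts; it is exact at any
count, symmetric under swapping the conditions (labels flip
induced↔repressed site-for-site, folds invert), and has no tuning
parameters. The two-sided p-value uses the minimum-likelihood convention
(sum of all outcomes no more likely than the observed one), as
implemented by `scipy.stats.binomtest`; the test suite carries an
independent brute-force summation oracle. An empty window returns p = 1.
No replicate-aware dispersion model is fitted: the design this targets
has one sample per condition, so the exact conditional test on the single
count pair is the strongest defensible statement.

**Classification.** Induced: fold ≥ 4 and p ≤ 10⁻⁴; repressed: fold ≤ 1/4
and p ≤ 10⁻⁴; common otherwise. Both thresholds are inclusive. The three
labels partition the evaluation set by construction.

## Genomic annotation and enrichment

Seven categories in fixed priority order: promoter, TTS, 5′ UTR, 3′ UTR,
exon, intron, intergenic. Promoter is the kilobase upstream of the TSS
and TTS the kilobase downstream of the transcript end, both strand-aware
and clipped to chromosome bounds; UTRs are exonic sequence outside the
CDS, split 5′/3′ by strand; "exon" means CDS-overlapping exonic sequence
(otherwise the UTR categories would be unreachable); intron is
transcript-interior non-exonic sequence. Where transcripts overlap, the
earliest listed category wins — promoter first, making the promoter call
the strongest claim, and intergenic strictly "the rest". Genomic
background fractions are computed by painting each chromosome base-wise
with the same priority rule (lower priorities first, higher overwrite),
so the seven fractions sum to exactly 1 for any gene set; site annotation
uses an interval-tree index and agrees with the painting by construction
(tested against an independent per-position rule).

**Enrichment ("Bernoulli" / per-region binomial).** For k of n sites in a
category of genomic fraction p₀, significance is the one-sided upper tail
P(X ≥ k), X ~ Binomial(n, p₀). The tail is evaluated in log space — the
log-pmf via log-gamma binomial coefficients, combined with
`logsumexp` — and reported as log₁₀ p. This is the whole point of the
implementation: at genome scale the tail drops far below the smallest
positive double (~1e−308), where `scipy.stats.binom.sf` returns 0, while
the log-space sum stays exact (cross-checked against scipy in the
non-underflow regime and against brute-force tail summation at n ≤ 500).
Cost is O(n − k) per call, negligible at n ~ 2·10⁴.

## Motif fractions

PWM scoring uses pseudocount-regularised frequencies (count + 0.25 per
cell) over a uniform background, in log2, summed along the motif; the
best score over both strands and all offsets of the 200-bp window around
a site center is compared to a threshold expressed as a fraction
(default 0.8) of the matrix's maximum achievable score. A
fraction-of-maximum threshold is portable across matrices and is a
single interpretable knob, recorded in output headers; `N` bases score
as background (0 contribution). The background rate is estimated
empirically — the motif-positive fraction of `background_samples`
(default 10 000) random genome windows of the same width, sampled with a
caller-supplied seed, chromosomes weighted by length — rather than from
a theoretical score distribution, matching the empirical notion of
background used in occupancy figures and working for any PWM. Per-class
fold is the class fraction over this background; a zero background makes
the fold infinite with a warning. A threshold fraction of 0 is the
degenerate "every window hits" case and short-circuits to true.

## Plumbing peak caller

A deliberately simple caller exists only so the pipeline runs end-to-end
on simulated data without external peak lists: 200-bp windows every
50 bp, Poisson upper-tail against the depth-scaled control count floored
at the genome-wide chip rate, Benjamini–Hochberg across windows at
q ≤ 0.001, a 4-fold-over-expectation filter, and merging of overlapping
significant windows (scored by the best window's −log10 q, capped at
300). It makes no claim of matching any production caller's output; real
analyses should supply externally called peaks.

## Synthetic-data generator

The generator emulates the statistical structure the analysis consumes —
window counts at sites of known relative enrichment — not the physics of
a real experiment.

* **Genome**: i.i.d. uniform A/C/G/T sequence, by default one 2-Mb
  chromosome; 60 non-overlapping multi-exon genes (2–5 exons of
  200–400 bp, introns 500–1500 bp, CDS leaving UTR stubs in terminal
  exons, random strand, ≥ 3-kb gaps plus a terminal kilobase so
  neighbouring promoter/TTS kilobases never collide).
* **Sites**: 50 per class by default. Induced sites have enrichment
  (1, 8) in (A, B), repressed (8, 1), common (4, 4) — the 8-fold effect
  is double the 4-fold classification threshold, so recovery failures
  indicate bugs rather than power limits, and the common 4-fold
  enrichment keeps common sites callable in both conditions. Half the
  induced and a tenth of the common sites are placed at promoter
  midpoints (one site per gene); the rest are intergenic, clear of
  transcripts ± 1.1 kb, all centers ≥ 1 kb apart so evaluation-site
  merging never collapses two planted sites.
* **Reads**: per site and condition, a Poisson count with mean
  `depth × background_rate × enrichment` (defaults 50 000 × 4·10⁻⁴ = 20
  reads at unit enrichment), midpoints uniform within ± one fragment
  length (150 bp) of the center, 50-bp reads; the remainder of the depth
  is uniform genome-wide background, so emitted reads always sum exactly
  to the configured depth. A configuration whose site reads would exceed
  the depth is rejected.
* **Peaks**: `center ± 100` for every site whose realised read count in
  that condition reaches 10; with the default means, essentially every
  site in every condition.
* **Motifs**: a 19-bp consensus is substituted into the sequence at each
  `has_motif` site (default: half of the induced class). The default PWM
  is generated from that consensus (91 % of counts on the consensus
  base), giving a random-window hit rate below 2 % at the 0.8 threshold.
  It is a synthetic stand-in for an architectural-protein motif, not a
  database matrix.

Everything derives from one seed through independent spawned RNG
streams; identical configurations give byte-identical output. Not
emulated: fragment-size distributions, PCR duplicates, mappability, GC
bias, diploidy, replicate structure. Passing recovery tests therefore
demonstrates the statistical machinery is correct under the stated
generative model, not that real libraries are free of these artefacts.

## Bench-assay statistics

Chromatin co-fractionation: CSB band intensities are normalised to a
loading control per fraction, and the chromatin-bound percentage is
`100 · nC / (nC + nS · f)` with f the chromatin-over-soluble
concentration factor (default 1.3 — a property of the extraction buffer
volumes, exposed as a parameter because other protocols change it).
Percent survival is `100 · treated/untreated` viable cells. Paired
enrichment measurements use the paired t-test (two-sided, n − 1 df) with
the conventional star thresholds (\* < 0.05, \*\* < 0.01, \*\*\* < 0.001);
degenerate inputs are defined explicitly: identical pairs give (t = 0,
p = 1), zero-variance nonzero differences give (±inf, 0) with a warning.

## Numerical and design choices

* Inclusive thresholds exactly as stated (fold = 4.0 and p = 10⁻⁴
  classify as significant); the boundary is tested at the neighbouring
  floats.
* Scaling both counts and both depths by the same factor leaves the fold
  unchanged to machine precision and can only deepen significance; the
  suite checks classification recovery at depths 10⁵ and 4·10⁵.
* p-values may underflow to exactly 0.0 in the differential test at
  extreme imbalance; this is harmless there (any p below 10⁻⁴ classifies
  identically), while the enrichment test — where the deep tail is the
  quantity of interest — never underflows by construction.
* Recovery statistics in the test suite average 20 fixed seeds (1–20);
  the rank-test check of common-site exchangeability pools 5 seeds at
  α = 0.01. Problem sizes (2-Mb genome, 5·10⁴ reads per condition) keep
  a full 20-seed bank under a minute while leaving per-site counts
  (≈ 13–230 reads/window) in the regime the classification rule targets.

## Known limitations

* No replicate dispersion modelling; the exact test treats depth as the
  only nuisance, so biological variability is out of scope by design.
* The plumbing caller's q-values are window-level, not peak-level.
* Motif thresholds are score-fraction-based, not p-value-calibrated;
  fractions therefore depend on the matrix's information content.
* GREAT-style distal region→gene assignment and pathway lookups are out
  of scope; enrichment is per-category, not per-gene-set.
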