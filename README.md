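# oxichip

Differential ChIP-seq occupancy analysis for two-condition (treated vs
untreated) experiments, built around the oxidative-stress response of the
chromatin remodeler CSB: when cells are challenged with menadione, CSB
redistributes across the genome, gaining occupancy at promoters and at
CTCF-motif-containing sites. The package classifies binding sites as
**induced**, **repressed**, or **common** between conditions, annotates
them against seven genomic feature categories with a log-space binomial
("Bernoulli") enrichment test, and measures motif-occurrence fractions per
site class. A deterministic synthetic-data generator with known ground
truth makes every stage verifiable at desk scale.

**Who it is for:** epigenomics analysts comparing a protein's ChIP-seq
occupancy between two conditions from peak lists and aligned reads, and
methods developers who want a testbed with planted ground truth.

## The model

For each evaluation site (the deduplicated union of peak centers from both
conditions), reads with midpoints inside a 200-bp window around the center
are counted per condition, and signals are depth-normalised to
reads-per-ten-million. With counts (c_A, c_B) at depths (d_A, d_B):

- **fold change** F = (10^7 c_B/d_B + 1) / (10^7 c_A/d_A + 1), condition B
  treated;
- **p-value** from the conditional exact binomial test: under the null of
  equal per-depth occupancy, c_B ~ Binomial(c_A + c_B, d_B/(d_A + d_B))
  (the standard exact comparison of two Poisson counts);
- **label**: induced if F ≥ 4 and p ≤ 10⁻⁴; repressed if F ≤ 1/4 and
  p ≤ 10⁻⁴; common otherwise. Both thresholds are inclusive.

Site centers are annotated into seven prioritised categories — promoter
(1 kb upstream of the TSS), TTS (1 kb downstream of the transcript end),
5′ UTR, 3′ UTR, exon (CDS), intron, intergenic — and each category's
enrichment over its genomic base fraction p₀ is the one-sided binomial
upper tail P(X ≥ k), X ~ Binomial(n, p₀), evaluated entirely in log space
so genome-scale significances (log₁₀ p < −310) are returned exactly
instead of underflowing. Motif occurrence is scored by PWM log-odds over
both strands, a site counting as motif-positive when its best window score
reaches 80 % of the matrix's maximum; class fractions are compared to the
rate in randomly sampled genome windows.

## Worked example

Simulate a two-condition experiment (one 2-Mb chromosome, 60 genes, 50
sites per class, 8-fold planted effects, the motif planted in half of the
induced sites), classify, annotate, and scan:

```python
import oxichip as ox

cfg = ox.SimConfig(seed=7)
genome, genes = ox.generate_genome(cfg)
reads_a, reads_b, truth, peaks_a, peaks_b = ox.simulate_two_condition_chip(
    genome, genes, cfg)

results = ox.compare_conditions(peaks_a, peaks_b, reads_a, reads_b)
print(results.summary())
```

```
Differential occupancy summary
==============================
evaluation sites : 150
window           : 200 bp around peak center
thresholds       : fold >= 4.0 (or <= 0.25), p <= 0.0001 (both inclusive)
depths (A, B)    : 50000, 50000 mapped reads
induced          : 47
repressed        : 50
common           : 53
```

The 150 planted sites are recovered with their true classes (47/50
induced survive both thresholds in this realisation; the remainder fall
just under the 4-fold cut and land in `common`). Annotation and
enrichment of the induced class:

```python
profiles = ox.category_profile(results.sites, genes)
background = ox.genomic_background_fractions(genes, genome)
frac = profiles["induced"].fractions["promoter"]
p0 = background.fractions["promoter"]
```

```
induced promoter fraction: 0.489 (genome background 0.030)
fold over background: 16.3
log10 p (Bernoulli upper tail): -22.1
```

Half of the induced sites were planted in promoters; the test finds the
fraction (0.489 ≈ 0.5) and its enrichment (16-fold over the 3 % genomic
background, log₁₀ p ≈ −22). Motif fractions per class:

```python
pwm = ox.make_informative_pwm()
report = ox.motif_fraction_report(results.sites, pwm, genome,
                                  ox.MotifScanParams(seed=7, background_samples=5000))
```

```
    class   n  n_motif  fraction  background_fraction     fold
      all 150       25    0.1667               0.0016 104.1667
   common  53        1    0.0189               0.0016  11.7925
  induced  47       24    0.5106               0.0016 319.1489
repressed  50        0    0.0000               0.0016   0.0000
```

The planted 50 % motif fraction of induced sites is recovered (0.51);
repressed and common sites sit at the sampled background rate.

The same pipeline is scriptable from the shell:

```sh
oxichip simulate --seed 7 --out-dir sim/
oxichip diff --genome sim/genome.chrom.sizes \
    --peaks-a sim/peaks_A.bed --peaks-b sim/peaks_B.bed \
    --reads-a sim/reads_A.bed --reads-b sim/reads_B.bed --out sim/diff.tsv
oxichip annotate --genome sim/genome.chrom.sizes --genes sim/genes.tsv \
    --sites sim/diff.tsv --out-profile sim/profile.tsv \
    --out-enrichment sim/enrichment.tsv
oxichip motif --pwm sim/motif.pwm --fasta sim/genome.fa --sites sim/diff.tsv \
    --seed 7 --out sim/motif.tsv
```

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and what it does and does not emulate, the numerical choices,
and known limitations.
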