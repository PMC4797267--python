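"""Synthetic two-condition ChIP experiment with known ground truth.

The generator emulates the statistical structure of a treated-vs-untreated
ChIP comparison at desk scale: a toy genome with non-overlapping gene
models, binding sites partitioned into **induced** (enriched only after
treatment), **repressed** (enriched only before), and **common** (equally
enriched in both), reads drawn per site from a Poisson around each center,
genome-wide uniform background reads topping each condition up to its exact
depth, and motif consensus sequences planted at a chosen fraction of
sites.  Site placement can target promoters so category-enrichment
recovery is testable against the planted fractions.

Everything is deterministic given ``SimConfig.seed``: identical configs
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import CategoryScheme
from .io import ALPHABET, GeneModel, GenomeModel, Peak, ReadSet, PWM

__all__ = [
    "SimConfig",
    "TruthSite",
    "generate_genome",
    "simulate_two_condition_chip",
    "make_informative_pwm",
    "DEFAULT_MOTIF_CONSENSUS",
]

CLASSES = ("induced", "repressed", "common")

# Synthetic 19-bp GC-rich consensus used as the default planted motif.  It
# stands in for an architectural-factor binding motif; it is generated, not
# taken from any motif database.
DEFAULT_MOTIF_CONSENSUS = "CCGCGAGGTGGCAGTGCCC"


def make_informative_pwm(
    consensus: str = DEFAULT_MOTIF_CONSENSUS,
    name: str = "synthetic_motif",
    counts_per_position: int = 100,
    consensus_weight: float = 0.91,
) -> PWM:
    """Build a synthetic PWM concentrated on a consensus sequence.

    Each position puts ``consensus_weight`` of the counts on the consensus
    base and splits the remainder evenly over the other three, giving an
    informative matrix whose random-window hit rate at the default 0.8
    threshold is at the low percent level.
    """
    consensus = consensus.upper()
    L = len(consensus)
    if L < 4:
        raise ValueError("consensus must be at least 4 bases")
    counts = np.full((L, 4), counts_per_position * (1 - consensus_weight) / 3.0)
    for i, base in enumerate(consensus):
        counts[i, ALPHABET.index(base)] = counts_per_position * consensus_weight
    return PWM(name=name, counts=counts)


@dataclass
class SimConfig:
    """Study conditions of the simulated experiment.

    Defaults describe a desk-scale two-condition comparison: one 2-Mb
    chromosome carrying 60 genes, 50 sites per class, 50 000 mapped reads
    per condition, a mean of 20 reads at a unit-enrichment site
    (``background_rate`` = 4e-4 of the depth), an 8-fold induction/
    repression effect (twice the 4-fold classification threshold, so
    recovery failures indicate bugs rather than power limits), a 4-fold
    common-site enrichment in both conditions, the motif planted in half of
    the induced sites, and half the induced / a tenth of the common sites
    placed in promoters.
    """

    seed: int
    n_induced: int = 50
    n_repressed: int = 50
    n_common: int = 50
    depth_a: int = 50_000
    depth_b: int = 50_000
    background_rate: float = 4e-4  # per-site read fraction of depth at enrichment 1
    fragment_length: int = 150
    read_length: int = 50
    effect_fold: float = 8.0
    common_enrichment: float = 4.0
    motif_fraction: dict = field(
        default_factory=lambda: {"induced": 0.5, "repressed": 0.0, "common": 0.0}
    )
    promoter_fraction: dict = field(
        default_factory=lambda: {"induced": 0.5, "repressed": 0.0, "common": 0.1}
    )
    genome_length: int = 2_000_000
    n_chroms: int = 1
    n_genes: int = 60
    min_peak_reads: int = 10
    min_site_spacing: int = 1000
    edge_margin: int = 2000

    def __post_init__(self) -> None:
        for attr in ("n_induced", "n_repressed", "n_common", "depth_a", "depth_b"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        for cls_map in (self.motif_fraction, self.promoter_fraction):
            for cls, frac in cls_map.items():
                if cls not in CLASSES:
                    raise ValueError(f"unknown site class {cls!r}")
                if not 0 <= frac <= 1:
                    raise ValueError("fractions must be in [0, 1]")
        if self.effect_fold <= 4:
            raise ValueError(
                "effect_fold must exceed 4 so classes are recoverable at the "
                "4-fold classification threshold"
            )
        if self.background_rate <= 0 or self.fragment_length <= 0:
            raise ValueError("background_rate and fragment_length must be > 0")

    def n_sites(self, cls: str) -> int:
        return {"induced": self.n_induced, "repressed": self.n_repressed,
                "common": self.n_common}[cls]


@dataclass
class TruthSite:
    chrom: str
    center: int
    true_class: str
    enrichment_a: float
    enrichment_b: float
    category_intent: str
    has_motif: bool


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_genome(config: SimConfig) -> tuple[GenomeModel, list[GeneModel]]:
    """Random uniform-base genome plus non-overlapping gene models.

    Genes are laid left to right with multi-exon structure and gaps wide
    enough that each gene's promoter and TTS kilobases stay clear of its
    neighbours.  Raises if the requested genes do not fit.
    """
    rng_seq, rng_genes = _rng_streams(config.seed, 5)[:2]
    per_chrom = config.genome_length // config.n_chroms
    chroms = [(f"chr{i + 1}", per_chrom) for i in range(config.n_chroms)]
    base_bytes = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    sequences = {
        name: base_bytes[rng_seq.integers(0, 4, length, dtype=np.uint8)]
        .tobytes()
        .decode("ascii")
        for name, length in chroms
    }
    genome = GenomeModel(chroms=chroms, sequences=sequences)

    genes: list[GeneModel] = []
    gene_idx = 0
    per_chrom_genes = [config.n_genes // config.n_chroms] * config.n_chroms
    per_chrom_genes[-1] += config.n_genes - sum(per_chrom_genes)
    for (chrom, length), n_genes in zip(chroms, per_chrom_genes):
        cursor = config.edge_margin + 1000  # room for the first promoter
        for _ in range(n_genes):
            n_exons = int(rng_genes.integers(2, 6))
            exon_lens = rng_genes.integers(200, 401, n_exons)
            intron_lens = rng_genes.integers(500, 1501, n_exons - 1)
            gap = int(rng_genes.integers(3000, 6001))
            tx_start = cursor
            exons = []
            pos = tx_start
            for i in range(n_exons):
                exons.append((pos, pos + int(exon_lens[i])))
                pos += int(exon_lens[i])
                if i < n_exons - 1:
                    pos += int(intron_lens[i])
            tx_end = exons[-1][1]
            if tx_end + 1000 + config.edge_margin > length:
                raise ValueError(
                    f"requested genes do not fit in genome length {length} ({chrom})"
                )
            # CDS leaves UTR stubs inside the terminal exons
            cds_start = exons[0][0] + int(rng_genes.integers(50, 150))
            cds_end = exons[-1][1] - int(rng_genes.integers(50, 150))
            strand = "+" if rng_genes.random() < 0.5 else "-"
            gene_idx += 1
            genes.append(
                GeneModel(
                    name=f"gene_{gene_idx}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    exons=exons,
                )
            )
            cursor = tx_end + 1000 + gap
    return genome, genes


def _promoter_center(gene: GeneModel, scheme: CategoryScheme) -> int:
    """Midpoint of the gene's promoter kilobase (strand-aware)."""
    if gene.strand == "+":
        return gene.tx_start - scheme.promoter_upstream // 2
    return gene.tx_end + scheme.promoter_upstream // 2


def _place_sites(
    config: SimConfig, genome: GenomeModel, genes: list[GeneModel], rng: np.random.Generator
) -> list[TruthSite]:
    scheme = CategoryScheme()
    taken: dict[str, list[int]] = {name: [] for name in genome.names}

    # intergenic exclusion zones: transcripts plus their promoter/TTS kilobases
    forbidden: dict[str, list[tuple[int, int]]] = {name: [] for name in genome.names}
    for g in genes:
        forbidden[g.chrom].append((g.tx_start - 1100, g.tx_end + 1100))

    def far_enough(chrom: str, pos: int) -> bool:
        return all(abs(pos - t) >= config.min_site_spacing for t in taken[chrom])

    promoter_genes = list(genes)
    rng.shuffle(promoter_genes)

    sites: list[TruthSite] = []
    for cls in CLASSES:
        n = config.n_sites(cls)
        n_promoter = int(round(config.promoter_fraction.get(cls, 0.0) * n))
        n_motif = int(round(config.motif_fraction.get(cls, 0.0) * n))
        if cls == "induced":
            enr_a, enr_b = 1.0, config.effect_fold
        elif cls == "repressed":
            enr_a, enr_b = config.effect_fold, 1.0
        else:
            enr_a = enr_b = config.common_enrichment
        placed = []
        for i in range(n):
            if i < n_promoter:
                while True:
                    if not promoter_genes:
                        raise ValueError(
                            "not enough genes for the requested promoter-site fractions"
                        )
                    gene = promoter_genes.pop()
                    center = _promoter_center(gene, scheme)
                    if far_enough(gene.chrom, center):
                        chrom = gene.chrom
                        intent = "promoter"
                        break
            else:
                for _ in range(10_000):
                    ci = int(rng.integers(0, len(genome.chroms)))
                    chrom, length = genome.chroms[ci]
                    center = int(
                        rng.integers(config.edge_margin, length - config.edge_margin)
                    )
                    clear = all(
                        not (lo <= center < hi) for lo, hi in forbidden[chrom]
                    )
                    if clear and far_enough(chrom, center):
                        break
                else:
                    raise ValueError("could not place intergenic sites; genome too crowded")
                intent = "intergenic"
            taken[chrom].append(center)
            placed.append(
                TruthSite(
                    chrom=chrom,
                    center=center,
                    true_class=cls,
                    enrichment_a=enr_a,
                    enrichment_b=enr_b,
                    category_intent=intent,
                    has_motif=i < n_motif,
                )
            )
        # decouple motif planting from promoter placement
        rng.shuffle(placed)
        for i, site in enumerate(placed):
            site.has_motif = i < n_motif
        sites.extend(placed)
    sites.sort(key=lambda s: (s.chrom, s.center))
    return sites


def _plant_motifs(genome: GenomeModel, sites: list[TruthSite], consensus: str) -> None:
    L = len(consensus)
    seqs = dict(genome.sequences)
    for site in sites:
        if not site.has_motif:
            continue
        seq = seqs[site.chrom]
        start = site.center - L // 2
        seqs[site.chrom] = seq[:start] + consensus + seq[start + L :]
    genome.sequences.update(seqs)


def _draw_reads(
    config: SimConfig,
    genome: GenomeModel,
    sites: list[TruthSite],
    condition: str,
    rng: np.random.Generator,
) -> list[tuple[str, int, int, str]]:
    depth = config.depth_a if condition == "A" else config.depth_b
    reads: list[tuple[str, int, int, str]] = []
    lengths = genome.lengths
    half_read = config.read_length // 2

    def emit(chrom: str, mid: int) -> None:
        length = lengths[chrom]
        mid = min(max(mid, 0), length - 1)
        start = max(0, mid - half_read)
        end = min(length, max(start + 1, mid + half_read))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append((chrom, start, end, strand))

    n_site_total = 0
    for site in sites:
        enr = site.enrichment_a if condition == "A" else site.enrichment_b
        n_i = int(rng.poisson(depth * config.background_rate * enr))
        n_site_total += n_i
        mids = site.center + rng.integers(
            -config.fragment_length, config.fragment_length + 1, n_i
        )
        for mid in mids:
            emit(site.chrom, int(mid))
    if n_site_total > depth:
        raise ValueError(
            "site reads exceed the configured depth; lower background_rate or site counts"
        )
    n_background = depth - n_site_total
    names = genome.names
    weights = np.array([lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    chosen = rng.choice(len(names), size=n_background, p=weights)
    for ci in chosen:
        chrom = names[ci]
        emit(chrom, int(rng.integers(0, lengths[chrom])))
    return reads


def _truth_peaks(
    config: SimConfig, sites: list[TruthSite], site_counts: dict[int, int]
) -> list[Peak]:
    peaks = []
    for i, site in enumerate(sites):
        if site_counts[i] >= config.min_peak_reads:
            peaks.append(
                Peak(chrom=site.chrom, start=site.center - 100, end=site.center + 100,
                     name=f"sim_{i + 1}")
            )
    return peaks


def simulate_two_condition_chip(
    genome: GenomeModel,
    genes: list[GeneModel],
    config: SimConfig,
    motif_consensus: str | None = DEFAULT_MOTIF_CONSENSUS,
):
    """Simulate reads, truth table and per-condition peaks.

    Returns ``(reads_a, reads_b, truth, peaks_a, peaks_b)`` where *truth*
    is a list of :class:`TruthSite`.  Per-condition peak lists contain
    ``center +/- 100`` intervals for sites whose drawn read count reached
    ``config.min_peak_reads``.  If *motif_consensus* is not None and the
    genome carries sequences, the consensus is substituted into the
    sequence at every ``has_motif`` site.
    """
    if motif_consensus is not None and genome.sequences is not None:
        if len(motif_consensus) > 2 * config.fragment_length:
            raise ValueError("motif longer than twice the fragment length")

    rngs = _rng_streams(config.seed, 5)
    rng_place, rng_a, rng_b = rngs[2], rngs[3], rngs[4]
    sites = _place_sites(config, genome, genes, rng_place)
    if motif_consensus is not None and genome.sequences is not None:
        _plant_motifs(genome, sites, motif_consensus.upper())

    # draw per-site counts first so peaks reflect the same realisation
    reads_a_list = _draw_reads(config, genome, sites, "A", rng_a)
    reads_b_list = _draw_reads(config, genome, sites, "B", rng_b)
    reads_a, reads_b = ReadSet(reads_a_list), ReadSet(reads_b_list)

    def realised_counts(reads: ReadSet) -> dict[int, int]:
        counts = {}
        for i, site in enumerate(sites):
            mids = reads.midpoints(site.chrom)
            lo = np.searchsorted(mids, site.center - config.fragment_length)
            hi = np.searchsorted(mids, site.center + config.fragment_length + 1)
            counts[i] = int(hi - lo)
        return counts

    peaks_a = _truth_peaks(config, sites, realised_counts(reads_a))
    peaks_b = _truth_peaks(config, sites, realised_counts(reads_b))
    return reads_a, reads_b, sites, peaks_a, peaks_b


def truth_table(sites: list[TruthSite]) -> pd.DataFrame:
    """Tab-friendly truth table; joins with pipeline output by (chrom, center)."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "center": s.center,
                "true_class": s.true_class,
                "enrichment_A": s.enrichment_a,
                "enrichment_B": s.enrichment_b,
                "category_intent": s.category_intent,
                "has_motif": s.has_motif,
            }
            for s in sites
        ]
    )
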