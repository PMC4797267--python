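"""Readers and writers for the on-disk formats used throughout the package,
plus the shared domain containers.

Coordinate conventions
----------------------
Everything is 0-based, half-open (BED-native).  UCSC refGene-flat dumps are
already in this frame, so ``txStart``/``txEnd`` and exon bounds are adopted
verbatim.  Parsers *reject* coordinate-order violations; they never repair
them silently.

Containers
----------
:class:`GenomeModel`
    Ordered chromosome names and lengths, optionally with sequences.  The
    coordinate frame every other object is validated against.
:class:`GeneModel`
    One transcript: strand, transcription/CDS bounds, exon structure.
:class:`Peak`
    An occupancy interval (one ChIP-seq peak).
:class:`ReadSet`
    Aligned-read intervals for one condition; ``depth`` is the total mapped
    read count used for depth normalisation.
:class:`PWM`
    A position count matrix over A/C/G/T with pseudocount and background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeModel",
    "GeneModel",
    "Peak",
    "ReadSet",
    "PWM",
    "ParseError",
    "read_chrom_sizes",
    "read_fasta",
    "read_gene_models",
    "write_gene_models",
    "read_bed_intervals",
    "read_peaks",
    "read_reads",
    "read_sam_reads",
    "write_bed",
    "write_fasta",
    "read_pwm",
]

ALPHABET = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class ParseError(ValueError):
    """Raised when an input file violates its format contract.

    The message names the offending file and line so the user can fix the
    input rather than guess.
    """


@dataclass
class GenomeModel:
    """Chromosome names/lengths and (optionally) their sequences."""

    chroms: list[tuple[str, int]]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in GenomeModel")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.sequences is not None:
            for name, length in self.chroms:
                seq = self.sequences.get(name)
                if seq is None:
                    raise ValueError(f"sequence missing for chromosome {name!r}")
                if len(seq) != length:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared length {length} for {name!r}"
                    )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chroms]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)

    def __len__(self) -> int:
        return len(self.chroms)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def sequence(self, chrom: str) -> str:
        if self.sequences is None:
            raise ValueError("GenomeModel carries no sequences")
        self.length(chrom)  # raises on unknown chrom
        return self.sequences[chrom]

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        """Validate a half-open interval against chromosome bounds."""
        length = self.length(chrom)
        if not (0 <= start < end <= length):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds [0, {length})"
            )


@dataclass
class GeneModel:
    """One transcript in refGene-flat coordinates (0-based half-open)."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name!r}: strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"gene {self.name!r}: txStart must be < txEnd")
        if not self.cds_start <= self.cds_end:
            raise ValueError(f"gene {self.name!r}: cdsStart must be <= cdsEnd")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"gene {self.name!r}: exon ({s},{e}) outside transcript bounds")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.name!r}: exons unsorted or overlapping")
            prev_end = e
        if self.is_coding:
            covered_start = any(s <= self.cds_start < e for s, e in self.exons)
            covered_end = any(s < self.cds_end <= e for s, e in self.exons)
            if not (covered_start and covered_end):
                raise ValueError(f"gene {self.name!r}: CDS bounds not covered by exons")

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def tss(self) -> int:
        """Transcription start: ``tx_start`` on +, ``tx_end`` on -."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tts(self) -> int:
        """Transcription termination: ``tx_end`` on +, ``tx_start`` on -."""
        return self.tx_end if self.strand == "+" else self.tx_start


@dataclass
class Peak:
    """An occupancy interval (half-open)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start must be < end")

    @property
    def center(self) -> int:
        """Floor of the interval midpoint (deterministic for even lengths)."""
        return (self.start + self.end) // 2


class ReadSet:
    """Aligned-read intervals for one condition.

    ``depth`` equals the number of reads held; per-chromosome sorted read
    midpoints are cached for fast window counting.
    """

    def __init__(self, reads: list[tuple[str, int, int, str]]):
        self.reads = reads
        self._midpoints: dict[str, np.ndarray] = {}

    @property
    def depth(self) -> int:
        return len(self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def midpoints(self, chrom: str) -> np.ndarray:
        """Sorted array of read midpoints (floor of (start+end)/2) on *chrom*."""
        if chrom not in self._midpoints:
            mids = np.array(
                [(s + e) // 2 for c, s, e, _ in self.reads if c == chrom], dtype=np.int64
            )
            mids.sort()
            self._midpoints[chrom] = mids
        return self._midpoints[chrom]

    def validate(self, genome: GenomeModel) -> None:
        for c, s, e, _ in self.reads:
            genome.check_interval(c, s, e)


@dataclass
class PWM:
    """Position count matrix with pseudocount-regularised log-odds scoring.

    ``counts`` is L x 4 over A,C,G,T.  Scoring (see :mod:`oxichip.motifs`)
    uses per-position frequencies ``(count + pseudocount) / (colsum + 4 *
    pseudocount)`` against ``background``, in log2.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.25
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("PWM counts must be an L x 4 matrix")
        if len(self) < 4:
            raise ValueError("PWM must be at least 4 positions long")
        if (self.counts < 0).any():
            raise ValueError("PWM counts must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if (self.background <= 0).any() or abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background must be strictly positive and sum to 1")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """Pseudocount-regularised per-position base frequencies (L x 4)."""
        num = self.counts + self.pseudocount
        return num / num.sum(axis=1, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 log2(frequency / background) score matrix."""
        return np.log2(self.frequencies / self.background)

    @property
    def max_score(self) -> float:
        """Best achievable log-odds score (consensus score)."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.log_odds.argmax(axis=1))


# ---------------------------------------------------------------------------
# chrom.sizes / FASTA
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> GenomeModel:
    """Read a two-column (name, length) chrom.sizes file into a GenomeModel."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: length {fields[1]!r} is not an integer") from None
            if length <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive length {length}")
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            chroms.append((name, length))
    return GenomeModel(chroms=chroms)


def read_fasta(path) -> GenomeModel:
    """Read a genome FASTA into a GenomeModel with sequences (uppercased)."""
    chroms: list[tuple[str, int]] = []
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        chroms.append((rec.id, len(seq)))
        sequences[rec.id] = seq
    return GenomeModel(chroms=chroms, sequences=sequences)


def write_fasta(genome: GenomeModel, path, width: int = 70) -> None:
    if genome.sequences is None:
        raise ValueError("GenomeModel carries no sequences to write")
    with open(path, "w") as fh:
        for name, _ in genome.chroms:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# refGene-flat gene models
# ---------------------------------------------------------------------------

_GENE_COLUMNS = (
    "name",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonStarts",
    "exonEnds",
)


def _parse_coord_list(text: str, path, lineno: int, label: str) -> list[int]:
    items = [t for t in text.strip().split(",") if t]
    try:
        return [int(t) for t in items]
    except ValueError:
        raise ParseError(f"{path}:{lineno}: malformed {label} list {text!r}") from None


def read_gene_models(path, genome: GenomeModel) -> tuple[list[GeneModel], int]:
    """Read a refGene-flat TSV (9 columns, comma-terminated exon lists).

    Genes on chromosomes absent from *genome* are excluded; the second
    return value counts them so callers can warn.
    """
    genes: list[GeneModel] = []
    skipped = 0
    known = set(genome.names)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_GENE_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(_GENE_COLUMNS)} tab-separated columns, "
                    f"got {len(fields)}"
                )
            name, chrom, strand = fields[0], fields[1], fields[2]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            try:
                tx_start, tx_end, cds_start, cds_end = (int(f) for f in fields[3:7])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from None
            starts = _parse_coord_list(fields[7], path, lineno, "exonStarts")
            ends = _parse_coord_list(fields[8], path, lineno, "exonEnds")
            if len(starts) != len(ends):
                raise ParseError(
                    f"{path}:{lineno}: exonStarts has {len(starts)} entries "
                    f"but exonEnds has {len(ends)}"
                )
            if chrom not in known:
                skipped += 1
                continue
            try:
                gene = GeneModel(
                    name=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    exons=list(zip(starts, ends)),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if tx_end > genome.length(chrom):
                raise ParseError(f"{path}:{lineno}: gene extends past end of {chrom}")
            genes.append(gene)
    if skipped:
        warnings.warn(f"{skipped} gene(s) on unknown chromosomes were excluded", stacklevel=2)
    return genes, skipped


def write_gene_models(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.name,
                        g.chrom,
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        str(g.cds_start),
                        str(g.cds_end),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED intervals: peaks and reads
# ---------------------------------------------------------------------------


def read_bed_intervals(path, genome: GenomeModel) -> list[tuple[str, int, int, str | None, float | None, str]]:
    """Parse BED3+ rows into (chrom, start, end, name, score, strand) tuples.

    Coordinates are validated against *genome* bounds; start >= end or
    out-of-bounds coordinates raise :class:`ParseError` naming the line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs at least 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            try:
                genome.check_interval(chrom, start, end)
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    return rows


def read_peaks(path, genome: GenomeModel) -> list[Peak]:
    """Read a peak BED into Peak objects."""
    return [
        Peak(chrom=c, start=s, end=e, name=n, score=sc)
        for c, s, e, n, sc, _ in read_bed_intervals(path, genome)
    ]


def read_reads(path, genome: GenomeModel) -> ReadSet:
    """Read an aligned-read BED into a ReadSet; depth = record count."""
    rows = read_bed_intervals(path, genome)
    return ReadSet(reads=[(c, s, e, strand) for c, s, e, _, _, strand in rows])


def read_sam_reads(path, genome: GenomeModel | None = None) -> ReadSet:
    """Thin SAM/BAM adapter: primary mapped records -> (chrom, start, end, strand).

    The analysis needs only positions and totals, so alignments are reduced
    to their reference intervals.
    """
    import pysam

    reads: list[tuple[str, int, int, str]] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            reads.append((aln.reference_name, aln.reference_start, aln.reference_end, strand))
    rs = ReadSet(reads=reads)
    if genome is not None:
        rs.validate(genome)
    return rs


def write_bed(items, path, header: str | None = None) -> None:
    """Write peaks or reads to BED.

    Accepts Peak objects or (chrom, start, end, strand) tuples.  Peak lists
    round-trip exactly through :func:`read_peaks`.
    """
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for item in items:
            if isinstance(item, Peak):
                name = item.name if item.name is not None else "."
                score = repr(item.score) if item.score is not None else "."
                fh.write(f"{item.chrom}\t{item.start}\t{item.end}\t{name}\t{score}\t.\n")
            else:
                c, s, e, strand = item
                fh.write(f"{c}\t{s}\t{e}\t.\t.\t{strand}\n")


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------


def read_pwm(path, pseudocount: float = 0.25, background=None) -> PWM:
    """Read a JASPAR-like 4-row count matrix (A, C, G, T rows).

    Accepts both bare whitespace-separated numeric rows and the JASPAR
    dialect (``>MA0000.0 NAME`` header, rows like ``A [ 3 12 0 ... ]``).
    """
    name = "pwm"
    rows: list[list[float]] = []
    row_labels: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                parts = line[1:].split()
                name = parts[-1] if parts else "pwm"
                continue
            label = None
            if line[0].upper() in "ACGT" and (len(line) == 1 or not line[1].isdigit()):
                label = line[0].upper()
                line = line[1:]
            body = line.replace("[", " ").replace("]", " ")
            try:
                values = [float(v) for v in body.split()]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric matrix entry") from None
            if not values:
                raise ParseError(f"{path}:{lineno}: empty matrix row")
            rows.append(values)
            row_labels.append(label if label else "ACGT"[len(rows) - 1])
    if len(rows) != 4:
        raise ParseError(f"{path}: expected 4 matrix rows (A, C, G, T), got {len(rows)}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ParseError(f"{path}: unequal matrix row lengths {sorted(lengths)}")
    order = {lab: i for i, lab in enumerate(row_labels)}
    if set(order) == set("ACGT"):
        rows = [rows[order[b]] for b in "ACGT"]
    counts = np.array(rows, dtype=float).T  # L x 4
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return PWM(name=name, counts=counts, pseudocount=pseudocount, background=bg)


def write_pwm(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for i, base in enumerate(ALPHABET):
            row = " ".join(f"{v:g}" for v in pwm.counts[:, i])
            fh.write(f"{base} [ {row} ]\n")
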