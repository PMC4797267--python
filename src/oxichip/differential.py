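"""Two-condition differential occupancy: the core computation.

For every evaluation site (the deduplicated union of peak centers from both
conditions) the reads falling in a fixed window around the center are
counted in each condition, depth-normalised to reads-per-ten-million, and
the site is classified:

* **induced**   — normalised treated/untreated fold >= ``fold_cut`` (default
  4) *and* exact-test p-value <= ``p_cut`` (default 1e-4);
* **repressed** — fold <= 1/``fold_cut`` and p <= ``p_cut``;
* **common**    — everything else.

Both thresholds are inclusive.  The significance test is the conditional
exact binomial: given ``n = count_A + count_B`` window reads, ``count_B`` is
binomial with success probability ``depth_B / (depth_A + depth_B)`` under
the null of equal per-depth occupancy — the standard exact comparison of
two Poisson counts.  It is symmetric under swapping the conditions and has
no tuning parameters.

The public surface is a model/results pair: build a
:class:`DifferentialOccupancy` from peak lists and read sets, call
:meth:`~DifferentialOccupancy.fit`, and read the classification off the
returned :class:`DifferentialOccupancyResults`.  The module-level functions
(:func:`window_count`, :func:`differential_pvalue`, :func:`fold_change`,
:func:`classify_site`, :func:`compare_conditions`) expose the individual
steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomeModel, Peak, ReadSet

__all__ = [
    "DiffParams",
    "SiteComparison",
    "DifferentialOccupancy",
    "DifferentialOccupancyResults",
    "window_count",
    "differential_pvalue",
    "fold_change",
    "classify_site",
    "compare_conditions",
]

SCALE = 1e7  # depth normalisation: reads per ten million mapped reads

LABELS = ("induced", "repressed", "common")


@dataclass
class DiffParams:
    """Thresholds of the classification rule.

    window : even window width in bp centred on the peak center (200)
    fold_cut : inclusive fold threshold on normalised signal (4)
    p_cut : inclusive p-value threshold (1e-4)
    pseudocount : added to both normalised signals before the ratio (1.0,
        in reads-per-ten-million units), making the fold total and bounded
    """

    window: int = 200
    fold_cut: float = 4.0
    p_cut: float = 1e-4
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % 2:
            raise ValueError("window must be even and > 0")
        if self.fold_cut <= 1:
            raise ValueError("fold_cut must be > 1")
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class SiteComparison:
    chrom: str
    center: int
    count_a: int
    count_b: int
    norm_a: float
    norm_b: float
    fold_change: float
    p_value: float
    label: str


def window_count(reads: ReadSet, chrom: str, center: int, window: int) -> int:
    """Number of reads whose midpoint lies in [center - w/2, center + w/2).

    Midpoint containment counts each read at most once per window and gives
    unambiguous half-open boundary semantics.
    """
    if window <= 0 or window % 2:
        raise ValueError("window must be even and > 0")
    mids = reads.midpoints(chrom)
    half = window // 2
    lo = np.searchsorted(mids, center - half, side="left")
    hi = np.searchsorted(mids, center + half, side="left")
    return int(hi - lo)


def differential_pvalue(count_a: int, count_b: int, depth_a: int, depth_b: int) -> float:
    """Two-sided conditional exact binomial p-value for a count pair.

    Tests ``count_b`` successes out of ``count_a + count_b`` trials against
    the depth-proportional expectation ``depth_b / (depth_a + depth_b)``.
    Returns 1.0 for an empty window (no evidence either way).
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("depths must be positive")
    n = count_a + count_b
    if n == 0:
        return 1.0
    p0 = depth_b / (depth_a + depth_b)
    return float(stats.binomtest(count_b, n, p0, alternative="two-sided").pvalue)


def fold_change(
    count_a: int, count_b: int, depth_a: int, depth_b: int, pseudocount: float = 1.0
) -> float:
    """Treated/untreated ratio of pseudocounted reads-per-ten-million signals."""
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("depths must be positive")
    norm_a = count_a * SCALE / depth_a
    norm_b = count_b * SCALE / depth_b
    return (norm_b + pseudocount) / (norm_a + pseudocount)


def classify_site(fold: float, p_value: float, params: DiffParams | None = None) -> str:
    """Apply the inclusive fold/p rule: induced, repressed, or common."""
    params = params or DiffParams()
    if p_value <= params.p_cut:
        if fold >= params.fold_cut:
            return "induced"
        if fold <= 1.0 / params.fold_cut:
            return "repressed"
    return "common"


def _merge_centers(
    centers: list[tuple[str, int]],
    counts: dict[tuple[str, int], int],
    min_sep: int,
) -> list[tuple[str, int]]:
    """Greedy dedup: keep the center with the larger summed window count,
    drop any center closer than *min_sep* to an already-kept one.

    Ties break on (chrom, center) so the result is deterministic.
    """
    order = sorted(centers, key=lambda c: (-counts[c], c[0], c[1]))
    kept: dict[str, list[int]] = {}
    result = []
    for chrom, center in order:
        near = kept.setdefault(chrom, [])
        if any(abs(center - k) < min_sep for k in near):
            continue
        near.append(center)
        result.append((chrom, center))
    result.sort()
    return result


class DifferentialOccupancy:
    """Model of differential ChIP occupancy between two conditions.

    Parameters
    ----------
    peaks_a, peaks_b
        Peak calls for the untreated (A) and treated (B) condition.  The
        evaluation sites are the union of their centers, deduplicated by
        greedy merging of centers closer than ``window/2``.
    reads_a, reads_b
        Aligned reads for each condition; ``depth`` normalises the signals.
    params
        :class:`DiffParams` thresholds.
    genome
        Optional :class:`GenomeModel`; when given, peak coordinates are
        validated against it.
    """

    def __init__(
        self,
        peaks_a: list[Peak],
        peaks_b: list[Peak],
        reads_a: ReadSet,
        reads_b: ReadSet,
        params: DiffParams | None = None,
        genome: GenomeModel | None = None,
    ):
        self.params = params or DiffParams()
        self.peaks_a = peaks_a
        self.peaks_b = peaks_b
        self.reads_a = reads_a
        self.reads_b = reads_b
        self.genome = genome
        if genome is not None:
            for p in [*peaks_a, *peaks_b]:
                genome.check_interval(p.chrom, p.start, p.end)
        if reads_a.depth == 0 or reads_b.depth == 0:
            raise ValueError("both read sets must be non-empty")

    def evaluation_sites(self) -> list[tuple[str, int]]:
        """Deduplicated union of peak centers, sorted by (chrom, center)."""
        w = self.params.window
        centers = []
        counts = {}
        for p in [*self.peaks_a, *self.peaks_b]:
            key = (p.chrom, p.center)
            if key not in counts:
                centers.append(key)
                counts[key] = window_count(self.reads_a, p.chrom, p.center, w) + window_count(
                    self.reads_b, p.chrom, p.center, w
                )
        return _merge_centers(centers, counts, min_sep=w // 2)

    def fit(self) -> "DifferentialOccupancyResults":
        """Count, test, and classify every evaluation site."""
        params = self.params
        depth_a, depth_b = self.reads_a.depth, self.reads_b.depth
        records = []
        for chrom, center in self.evaluation_sites():
            ca = window_count(self.reads_a, chrom, center, params.window)
            cb = window_count(self.reads_b, chrom, center, params.window)
            fold = fold_change(ca, cb, depth_a, depth_b, params.pseudocount)
            p = differential_pvalue(ca, cb, depth_a, depth_b)
            records.append(
                SiteComparison(
                    chrom=chrom,
                    center=center,
                    count_a=ca,
                    count_b=cb,
                    norm_a=ca * SCALE / depth_a,
                    norm_b=cb * SCALE / depth_b,
                    fold_change=fold,
                    p_value=p,
                    label=classify_site(fold, p, params),
                )
            )
        return DifferentialOccupancyResults(self, records)


class DifferentialOccupancyResults:
    """Classified sites with their fold changes, p-values, and summaries."""

    def __init__(self, model: DifferentialOccupancy, sites: list[SiteComparison]):
        self.model = model
        self.site_records = sites

    @property
    def sites(self) -> pd.DataFrame:
        """One row per evaluation site, sorted by (chrom, center)."""
        return pd.DataFrame(
            [
                {
                    "chrom": s.chrom,
                    "center": s.center,
                    "count_A": s.count_a,
                    "count_B": s.count_b,
                    "norm_A": s.norm_a,
                    "norm_B": s.norm_b,
                    "fold_change": s.fold_change,
                    "p_value": s.p_value,
                    "label": s.label,
                }
                for s in self.site_records
            ],
            columns=[
                "chrom",
                "center",
                "count_A",
                "count_B",
                "norm_A",
                "norm_B",
                "fold_change",
                "p_value",
                "label",
            ],
        )

    @property
    def n_sites(self) -> int:
        return len(self.site_records)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in LABELS}
        for s in self.site_records:
            counts[s.label] += 1
        return counts

    def volcano_table(self) -> pd.DataFrame:
        """log2 fold change vs -log10 p, the volcano plot's underlying table."""
        df = self.sites
        out = df[["chrom", "center", "label"]].copy()
        out["log2_fold"] = np.log2(df["fold_change"])
        with np.errstate(divide="ignore"):
            out["neg_log10_p"] = -np.log10(df["p_value"])
        return out

    def plot_volcano(self, ax=None):
        """Scatter the volcano table; induced blue, repressed green, common red."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"induced": "tab:blue", "repressed": "tab:green", "common": "tab:red"}
        table = self.volcano_table()
        for label, sub in table.groupby("label"):
            ax.scatter(sub["log2_fold"], sub["neg_log10_p"], s=8, label=label,
                       color=colors.get(label, "gray"), alpha=0.6)
        ax.axvline(np.log2(self.model.params.fold_cut), ls="--", lw=0.5, c="k")
        ax.axvline(-np.log2(self.model.params.fold_cut), ls="--", lw=0.5, c="k")
        ax.axhline(-np.log10(self.model.params.p_cut), ls="--", lw=0.5, c="k")
        ax.set_xlabel("log2 fold change (treated / untreated)")
        ax.set_ylabel("-log10 p")
        ax.legend()
        return ax

    def summary(self) -> str:
        counts = self.class_counts
        p = self.model.params
        depth_a, depth_b = self.model.reads_a.depth, self.model.reads_b.depth
        lines = [
            "Differential occupancy summary",
            "==============================",
            f"evaluation sites : {self.n_sites}",
            f"window           : {p.window} bp around peak center",
            f"thresholds       : fold >= {p.fold_cut} (or <= {1 / p.fold_cut:.4g}), "
            f"p <= {p.p_cut} (both inclusive)",
            f"depths (A, B)    : {depth_a}, {depth_b} mapped reads",
            f"induced          : {counts['induced']}",
            f"repressed        : {counts['repressed']}",
            f"common           : {counts['common']}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        counts = self.class_counts
        with open(path, "w") as fh:
            fh.write(
                "# differential occupancy: window={} fold_cut={} p_cut={}\n".format(
                    self.model.params.window, self.model.params.fold_cut, self.model.params.p_cut
                )
            )
            fh.write(
                "# summary: sites={} induced={} repressed={} common={}\n".format(
                    self.n_sites, counts["induced"], counts["repressed"], counts["common"]
                )
            )
            self.sites.to_csv(fh, sep="\t", index=False)


def compare_conditions(
    peaks_a: list[Peak],
    peaks_b: list[Peak],
    reads_a: ReadSet,
    reads_b: ReadSet,
    params: DiffParams | None = None,
    genome: GenomeModel | None = None,
) -> DifferentialOccupancyResults:
    """Convenience wrapper: build the model and fit it in one call."""
    return DifferentialOccupancy(peaks_a, peaks_b, reads_a, reads_b, params, genome).fit()
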