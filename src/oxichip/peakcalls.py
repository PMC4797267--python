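"""Minimal sliding-window peak caller and peak-center utilities.

This caller exists so the pipeline runs end-to-end on simulated data when
no external peak list is supplied.  It is an explicitly simple
approximation — fixed windows scored by a Poisson upper tail against the
depth-scaled control expectation, Benjamini-Hochberg across windows, and a
fold-over-input filter — not a reimplementation of a production caller.
Real analyses should supply externally called peak BEDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GenomeModel, Peak, ReadSet

__all__ = ["CallerParams", "call_peaks", "peak_center"]


@dataclass
class CallerParams:
    window: int = 200
    step: int = 50
    fdr_alpha: float = 0.001
    min_fold_over_input: float = 4.0

    def __post_init__(self) -> None:
        if not self.window >= self.step > 0:
            raise ValueError("require window >= step > 0")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.min_fold_over_input <= 0:
            raise ValueError("min_fold_over_input must be > 0")


def peak_center(peak: Peak) -> int:
    """Floor of the interval midpoint."""
    return peak.center


def call_peaks(
    chip: ReadSet,
    control: ReadSet,
    genome: GenomeModel,
    params: CallerParams | None = None,
) -> list[Peak]:
    """Call enriched windows of *chip* over *control* and merge them.

    Window counts use read midpoints.  The null expectation per window is
    the depth-scaled control count, floored at the genome-wide chip rate so
    zero-control windows still have a proper Poisson null.  Significance is
    Poisson upper-tail with BH control at ``fdr_alpha``; windows must also
    exceed ``min_fold_over_input`` over their expectation.  Overlapping
    significant windows merge into one peak scored by the best window's
    -log10 q.
    """
    params = params or CallerParams()
    if chip.depth == 0:
        raise ValueError("empty chip read set")
    if control.depth == 0:
        raise ValueError("control read set has depth 0")

    ratio = chip.depth / control.depth
    global_rate = chip.depth / genome.total_length  # reads per base

    all_windows = []  # (chrom, start, count, expected)
    for chrom, length in genome.chroms:
        if length < params.window:
            continue
        starts = np.arange(0, length - params.window + 1, params.step)
        chip_mids = chip.midpoints(chrom)
        ctrl_mids = control.midpoints(chrom)
        counts = np.searchsorted(chip_mids, starts + params.window) - np.searchsorted(
            chip_mids, starts
        )
        ctrl = np.searchsorted(ctrl_mids, starts + params.window) - np.searchsorted(
            ctrl_mids, starts
        )
        expected = np.maximum(ctrl * ratio, global_rate * params.window)
        all_windows.append((chrom, starts, counts, expected))

    if not all_windows:
        return []

    pvals = np.concatenate(
        [stats.poisson.sf(c - 1, e) for _, _, c, e in all_windows]
    )
    qvals = stats.false_discovery_control(pvals, method="bh")

    peaks: list[Peak] = []
    offset = 0
    for chrom, starts, counts, expected in all_windows:
        q = qvals[offset : offset + len(starts)]
        offset += len(starts)
        fold = counts / np.maximum(expected, 1e-300)
        keep = (q <= params.fdr_alpha) & (fold >= params.min_fold_over_input)
        # merge overlapping/adjacent significant windows
        open_start = None
        open_end = None
        best_q = 1.0
        for s, flag, qi in zip(starts, keep, q):
            if not flag:
                continue
            e = int(s) + params.window
            if open_start is not None and s <= open_end:
                open_end = max(open_end, e)
                best_q = min(best_q, qi)
            else:
                if open_start is not None:
                    peaks.append(_finish_peak(chrom, open_start, open_end, best_q, len(peaks)))
                open_start, open_end, best_q = int(s), e, qi
        if open_start is not None:
            peaks.append(_finish_peak(chrom, open_start, open_end, best_q, len(peaks)))
    return peaks


def _finish_peak(chrom: str, start: int, end: int, q: float, index: int) -> Peak:
    score = float(min(300.0, -np.log10(max(q, 1e-300))))
    return Peak(chrom=chrom, start=start, end=end, name=f"peak_{index + 1}", score=score)
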