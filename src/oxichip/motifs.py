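"""PWM motif scanning and per-class motif-occurrence fractions.

A site is motif-positive when the best log-odds score over both strands of
the window around its center reaches ``threshold_fraction`` of the PWM's
maximum achievable score (default 0.8).  The headline readout is the
fraction of motif-positive sites per class (induced / repressed / common),
compared against an empirical background: the motif-positive fraction of
randomly sampled genome windows of the same width.

Scoring: per position, log2 of the pseudocount-regularised base frequency
over the background frequency, summed along the motif.  ``N`` bases score
as background (contribute 0).  The reverse strand is scored on the reverse
complement, so scanning is strand-symmetric by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import _BASE_INDEX, PWM, GenomeModel

__all__ = [
    "MotifScanParams",
    "best_log_odds",
    "site_has_motif",
    "motif_fraction_report",
    "encode_sequence",
]

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


@dataclass
class MotifScanParams:
    """Knobs of the motif scan.

    threshold_fraction : fraction of the maximum achievable log-odds score
        required to call a hit, in (0, 1] (0.8)
    scan_window : even window width (bp) around the site center (200)
    background_samples : random genome windows used to estimate the
        background motif rate (10000)
    seed : RNG seed for background sampling
    """

    threshold_fraction: float = 0.8
    scan_window: int = 200
    background_samples: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must be in [0, 1]")
        if self.scan_window <= 0 or self.scan_window % 2:
            raise ValueError("scan_window must be even and > 0")
        if self.background_samples < 0:
            raise ValueError("background_samples must be >= 0")


def encode_sequence(sequence: str) -> np.ndarray:
    """Map A/C/G/T/N (case-insensitive) to indices 0..4."""
    try:
        return np.array([_BASE_INDEX[b] for b in sequence.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGTN character {exc.args[0]!r} in sequence") from None


def _score_matrix(pwm: PWM) -> np.ndarray:
    """L x 5 log-odds matrix; the 5th column (N) contributes 0."""
    lo = pwm.log_odds
    return np.hstack([lo, np.zeros((len(pwm), 1))])


def _best_scores_batch(pwm: PWM, windows: np.ndarray) -> np.ndarray:
    """Best double-strand score per window for an (B, W) index matrix."""
    mat = _score_matrix(pwm)
    L = len(pwm)
    if windows.shape[1] < L:
        raise ValueError("sequence shorter than motif")
    pos = np.arange(L)

    def strand_best(idx: np.ndarray) -> np.ndarray:
        sw = np.lib.stride_tricks.sliding_window_view(idx, L, axis=1)  # (B, O, L)
        scores = mat[pos[None, None, :], sw].sum(axis=2)
        return scores.max(axis=1)

    fwd = strand_best(windows)
    rev = strand_best(_COMPLEMENT[windows][:, ::-1])
    return np.maximum(fwd, rev)


def best_log_odds(pwm: PWM, sequence: str) -> float:
    """Maximum log-odds score over both strands and all offsets.

    Raises if the sequence is shorter than the motif.
    """
    idx = encode_sequence(sequence)
    if idx.size < len(pwm):
        raise ValueError(
            f"sequence of length {idx.size} shorter than motif of length {len(pwm)}"
        )
    return float(_best_scores_batch(pwm, idx[None, :])[0])


def site_has_motif(
    pwm: PWM, genome: GenomeModel, chrom: str, center: int, params: MotifScanParams | None = None
) -> bool:
    """True iff the window around *center* scores >= threshold * max score.

    Windows running past a chromosome end are truncated to the bounds; only
    if the remaining stretch is shorter than the motif is this an error.
    """
    params = params or MotifScanParams()
    seq = genome.sequence(chrom)
    half = params.scan_window // 2
    lo = max(0, center - half)
    hi = min(len(seq), center + half)
    window = seq[lo:hi]
    if len(window) < len(pwm):
        raise ValueError(
            f"window {chrom}:{lo}-{hi} shorter than motif after truncation to bounds"
        )
    if params.threshold_fraction == 0:  # degenerate: every window is a hit
        return True
    return best_log_odds(pwm, window) >= params.threshold_fraction * pwm.max_score


def _sample_background_windows(
    genome: GenomeModel, width: int, n: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """(chrom, start) of n random windows, chromosomes weighted by length."""
    usable = [(name, length) for name, length in genome.chroms if length >= width]
    if not usable:
        raise ValueError("no chromosome long enough for the scan window")
    names = [u[0] for u in usable]
    weights = np.array([u[1] - width + 1 for u in usable], dtype=float)
    weights /= weights.sum()
    chosen = rng.choice(len(usable), size=n, p=weights)
    return [
        (names[i], int(rng.integers(0, usable[i][1] - width + 1))) for i in chosen
    ]


def background_motif_fraction(
    pwm: PWM, genome: GenomeModel, params: MotifScanParams | None = None
) -> float:
    """Fraction of random same-width genome windows that are motif-positive."""
    params = params or MotifScanParams()
    if params.threshold_fraction == 0:
        return 1.0
    rng = np.random.default_rng(params.seed)
    spots = _sample_background_windows(genome, params.scan_window, params.background_samples, rng)
    cutoff = params.threshold_fraction * pwm.max_score
    hits = 0
    chunk = 1000
    for i in range(0, len(spots), chunk):
        batch = spots[i : i + chunk]
        windows = np.stack(
            [
                encode_sequence(genome.sequence(c)[s : s + params.scan_window])
                for c, s in batch
            ]
        )
        hits += int((_best_scores_batch(pwm, windows) >= cutoff).sum())
    return hits / len(spots) if spots else 0.0


def motif_fraction_report(
    sites,
    pwm: PWM,
    genome: GenomeModel,
    params: MotifScanParams | None = None,
) -> pd.DataFrame:
    """Motif-positive fraction per site class, with background and fold.

    *sites* is a DataFrame with ``chrom``/``center`` (and optionally
    ``label``) columns, or a list of objects with those attributes.  Output
    columns: class, n, n_motif, fraction, background_fraction, fold; one
    row per class plus an ``all`` row.  A zero background makes the fold
    infinite and emits a warning.
    """
    params = params or MotifScanParams()
    if isinstance(sites, pd.DataFrame):
        rows = [
            (r.chrom, int(r.center), getattr(r, "label", "all"))
            for r in sites.itertuples(index=False)
        ]
    else:
        rows = [(s.chrom, int(s.center), getattr(s, "label", "all")) for s in sites]
    if not rows:
        raise ValueError("empty site list")

    flags = [site_has_motif(pwm, genome, c, pos, params) for c, pos, _ in rows]
    bg = background_motif_fraction(pwm, genome, params)

    per_class: dict[str, list[bool]] = {"all": []}
    for (c, pos, lab), flag in zip(rows, flags):
        per_class["all"].append(flag)
        if lab != "all":
            per_class.setdefault(lab, []).append(flag)

    out = []
    for label, hits in per_class.items():
        n, n_motif = len(hits), int(sum(hits))
        fraction = n_motif / n
        if bg > 0:
            fold = fraction / bg
        else:
            warnings.warn("background motif fraction is 0; fold reported as inf", stacklevel=2)
            fold = float("inf")
        out.append(
            {"class": label, "n": n, "n_motif": n_motif, "fraction": fraction,
             "background_fraction": bg, "fold": fold}
        )
    return pd.DataFrame(out)
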