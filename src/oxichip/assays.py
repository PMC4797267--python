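"""Bench-assay quantification: chromatin co-fractionation, survival, and
paired significance testing for ChIP-qPCR enrichment.

``chromatin_fraction_percent`` implements the fractionation readout: CSB
band intensities in the chromatin ('C') and soluble ('S') fractions are
first normalised to a loading control (BRG1), then the chromatin-bound
percentage is ``100 * nC / (nC + nS * f)`` where ``f`` corrects for the
chromatin fraction being more concentrated than the soluble one (default
1.3, a property of the extraction volumes; expose it when the protocol
differs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FractionationMeasurement",
    "chromatin_fraction_percent",
    "percent_survival",
    "paired_t_test",
    "significance_stars",
]


@dataclass
class FractionationMeasurement:
    """Band intensities for one fractionation western (arbitrary units)."""

    csb_c: float
    csb_s: float
    brg1_c: float
    brg1_s: float
    concentration_factor: float = 1.3

    def __post_init__(self) -> None:
        if self.csb_c < 0 or self.csb_s < 0:
            raise ValueError("band intensities must be non-negative")
        if self.brg1_c <= 0 or self.brg1_s <= 0:
            raise ValueError("loading-control intensities must be positive")
        if self.concentration_factor <= 0:
            raise ValueError("concentration_factor must be positive")


def chromatin_fraction_percent(m: FractionationMeasurement) -> float:
    """Percent of the protein co-fractionating with chromatin.

    Scale-invariant: multiplying all four intensities by any c > 0 leaves
    the result unchanged.
    """
    n_c = m.csb_c / m.brg1_c
    n_s = m.csb_s / m.brg1_s
    denom = n_c + n_s * m.concentration_factor
    if denom == 0:
        raise ValueError("both normalised signals are zero; fraction undefined")
    return 100.0 * n_c / denom


def percent_survival(treated_viable: float, untreated_viable: float) -> float:
    """100 x ratio of viable treated to viable untreated cells."""
    if untreated_viable <= 0:
        raise ValueError("untreated viable count must be positive")
    if treated_viable < 0:
        raise ValueError("treated viable count must be non-negative")
    return 100.0 * treated_viable / untreated_viable


def paired_t_test(x, y) -> tuple[float, float]:
    """Paired t statistic and two-sided p (t distribution, n-1 df).

    Degenerate inputs: identical pairs give (0.0, 1.0); zero-variance
    differences with a nonzero mean give (signed inf, 0.0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        warnings.warn(
            "zero-variance nonzero differences: t is infinite, p reported as 0",
            stacklevel=2,
        )
        return float(np.sign(d[0]) * np.inf), 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Conventional significance stars: * <0.05, ** <0.01, *** <0.001."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
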