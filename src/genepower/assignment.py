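"""Rules for assigning intergenic SNPs to a gene.

Two rules are implemented: the plain window rule (extend the gene's start
and stop by ``w`` kb and take every SNP inside) and the hybrid window+LD rule
(all intragenic SNPs, plus intergenic SNPs inside the window whose maximum
squared correlation with any intragenic SNP strictly exceeds a threshold,
0.7 by convention).  Coordinates are 1-based with inclusive boundaries; a
single-gene context is assumed (no nearest-gene competition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .settests import LDMatrix

__all__ = ["GenomicInterval", "SelectionRule", "select_by_window", "select_by_ld"]


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive [start, stop] in base pairs."""

    start: int
    stop: int

    def __post_init__(self):
        if self.start > self.stop:
            raise ParameterError("interval start must not exceed stop")

    def contains(self, positions) -> np.ndarray:
        positions = np.asarray(positions)
        return (positions >= self.start) & (positions <= self.stop)


@dataclass(frozen=True)
class SelectionRule:
    """kind='window' for the plain rule, 'ld_window' for window + r^2 filter."""

    kind: str
    window_kb: float
    r2_threshold: float | None = None

    def __post_init__(self):
        if self.kind not in ("window", "ld_window"):
            raise ParameterError("rule kind must be 'window' or 'ld_window'")
        if self.window_kb < 0:
            raise ParameterError("window_kb must be non-negative")
        if self.kind == "ld_window":
            if self.r2_threshold is None or not 0.0 < self.r2_threshold < 1.0:
                raise ParameterError("r2_threshold must lie in (0, 1)")


def select_by_window(positions, gene: GenomicInterval, window_kb: float) -> np.ndarray:
    """Indices of SNPs within ``window_kb`` kb of the gene (window 0 =
    intragenic SNPs only)."""
    if window_kb < 0:
        raise ParameterError("window_kb must be non-negative")
    positions = np.asarray(positions)
    pad = 1000.0 * window_kb
    widened = GenomicInterval(int(np.floor(gene.start - pad)),
                              int(np.ceil(gene.stop + pad)))
    return np.flatnonzero(widened.contains(positions))


def select_by_ld(positions, ld: LDMatrix, gene: GenomicInterval,
                 rule: SelectionRule) -> np.ndarray:
    """All intragenic SNPs plus windowed intergenic SNPs in LD with the gene.

    An intergenic SNP qualifies when its maximum r^2 against any intragenic
    SNP strictly exceeds ``rule.r2_threshold``; LD chains through other
    intergenic SNPs do not count.
    """
    positions = np.asarray(positions)
    if ld.r.shape[0] != positions.shape[0]:
        raise ParameterError("LD matrix and positions vector dimensions differ")
    intragenic = np.flatnonzero(gene.contains(positions))
    windowed = select_by_window(positions, gene, rule.window_kb)
    candidates = np.setdiff1d(windowed, intragenic)
    if intragenic.size == 0 or candidates.size == 0:
        return intragenic
    max_r2 = ld.r2[np.ix_(candidates, intragenic)].max(axis=1)
    threshold = rule.r2_threshold if rule.r2_threshold is not None else 0.7
    chosen = candidates[max_r2 > threshold]
    return np.sort(np.concatenate([intragenic, chosen]))
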