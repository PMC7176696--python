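"""Genetic maps: monotone bp -> cM mapping with linear interpolation.

A genetic map anchors physical positions (bp) to genetic positions (cM) per
chromosome.  Queries between anchors are linearly interpolated; queries
outside the anchored range clamp to the terminal cM value so telomeric
segments cannot acquire negative or inflated genetic lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .segments import IBDSegment, normalize_chrom

__all__ = ["GeneticMap"]


@dataclass
class GeneticMap:
    """Per-chromosome (bp, cM) anchor lists with linear interpolation.

    ``anchors`` maps a chromosome label to a pair of equal-length arrays
    ``(bp, cM)``; bp strictly increasing, cM non-decreasing.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_chromosome(self, chrom: str, bp: np.ndarray, cM: np.ndarray) -> None:
        chrom = normalize_chrom(chrom)
        bp = np.asarray(bp, dtype=float)
        cM = np.asarray(cM, dtype=float)
        if bp.shape != cM.shape or bp.ndim != 1 or bp.size == 0:
            raise ValueError(f"chromosome {chrom}: need equal-length 1-d anchor arrays")
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"chromosome {chrom}: bp positions not strictly increasing")
        if np.any(np.diff(cM) < 0):
            raise ValueError(f"chromosome {chrom}: cM positions decrease")
        self.anchors[chrom] = (bp, cM)

    @classmethod
    def from_anchors(
        cls, anchors: Mapping[str, tuple[np.ndarray, np.ndarray]]
    ) -> "GeneticMap":
        m = cls()
        for chrom, (bp, cM) in anchors.items():
            m.add_chromosome(chrom, bp, cM)
        return m

    @classmethod
    def uniform(cls, spans: Mapping[str, tuple[float, float]]) -> "GeneticMap":
        """Linear map per chromosome from ``{chrom: (bp_span, cM_span)}``.

        Anchors (1, 0 cM) and (bp_span, cM_span): constant recombination rate.
        """
        m = cls()
        for chrom, (bp_span, cM_span) in spans.items():
            m.add_chromosome(chrom, np.array([1.0, float(bp_span)]), np.array([0.0, float(cM_span)]))
        return m

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    def interpolate(self, chrom: str, bp) -> float | np.ndarray:
        """cM position of ``bp`` on ``chrom``; out-of-range queries clamp."""
        chrom = normalize_chrom(chrom)
        try:
            xs, ys = self.anchors[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genetic map") from None
        out = np.interp(bp, xs, ys)  # np.interp clamps at both ends
        return float(out) if np.isscalar(bp) or np.ndim(bp) == 0 else out

    def bp_at(self, chrom: str, cM) -> float | np.ndarray:
        """Inverse query: physical position at genetic position ``cM``.

        Only meaningful where the map is strictly increasing in cM.
        """
        chrom = normalize_chrom(chrom)
        xs, ys = self.anchors[chrom]
        out = np.interp(cM, ys, xs)
        return float(out) if np.isscalar(cM) or np.ndim(cM) == 0 else out

    def segment_length(self, segment: IBDSegment) -> float:
        """Genetic length of a segment: cM(end) - cM(start) >= 0."""
        return float(
            self.interpolate(segment.chrom, segment.end_bp)
            - self.interpolate(segment.chrom, segment.start_bp)
        )

    def chrom_length_cM(self, chrom: str) -> float:
        xs, ys = self.anchors[normalize_chrom(chrom)]
        return float(ys[-1] - ys[0])
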