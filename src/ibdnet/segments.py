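"""Core segment and region types.

An IBD (identity-by-descent) segment is a stretch of genome two individuals
co-inherited from a recent common ancestor.  Detectors report one row per
shared haplotype pair with genomic coordinates, a genetic length in
centimorgans (cM) and a LOD-like confidence score.

Coordinates are 1-based inclusive throughout the package; BED input (0-based
half-open) is converted on read.  Chromosome labels are normalised by
stripping a leading ``chr`` so mixed-source inputs compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

__all__ = ["IBDSegment", "ExclusionRegion", "normalize_chrom", "pair_key", "segments_overlap"]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix from a chromosome label."""
    chrom = str(chrom)
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True, slots=True)
class IBDSegment:
    """One detected IBD segment between two individuals.

    Parameters
    ----------
    sample_a, sample_b
        Identifiers of the two individuals; must differ.
    hap_a, hap_b
        Haplotype index of the shared haplotype in each individual:
        1 or 2, or 0 when unknown/unphased.
    chrom
        Chromosome label (``chr`` prefix stripped).
    start_bp, end_bp
        1-based inclusive physical coordinates, ``start_bp <= end_bp``.
    length_cM
        Genetic length in centimorgans, non-negative.
    score
        Detector confidence (LOD-like), arbitrary real.
    n_snps
        Optional marker support count for the segment.
    """

    sample_a: str
    hap_a: int
    sample_b: str
    hap_b: int
    chrom: str
    start_bp: int
    end_bp: int
    score: float
    length_cM: float
    n_snps: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.sample_a == self.sample_b:
            raise ValueError(f"segment joins {self.sample_a!r} to itself")
        if self.start_bp > self.end_bp:
            raise ValueError(f"start_bp {self.start_bp} > end_bp {self.end_bp}")
        if self.length_cM < 0:
            raise ValueError(f"negative length_cM {self.length_cM}")
        for h in (self.hap_a, self.hap_b):
            if h not in (0, 1, 2):
                raise ValueError(f"haplotype index {h} not in {{0,1,2}}")

    @property
    def samples(self) -> frozenset[str]:
        return frozenset((self.sample_a, self.sample_b))

    def hap_of(self, sample: str) -> int:
        if sample == self.sample_a:
            return self.hap_a
        if sample == self.sample_b:
            return self.hap_b
        raise KeyError(sample)

    def key(self) -> str:
        """Stable identifier used in QC reports and planted-truth records."""
        a, b = sorted((self.sample_a, self.sample_b))
        return f"{a}|{b}|{self.chrom}:{self.start_bp}-{self.end_bp}"

    def with_length(self, length_cM: float) -> "IBDSegment":
        return replace(self, length_cM=length_cM)


def pair_key(segment: IBDSegment) -> tuple[str, str]:
    """Unordered individual pair as a sorted tuple."""
    return tuple(sorted((segment.sample_a, segment.sample_b)))  # type: ignore[return-value]


def segments_overlap(a: IBDSegment, b: IBDSegment) -> bool:
    """True when two segments share >= 1 bp on the same chromosome."""
    return a.chrom == b.chrom and max(a.start_bp, b.start_bp) <= min(a.end_bp, b.end_bp)


@dataclass(frozen=True, slots=True)
class ExclusionRegion:
    """A genomic interval to exclude (centromere, telomere, ...).

    Stored 1-based inclusive after input conversion.
    """

    chrom: str
    start_bp: int
    end_bp: int
    kind: Literal["centromere", "telomere", "other"] = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start_bp > self.end_bp:
            raise ValueError(f"start_bp {self.start_bp} > end_bp {self.end_bp}")

    def overlaps(self, segment: IBDSegment) -> bool:
        return self.chrom == segment.chrom and max(
            self.start_bp, segment.start_bp
        ) <= min(self.end_bp, segment.end_bp)
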