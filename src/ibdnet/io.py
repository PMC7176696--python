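"""Readers and writers for the package's tabular formats.

Supported inputs: Refined-IBD-style segment TSV (9 whitespace/tab separated
columns: sample1, hap1, sample2, hap2, chrom, start bp, end bp, LOD score,
length cM), two-column population tables, genetic maps (plain ``chrom bp cM``
or HapMap-style ``chrom pos rate cM``) and BED exclusion regions.

The segment column layout is a declared dialect, never sniffed: silently
mis-parsing haplotype columns would corrupt triangulation typologies
downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .genmap import GeneticMap
from .populations import PopulationTable
from .segments import ExclusionRegion, IBDSegment, normalize_chrom

__all__ = [
    "SegmentDialect",
    "REFINED_IBD",
    "read_ibd_segments",
    "write_segments",
    "read_population_table",
    "read_genetic_map",
    "read_bed_regions",
]


class ParseError(ValueError):
    """Raised for malformed input rows; message names the offending line."""


@dataclass(frozen=True)
class SegmentDialect:
    """Column positions (0-based) of the segment fields in a TSV row."""

    name: str = "refined-ibd"
    sample_a: int = 0
    hap_a: int = 1
    sample_b: int = 2
    hap_b: int = 3
    chrom: int = 4
    start_bp: int = 5
    end_bp: int = 6
    score: int = 7
    length_cM: int = 8
    n_snps: int | None = None

    @property
    def min_columns(self) -> int:
        cols = [self.sample_a, self.hap_a, self.sample_b, self.hap_b, self.chrom,
                self.start_bp, self.end_bp, self.score, self.length_cM]
        if self.n_snps is not None:
            cols.append(self.n_snps)
        return max(cols) + 1


REFINED_IBD = SegmentDialect()

_DIALECTS = {"refined-ibd": REFINED_IBD}


def resolve_dialect(dialect: SegmentDialect | str) -> SegmentDialect:
    if isinstance(dialect, SegmentDialect):
        return dialect
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown segment dialect {dialect!r}; known: {sorted(_DIALECTS)}"
        ) from None


def read_ibd_segments(
    path: str | Path, dialect: SegmentDialect | str = REFINED_IBD
) -> list[IBDSegment]:
    """Read a segment TSV into a list of :class:`IBDSegment`.

    Rows are whitespace- or tab-separated with at least ``dialect.min_columns``
    fields.  Malformed rows raise :class:`ParseError` naming the line number.
    """
    d = resolve_dialect(dialect)
    segments: list[IBDSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < d.min_columns:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {d.min_columns} columns, got {len(fields)}"
                )
            try:
                seg = IBDSegment(
                    sample_a=fields[d.sample_a],
                    hap_a=int(fields[d.hap_a]),
                    sample_b=fields[d.sample_b],
                    hap_b=int(fields[d.hap_b]),
                    chrom=fields[d.chrom],
                    start_bp=int(fields[d.start_bp]),
                    end_bp=int(fields[d.end_bp]),
                    score=float(fields[d.score]),
                    length_cM=float(fields[d.length_cM]),
                    n_snps=int(fields[d.n_snps]) if d.n_snps is not None else None,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            segments.append(seg)
    return segments


def write_segments(
    segments: Iterable[IBDSegment],
    path: str | Path,
    dialect: SegmentDialect | str = REFINED_IBD,
) -> None:
    """Write segments in the dialect's column order (round-trips with the reader)."""
    d = resolve_dialect(dialect)
    ncols = d.min_columns
    with open(path, "w") as fh:
        for seg in segments:
            row = [""] * ncols
            row[d.sample_a] = seg.sample_a
            row[d.hap_a] = str(seg.hap_a)
            row[d.sample_b] = seg.sample_b
            row[d.hap_b] = str(seg.hap_b)
            row[d.chrom] = seg.chrom
            row[d.start_bp] = str(seg.start_bp)
            row[d.end_bp] = str(seg.end_bp)
            row[d.score] = repr(seg.score)
            row[d.length_cM] = repr(seg.length_cM)
            if d.n_snps is not None:
                row[d.n_snps] = str(seg.n_snps if seg.n_snps is not None else 0)
            fh.write("\t".join(row) + "\n")


def read_population_table(path: str | Path) -> PopulationTable:
    """Read a two-column TSV (individual, population) into a PopulationTable."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            pairs.append((fields[0], fields[1]))
    return PopulationTable.from_pairs(pairs)


def read_genetic_map(
    path: str | Path, format: Literal["plain", "hapmap"] = "plain"
) -> GeneticMap:
    """Read a genetic map.

    ``plain``: three columns ``chrom bp cM``.  ``hapmap``: four columns
    ``chrom pos rate cM`` (the rate column is ignored).  A header line whose
    position column is non-numeric is skipped.  Positions must be sorted per
    chromosome; decreasing cM or unsorted bp raise an error.
    """
    if format not in ("plain", "hapmap"):
        raise ValueError(f"unknown genetic map format {format!r}")
    bp_col, cm_col = (1, 2) if format == "plain" else (1, 3)
    per_chrom: dict[str, tuple[list[float], list[float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) <= max(bp_col, cm_col):
                raise ParseError(f"{path}:{lineno}: too few columns")
            try:
                bp = float(fields[bp_col])
                cm = float(fields[cm_col])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric map position") from None
            chrom = normalize_chrom(fields[0])
            per_chrom.setdefault(chrom, ([], []))[0].append(bp)
            per_chrom[chrom][1].append(cm)
    gmap = GeneticMap()
    for chrom, (bps, cms) in per_chrom.items():
        gmap.add_chromosome(chrom, np.array(bps), np.array(cms))  # validates order
    return gmap


def read_bed_regions(
    path: str | Path, kind: Literal["centromere", "telomere", "other"] = "other"
) -> list[ExclusionRegion]:
    """Read BED (0-based half-open) into 1-based inclusive exclusion regions.

    A BED interval ``[start, end)`` becomes ``start+1 .. end`` inclusive.
    An optional 4th column naming the kind (centromere/telomere) overrides
    the ``kind`` argument.
    """
    regions: list[ExclusionRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith(("#", "track", "browser")):
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinate") from None
            if start0 >= end0:
                raise ParseError(f"{path}:{lineno}: empty or inverted BED interval")
            row_kind = kind
            if len(fields) >= 4 and fields[3] in ("centromere", "telomere", "other"):
                row_kind = fields[3]  # type: ignore[assignment]
            regions.append(
                ExclusionRegion(chrom=fields[0], start_bp=start0 + 1, end_bp=end0, kind=row_kind)
            )
    return regions
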