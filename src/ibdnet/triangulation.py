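"""Triangulation (transitivity) validation of IBD calls.

IBD is transitive at the haplotype level: if A and B share a stretch from a
common ancestor and B shares the same stretch with C *on the same
haplotype*, then A and C must share it too.  Pairs of overlapping calls
where the expected third segment is absent point to artifacts in the
discovery process.

Two segments are linked when they lie on the same chromosome, share at
least one individual, and overlap by at least one base pair; clusters are
the connected components of that relation.  Every linked pair sharing
exactly one pivot individual is classified into one of four mechanically
decidable typologies:

``transitive``
    a third segment joining the two outer individuals overlaps the
    intersection interval;
``explained_short_overlap``
    the intersection interval is shorter (in cM) than the detector's
    minimum reportable length, so the third segment could not have been
    reported;
``explained_haplotype``
    the pivot individual carries the two segments on different (known)
    haplotypes, so no single ancestral stretch is implied;
``unexplained``
    none of the above — a candidate artifact.

Linked pairs sharing *both* individuals (duplicate calls for one pair) are
excluded from trio classification and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .genmap import GeneticMap
from .segments import IBDSegment, segments_overlap

__all__ = [
    "SegmentCluster",
    "TrioClassification",
    "TriangulationReport",
    "cluster_segments",
    "classify_trio_pairs",
    "triangulation_report",
]

TYPOLOGIES = ("transitive", "explained_short_overlap", "explained_haplotype", "unexplained")


@dataclass
class SegmentCluster:
    """Connected set of overlapping same-chromosome segments."""

    chrom: str
    members: list[IBDSegment]
    links: list[tuple[int, int]]  # index pairs into members, i < j


@dataclass(frozen=True)
class TrioClassification:
    segment_ab: IBDSegment
    segment_bc: IBDSegment
    pivot: str
    typology: str
    overlap_bp: tuple[int, int]
    overlap_cM: float
    third_segment: IBDSegment | None = None


@dataclass
class TriangulationReport:
    counts: dict[str, int]
    n_pairs: int
    n_duplicate_pairs: int
    unexplained: list[TrioClassification]
    n_clusters: int

    @property
    def unexplained_fraction(self) -> float:
        return self.counts["unexplained"] / self.n_pairs if self.n_pairs else 0.0


def _linked(a: IBDSegment, b: IBDSegment) -> bool:
    return bool(a.samples & b.samples) and segments_overlap(a, b)


def cluster_segments(segments: Sequence[IBDSegment]) -> list[SegmentCluster]:
    """Group segments into overlap clusters per chromosome.

    Link rule: same chromosome AND >= 1 shared individual AND >= 1 bp
    interval overlap.  Clusters are connected components; a segment linked
    to nothing forms a singleton cluster.
    """
    by_chrom: dict[str, list[IBDSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)

    clusters: list[SegmentCluster] = []
    for chrom in sorted(by_chrom, key=str):
        segs = by_chrom[chrom]
        n = len(segs)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        links: list[tuple[int, int]] = []
        for i in range(n):
            for j in range(i + 1, n):
                if _linked(segs[i], segs[j]):
                    links.append((i, j))
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        for root in sorted(groups, key=lambda r: min(groups[r])):
            idxs = groups[root]
            local = {orig: k for k, orig in enumerate(idxs)}
            clusters.append(
                SegmentCluster(
                    chrom=chrom,
                    members=[segs[i] for i in idxs],
                    links=[(local[i], local[j]) for i, j in links if find(i) == root],
                )
            )
    return clusters


def classify_trio_pairs(
    cluster: SegmentCluster, min_reportable_cM: float, gmap: GeneticMap
) -> tuple[list[TrioClassification], int]:
    """Classify every linked pair of the cluster sharing one pivot individual.

    Returns the classifications plus the number of duplicate pairs (linked
    pairs sharing both individuals), which are excluded from classification.
    The search for the third segment is confined to the cluster: any
    qualifying outer-pair segment overlaps both members and shares an
    individual with each, so it necessarily belongs to the same cluster.
    """
    if min_reportable_cM <= 0:
        raise ValueError(f"min_reportable_cM must be > 0, got {min_reportable_cM}")
    out: list[TrioClassification] = []
    n_dup = 0
    members = cluster.members
    for i, j in cluster.links:
        s, t = members[i], members[j]
        shared = s.samples & t.samples
        if len(shared) == 2:
            n_dup += 1
            continue
        (pivot,) = shared
        (a,) = s.samples - {pivot}
        (c,) = t.samples - {pivot}
        lo = max(s.start_bp, t.start_bp)
        hi = min(s.end_bp, t.end_bp)
        overlap_cM = float(
            gmap.interpolate(cluster.chrom, hi) - gmap.interpolate(cluster.chrom, lo)
        )
        third = next(
            (
                u
                for u in members
                if u.samples == {a, c} and max(u.start_bp, lo) <= min(u.end_bp, hi)
            ),
            None,
        )
        if third is not None:
            typ = "transitive"
        elif overlap_cM < min_reportable_cM:
            typ = "explained_short_overlap"
        elif (
            s.hap_of(pivot) != t.hap_of(pivot)
            and s.hap_of(pivot) != 0
            and t.hap_of(pivot) != 0
        ):
            typ = "explained_haplotype"
        else:
            typ = "unexplained"
        out.append(
            TrioClassification(s, t, pivot, typ, (lo, hi), overlap_cM, third)
        )
    return out, n_dup


def triangulation_report(
    segments: Sequence[IBDSegment],
    min_reportable_cM: float,
    gmap: GeneticMap,
) -> TriangulationReport:
    """Cluster the segments and total the trio typologies.

    ``min_reportable_cM`` is the detector's minimum reported segment length
    (the threshold below which an absent third segment is expected).
    """
    clusters = cluster_segments(segments)
    counts = {t: 0 for t in TYPOLOGIES}
    unexplained: list[TrioClassification] = []
    n_pairs = n_dup = 0
    for cluster in clusters:
        classifications, dups = classify_trio_pairs(cluster, min_reportable_cM, gmap)
        n_dup += dups
        for cl in classifications:
            counts[cl.typology] += 1
            n_pairs += 1
            if cl.typology == "unexplained":
                unexplained.append(cl)
    return TriangulationReport(
        counts=counts,
        n_pairs=n_pairs,
        n_duplicate_pairs=n_dup,
        unexplained=unexplained,
        n_clusters=len(clusters),
    )
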