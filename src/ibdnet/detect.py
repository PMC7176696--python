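"""Naive IBD detector for phased synthetic panels.

A deliberately simple stand-in for production IBD callers: it scans every
ordered pair of haplotypes from different individuals for maximal runs of
marker-wise identity and reports runs spanning at least ``min_cM`` with at
least ``min_markers`` markers.  Exact identity (no mismatch allowance) is
the default because synthetic panels are error-free; this keeps the
detector trivially verifiable against the simulator's ground truth.

The score column is an arbitrary-scale proxy (marker count x log10 2, the
log-odds of a run of per-marker matches each with probability 1/2) and is
never comparable to a real detector's LOD values.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .genmap import GeneticMap
from .segments import IBDSegment
from .simulate import HaplotypePanel

__all__ = ["detect_ibd", "interval_jaccard"]

_SCORE_PER_MARKER = math.log10(2.0)


def _runs(eq: np.ndarray, max_mismatch: int) -> list[tuple[int, int]]:
    """Maximal index runs of True, bridging gaps of <= max_mismatch Falses."""
    idx = np.nonzero(eq)[0]
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 <= max_mismatch:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def detect_ibd(
    panel: HaplotypePanel,
    min_cM: float = 1.0,
    min_markers: int = 2,
    max_mismatch: int = 0,
) -> list[IBDSegment]:
    """Report maximal identical runs between haplotypes of distinct individuals.

    Segments never overlap for a given haplotype pair, detection is
    symmetric in the two individuals, and raising ``min_cM`` can only
    remove segments.
    """
    if min_cM <= 0:
        raise ValueError(f"min_cM must be > 0, got {min_cM}")
    inds = panel.individuals
    out: list[IBDSegment] = []
    grids = {c: panel.marker_cM[c].shape for c in panel.chromosomes}
    for key, per_chrom in panel.labels.items():
        for c, arr in per_chrom.items():
            if arr.shape != grids[c]:
                raise ValueError(f"haplotype {key} has a mismatched marker grid on {c}")
    for i in range(len(inds)):
        for j in range(i + 1, len(inds)):
            a, b = inds[i], inds[j]
            for ha in (1, 2):
                for hb in (1, 2):
                    for chrom in panel.chromosomes:
                        la = panel.labels[(a, ha)][chrom]
                        lb = panel.labels[(b, hb)][chrom]
                        cms = panel.marker_cM[chrom]
                        bps = panel.marker_bp[chrom]
                        for s, e in _runs(la == lb, max_mismatch):
                            span = float(cms[e] - cms[s])
                            n_mark = e - s + 1
                            if span < min_cM or n_mark < min_markers:
                                continue
                            out.append(
                                IBDSegment(
                                    sample_a=a,
                                    hap_a=ha,
                                    sample_b=b,
                                    hap_b=hb,
                                    chrom=chrom,
                                    start_bp=int(bps[s]),
                                    end_bp=int(bps[e]),
                                    score=n_mark * _SCORE_PER_MARKER,
                                    length_cM=span,
                                    n_snps=n_mark,
                                )
                            )
    return out


def _merge(ivs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    ivs = sorted(ivs)
    out: list[tuple[float, float]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _intersect(
    x: list[tuple[float, float]], y: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    i = j = 0
    while i < len(x) and j < len(y):
        a, b = max(x[i][0], y[j][0]), min(x[i][1], y[j][1])
        if b > a:
            out.append((a, b))
        if x[i][1] < y[j][1]:
            i += 1
        else:
            j += 1
    return out


def interval_jaccard(
    truth: Sequence[IBDSegment],
    detected: Sequence[IBDSegment],
    gmap: GeneticMap,
) -> float:
    """Aggregate interval-overlap Jaccard between two segment sets, in cM.

    Segments are grouped by (individual pair, haplotype pair, chromosome);
    the statistic is total intersection length over total union length
    across all groups.  Returns 1.0 when both sets are empty.
    """
    def pool(segs: Sequence[IBDSegment]) -> dict:
        d: dict = {}
        for s in segs:
            lo_ind, hi_ind = sorted(s.samples)
            key = (lo_ind, hi_ind, s.hap_of(lo_ind), s.hap_of(hi_ind), s.chrom)
            d.setdefault(key, []).append(
                (gmap.interpolate(s.chrom, s.start_bp), gmap.interpolate(s.chrom, s.end_bp))
            )
        return d

    t, d = pool(truth), pool(detected)
    inter = union = 0.0
    for key in set(t) | set(d):
        tv = _merge(t.get(key, []))
        dv = _merge(d.get(key, []))
        both = sum(b - a for a, b in _intersect(tv, dv))
        inter += both
        union += sum(b - a for a, b in tv) + sum(b - a for a, b in dv) - both
    return inter / union if union > 0 else 1.0
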