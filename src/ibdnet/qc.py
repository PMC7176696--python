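"""Segment-level quality control.

Filters mirror the detector-output QC narrative for IBD studies: a genetic
length threshold (e.g. keep segments longer than 6 cM for dense modern
panels, 2 cM for a sparse focal genome), a minimum confidence score
(segments scoring below 4.8 removed), exclusion of segments overlapping
centromeric/telomeric regions, and a score-vs-length outlier diagnostic
that flags segments whose score is abnormally low for their length.

Every filter returns the retained segments plus a :class:`QCStage` whose
counts are conserved (input = retained + removed); a :class:`QCReport`
accumulates stages.  The outlier rule is advisory by default — segments are
flagged, not dropped, unless explicitly requested — because the underlying
criterion in manual workflows is a visual call, and automation of it is an
approximation that should never silently discard data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .segments import ExclusionRegion, IBDSegment

__all__ = [
    "QCStage",
    "QCReport",
    "RegressionDiagnostic",
    "filter_by_length",
    "filter_by_score",
    "filter_exclusion_overlap",
    "flag_score_length_outliers",
    "snp_count_score_regression",
    "apply_qc",
]

# MAD -> sigma consistency factor for a normal distribution
_MAD_SCALE = 1.4826


@dataclass
class QCStage:
    name: str
    n_in: int
    n_retained: int
    n_removed: int
    params: dict = field(default_factory=dict)
    removed: list[tuple[str, str]] = field(default_factory=list)  # (segment key, reason)

    def __post_init__(self) -> None:
        if self.n_in != self.n_retained + self.n_removed:
            raise ValueError(
                f"stage {self.name}: {self.n_in} != {self.n_retained} + {self.n_removed}"
            )


@dataclass
class RegressionDiagnostic:
    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    p_value: float
    n: int


@dataclass
class QCReport:
    stages: list[QCStage] = field(default_factory=list)
    regression: RegressionDiagnostic | None = None

    def add(self, stage: QCStage) -> None:
        if self.stages and stage.n_in != self.stages[-1].n_retained:
            raise ValueError(
                f"stage {stage.name} input count {stage.n_in} does not match "
                f"previous stage output {self.stages[-1].n_retained}"
            )
        self.stages.append(stage)

    @property
    def n_in(self) -> int:
        return self.stages[0].n_in if self.stages else 0

    @property
    def n_retained(self) -> int:
        return self.stages[-1].n_retained if self.stages else 0

    def to_json(self, path=None) -> str:
        payload = {
            "stages": [asdict(s) for s in self.stages],
            "regression": asdict(self.regression) if self.regression else None,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def filter_by_length(
    segments: Sequence[IBDSegment], min_cM: float, strict: bool = True
) -> tuple[list[IBDSegment], QCStage]:
    """Keep segments longer than ``min_cM`` (strictly by default)."""
    if min_cM < 0:
        raise ValueError(f"negative length threshold {min_cM}")
    keep = (lambda s: s.length_cM > min_cM) if strict else (lambda s: s.length_cM >= min_cM)
    retained = [s for s in segments if keep(s)]
    removed = [(s.key(), "length") for s in segments if not keep(s)]
    stage = QCStage(
        "length", len(segments), len(retained), len(removed),
        params={"min_cM": min_cM, "strict": strict}, removed=removed,
    )
    return retained, stage


def filter_by_score(
    segments: Sequence[IBDSegment], min_score: float
) -> tuple[list[IBDSegment], QCStage]:
    """Keep segments with ``score >= min_score``.

    Removal targets scores strictly below the threshold, so a segment scoring
    exactly the threshold survives.  Pass ``-math.inf`` to disable.
    """
    retained = [s for s in segments if s.score >= min_score]
    removed = [(s.key(), "score") for s in segments if s.score < min_score]
    stage = QCStage(
        "score", len(segments), len(retained), len(removed),
        params={"min_score": min_score}, removed=removed,
    )
    return retained, stage


def filter_exclusion_overlap(
    segments: Sequence[IBDSegment], regions: Sequence[ExclusionRegion]
) -> tuple[list[IBDSegment], QCStage]:
    """Remove segments overlapping any exclusion region by >= 1 bp."""
    by_chrom: dict[str, list[ExclusionRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    def hit(s: IBDSegment) -> bool:
        return any(r.overlaps(s) for r in by_chrom.get(s.chrom, ()))

    retained = [s for s in segments if not hit(s)]
    removed = [(s.key(), "exclusion_overlap") for s in segments if hit(s)]
    stage = QCStage(
        "exclusion", len(segments), len(retained), len(removed),
        params={"n_regions": len(regions)}, removed=removed,
    )
    return retained, stage


def flag_score_length_outliers(
    segments: Sequence[IBDSegment], k: float = 3.0
) -> tuple[list[str], tuple[float, float]]:
    """Flag segments whose score is abnormally low for their length.

    Fits a least-squares line of score on length_cM and flags segments whose
    residual falls below ``-k`` robust standard deviations (median absolute
    deviation of the residuals scaled by 1.4826).  Returns the flagged
    segment keys and the fitted ``(slope, intercept)``.  With fewer than
    3 segments the flag set is empty.  ``k = math.inf`` disables flagging.
    """
    if len(segments) < 3:
        return [], (math.nan, math.nan)
    x = np.array([s.length_cM for s in segments], dtype=float)
    y = np.array([s.score for s in segments], dtype=float)
    if np.ptp(x) == 0:
        slope, intercept = 0.0, float(np.mean(y))
    else:
        slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    mad = _MAD_SCALE * np.median(np.abs(resid - np.median(resid)))
    if not math.isfinite(k) or mad == 0:
        flagged_idx = np.array([], dtype=int)
    else:
        flagged_idx = np.nonzero(resid < -k * mad)[0]
    return [segments[i].key() for i in flagged_idx], (float(slope), float(intercept))


def snp_count_score_regression(segments: Sequence[IBDSegment]) -> RegressionDiagnostic:
    """OLS of score on per-segment SNP count, with adjusted R^2.

    Diagnostic for sparse-genome IBD calls: segments supported by more
    markers should score higher; a weak or absent relationship hints at
    false-positive calls.  Requires >= 3 segments carrying ``n_snps``.
    """
    pts = [(s.n_snps, s.score) for s in segments if s.n_snps is not None]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 segments with SNP counts, got {len(pts)}")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in SNP counts; regression undefined")
    n = len(x)
    if np.ptp(y) == 0:
        # constant response: R^2 = 0, flat line
        return RegressionDiagnostic(0.0, float(y[0]), 0.0, -1.0 / (n - 2), 1.0, n)
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionDiagnostic(
        float(res.slope), float(res.intercept), float(r2), float(adj), float(res.pvalue), n
    )


def apply_qc(
    segments: Sequence[IBDSegment],
    min_cM: float = 6.0,
    strict: bool = True,
    min_score: float = -math.inf,
    regions: Sequence[ExclusionRegion] = (),
    outlier_k: float = 3.0,
    drop_outliers: bool = False,
) -> tuple[list[IBDSegment], QCReport]:
    """Run the default QC chain: length -> score -> exclusion -> outlier.

    The outlier stage flags by default; removal requires ``drop_outliers``.
    """
    report = QCReport()
    retained, stage = filter_by_length(segments, min_cM, strict)
    report.add(stage)
    retained, stage = filter_by_score(retained, min_score)
    report.add(stage)
    retained, stage = filter_exclusion_overlap(retained, regions)
    report.add(stage)
    flagged, _line = flag_score_length_outliers(retained, outlier_k)
    if drop_outliers and flagged:
        flagged_set = set(flagged)
        kept = [s for s in retained if s.key() not in flagged_set]
        stage = QCStage(
            "outlier", len(retained), len(kept), len(retained) - len(kept),
            params={"k": outlier_k, "dropped": True},
            removed=[(key, "score_length_outlier") for key in flagged],
        )
        retained = kept
    else:
        stage = QCStage(
            "outlier", len(retained), len(retained), 0,
            params={"k": outlier_k, "dropped": False, "flagged": flagged},
        )
    report.add(stage)
    return retained, report
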