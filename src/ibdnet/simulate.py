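"""Synthetic IBD data with ground truth.

Two generation modes:

* **segment-level** (:func:`simulate_segments`): draws segment counts per
  pair of individuals directly — Poisson(lambda_intra) within a population,
  Poisson(lambda_inter) between — with exponential segment lengths and
  scores increasing in length plus noise.  Fast; suitable for network and
  enrichment tests.  Default per-pair rates (0.19 intra, 0.0027 inter)
  reproduce the sharing regime observed in dense European panels, where
  IBD blocks fall within populations roughly 70 times more often than
  between them.

* **pedigree** (:func:`simulate_pedigree`): simulates meioses through an
  explicit pedigree.  Founder haplotypes get unique labels; each
  transmission draws a Poisson(L Morgans) number of crossovers placed
  uniformly in cM (Haldane model, no interference) and splices a mosaic.
  True IBD between two haplotypes is the set of maximal intervals where
  founder labels agree, with exact cM lengths — the ground truth the
  naive detector and the triangulation audit are checked against.
  Segment lengths shrink as pedigree depth grows, emulating the
  progressive fragmentation of ancestral haplotypes by recombination.

All randomness flows from the config seed; identical configs give
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genmap import GeneticMap
from .populations import PopulationTable
from .segments import IBDSegment

__all__ = [
    "SegmentSimConfig",
    "PedigreeSimConfig",
    "FocalStudyConfig",
    "HaplotypePanel",
    "simulate_segments",
    "simulate_pedigree",
    "true_ibd_segments",
    "meiosis",
    "plant_artifact_pair",
    "plant_transitive_trio",
    "simulate_focal_study",
]

# three desk-scale chromosomes at a uniform 1 cM/Mb
DEFAULT_CHROM_SPANS: dict[str, tuple[float, float]] = {
    "1": (120e6, 120.0),
    "2": (100e6, 100.0),
    "3": (80e6, 80.0),
}


def _default_spans() -> dict[str, tuple[float, float]]:
    return dict(DEFAULT_CHROM_SPANS)


@dataclass
class SegmentSimConfig:
    """Configuration for the segment-level generator."""

    populations: dict[str, int] = field(
        default_factory=lambda: {"P1": 25, "P2": 25, "P3": 25, "P4": 25}
    )
    lambda_intra: float = 0.19
    lambda_inter: float = 0.0027
    mean_length_cM: float = 10.0
    score_intercept: float = 3.0
    score_slope: float = 0.35
    score_sd: float = 0.5
    chrom_spans: dict[str, tuple[float, float]] = field(default_factory=_default_spans)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.populations.values()):
            raise ValueError("population sizes must be >= 1")
        if self.lambda_intra < 0 or self.lambda_inter < 0:
            raise ValueError("Poisson rates must be >= 0")
        if self.mean_length_cM <= 0:
            raise ValueError("mean segment length must be > 0")


@dataclass
class PedigreeSimConfig:
    """Configuration for the pedigree generator.

    ``generations`` is the number of meiosis layers between the founders and
    the sampled individuals; ``migration`` is the per-parent probability of
    drawing the parent from a different population.
    """

    populations: dict[str, int] = field(default_factory=lambda: {"P1": 12, "P2": 12})
    generations: int = 5
    migration: float = 0.0
    markers_per_chrom: int = 400
    chrom_spans: dict[str, tuple[float, float]] = field(default_factory=_default_spans)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 <= self.migration <= 1.0:
            raise ValueError("migration must be in [0, 1]")
        if any(n < 2 for n in self.populations.values()):
            raise ValueError("pedigree populations need >= 2 individuals")


@dataclass
class FocalStudyConfig:
    """Configuration for the focal-individual enrichment study generator."""

    populations: dict[str, int] = field(
        default_factory=lambda: {f"P{i+1}": 43 for i in range(10)}
    )
    base_rate: float = 0.072
    enrichment_factor: float = 5.0
    focal_population: str | None = None  # population receiving the factor
    focal_id: str = "FOCAL"
    focal_label: str = "focal"
    mean_length_cM: float = 3.0
    score_intercept: float = 4.8
    score_slope: float = 0.5
    score_sd: float = 0.3
    chrom_spans: dict[str, tuple[float, float]] = field(default_factory=_default_spans)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate < 0 or self.enrichment_factor < 0:
            raise ValueError("rates and enrichment factor must be >= 0")
        if self.focal_population is not None and self.focal_population not in self.populations:
            raise ValueError(f"unknown focal population {self.focal_population!r}")


def _individual_ids(populations: dict[str, int]) -> PopulationTable:
    labels = {}
    for pop, size in populations.items():
        for k in range(size):
            labels[f"{pop}_{k:03d}"] = pop
    return PopulationTable.from_mapping(labels)


def _place_segment(
    rng: np.random.Generator,
    gmap: GeneticMap,
    chroms: list[str],
    weights: np.ndarray,
    length_cM: float,
) -> tuple[str, int, int, float]:
    """Pick a chromosome (weight ~ cM span) and a uniform placement."""
    chrom = chroms[rng.choice(len(chroms), p=weights)]
    span = gmap.chrom_length_cM(chrom)
    length = min(length_cM, span)
    start_cM = rng.uniform(0.0, span - length)
    start_bp = int(round(gmap.bp_at(chrom, start_cM)))
    end_bp = int(round(gmap.bp_at(chrom, start_cM + length)))
    return chrom, max(1, start_bp), max(1, end_bp), length


def simulate_segments(
    config: SegmentSimConfig,
) -> tuple[list[IBDSegment], PopulationTable, GeneticMap]:
    """Draw an IBD segment list pair by pair.

    Intra-population pairs share Poisson(lambda_intra) segments, inter
    pairs Poisson(lambda_inter); lengths are exponential with the
    configured mean, positions uniform over the genetic map, scores a
    linear function of length plus Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    table = _individual_ids(config.populations)
    gmap = GeneticMap.uniform(config.chrom_spans)
    chroms = gmap.chromosomes
    spans = np.array([gmap.chrom_length_cM(c) for c in chroms])
    weights = spans / spans.sum()
    inds = table.individuals
    segments: list[IBDSegment] = []
    for i in range(len(inds)):
        for j in range(i + 1, len(inds)):
            a, b = inds[i], inds[j]
            lam = config.lambda_intra if table[a] == table[b] else config.lambda_inter
            for _ in range(rng.poisson(lam)):
                length = rng.exponential(config.mean_length_cM)
                chrom, s_bp, e_bp, length = _place_segment(rng, gmap, chroms, weights, length)
                score = (
                    config.score_intercept
                    + config.score_slope * length
                    + rng.normal(0.0, config.score_sd)
                )
                segments.append(
                    IBDSegment(
                        sample_a=a,
                        hap_a=int(rng.integers(1, 3)),
                        sample_b=b,
                        hap_b=int(rng.integers(1, 3)),
                        chrom=chrom,
                        start_bp=s_bp,
                        end_bp=e_bp,
                        score=float(score),
                        length_cM=float(length),
                    )
                )
    return segments, table, gmap


# ---------------------------------------------------------------------------
# pedigree mode
# ---------------------------------------------------------------------------

Intervals = list[tuple[float, float, int]]  # (start_cM, end_cM, founder label)


def meiosis(
    hap1: Intervals, hap2: Intervals, length_cM: float, rng: np.random.Generator
) -> tuple[Intervals, int]:
    """One transmission: Poisson(L Morgans) crossovers uniform in cM.

    Returns the transmitted mosaic and the crossover count.
    """
    n_x = int(rng.poisson(length_cM / 100.0))
    breaks = np.sort(rng.uniform(0.0, length_cM, size=n_x))
    cur = int(rng.integers(0, 2))
    haps = (hap1, hap2)
    bounds = [0.0, *breaks.tolist(), length_cM]
    child: Intervals = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if hi <= lo:
            cur ^= 1
            continue
        for s, e, lab in haps[cur]:
            a, b = max(s, lo), min(e, hi)
            if b > a:
                if child and child[-1][2] == lab and child[-1][1] == a:
                    child[-1] = (child[-1][0], b, lab)
                else:
                    child.append((a, b, lab))
        cur ^= 1
    return child, n_x


@dataclass
class HaplotypePanel:
    """Phased haplotypes over a shared marker grid, with continuous truth.

    ``labels[(individual, hap)][chrom]`` is the founder-label array at the
    marker positions; ``intervals`` holds the exact piecewise-constant
    label functions the markers were sampled from.
    """

    gmap: GeneticMap
    marker_bp: dict[str, np.ndarray]
    marker_cM: dict[str, np.ndarray]
    populations: PopulationTable
    labels: dict[tuple[str, int], dict[str, np.ndarray]]
    intervals: dict[tuple[str, int], dict[str, Intervals]]

    @property
    def individuals(self) -> list[str]:
        return self.populations.individuals

    @property
    def chromosomes(self) -> list[str]:
        return list(self.marker_bp)


def _labels_at(intervals: Intervals, positions: np.ndarray) -> np.ndarray:
    starts = np.array([iv[0] for iv in intervals])
    labs = np.array([iv[2] for iv in intervals])
    idx = np.clip(np.searchsorted(starts, positions, side="right") - 1, 0, len(labs) - 1)
    return labs[idx]


def simulate_pedigree(config: PedigreeSimConfig) -> HaplotypePanel:
    """Simulate ``generations`` layers of random mating within populations.

    Founders carry globally unique labels on both haplotypes; each child
    draws two distinct parents (from another population with probability
    ``migration``) and receives one recombinant haplotype from each.  The
    final generation is the sampled panel.
    """
    rng = np.random.default_rng(config.seed)
    gmap = GeneticMap.uniform(config.chrom_spans)
    chroms = list(config.chrom_spans)
    pops = list(config.populations)

    label = 0
    # generation 0: founders, one interval per chromosome per haplotype
    current: dict[str, list[dict]] = {p: [] for p in pops}
    for p in pops:
        for _ in range(config.populations[p]):
            haps = []
            for _hap in range(2):
                per_chrom = {
                    c: [(0.0, gmap.chrom_length_cM(c), label)] for c in chroms
                }
                label += 1
                haps.append(per_chrom)
            current[p].append({"haps": haps})

    for _g in range(config.generations):
        nxt: dict[str, list[dict]] = {p: [] for p in pops}
        for p in pops:
            for _ in range(config.populations[p]):
                parents = []
                pool_pops = []
                for _side in range(2):
                    if len(pops) > 1 and rng.uniform() < config.migration:
                        q = pops[rng.choice([k for k, pp in enumerate(pops) if pp != p])]
                    else:
                        q = p
                    pool_pops.append(q)
                i1 = int(rng.integers(len(current[pool_pops[0]])))
                while True:
                    i2 = int(rng.integers(len(current[pool_pops[1]])))
                    if pool_pops[0] != pool_pops[1] or i2 != i1:
                        break
                parents = [current[pool_pops[0]][i1], current[pool_pops[1]][i2]]
                haps = []
                for parent in parents:
                    per_chrom = {}
                    for c in chroms:
                        child, _ = meiosis(
                            parent["haps"][0][c],
                            parent["haps"][1][c],
                            gmap.chrom_length_cM(c),
                            rng,
                        )
                        per_chrom[c] = child
                    haps.append(per_chrom)
                nxt[p].append({"haps": haps})
        current = nxt

    table = _individual_ids(config.populations)
    inds_by_pop = {p: [i for i in table.individuals if table[i] == p] for p in pops}
    marker_bp: dict[str, np.ndarray] = {}
    marker_cM: dict[str, np.ndarray] = {}
    for c in chroms:
        span = gmap.chrom_length_cM(c)
        cms = np.linspace(0.0, span, config.markers_per_chrom)
        marker_cM[c] = cms
        marker_bp[c] = np.maximum(1, np.round(gmap.bp_at(c, cms)).astype(int))
    labels_out: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    intervals_out: dict[tuple[str, int], dict[str, Intervals]] = {}
    for p in pops:
        for ind, record in zip(inds_by_pop[p], current[p]):
            for hap in (1, 2):
                per_chrom = record["haps"][hap - 1]
                labels_out[(ind, hap)] = {
                    c: _labels_at(per_chrom[c], marker_cM[c]) for c in chroms
                }
                intervals_out[(ind, hap)] = per_chrom
    return HaplotypePanel(
        gmap=gmap,
        marker_bp=marker_bp,
        marker_cM=marker_cM,
        populations=table,
        labels=labels_out,
        intervals=intervals_out,
    )


def _equal_label_runs(a: Intervals, b: Intervals) -> list[tuple[float, float]]:
    """Maximal cM intervals where two piecewise-constant labelings agree."""
    bounds = sorted({x for s, e, _ in a for x in (s, e)} | {x for s, e, _ in b for x in (s, e)})
    runs: list[tuple[float, float]] = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if hi <= lo:
            continue
        mid = (lo + hi) / 2.0
        la = next((lab for s, e, lab in a if s <= mid < e), None)
        lb = next((lab for s, e, lab in b if s <= mid < e), None)
        if la is not None and la == lb:
            if runs and abs(runs[-1][1] - lo) < 1e-12:
                runs[-1] = (runs[-1][0], hi)
            else:
                runs.append((lo, hi))
    return runs


def true_ibd_segments(panel: HaplotypePanel, min_cM: float = 1.0) -> list[IBDSegment]:
    """Ground-truth IBD between every pair of individuals.

    Maximal intervals of identical founder labels between any two
    haplotypes of different individuals, with exact cM lengths; segments
    shorter than ``min_cM`` are suppressed.  The score column carries the
    cM length (truth segments have no detector score).
    """
    inds = panel.individuals
    out: list[IBDSegment] = []
    for i in range(len(inds)):
        for j in range(i + 1, len(inds)):
            a, b = inds[i], inds[j]
            for ha in (1, 2):
                for hb in (1, 2):
                    for chrom in panel.chromosomes:
                        runs = _equal_label_runs(
                            panel.intervals[(a, ha)][chrom],
                            panel.intervals[(b, hb)][chrom],
                        )
                        for lo, hi in runs:
                            length = hi - lo
                            if length < min_cM:
                                continue
                            out.append(
                                IBDSegment(
                                    sample_a=a,
                                    hap_a=ha,
                                    sample_b=b,
                                    hap_b=hb,
                                    chrom=chrom,
                                    start_bp=max(1, int(round(panel.gmap.bp_at(chrom, lo)))),
                                    end_bp=max(1, int(round(panel.gmap.bp_at(chrom, hi)))),
                                    score=float(length),
                                    length_cM=float(length),
                                )
                            )
    return out


# ---------------------------------------------------------------------------
# planted structures for triangulation audits
# ---------------------------------------------------------------------------


def plant_artifact_pair(
    segments: Sequence[IBDSegment],
    gmap: GeneticMap,
    chrom: str | None = None,
    start_bp: int = 1_000_000,
    end_bp: int = 21_000_000,
    ids: tuple[str, str, str] = ("ARTa", "ARTp", "ARTc"),
    score: float = 10.0,
) -> tuple[list[IBDSegment], dict]:
    """Append a non-transitive A-B / B-C pair with no A-C segment.

    Both segments sit on the same haplotype of the pivot and overlap over
    their full span, so the only available explanation is 'artifact'
    (unexplained).  Fresh sample identifiers keep the planted structure
    disjoint from the base list.
    """
    chrom = chrom or gmap.chromosomes[0]
    a, pivot, c = ids
    mk = lambda x, y: IBDSegment(  # noqa: E731
        sample_a=x, hap_a=1, sample_b=y, hap_b=1, chrom=chrom,
        start_bp=start_bp, end_bp=end_bp, score=score,
        length_cM=float(gmap.interpolate(chrom, end_bp) - gmap.interpolate(chrom, start_bp)),
    )
    planted = [mk(a, pivot), mk(pivot, c)]
    record = {
        "kind": "artifact_pair",
        "ids": list(ids),
        "chrom": chrom,
        "span": [start_bp, end_bp],
        "keys": [s.key() for s in planted],
    }
    return [*segments, *planted], record


def plant_transitive_trio(
    segments: Sequence[IBDSegment],
    gmap: GeneticMap,
    chrom: str | None = None,
    start_bp: int = 1_000_000,
    end_bp: int = 21_000_000,
    ids: tuple[str, str, str] = ("TRIa", "TRIp", "TRIc"),
    score: float = 10.0,
) -> tuple[list[IBDSegment], dict]:
    """Append a full transitive triangle A-B, B-C, A-C over one interval."""
    chrom = chrom or gmap.chromosomes[0]
    a, pivot, c = ids
    mk = lambda x, y: IBDSegment(  # noqa: E731
        sample_a=x, hap_a=1, sample_b=y, hap_b=1, chrom=chrom,
        start_bp=start_bp, end_bp=end_bp, score=score,
        length_cM=float(gmap.interpolate(chrom, end_bp) - gmap.interpolate(chrom, start_bp)),
    )
    planted = [mk(a, pivot), mk(pivot, c), mk(a, c)]
    record = {
        "kind": "transitive_trio",
        "ids": list(ids),
        "chrom": chrom,
        "span": [start_bp, end_bp],
        "keys": [s.key() for s in planted],
    }
    return [*segments, *planted], record


def simulate_focal_study(
    config: FocalStudyConfig,
) -> tuple[list[IBDSegment], str, PopulationTable, GeneticMap, dict]:
    """One focal individual sharing segments with panel members.

    Each panel individual shares a segment with the focal individual with
    probability ``base_rate`` — multiplied by ``enrichment_factor`` for
    members of ``focal_population`` (capped at 1).  The focal individual
    joins the table under its own label.  Returns the segments, the focal
    id, the table, the map and a truth record carrying the planted factor.
    """
    rng = np.random.default_rng(config.seed)
    table = _individual_ids(config.populations)
    labels = dict(table.labels)
    labels[config.focal_id] = config.focal_label
    table = PopulationTable.from_mapping(labels)
    gmap = GeneticMap.uniform(config.chrom_spans)
    chroms = gmap.chromosomes
    spans = np.array([gmap.chrom_length_cM(c) for c in chroms])
    weights = spans / spans.sum()
    segments: list[IBDSegment] = []
    for ind in table.individuals:
        if ind == config.focal_id:
            continue
        rate = config.base_rate
        if config.focal_population is not None and table[ind] == config.focal_population:
            rate *= config.enrichment_factor
        if rng.uniform() >= min(1.0, rate):
            continue
        length = rng.exponential(config.mean_length_cM)
        chrom, s_bp, e_bp, length = _place_segment(rng, gmap, chroms, weights, length)
        score = (
            config.score_intercept + config.score_slope * length + rng.normal(0.0, config.score_sd)
        )
        segments.append(
            IBDSegment(
                sample_a=config.focal_id,
                hap_a=int(rng.integers(1, 3)),
                sample_b=ind,
                hap_b=int(rng.integers(1, 3)),
                chrom=chrom,
                start_bp=s_bp,
                end_bp=e_bp,
                score=float(score),
                length_cM=float(length),
            )
        )
    truth = {
        "focal_population": config.focal_population,
        "enrichment_factor": config.enrichment_factor,
        "base_rate": config.base_rate,
        "n_segments": len(segments),
    }
    return segments, config.focal_id, table, gmap, truth
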