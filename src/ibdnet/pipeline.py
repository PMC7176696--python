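"""End-to-end pipelines: modern-panel analysis and focal-individual analysis.

Each run applies the configured QC chain, computes the stage results and
writes every artifact to the output directory together with a manifest
(sha256 of each written file, the effective configuration, the seed and the
package version), so a rerun with the same inputs and seed reproduces the
manifest hashes byte for byte.

Default thresholds follow common practice for dense modern panels versus a
sparse focal genome: segments longer than 6 cM for the modern network,
longer than 2 cM with score >= 4.8 for the focal analysis, detector
reporting floor 1 cM, and alpha = 0.05 for the enrichment test.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import enrichment_report
from .genmap import GeneticMap
from .io import read_bed_regions, read_genetic_map, read_ibd_segments, read_population_table, write_segments
from .network import (
    build_network,
    components_and_isolated,
    export_network,
    population_pair_matrix,
    sharing_rates,
)
from .populations import PopulationTable
from .qc import apply_qc, snp_count_score_regression
from .segments import ExclusionRegion, IBDSegment
from .simulate import SegmentSimConfig, simulate_segments
from .triangulation import triangulation_report

__all__ = ["PipelineConfig", "ModernResult", "FocalResult", "run_modern_analysis", "run_focal_analysis"]


class ConfigError(ValueError):
    """Configuration problem detected before any computation."""


@dataclass
class PipelineConfig:
    """Inputs and thresholds for a pipeline run.

    Provide either file paths (``segments_path`` + ``populations_path`` +
    ``map_path``) or a :class:`SegmentSimConfig` under ``simulation``.
    """

    segments_path: str | None = None
    populations_path: str | None = None
    map_path: str | None = None
    map_format: str = "plain"
    exclude_bed: str | None = None
    simulation: SegmentSimConfig | None = None
    min_cM_modern: float = 6.0
    min_cM_focal: float = 2.0
    min_score: float = 4.8
    score_filter_modern: bool = False
    strict_length: bool = True
    outlier_k: float = 3.0
    drop_outliers: bool = False
    min_reportable_cM: float = 1.0
    alpha: float = 0.05
    out_dir: str = "ibdnet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_cM_modern", "min_cM_focal", "min_reportable_cM"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha {self.alpha} outside (0, 1)")
        if self.simulation is None:
            missing = [
                n for n in ("segments_path", "populations_path", "map_path")
                if getattr(self, n) is None
            ]
            if missing:
                raise ConfigError(f"no simulation config and missing inputs: {missing}")


@dataclass
class ModernResult:
    qc_report: object
    summary: object
    matrix: pd.DataFrame
    network: object
    components: list[set]
    disconnected: set
    triangulation: object
    out_dir: Path
    manifest: dict


@dataclass
class FocalResult:
    qc_report: object
    enrichment: pd.DataFrame
    regression: object | None
    out_dir: Path
    manifest: dict


def _load_inputs(
    config: PipelineConfig,
) -> tuple[list[IBDSegment], PopulationTable, GeneticMap, list[ExclusionRegion]]:
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        segments, table, gmap = simulate_segments(sim)
    else:
        for name in ("segments_path", "populations_path", "map_path"):
            p = getattr(config, name)
            if not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        segments = read_ibd_segments(config.segments_path)
        table = read_population_table(config.populations_path)
        gmap = read_genetic_map(config.map_path, format=config.map_format)
    regions: list[ExclusionRegion] = []
    if config.exclude_bed is not None:
        if not Path(config.exclude_bed).exists():
            raise ConfigError(f"exclude_bed does not exist: {config.exclude_bed}")
        regions = read_bed_regions(config.exclude_bed)
    return segments, table, gmap, regions


def _write_manifest(out: Path, config: PipelineConfig, files: list[Path], extra: dict) -> dict:
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "files": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files
        },
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def run_modern_analysis(config: PipelineConfig) -> ModernResult:
    """QC -> sharing statistics -> network -> triangulation, with artifacts."""
    segments, table, gmap, regions = _load_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    retained, qc = apply_qc(
        segments,
        min_cM=config.min_cM_modern,
        strict=config.strict_length,
        min_score=config.min_score if config.score_filter_modern else -math.inf,
        regions=regions,
        outlier_k=config.outlier_k,
        drop_outliers=config.drop_outliers,
    )
    summary = sharing_rates(retained, table)
    matrix = population_pair_matrix(retained, table)
    net = build_network(retained, table)
    comps, disconnected = components_and_isolated(net)
    tri = triangulation_report(retained, config.min_reportable_cM, gmap)

    write_segments(retained, out / "segments_retained.tsv")
    qc.to_json(out / "qc_report.json")
    matrix.to_csv(out / "population_matrix.tsv", sep="\t")
    export_network(net, out / "network.graphml", "graphml")
    export_network(net, out / "network_edges.tsv", "tsv")
    summary_payload = {
        "intra_pair_count": summary.intra_pair_count,
        "inter_pair_count": summary.inter_pair_count,
        "intra_segment_count": summary.intra_segment_count,
        "inter_segment_count": summary.inter_segment_count,
        "intra_rate": summary.intra_rate,
        "inter_rate": summary.inter_rate,
        "ratio": summary.ratio,
        "n_components": len(comps),
        "n_disconnected": len(disconnected),
    }
    (out / "sharing_summary.json").write_text(json.dumps(summary_payload, indent=2) + "\n")
    tri_payload = {
        "counts": tri.counts,
        "n_pairs": tri.n_pairs,
        "n_duplicate_pairs": tri.n_duplicate_pairs,
        "n_clusters": tri.n_clusters,
        "unexplained_fraction": tri.unexplained_fraction,
    }
    (out / "triangulation.json").write_text(json.dumps(tri_payload, indent=2) + "\n")
    with open(out / "unexplained_pairs.tsv", "w") as fh:
        fh.write("segment_ab\tsegment_bc\tpivot\toverlap_cM\n")
        for cl in tri.unexplained:
            fh.write(
                f"{cl.segment_ab.key()}\t{cl.segment_bc.key()}\t{cl.pivot}\t{cl.overlap_cM!r}\n"
            )
    files = [
        out / n
        for n in (
            "segments_retained.tsv", "qc_report.json", "population_matrix.tsv",
            "network.graphml", "network_edges.tsv", "sharing_summary.json",
            "triangulation.json", "unexplained_pairs.tsv",
        )
    ]
    manifest = _write_manifest(
        out, config, files,
        {"stage_counts": {s.name: [s.n_in, s.n_retained] for s in qc.stages}},
    )
    return ModernResult(qc, summary, matrix, net, comps, disconnected, tri, out, manifest)


def run_focal_analysis(config: PipelineConfig, focal_id: str) -> FocalResult:
    """Focal-threshold QC -> enrichment test -> SNP/score diagnostic."""
    segments, table, gmap, regions = _load_inputs(config)
    if focal_id not in table:
        raise ConfigError(f"focal individual {focal_id!r} not in population table")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    focal_segs = [s for s in segments if focal_id in s.samples]
    retained, qc = apply_qc(
        focal_segs,
        min_cM=config.min_cM_focal,
        strict=config.strict_length,
        min_score=config.min_score,
        regions=regions,
        outlier_k=config.outlier_k,
        drop_outliers=config.drop_outliers,
    )
    table_df = enrichment_report(retained, focal_id, table, alpha=config.alpha)
    regression = None
    if sum(s.n_snps is not None for s in retained) >= 3:
        regression = snp_count_score_regression(retained)
        qc.regression = regression

    write_segments(retained, out / "focal_segments.tsv")
    qc.to_json(out / "qc_report.json")
    table_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    payload = {
        "T": int(table_df.attrs["T"]),
        "N": int(table_df.attrs["N"]),
        "p_null": table_df.attrs["p_null"],
        "m0": int(table_df.attrs["m0"]),
        "alpha": config.alpha,
        "rejected": table_df.loc[table_df["reject"], "population"].tolist(),
    }
    (out / "enrichment_summary.json").write_text(json.dumps(payload, indent=2) + "\n")
    files = [out / n for n in ("focal_segments.tsv", "qc_report.json", "enrichment.tsv", "enrichment_summary.json")]
    manifest = _write_manifest(
        out, config, files,
        {"stage_counts": {s.name: [s.n_in, s.n_retained] for s in qc.stages}},
    )
    return FocalResult(qc, table_df, regression, out, manifest)
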