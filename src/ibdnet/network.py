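"""Co-ancestry network construction and sharing statistics.

Individuals are nodes; an undirected edge joins every pair sharing at least
one IBD segment.  A pair sharing k segments contributes k to segment counts
but a single edge; multiplicity is kept as the edge weight (``count`` and
``total_cM``).  Haplotype indices are ignored at network level — the unit
is the unordered pair of individuals.

Sharing statistics split segments into intra- vs inter-population by the
two carriers' labels, normalised by the number of *possible* pairs:
intra = sum_i n_i(n_i-1)/2, inter = N(N-1)/2 - intra.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .populations import PopulationTable
from .segments import IBDSegment, pair_key

__all__ = [
    "SharingSummary",
    "build_network",
    "possible_pair_counts",
    "sharing_rates",
    "population_pair_matrix",
    "components_and_isolated",
    "modularity_communities",
    "regional_subnetwork",
    "export_network",
    "import_network",
]


@dataclass(frozen=True)
class SharingSummary:
    """Intra/inter-population IBD sharing, per possible pair of individuals."""

    intra_pair_count: int
    inter_pair_count: int
    intra_segment_count: int
    inter_segment_count: int

    @property
    def intra_rate(self) -> float:
        return self.intra_segment_count / self.intra_pair_count if self.intra_pair_count else 0.0

    @property
    def inter_rate(self) -> float:
        return self.inter_segment_count / self.inter_pair_count if self.inter_pair_count else 0.0

    @property
    def ratio(self) -> float | None:
        """intra_rate / inter_rate from unrounded rates; None when undefined."""
        if self.inter_rate > 0:
            return self.intra_rate / self.inter_rate
        return None

    @classmethod
    def from_counts(
        cls,
        intra_segments: int,
        inter_segments: int,
        intra_pairs: int,
        inter_pairs: int,
    ) -> "SharingSummary":
        return cls(intra_pairs, inter_pairs, intra_segments, inter_segments)


def build_network(
    segments: Sequence[IBDSegment],
    population_table: PopulationTable,
    include_isolated: bool = False,
    strict: bool = True,
) -> nx.Graph:
    """Build the co-ancestry graph from a segment list.

    Nodes carry a ``population`` attribute; edges carry ``count`` (number of
    shared segments) and ``total_cM``.  By default only individuals appearing
    in at least one segment become nodes; ``include_isolated`` adds every
    individual in the table as a degree-0 node.  Unknown samples raise under
    ``strict``; otherwise they are labelled ``"unknown"``.
    """
    g = nx.Graph()

    def pop_of(sample: str) -> str:
        label = population_table.get(sample)
        if label is None:
            if strict:
                raise KeyError(f"sample {sample!r} not in population table")
            return "unknown"
        return label

    for seg in segments:
        a, b = pair_key(seg)
        for s in (a, b):
            if s not in g:
                g.add_node(s, population=pop_of(s))
        if g.has_edge(a, b):
            g[a][b]["count"] += 1
            g[a][b]["total_cM"] += seg.length_cM
        else:
            g.add_edge(a, b, count=1, total_cM=seg.length_cM)
    if include_isolated:
        for ind in population_table.individuals:
            if ind not in g:
                g.add_node(ind, population=population_table[ind])
    return g


def possible_pair_counts(population_table: PopulationTable) -> tuple[int, int]:
    """(intra, inter) counts of possible unordered pairs of individuals."""
    n = population_table.n_individuals
    if n < 2:
        raise ValueError(f"need >= 2 individuals, got {n}")
    intra = sum(ni * (ni - 1) // 2 for ni in population_table.sizes.values())
    inter = n * (n - 1) // 2 - intra
    return intra, inter


def sharing_rates(
    segments: Sequence[IBDSegment], population_table: PopulationTable
) -> SharingSummary:
    """Classify each segment intra/inter and normalise by possible pairs."""
    intra_pairs, inter_pairs = possible_pair_counts(population_table)
    intra_seg = inter_seg = 0
    for seg in segments:
        if population_table[seg.sample_a] == population_table[seg.sample_b]:
            intra_seg += 1
        else:
            inter_seg += 1
    return SharingSummary(intra_pairs, inter_pairs, intra_seg, inter_seg)


def population_pair_matrix(
    segments: Sequence[IBDSegment], population_table: PopulationTable
) -> pd.DataFrame:
    """Mean segments per possible pair, for every pair of populations.

    Entry (i, j) = segments between populations i and j divided by
    n_i * n_j (off-diagonal) or n_i(n_i-1)/2 (diagonal).  Diagonal entries
    for populations of size < 2 are NaN (no possible intra pair).
    """
    pops = population_table.populations
    sizes = population_table.sizes
    idx = {p: i for i, p in enumerate(pops)}
    counts = np.zeros((len(pops), len(pops)))
    for seg in segments:
        i = idx[population_table[seg.sample_a]]
        j = idx[population_table[seg.sample_b]]
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    denom = np.empty_like(counts)
    for p in pops:
        for q in pops:
            i, j = idx[p], idx[q]
            if i == j:
                pairs = sizes[p] * (sizes[p] - 1) / 2
                denom[i, j] = pairs if pairs > 0 else np.nan
            else:
                denom[i, j] = sizes[p] * sizes[q]
    with np.errstate(invalid="ignore"):
        m = counts / denom
    return pd.DataFrame(m, index=pops, columns=pops)


def components_and_isolated(network: nx.Graph) -> tuple[list[set], set]:
    """Connected components plus the individuals outside the largest one.

    Components are sorted largest-first; ties broken by the lexicographically
    smallest member.  "Disconnected" individuals are all nodes not in the
    largest component.
    """
    comps = [set(c) for c in nx.connected_components(network)]
    if not comps:
        return [], set()
    comps.sort(key=lambda c: (-len(c), min(c)))
    disconnected = set(network.nodes) - comps[0]
    return comps, disconnected


def modularity_communities(network: nx.Graph, weight: str | None = "count") -> list[set]:
    """Exploratory greedy-modularity grouping of the network.

    Visible "modules" of a co-ancestry network are usually read off a
    layout by eye; this gives a reproducible approximation, but community
    assignments are descriptive only and carry no statistical guarantee.
    Returns communities sorted largest-first.
    """
    if network.number_of_nodes() == 0:
        return []
    comms = nx.community.greedy_modularity_communities(network, weight=weight)
    return sorted((set(c) for c in comms), key=lambda c: (-len(c), min(c)))


def regional_subnetwork(
    network: nx.Graph,
    population_table: PopulationTable,
    focal_populations: Iterable[str],
) -> nx.Graph:
    """Induced subgraph on focal-population members plus their IBD neighbors.

    One hop only: neighbors-of-neighbors are excluded.
    """
    focal = list(focal_populations)
    known = set(population_table.populations)
    for p in focal:
        if p not in known:
            raise KeyError(f"unknown population {p!r}")
    focal_set = set(focal)
    members = {n for n in network.nodes if network.nodes[n].get("population") in focal_set}
    neighbors = {nb for n in members for nb in network.neighbors(n)}
    return network.subgraph(members | neighbors).copy()


def export_network(
    network: nx.Graph,
    path: str | Path,
    format: Literal["graphml", "tsv"] = "graphml",
) -> None:
    """Write the network to GraphML or an edge-list TSV.

    GraphML preserves isolated nodes and all attributes and round-trips via
    :func:`import_network`.  The TSV lists one edge per row with both node
    populations and the edge weights; isolated nodes are not representable
    in an edge list.
    """
    if format == "graphml":
        nx.write_graphml(network, path)
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("sample_a\tpopulation_a\tsample_b\tpopulation_b\tcount\ttotal_cM\n")
            for a, b, data in sorted(network.edges(data=True)):
                fh.write(
                    f"{a}\t{network.nodes[a].get('population', '')}\t"
                    f"{b}\t{network.nodes[b].get('population', '')}\t"
                    f"{data['count']}\t{data['total_cM']!r}\n"
                )
    else:
        raise ValueError(f"unknown network format {format!r}")


def import_network(path: str | Path, format: Literal["graphml", "tsv"] = "graphml") -> nx.Graph:
    """Read a network written by :func:`export_network`."""
    if format == "graphml":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, str)
        for _, _, data in g.edges(data=True):
            data["count"] = int(data["count"])
            data["total_cM"] = float(data["total_cM"])
        return g
    if format == "tsv":
        g = nx.Graph()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                a, pa, b, pb, count, total = line.rstrip("\n").split("\t")
                g.add_node(a, population=pa)
                g.add_node(b, population=pb)
                g.add_edge(a, b, count=int(count), total_cM=float(total))
        return g
    raise ValueError(f"unknown network format {format!r}")
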