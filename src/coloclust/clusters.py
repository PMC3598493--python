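"""Gap-bounded cluster detection and distance distributions.

A run of query genes G_1..G_n on one chromosome forms a cluster when the
total number of intervening non-query genes does not exceed the gap
parameter d:

    x(G_n) - x(G_1) - n + 1 <= d

with x(G) the gene's positional order on its chromosome.  Clusters are
built by a single greedy left-to-right scan: the open cluster is extended
with the next query gene exactly when the extended run still satisfies
the inequality; otherwise it is closed and a new one opened.  Query genes
ending up alone are singletons and are excluded from cluster counts and
size histograms (clusters are size 2 or larger).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

from .genome import ConfigurationError, GeneRecord, GenomeAnnotation

__all__ = [
    "DEFAULT_GAP_PARAMETER",
    "Cluster",
    "ClusterSet",
    "DistanceHistogram",
    "find_clusters",
    "distance_distribution",
    "cluster_size_histogram",
]

#: Default maximum number of total intervening genes allowed in a cluster.
DEFAULT_GAP_PARAMETER = 2


@dataclass
class Cluster:
    """A maximal gap-bounded run of query genes on one chromosome."""

    species: str
    chromosome: str
    members: list[GeneRecord]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span_gaps(self) -> int:
        """Total intervening non-member genes: x(G_n) - x(G_1) - n + 1."""
        return self.members[-1].rank - self.members[0].rank - self.size + 1

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.members]

    @property
    def start_bp(self) -> int:
        return min(g.start for g in self.members)

    @property
    def end_bp(self) -> int:
        return max(g.end for g in self.members)


@dataclass
class ClusterSet:
    """All clusters (size >= 2) and singletons for one species at one d."""

    species: str
    d: int
    clusters: list[Cluster] = field(default_factory=list)
    singletons: list[GeneRecord] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_query_genes(self) -> int:
        return sum(c.size for c in self.clusters) + len(self.singletons)

    def member_sets(self) -> list[set[str]]:
        """Cluster memberships as sets of gene ids (for conservation math)."""
        return [set(c.gene_ids) for c in self.clusters]


@dataclass
class DistanceHistogram:
    """Counts of rank distances between consecutive query genes.

    Distance 1 means adjacent genes; pairs never span chromosomes, so
    total_pairs = sum over chromosomes of max(m_c - 1, 0).
    """

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total_pairs(self) -> int:
        return sum(self.counts.values())

    def get(self, distance: int) -> int:
        return self.counts.get(distance, 0)

    @property
    def max_distance(self) -> int:
        return max(self.counts) if self.counts else 0


def _query_ranks_by_chromosome(
    annotation: GenomeAnnotation, query_genes: Iterable[str]
) -> dict[str, list[GeneRecord]]:
    query = set(query_genes)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in annotation.genes:  # already in (chromosome, rank) order
        if g.gene_id in query:
            by_chrom.setdefault(g.chromosome, []).append(g)
    return by_chrom


def find_clusters(
    annotation: GenomeAnnotation,
    query_genes: Iterable[str],
    d: int = DEFAULT_GAP_PARAMETER,
) -> ClusterSet:
    """Greedy left-to-right gap-bounded clustering of the query genes.

    Every resolved query gene lands in exactly one cluster or singleton;
    query ids absent from the annotation are silently skipped (they were
    reported missing upstream).
    """
    if d < 0:
        raise ConfigurationError(f"gap parameter d must be >= 0, got {d}")
    clusters: list[Cluster] = []
    singletons: list[GeneRecord] = []

    def close(run: list[GeneRecord], chrom: str) -> None:
        if len(run) >= 2:
            clusters.append(Cluster(annotation.species, chrom, list(run)))
        else:
            singletons.extend(run)

    for chrom, genes in _query_ranks_by_chromosome(annotation, query_genes).items():
        run: list[GeneRecord] = []
        for g in genes:
            if run and g.rank - run[0].rank - len(run) > d:
                # extending would exceed d intervening genes
                close(run, chrom)
                run = []
            run.append(g)
        if run:
            close(run, chrom)
    return ClusterSet(species=annotation.species, d=d, clusters=clusters, singletons=singletons)


def distance_distribution(
    annotation: GenomeAnnotation, query_genes: Iterable[str]
) -> DistanceHistogram:
    """Histogram of rank distances between consecutive query genes."""
    counts: dict[int, int] = {}
    for genes in _query_ranks_by_chromosome(annotation, query_genes).values():
        for a, b in zip(genes, genes[1:]):
            dist = b.rank - a.rank
            counts[dist] = counts.get(dist, 0) + 1
    return DistanceHistogram(counts=counts)


def cluster_size_histogram(
    cluster_set: ClusterSet, max_size: int = 10
) -> dict[Union[int, str], int]:
    """Cluster-size counts with sizes beyond ``max_size`` pooled into ">N".

    Only clusters (size >= 2) are counted; singletons never appear.
    """
    if max_size < 2:
        raise ConfigurationError(f"max_size must be >= 2, got {max_size}")
    hist: dict[Union[int, str], int] = {}
    overflow_key = f">{max_size}"
    for c in cluster_set.clusters:
        key: Union[int, str] = c.size if c.size <= max_size else overflow_key
        hist[key] = hist.get(key, 0) + 1
    return hist
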