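"""Synthetic genomes with planted clusters and controlled rearrangement.

The generator builds a genome whose query genes are laid out in planted
runs: each run holds ``cluster_size`` query genes with exactly
``intra_cluster_gaps`` non-query genes inside it, and runs are separated
by strictly more non-query genes than that, so a gap parameter
d >= intra_cluster_gaps recovers every planted run exactly and never
merges two of them (given the background is wide enough).  A derived
"species" relocates a controlled fraction of genes to uniform random
slots, degrading colocalization continuously from perfect conservation
(rate 0) to near-total cluster loss (rate 1) while conserving gene
content one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome import ConfigurationError, GeneRecord, GenomeAnnotation, assign_ranks
from .homology import HomologyTable

__all__ = ["SyntheticSpec", "generate_genome", "derive_species", "planted_cluster_ids"]

_GENE_BP = 500
_SLOT_BP = 1000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic genome with planted query clusters."""

    n_genes: int = 1000
    n_chromosomes: int = 4
    n_planted_clusters: int = 10
    cluster_size: int = 4
    intra_cluster_gaps: int = 2
    rearrangement_rate: float = 0.0
    seed: int = 0
    n_background_query: int = 0

    def __post_init__(self) -> None:
        if self.cluster_size < 2:
            raise ConfigurationError("cluster_size must be >= 2")
        if self.intra_cluster_gaps < 0:
            raise ConfigurationError("intra_cluster_gaps must be >= 0")
        if not 0.0 <= self.rearrangement_rate <= 1.0:
            raise ConfigurationError("rearrangement_rate must be in [0, 1]")
        if self.n_planted_clusters * (self.cluster_size + self.intra_cluster_gaps) > self.n_genes:
            raise ConfigurationError(
                "planted clusters do not fit: "
                f"{self.n_planted_clusters} x ({self.cluster_size} + "
                f"{self.intra_cluster_gaps}) > {self.n_genes} genes"
            )


def _chromosome_sizes(n_genes: int, n_chromosomes: int) -> list[int]:
    base, extra = divmod(n_genes, n_chromosomes)
    return [base + (1 if i < extra else 0) for i in range(n_chromosomes)]


def _cluster_layout(cluster_size: int, gaps: int) -> list[bool]:
    """Flags (True = query gene) for one planted run, gaps spread evenly
    over the cluster's inner slots."""
    inner = cluster_size - 1
    per_slot, extra = divmod(gaps, inner)
    layout: list[bool] = []
    for i in range(cluster_size):
        layout.append(True)
        if i < inner:
            layout.extend([False] * (per_slot + (1 if i < extra else 0)))
    return layout


def generate_genome(spec: SyntheticSpec) -> tuple[GenomeAnnotation, list[str]]:
    """Build the synthetic genome and its query gene list.

    Genes are named ``s1..sN`` in genome order and distributed
    round-robin-proportionally over chromosomes; coordinates are
    synthetic (start = rank * 1000, 500 bp long).  Returns the ranked
    annotation and the query list (planted genes first, in genome order,
    then any background query genes).
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _chromosome_sizes(spec.n_genes, spec.n_chromosomes)
    run_len = spec.cluster_size + spec.intra_cluster_gaps
    # planted runs round-robin over chromosomes
    runs_per_chrom = [0] * spec.n_chromosomes
    for c in range(spec.n_planted_clusters):
        runs_per_chrom[c % spec.n_chromosomes] += 1

    layout = _cluster_layout(spec.cluster_size, spec.intra_cluster_gaps)
    # per-chromosome boolean sequence: True = planted query gene
    is_query: list[bool] = []
    chrom_of: list[int] = []
    for c, (m_c, n_runs) in enumerate(zip(sizes, runs_per_chrom)):
        background = m_c - n_runs * run_len
        n_segments = n_runs + 1
        if n_runs and background < n_segments * (spec.intra_cluster_gaps + 1):
            raise ConfigurationError(
                f"chromosome {c + 1}: not enough background genes ({background}) to "
                f"separate {n_runs} planted runs by more than "
                f"{spec.intra_cluster_gaps} genes"
            )
        seg, extra = divmod(background, n_segments)
        flags: list[bool] = []
        for s in range(n_segments):
            flags.extend([False] * (seg + (1 if s < extra else 0)))
            if s < n_runs:
                flags.extend(layout)
        assert len(flags) == m_c
        is_query.extend(flags)
        chrom_of.extend([c] * m_c)

    genes: list[GeneRecord] = []
    query: list[str] = []
    rank_in_chrom = 0
    current_chrom = -1
    for idx, (flag, c) in enumerate(zip(is_query, chrom_of), start=1):
        if c != current_chrom:
            current_chrom = c
            rank_in_chrom = 0
        rank_in_chrom += 1
        start = rank_in_chrom * _SLOT_BP
        gid = f"s{idx}"
        genes.append(
            GeneRecord(
                gene_id=gid,
                chromosome=f"chr{c + 1}",
                start=start,
                end=start + _GENE_BP - 1,
            )
        )
        if flag:
            query.append(gid)

    if spec.n_background_query:
        non_planted = [g.gene_id for g, f in zip(genes, is_query) if not f]
        if spec.n_background_query > len(non_planted):
            raise ConfigurationError("n_background_query exceeds available background genes")
        picks = rng.choice(len(non_planted), size=spec.n_background_query, replace=False)
        query.extend(non_planted[i] for i in sorted(picks))

    annotation = assign_ranks(GenomeAnnotation(species="ref", genes=genes))
    return annotation, query


def planted_cluster_ids(
    annotation: GenomeAnnotation, query: list[str], spec: SyntheticSpec
) -> list[set[str]]:
    """Recover the planted runs as sets of gene ids (ground truth for recall)."""
    planted = query[: spec.n_planted_clusters * spec.cluster_size]
    return [
        set(planted[i : i + spec.cluster_size])
        for i in range(0, len(planted), spec.cluster_size)
    ]


def derive_species(
    ref: GenomeAnnotation,
    query: list[str],
    rate: float,
    species_name: str,
    seed: int,
) -> tuple[GenomeAnnotation, HomologyTable]:
    """Derive a rearranged species from the reference genome.

    Every gene gets a one-to-one ortholog named ``<species>_<gene_id>``.
    A fraction ``rate`` of genes, chosen uniformly, is removed from the
    gene order and reinserted at uniform random positions; chromosome
    sizes are preserved and positions re-ranked, so rate 0 reproduces the
    reference order exactly and rate 1 approaches a random shuffle.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"rearrangement rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    order = [g.gene_id for g in ref.genes]  # genome order: chrom then rank
    chrom_sizes = [(c, len(ref.genes_on(c))) for c in ref.chromosomes]
    n = len(order)
    n_move = int(round(rate * n))
    if n_move:
        move_idx = set(rng.choice(n, size=n_move, replace=False).tolist())
        movers = [order[i] for i in sorted(move_idx)]
        remaining = [g for i, g in enumerate(order) if i not in move_idx]
        for gid in movers:
            pos = int(rng.integers(0, len(remaining) + 1))
            remaining.insert(pos, gid)
        order = remaining

    genes: list[GeneRecord] = []
    pos = 0
    for chrom, m_c in chrom_sizes:
        for r in range(1, m_c + 1):
            gid = order[pos]
            start = r * _SLOT_BP
            genes.append(
                GeneRecord(
                    gene_id=f"{species_name}_{gid}",
                    chromosome=chrom,
                    start=start,
                    end=start + _GENE_BP - 1,
                )
            )
            pos += 1
    derived = assign_ranks(GenomeAnnotation(species=species_name, genes=genes))
    table = HomologyTable(
        entries=[(g.gene_id, species_name, f"{species_name}_{g.gene_id}") for g in ref.genes]
    )
    return derived, table
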