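"""Run orchestration, tabular outputs, and Circos data files.

An analysis run resolves the query per species (through the homology
table for non-reference species), finds clusters, builds the distance
and cluster-size histograms, estimates the permutation null, and writes
everything as TSV plus a machine-readable summary.  Species are
processed independently: a failure in one species is recorded in the
summary and does not abort the others.

Every table written here is re-parseable by the readers in this module;
runs with the same seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .clusters import (
    DEFAULT_GAP_PARAMETER,
    Cluster,
    ClusterSet,
    DistanceHistogram,
    cluster_size_histogram,
    distance_distribution,
    find_clusters,
)
from .conservation import ConservationResult, conservation_matrix
from .genome import (
    GeneRecord,
    GenomeAnnotation,
    InputError,
    QueryResolution,
    load_annotation,
    read_query_file,
    resolve_query,
)
from .homology import HomologyTable, load_homology, map_query
from .significance import DEFAULT_P_MIN, NullEstimate, estimate_null, n_iterations_for, simulate_null

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunSummary",
    "run_analyze",
    "run_compare",
    "write_circos",
    "write_clusters_tsv",
    "read_clusters_tsv",
    "write_distance_hist_tsv",
    "read_distance_hist_tsv",
    "write_pvalues_tsv",
    "write_size_hist_tsv",
    "write_conservation_tsv",
]

_CIRCOS_COLORS = [
    "chr1", "chr2", "chr3", "chr4", "chr5", "chr6", "chr7", "chr8",
    "chr9", "chr10", "chr11", "chr12", "chr13", "chr14", "chr15", "chr16",
    "chr17", "chr18", "chr19", "chr20", "chr21", "chr22",
]


@dataclass
class RunConfig:
    """Effective parameters of one analysis run (all logged)."""

    d: int = DEFAULT_GAP_PARAMETER
    p_min: float = DEFAULT_P_MIN
    max_distance_axis: int = 50
    max_cluster_size_axis: int = 10
    seed: int = 42
    ref_species: str = "human"
    output_dir: Path = Path(".")
    add_one: bool = False

    @property
    def n_iterations(self) -> int:
        return n_iterations_for(self.p_min)


@dataclass
class SpeciesReport:
    species: str
    n_found: int = 0
    missing: list[str] = field(default_factory=list)
    duplicates_removed: int = 0
    n_clusters: int = 0
    n_singletons: int = 0
    largest_cluster: int = 0
    error: Optional[str] = None
    files: dict[str, str] = field(default_factory=dict)


@dataclass
class RunSummary:
    config: RunConfig
    species: dict[str, SpeciesReport] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "parameters": {
                "d": self.config.d,
                "p_min": self.config.p_min,
                "n_iterations": self.config.n_iterations,
                "max_distance_axis": self.config.max_distance_axis,
                "max_cluster_size_axis": self.config.max_cluster_size_axis,
                "seed": self.config.seed,
                "ref_species": self.config.ref_species,
                "add_one": self.config.add_one,
            },
            "species": {
                name: {
                    "genes_found": rep.n_found,
                    "missing": rep.missing,
                    "duplicates_removed": rep.duplicates_removed,
                    "n_clusters": rep.n_clusters,
                    "n_singletons": rep.n_singletons,
                    "largest_cluster": rep.largest_cluster,
                    "error": rep.error,
                    "files": rep.files,
                }
                for name, rep in self.species.items()
            },
        }


# ---------------------------------------------------------------------------
# TSV writers / readers (all round-trip)


def write_clusters_tsv(cluster_set: ClusterSet, path: Union[str, Path]) -> None:
    lines = ["species\tcluster_id\tchromosome\tsize\tspan_gaps\tgene_ids\tstart_bp\tend_bp"]
    for i, c in enumerate(cluster_set.clusters, start=1):
        lines.append(
            f"{c.species}\tc{i}\t{c.chromosome}\t{c.size}\t{c.span_gaps}\t"
            f"{','.join(c.gene_ids)}\t{c.start_bp}\t{c.end_bp}"
        )
    for j, g in enumerate(cluster_set.singletons, start=1):
        lines.append(
            f"{cluster_set.species}\tsingleton{j}\t{g.chromosome}\t1\t0\t"
            f"{g.gene_id}\t{g.start}\t{g.end}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_clusters_tsv(
    path: Union[str, Path], annotation: GenomeAnnotation, d: int
) -> ClusterSet:
    """Rebuild a ClusterSet from its TSV, resolving members in the annotation."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_ids": str})
    index = annotation.by_id()
    clusters: list[Cluster] = []
    singletons: list[GeneRecord] = []
    species = str(df["species"].iloc[0]) if len(df) else annotation.species
    for row in df.itertuples(index=False):
        ids = str(row.gene_ids).split(",")
        try:
            members = [index[g] for g in ids]
        except KeyError as exc:
            raise InputError(f"{path}: gene {exc.args[0]!r} not in annotation") from exc
        if len(members) >= 2:
            clusters.append(Cluster(species, str(row.chromosome), members))
        else:
            singletons.extend(members)
    return ClusterSet(species=species, d=d, clusters=clusters, singletons=singletons)


def write_distance_hist_tsv(hist: DistanceHistogram, path: Union[str, Path]) -> None:
    lines = ["distance\tcount"]
    lines += [f"{t}\t{hist.counts[t]}" for t in sorted(hist.counts)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_distance_hist_tsv(path: Union[str, Path]) -> DistanceHistogram:
    df = pd.read_csv(path, sep="\t")
    return DistanceHistogram(counts={int(r.distance): int(r.count) for r in df.itertuples()})


def write_size_hist_tsv(hist: Mapping[Union[int, str], int], path: Union[str, Path]) -> None:
    def sort_key(k: Union[int, str]):
        return (0, k) if isinstance(k, int) else (1, 0)

    lines = ["size\tcount"]
    lines += [f"{k}\t{hist[k]}" for k in sorted(hist, key=sort_key)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_pvalues_tsv(
    observed: DistanceHistogram, estimate: NullEstimate, path: Union[str, Path]
) -> None:
    lines = ["distance\tobserved_count\tnull_mean\tp_value\tn_iterations"]
    for t in sorted(estimate.p_values):
        lines.append(
            f"{t}\t{observed.get(t)}\t{estimate.mean_counts[t]:.6g}\t"
            f"{estimate.format_p(t)}\t{estimate.n_iterations}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_conservation_tsv(result: ConservationResult, path: Union[str, Path]) -> None:
    lines = ["ref_species\ttarget_species\tscore\tn_ref_clusters\tn_target_clusters"]
    for sp in result.scores:
        lines.append(
            f"{result.ref_species}\t{sp}\t{result.scores[sp]:.6f}\t"
            f"{result.n_ref_clusters}\t{result.n_target_clusters[sp]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Circos data files


def write_circos(
    annotation: GenomeAnnotation,
    cluster_set: ClusterSet,
    output_dir: Union[str, Path],
) -> list[Path]:
    """Emit Circos-syntax data files for one species' clusters.

    Writes a karyotype (one line per chromosome carrying >= 1 gene), a
    histogram track (one line per cluster, value = cluster size), and a
    text-label track (one line per clustered gene).  Rendering is left
    to an external Circos install.
    """
    if cluster_set.n_clusters == 0:
        warnings.warn(
            f"no clusters of size >= 2 for species {cluster_set.species!r}; "
            "skipping Circos output",
            stacklevel=2,
        )
        return []
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    karyotype = outdir / "karyotype.txt"
    lines = []
    for i, chrom in enumerate(annotation.chromosomes):
        length = annotation.chromosome_lengths.get(chrom, 0)
        color = _CIRCOS_COLORS[i % len(_CIRCOS_COLORS)]
        lines.append(f"chr - {chrom} {chrom} 0 {length} {color}")
    karyotype.write_text("\n".join(lines) + "\n")

    hist = outdir / "clusters.hist.txt"
    lines = [
        f"{c.chromosome} {c.start_bp} {c.end_bp} {c.size}" for c in cluster_set.clusters
    ]
    hist.write_text("\n".join(lines) + "\n")

    labels = outdir / "labels.txt"
    lines = [
        f"{c.chromosome} {g.start} {g.end} {g.gene_id}"
        for c in cluster_set.clusters
        for g in c.members
    ]
    labels.write_text("\n".join(lines) + "\n")
    return [karyotype, hist, labels]


# ---------------------------------------------------------------------------
# orchestration


def _analyze_one_species(
    config: RunConfig,
    species: str,
    annotation: GenomeAnnotation,
    query_ids: Sequence[str],
    outdir: Path,
) -> SpeciesReport:
    report = SpeciesReport(species=species)
    resolution = resolve_query(annotation, query_ids)
    report.n_found = len(resolution.found)
    report.missing = list(resolution.missing)
    report.duplicates_removed = resolution.duplicates_removed

    cluster_set = find_clusters(annotation, resolution.found_ids, config.d)
    report.n_clusters = cluster_set.n_clusters
    report.n_singletons = len(cluster_set.singletons)
    report.largest_cluster = max((c.size for c in cluster_set.clusters), default=0)

    observed = distance_distribution(annotation, resolution.found_ids)
    size_hist = cluster_size_histogram(cluster_set, config.max_cluster_size_axis)

    outdir.mkdir(parents=True, exist_ok=True)
    write_clusters_tsv(cluster_set, outdir / "clusters.tsv")
    write_distance_hist_tsv(observed, outdir / "distance_hist.tsv")
    write_size_hist_tsv(size_hist, outdir / "size_hist.tsv")
    # paths are kept relative to the run's output root so identical runs
    # into different directories stay byte-identical
    report.files = {
        "clusters": f"{species}/clusters.tsv",
        "distance_hist": f"{species}/distance_hist.tsv",
        "size_hist": f"{species}/size_hist.tsv",
    }

    k = len(resolution.found)
    if k >= 2:
        draws = simulate_null(annotation, k, config.n_iterations, config.seed)
        estimate = estimate_null(
            observed,
            draws,
            p_min=config.p_min,
            add_one=config.add_one,
            seed=config.seed,
            max_distance_axis=config.max_distance_axis,
        )
        write_pvalues_tsv(observed, estimate, outdir / "pvalues.tsv")
        report.files["pvalues"] = f"{species}/pvalues.tsv"
    else:
        logger.warning("species %s: fewer than 2 query genes found; null model skipped", species)
    return report


def run_analyze(
    config: RunConfig,
    annotations: Mapping[str, GenomeAnnotation],
    query: Sequence[str],
    homology: Optional[HomologyTable] = None,
) -> RunSummary:
    """Run the per-species colocalization analysis.

    ``annotations`` maps species label -> ranked annotation and must
    include ``config.ref_species``; for any other species a homology
    table is required to translate the query.  Writes per-species TSVs
    under ``output_dir/<species>/`` and a summary.json at the top.
    """
    if config.ref_species not in annotations:
        raise InputError(
            f"reference species {config.ref_species!r} not among annotations "
            f"{sorted(annotations)}"
        )
    non_ref = [s for s in annotations if s != config.ref_species]
    if non_ref and homology is None:
        raise InputError("a homology table is required when analyzing more than one species")

    summary = RunSummary(config=config)
    outroot = Path(config.output_dir)
    for species, annotation in annotations.items():
        outdir = outroot / species
        try:
            if species == config.ref_species:
                species_query: Sequence[str] = list(query)
            else:
                assert homology is not None
                ref_found = resolve_query(annotations[config.ref_species], query).found_ids
                sq = map_query(homology, ref_found, species)
                if sq.empty_species:
                    logger.warning("species %s absent from homology table", species)
                species_query = sorted(sq.target_genes)
                if not species_query:
                    summary.species[species] = SpeciesReport(
                        species=species, error="no orthologs found"
                    )
                    continue
            summary.species[species] = _analyze_one_species(
                config, species, annotation, species_query, outdir
            )
        except Exception as exc:  # independent per-species processing
            logger.error("species %s failed: %s", species, exc)
            summary.species[species] = SpeciesReport(species=species, error=str(exc))

    outroot.mkdir(parents=True, exist_ok=True)
    (outroot / "summary.json").write_text(
        json.dumps(summary.to_json(), indent=2, sort_keys=True) + "\n"
    )
    return summary


def run_compare(
    config: RunConfig,
    cluster_sets: Mapping[str, ClusterSet],
    back_maps: Mapping[str, Optional[Mapping[str, set[str]]]],
) -> ConservationResult:
    """Conservation of the reference clusters in every other species.

    ``back_maps[species]`` translates that species' gene ids back to
    reference query genes (``None`` for the reference itself).  Writes
    conservation.tsv under the output directory.
    """
    if config.ref_species not in cluster_sets:
        raise InputError(f"reference species {config.ref_species!r} missing from cluster sets")
    if len(cluster_sets) < 1:
        raise InputError("nothing to compare")
    ref = cluster_sets[config.ref_species]
    targets = []
    for species, cs in cluster_sets.items():
        back_map = None if species == config.ref_species else back_maps.get(species)
        targets.append((species, cs, back_map))
    result = conservation_matrix(ref, targets)
    outroot = Path(config.output_dir)
    outroot.mkdir(parents=True, exist_ok=True)
    write_conservation_tsv(result, outroot / "conservation.tsv")
    return result
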