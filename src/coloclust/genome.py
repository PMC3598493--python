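"""Genome annotations and per-chromosome gene ranks.

Every downstream computation — cluster detection, distance histograms,
the permutation null — works on the *positional order* of genes, not on
base-pair coordinates: the rank of a gene is its 1-based index within
its chromosome once genes are sorted by position.  This module reads
annotations from TSV / GFF3 / BED, normalizes coordinates to a 1-based
inclusive convention, and assigns those ranks deterministically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "QueryResolution",
    "InputError",
    "ConfigurationError",
    "load_annotation",
    "assign_ranks",
    "resolve_query",
    "write_annotation_tsv",
    "read_query_file",
]


class InputError(ValueError):
    """Malformed or inconsistent user input (files, queries)."""


class ConfigurationError(ValueError):
    """Invalid parameter or option combination."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identifier, location, and (once assigned) its rank.

    Coordinates are 1-based inclusive; ``rank`` is the gene's 1-based
    positional order within its chromosome, unique per chromosome and
    contiguous 1..m_c.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    biotype: Optional[str] = None
    strand: Optional[str] = None  # read if present, ignored by all math
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InputError(
                f"gene {self.gene_id!r}: end ({self.end}) < start ({self.start})"
            )


@dataclass
class GenomeAnnotation:
    """Ordered gene records for one species.

    ``genes`` is kept sorted by (chromosome, rank) once ranks are
    assigned.  ``chromosome_lengths`` defaults to the maximum observed
    gene end per chromosome when not supplied.
    """

    species: str
    genes: list[GeneRecord] = field(default_factory=list)
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise InputError(
                    f"duplicate gene_id {g.gene_id!r} in species {self.species!r}"
                )
            seen.add(g.gene_id)
        if not self.chromosome_lengths:
            lengths: dict[str, int] = {}
            for g in self.genes:
                lengths[g.chromosome] = max(lengths.get(g.chromosome, 0), g.end)
            self.chromosome_lengths = lengths

    # -- convenience accessors -------------------------------------------

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.chromosome, None)
        return list(seen)

    def by_id(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}

    def genes_on(self, chromosome: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.chromosome == chromosome]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chromosome": [g.chromosome for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "biotype": [g.biotype for g in self.genes],
                "rank": [g.rank for g in self.genes],
            }
        )


@dataclass
class QueryResolution:
    """Outcome of matching a query gene list against one annotation."""

    found: list[GeneRecord]
    missing: list[str]
    duplicates_removed: int

    @property
    def found_ids(self) -> list[str]:
        return [g.gene_id for g in self.found]


def assign_ranks(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """Assign per-chromosome positional ranks 1..m_c.

    Genes on each chromosome are sorted by (start, end, gene_id); the
    identifier tie-break makes the ordering deterministic for genes with
    identical coordinates.  Idempotent.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in annotation.genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    ranked: list[GeneRecord] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        ranked.extend(replace(g, rank=i) for i, g in enumerate(genes, start=1))
    return GenomeAnnotation(
        species=annotation.species,
        genes=ranked,
        chromosome_lengths=dict(annotation.chromosome_lengths),
    )


# ---------------------------------------------------------------------------
# readers


_TSV_REQUIRED = ("gene_id", "chromosome", "start", "end")


def _read_tsv(path: Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    missing = [c for c in _TSV_REQUIRED if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    has_biotype = "biotype" in df.columns
    has_strand = "strand" in df.columns
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                chromosome=str(row.chromosome),
                start=int(row.start),
                end=int(row.end),
                biotype=(None if not has_biotype or pd.isna(row.biotype) else str(row.biotype)),
                strand=(None if not has_strand or pd.isna(row.strand) else str(row.strand)),
            )
        )
    return records


def _read_gff3(path: Path) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        if "ID" in attrs:
            gene_id = attrs["ID"][0]
        elif "gene_name" in attrs:
            gene_id = attrs["gene_name"][0]
        else:
            raise InputError(
                f"{path}: gene feature at {feat.seqid}:{feat.start} has no ID or gene_name"
            )
        biotype = attrs["biotype"][0] if "biotype" in attrs else (
            attrs["gene_biotype"][0] if "gene_biotype" in attrs else None
        )
        records.append(
            GeneRecord(
                gene_id=gene_id,
                chromosome=feat.seqid,
                start=feat.start,  # gffutils is already 1-based inclusive
                end=feat.end,
                biotype=biotype,
                strand=feat.strand if feat.strand in ("+", "-") else None,
            )
        )
    return records


def _read_bed(path: Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype={0: str, 3: str})
    if df.shape[1] < 4:
        raise InputError(f"{path}: BED input needs at least 4 columns (chrom start end name)")
    records = []
    for row in df.itertuples(index=False):
        strand = None
        if df.shape[1] >= 6 and row[5] in ("+", "-"):
            strand = row[5]
        # BED is 0-based half-open; internal convention is 1-based inclusive
        records.append(
            GeneRecord(
                gene_id=str(row[3]),
                chromosome=str(row[0]),
                start=int(row[1]) + 1,
                end=int(row[2]),
                strand=strand,
            )
        )
    return records


def load_annotation(
    path: str | Path,
    format: str = "tsv",
    biotype_filter: Optional[str] = None,
    species: Optional[str] = None,
) -> GenomeAnnotation:
    """Read a gene annotation and return it with ranks assigned.

    Parameters
    ----------
    path
        Annotation file.  TSV needs a header with gene_id, chromosome,
        start, end (biotype optional); GFF3 contributes only ``gene``
        features; BED columns 1-4 are used, with 0-based half-open
        coordinates converted on read.
    format
        One of ``tsv``, ``gff3``, ``bed``.
    biotype_filter
        If given and the source carries a biotype field, only matching
        genes are retained before ranking.
    species
        Label for the annotation; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    readers = {"tsv": _read_tsv, "gff3": _read_gff3, "bed": _read_bed}
    if format not in readers:
        raise ConfigurationError(
            f"unknown annotation format {format!r}; expected one of {sorted(readers)}"
        )
    records = readers[format](path)
    if biotype_filter is not None:
        records = [g for g in records if g.biotype == biotype_filter]
    annotation = GenomeAnnotation(
        species=species if species is not None else path.stem, genes=records
    )
    return assign_ranks(annotation)


def write_annotation_tsv(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation in the package's TSV dialect (round-trips)."""
    has_biotype = any(g.biotype is not None for g in annotation.genes)
    cols = ["gene_id", "chromosome", "start", "end"] + (["biotype"] if has_biotype else [])
    buf = io.StringIO()
    buf.write("\t".join(cols) + "\n")
    for g in annotation.genes:
        row = [g.gene_id, g.chromosome, str(g.start), str(g.end)]
        if has_biotype:
            row.append(g.biotype if g.biotype is not None else "")
        buf.write("\t".join(row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_query_file(path: str | Path, column: Optional[int] = None) -> list[str]:
    """Read a query gene list.

    Plain newline-delimited by default; for delimited files, ``column``
    selects the 1-based column holding the gene names (comma or tab
    separators are auto-detected).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"query file not found: {path}")
    text = path.read_text()
    if column is None:
        return [line.strip() for line in text.splitlines() if line.strip()]
    if column < 1:
        raise ConfigurationError("query column is 1-based; got %d" % column)
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if column > df.shape[1]:
        raise InputError(
            f"{path}: query column {column} requested but file has {df.shape[1]} columns"
        )
    return [v.strip() for v in df.iloc[:, column - 1].dropna().tolist() if v.strip()]


def resolve_query(
    annotation: GenomeAnnotation, query: Sequence[str] | Iterable[str]
) -> QueryResolution:
    """Match a query gene list against the annotation.

    Matching is case-sensitive and exact on gene_id.  Repeated query
    strings collapse to a single occurrence (counted); found genes come
    back in genome order (chromosome, rank).
    """
    query = list(query)
    if not query:
        raise InputError("query gene list is empty")
    seen: set[str] = set()
    unique: list[str] = []
    for q in query:
        if q in seen:
            continue
        seen.add(q)
        unique.append(q)
    duplicates_removed = len(query) - len(unique)
    index = annotation.by_id()
    found = [index[q] for q in unique if q in index]
    found.sort(key=lambda g: (g.chromosome, g.rank if g.rank is not None else 0))
    missing = [q for q in unique if q not in index]
    return QueryResolution(found=found, missing=missing, duplicates_removed=duplicates_removed)
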