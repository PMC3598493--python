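"""Local ortholog tables mapping a reference query set into other species.

A plain TSV of (ref_gene_id, target_species, target_gene_id) triples
stands in for a live homology service.  Many-to-many relations are kept
as-is: a target gene with several reference parents participates once in
clustering, but contributes every parent when cluster conservation is
computed in reference-gene space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome import InputError

__all__ = ["HomologyTable", "SpeciesQuery", "load_homology", "map_query"]

_REQUIRED = ("ref_gene_id", "target_species", "target_gene_id")


@dataclass
class HomologyTable:
    """Deduplicated collection of (ref gene, target species, target gene) triples."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        unique = []
        for e in self.entries:
            if e not in seen:
                seen.add(e)
                unique.append(e)
        self.entries = unique

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, sp, _ in self.entries:
            seen.setdefault(sp, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SpeciesQuery:
    """The query set translated into one target species.

    ``back_map`` inverts the homology relation restricted to the query:
    target gene id -> the set of reference query genes it descends from.
    ``empty_species`` flags a species absent from the table (no orthologs
    found) as a warning condition rather than an error.
    """

    species: str
    target_genes: set[str] = field(default_factory=set)
    back_map: dict[str, set[str]] = field(default_factory=dict)
    empty_species: bool = False


def load_homology(path: str | Path) -> HomologyTable:
    """Read a homology TSV with header ref_gene_id, target_species, target_gene_id."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"homology file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    entries = [
        (str(r.ref_gene_id), str(r.target_species), str(r.target_gene_id))
        for r in df.itertuples(index=False)
    ]
    return HomologyTable(entries=entries)


def write_homology_tsv(table: HomologyTable, path: str | Path) -> None:
    lines = ["\t".join(_REQUIRED)]
    lines += ["\t".join(e) for e in table.entries]
    Path(path).write_text("\n".join(lines) + "\n")


def map_query(
    table: HomologyTable, ref_query: Sequence[str] | Iterable[str], species: str
) -> SpeciesQuery:
    """Translate reference query genes into ``species`` via the table.

    Monotone in the query (adding query genes never removes targets).  A
    species absent from the table yields an empty SpeciesQuery flagged
    ``empty_species`` — mirroring "no orthologs found", not an error.
    """
    query = set(ref_query)
    species_seen = False
    target_genes: set[str] = set()
    back_map: dict[str, set[str]] = {}
    for ref_id, sp, target_id in table.entries:
        if sp != species:
            continue
        species_seen = True
        if ref_id not in query:
            continue
        target_genes.add(target_id)
        back_map.setdefault(target_id, set()).add(ref_id)
    return SpeciesQuery(
        species=species,
        target_genes=target_genes,
        back_map=back_map,
        empty_species=not species_seen,
    )
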