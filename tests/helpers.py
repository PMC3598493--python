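"""Shared builders and independent oracles for the test suite.

The oracles here are deliberately naive (enumeration, longest-valid-
prefix search) and independent of the library's scanning/vectorized
implementations they check.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

from coloclust.genome import GeneRecord, GenomeAnnotation, assign_ranks


def make_annotation(chrom_sizes: Sequence[int], species: str = "ref") -> GenomeAnnotation:
    """Genome with chromosomes chr1.. of the given gene counts; genes are
    named s1..sN in genome order with synthetic coordinates."""
    genes = []
    gid = 0
    for c, m in enumerate(chrom_sizes):
        for r in range(1, m + 1):
            gid += 1
            genes.append(
                GeneRecord(f"s{gid}", f"chr{c + 1}", r * 1000, r * 1000 + 499)
            )
    return assign_ranks(GenomeAnnotation(species, genes))


def annotation_from_ranks(rank_map: dict[str, list[int]], species: str = "ref") -> GenomeAnnotation:
    """Genome where chromosome c has genes named <c>_g<rank> occupying the
    given ranks (all intermediate ranks are filled with <c>_f<rank>)."""
    genes = []
    for chrom, ranks in rank_map.items():
        top = max(ranks)
        for r in range(1, top + 1):
            name = f"{chrom}_g{r}" if r in ranks else f"{chrom}_f{r}"
            genes.append(GeneRecord(name, chrom, r * 1000, r * 1000 + 499))
    return assign_ranks(GenomeAnnotation(species, genes))


# ---------------------------------------------------------------------------
# greedy clustering oracle: longest valid prefix, found by checking every
# prefix, rather than by an incremental scan


def oracle_segments(ranks: Sequence[int], d: int) -> list[list[int]]:
    """Partition sorted ranks into blocks, each block the longest prefix of
    the remainder satisfying max - min - len + 1 <= d."""
    ranks = sorted(ranks)
    segments: list[list[int]] = []
    i = 0
    while i < len(ranks):
        best = i + 1
        for j in range(i + 1, len(ranks) + 1):
            block = ranks[i:j]
            if block[-1] - block[0] - len(block) + 1 <= d:
                best = j
        segments.append(ranks[i:best])
        i = best
    return segments


# ---------------------------------------------------------------------------
# exact null-distribution oracle by enumeration of all C(N, k) placements


def slot_distance_counts(slots: Sequence[int], chrom_sizes: Sequence[int]) -> np.ndarray:
    """Distance counts (index = distance) for one sorted placement of
    global gene slots over chromosomes of the given sizes."""
    n = int(sum(chrom_sizes))
    boundaries = np.cumsum(chrom_sizes)
    counts = np.zeros(n, dtype=np.int64)
    chroms = np.searchsorted(boundaries, slots, side="right")
    for (a, ca), (b, cb) in zip(zip(slots, chroms), zip(slots[1:], chroms[1:])):
        if ca == cb:
            counts[b - a] += 1
    return counts


def enumerate_null(chrom_sizes: Sequence[int], k: int) -> np.ndarray:
    """All C(N, k) placements as a (C(N,k) x N) matrix of distance counts."""
    n = int(sum(chrom_sizes))
    return np.array(
        [
            slot_distance_counts(c, chrom_sizes)
            for c in itertools.combinations(range(n), k)
        ]
    )
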