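"""Cross-species conservation of gene clusters.

Conservation of the reference species' clusters S_1..S_{N_S} in a target
species with clusters T_1..T_{N_T} is scored as

    Score(S, T) = (1/N_S) * sum_i sum_j |S_i ∩ T_j| / |S_i|

i.e. for each reference cluster, the fraction of its genes recovered
inside each target cluster, summed over target clusters and averaged
over reference clusters.  Intersections are taken in reference-gene
space: each target cluster is first translated through the homology
back-map (target gene -> reference query genes it descends from).  The
score is 1 when every reference cluster survives intact, 0 when no
reference cluster shares a gene with any target cluster, and is
asymmetric by design (normalization is by |S_i| only).  One-to-many
homology can push the score above 1; that is surfaced as a warning, not
an error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .clusters import ClusterSet
from .genome import InputError

__all__ = ["ConservationResult", "conservation_score", "translate_clusters", "conservation_matrix"]


@dataclass
class ConservationResult:
    """Scores of one reference species' clusters against each target."""

    ref_species: str
    scores: dict[str, float] = field(default_factory=dict)
    n_ref_clusters: int = 0
    n_target_clusters: dict[str, int] = field(default_factory=dict)
    per_cluster: dict[tuple[int, str], float] = field(default_factory=dict)


def translate_clusters(
    target_clusters: ClusterSet,
    back_map: Optional[Mapping[str, set[str]]] = None,
) -> list[set[str]]:
    """Translate target clusters into reference-gene space.

    Each cluster becomes the union of the back-map images of its member
    genes (set-deduplicated).  ``back_map=None`` means identity (same
    species, or pre-translated ids).
    """
    out = []
    for cluster in target_clusters.clusters:
        if back_map is None:
            out.append(set(cluster.gene_ids))
        else:
            translated: set[str] = set()
            for gid in cluster.gene_ids:
                translated |= set(back_map.get(gid, ()))
            out.append(translated)
    return out


def conservation_score(
    ref_clusters: ClusterSet,
    target_clusters: ClusterSet,
    back_map: Optional[Mapping[str, set[str]]] = None,
) -> float:
    """Score(S, T) for one species pair.

    Returns NaN (not 0) when the reference has no clusters: an undefined
    score is a different fact from "no overlap".  An empty target yields
    0 (empty inner sum).
    """
    if ref_clusters.n_clusters == 0:
        return math.nan
    ref_sets = ref_clusters.member_sets()
    target_sets = translate_clusters(target_clusters, back_map)
    total = 0.0
    for s in ref_sets:
        inner = sum(len(s & t) / len(s) for t in target_sets)
        total += inner
    score = total / len(ref_sets)
    if score > 1.0 + 1e-12:
        warnings.warn(
            f"conservation score {score:.4f} exceeds 1: many-to-many homology "
            "inflates reference-space intersections",
            stacklevel=2,
        )
    return score


def conservation_matrix(
    ref: ClusterSet,
    targets: Sequence[tuple[str, ClusterSet, Optional[Mapping[str, set[str]]]]],
) -> ConservationResult:
    """Score the reference cluster set against every target species.

    ``targets`` holds (species label, cluster set, back-map) triples; a
    ``None`` back-map means clusters are already in reference-gene space
    (the reference itself scores 1 against itself).
    """
    if ref.n_clusters == 0:
        raise InputError(
            f"reference species {ref.species!r} has no clusters of size >= 2; "
            "conservation is undefined"
        )
    result = ConservationResult(ref_species=ref.species, n_ref_clusters=ref.n_clusters)
    ref_sets = ref.member_sets()
    for species, cluster_set, back_map in targets:
        target_sets = translate_clusters(cluster_set, back_map)
        total = 0.0
        for i, s in enumerate(ref_sets):
            inner = sum(len(s & t) / len(s) for t in target_sets)
            result.per_cluster[(i, species)] = inner
            total += inner
        score = total / len(ref_sets)
        if score > 1.0 + 1e-12:
            warnings.warn(
                f"Score({ref.species}, {species}) = {score:.4f} exceeds 1 "
                "(many-to-many homology inflation)",
                stacklevel=2,
            )
        result.scores[species] = score
        result.n_target_clusters[species] = cluster_set.n_clusters
    return result
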