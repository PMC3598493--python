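"""Monte-Carlo significance of the consecutive-pair distance distribution.

The null model redistributes the k query genes uniformly at random over
all N gene slots of the genome (without replacement, genome-wide — a
relocated gene's chromosome is implied by the slot it lands in) and
recomputes the distance histogram.  Iterating and averaging gives the
expected null counts; the p-value at each distance is the frequency with
which a null count reaches or exceeds the observed count.  The iteration
count is set from the target minimum p-value as ceil(1/p_min), so the
smallest resolvable nonzero p is p_min itself; an observed count never
reached by the null is reported as "< 1/n".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .genome import GenomeAnnotation, InputError
from .clusters import DistanceHistogram

__all__ = [
    "DEFAULT_P_MIN",
    "NullEstimate",
    "n_iterations_for",
    "simulate_null",
    "estimate_null",
]

#: Default target minimum p-value -> 1000 iterations.
DEFAULT_P_MIN = 0.001


def n_iterations_for(p_min: float) -> int:
    """Iteration count implied by a target minimum p-value: ceil(1/p_min)."""
    if not 0 < p_min <= 1:
        raise InputError(f"p_min must be in (0, 1], got {p_min}")
    return math.ceil(1.0 / p_min)


@dataclass
class NullEstimate:
    """Per-distance null means and Monte-Carlo p-values."""

    mean_counts: dict[int, float]
    p_values: dict[int, float]
    n_iterations: int
    p_min: Optional[float] = None
    seed: Optional[int] = None
    add_one: bool = False

    def format_p(self, distance: int) -> str:
        """Render a p-value, with exact zero reported as a bound."""
        p = self.p_values[distance]
        if p == 0.0:
            return f"< {1.0 / self.n_iterations:g}"
        return f"{p:g}"


def _chromosome_sizes(annotation: GenomeAnnotation) -> np.ndarray:
    sizes: dict[str, int] = {}
    for g in annotation.genes:
        sizes[g.chromosome] = sizes.get(g.chromosome, 0) + 1
    return np.array([sizes[c] for c in sorted(sizes)], dtype=np.int64)


def _null_counts_matrix(
    chrom_sizes: np.ndarray, k: int, n_iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """Counts matrix (n_iterations x (N)) with column t = count at distance t.

    Column 0 is unused padding; distances are 1..N-1 at most.
    """
    n_total = int(chrom_sizes.sum())
    # k slots uniformly without replacement, per iteration, vectorized
    draws = np.argsort(rng.random((n_iterations, n_total)), axis=1)[:, :k]
    draws.sort(axis=1)
    boundaries = np.cumsum(chrom_sizes)
    chrom_of = np.searchsorted(boundaries, draws, side="right")
    diffs = np.diff(draws, axis=1)
    same = chrom_of[:, 1:] == chrom_of[:, :-1]
    rows = np.nonzero(same)[0]
    dists = diffs[same]
    mat = np.zeros((n_iterations, n_total), dtype=np.int64)
    np.add.at(mat, (rows, dists), 1)
    return mat


def simulate_null(
    annotation: GenomeAnnotation, k: int, n_iterations: int, seed: int
) -> list[DistanceHistogram]:
    """Draw ``n_iterations`` random placements of k genes and histogram each.

    Reproducible: the same (annotation, k, n_iterations, seed) always
    yields the same sequence of histograms.
    """
    n_total = len(annotation)
    if not 2 <= k <= n_total:
        raise InputError(f"query size k={k} must satisfy 2 <= k <= {n_total}")
    if n_iterations < 1:
        raise InputError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    mat = _null_counts_matrix(_chromosome_sizes(annotation), k, n_iterations, rng)
    out = []
    for row in mat:
        nz = np.nonzero(row)[0]
        out.append(DistanceHistogram(counts={int(t): int(row[t]) for t in nz}))
    return out


def _as_matrix(null_draws: Union[np.ndarray, Sequence[DistanceHistogram]]) -> np.ndarray:
    if isinstance(null_draws, np.ndarray):
        return null_draws
    draws = list(null_draws)
    maxd = max((h.max_distance for h in draws), default=0)
    mat = np.zeros((len(draws), maxd + 1), dtype=np.int64)
    for i, h in enumerate(draws):
        for t, c in h.counts.items():
            mat[i, t] = c
    return mat


def estimate_null(
    observed: DistanceHistogram,
    null_draws: Union[np.ndarray, Sequence[DistanceHistogram]],
    p_min: Optional[float] = None,
    add_one: bool = False,
    seed: Optional[int] = None,
    max_distance_axis: Optional[int] = None,
) -> NullEstimate:
    """Average the null draws and compute per-distance p-values.

    p[t] = (# draws with null count at t >= observed count at t) / n.
    The comparison is inclusive (ties count against the observation),
    the conservative reading.  With ``add_one`` the small-sample
    correction (b+1)/(n+1) is applied instead.

    The table covers every distance up to ``max_distance_axis`` (the
    histogram's reporting window) plus any larger distance actually
    observed; with ``max_distance_axis=None`` it spans the union of
    observed and null support.  An observed count of 0 gives p = 1 by
    construction.
    """
    mat = _as_matrix(null_draws)
    if mat.shape[0] == 0:
        raise InputError("null_draws must be nonempty")
    n = mat.shape[0]
    max_null = mat.shape[1] - 1
    if max_distance_axis is None:
        table_distances = range(1, max(observed.max_distance, max_null) + 1)
    else:
        table_distances = sorted(
            set(range(1, max_distance_axis + 1)) | set(observed.counts)
        )
    mean_counts: dict[int, float] = {}
    p_values: dict[int, float] = {}
    for t in table_distances:
        null_t = mat[:, t] if t <= max_null else np.zeros(n, dtype=np.int64)
        obs_t = observed.get(t)
        b = int(np.count_nonzero(null_t >= obs_t))
        p = (b + 1) / (n + 1) if add_one else b / n
        mean_counts[t] = float(null_t.mean())
        p_values[t] = p
    return NullEstimate(
        mean_counts=mean_counts,
        p_values=p_values,
        n_iterations=n,
        p_min=p_min,
        seed=seed,
        add_one=add_one,
    )
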