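# Methods

## Gene ranks and coordinates

All statistics operate on the *positional order* of genes, not on
base-pair coordinates: within each chromosome, genes sorted by
(start, end, gene_id) receive ranks 1..m_c. The identifier tie-break is
a convention — annotations contain overlapping genes with identical
starts, and determinism across input permutations matters more than any
particular choice. Internal coordinates are 1-based inclusive
(GFF3-native); BED's 0-based half-open intervals are converted on read.
Strand is read when present but ignored: no downstream quantity depends
on it. Biotype filtering (e.g. `protein_coding`) is opt-in because
plain TSV/BED inputs often carry no biotype column; when requested, the
filter is applied before ranking.

Distances between consecutive query genes are measured in rank units
(1 = adjacent), the same unit as the gap parameter d. Using one unit
for both keeps the distance histogram directly comparable with the
cluster definition; a base-pair x-axis would decouple the two.

## Cluster detection

A run of query genes G₁..Gₙ on one chromosome is a valid cluster when
x(Gₙ) − x(G₁) − n + 1 ≤ d, i.e. at most d non-query genes intervene in
total. The segmentation of an ambiguous run (e.g. ranks {1, 4, 7} at
d = 2, where either pair could cluster) is not dictated by the
inequality alone; we use a greedy left-to-right scan that extends the
open cluster while the inequality holds and otherwise closes it. This
is deterministic, linear-time, and equivalent to repeatedly taking the
longest valid prefix — the property the test suite checks against an
independent enumeration oracle. Clusters must have ≥ 2 members;
singletons are tracked separately and excluded from cluster counts,
size histograms, and conservation scores.

## Permutation null and p-values

The null hypothesis is that the query genes are placed uniformly at
random over the genome's N gene slots, without replacement and
genome-wide (not stratified by chromosome — a relocated gene's
chromosome is implied by the slot it lands in). Each of n iterations
recomputes the distance histogram; n = ceil(1/p_min) with default
p_min = 0.001, so the smallest resolvable nonzero p equals p_min.

The p-value at distance t is the frequency b/n of null counts ≥ the
observed count. The comparison is inclusive: counting ties against the
observation is the conservative choice for a discrete statistic. A zero
frequency is rendered as the bound "< 1/n" rather than 0. The add-one
correction (b+1)/(n+1) is available behind a flag but is off by
default, matching the plain-frequency definition. No multiple-testing
correction is applied across distance bins; the table carries raw
per-distance p-values and n.

The reported table covers every distance up to the histogram's x-axis
cap (`max_distance_axis`, default 50) plus any larger distance actually
observed. This window is what a user inspects alongside the distance
plot; distances beyond it with no observation are omitted rather than
padded with p = 1 rows.

Sampling is vectorized: each iteration's k slots come from one
`argsort` of uniform variates (an exact uniform draw without
replacement), and per-distance counts accumulate with `np.add.at`. At
the default problem sizes (N ≈ 10³–10⁵, n = 1000) a run takes seconds.

## Conservation score

Score(S, T) = (1/Nₛ) Σᵢ Σⱼ |Sᵢ ∩ Tⱼ| / |Sᵢ| over reference clusters Sᵢ
and target clusters Tⱼ. Intersections are computed in reference-gene
space: each target cluster is first translated through the homology
back-map (target gene → the set of reference query genes it descends
from), because one-to-many orthology makes an intersection of raw gene
ids ill-defined across species. A target gene with several reference
parents contributes each of them (set-deduplicated within a cluster);
when multiple target clusters map onto the same reference genes the
score can exceed 1, which is surfaced as a warning, not an error — it
is a property of the orthology table, not a failure. A reference with
no size-≥2 clusters yields NaN (undefined), never 0, since 0 is the
distinct statement "no overlap". The score is asymmetric by
construction; conservation of T's clusters relative to S requires the
reverse call.

## Synthetic genomes

The generator plants `n_planted_clusters` runs of `cluster_size` query
genes, each containing exactly `intra_cluster_gaps` non-query genes
(spread evenly over the run's interior), on chromosomes of near-equal
size, with runs separated by strictly more background genes than the
intra-run gap count. Construction therefore guarantees that
`find_clusters` at d ≥ intra_cluster_gaps recovers every planted run
exactly, and that d < the spacing between members leaves singletons —
the recall properties the tests assert are consequences of the layout,
not tuned behavior. Default spec (1000 genes, 4 chromosomes, 10
planted clusters of size 4 with 2 internal gaps) gives each chromosome
≈ 95 background genes between runs, far above any plausible d.

Derived species model rearrangement as single-gene relocation: a
fraction `rate` of genes, chosen uniformly, is removed from the gene
order and reinserted at uniform random positions, preserving
chromosome sizes. This degrades colocalization continuously — rate 0
is the identity, rate 1 approaches a random shuffle — without modeling
block inversions, translocations, duplication or loss. Orthology is
one-to-one by construction (`<species>_<gene>`), so conservation-score
inflation never arises from the generator. What the synthetic data does
not emulate: realistic gene-density variation, chromosome-scale
rearrangement structure, missing orthologs, or many-to-many homology;
passing tests demonstrate the algorithms' correctness under the model,
not the biology of any particular clade.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; same-seed runs are byte-identical down to
the emitted TSVs (the run summary stores file paths relative to the
output root for this reason).

## Problem sizes and numerical choices

The validation suite uses N ≤ 30 genomes against enumeration oracles
for clustering, all N ≤ 12, k ≤ 4 configurations at 10,000 iterations
against the exact placement distribution for the null, 200 replicates
at N = 500, k = 30 for p-value calibration, and 20 replicates per
rearrangement rate at N = 1000 for conservation trends — sizes chosen
so the full suite completes in well under a minute per component while
keeping Monte-Carlo standard errors small relative to the effects
checked. Degenerate inputs are defined, not special-cased: an empty
chromosome contributes no ranks, a single query gene yields an empty
distance histogram, an observed count of 0 gives p = 1, and an empty
target cluster set scores 0.

## Known limitations

- Cluster segmentation is the greedy one; alternative valid
  segmentations of ambiguous runs are not enumerated.
- The null shuffles genome-wide and unconditionally; no GC-, length- or
  chromosome-matched backgrounds.
- No significance measure is attached to the conservation score itself.
- Identifier matching is exact and case-sensitive; synonym or
  cross-scheme translation is out of scope.
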