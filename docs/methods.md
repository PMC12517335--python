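# Methods

## Model and assumptions

The pipeline treats per-protein embeddings as points in a Euclidean space
in which evolutionary relatedness appears as proximity. Orthologous groups
are assumed to form compact, roughly isotropic neighborhoods, so a
partition minimizing the within-cluster sum of squares (k-means) is a
reasonable estimator of the orthologous-group partition. Two consequences
of this assumption shape everything downstream:

* the number of clusters k must grow with the dataset: the default
  k = ⌊n/2⌋ reflects that most orthologous groups are small (one or two
  proteins per species), so the number of groups is of the order of half
  the number of proteins;
* distance to the cluster centroid is meaningful: the centroid-nearest
  member is the cluster's most "typical" protein, which motivates
  distance-based pairing.

The package never runs an embedding model. Embeddings are inputs, read
from a delimited table; per-residue inputs can be mean-pooled
(`pool_mean`), the only pooling operator offered because it is the
convention of the embedding-tool family this pipeline targets. Sequences
longer than the embedder's truncation limit are assumed to have been
truncated upstream; the package validates nothing about sequence length.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `fraction` | 0.5 | k = ⌊n·fraction⌋, clamped to [1, n] |
| `seed` | 0 | k-means random state; fixed for reproducibility |
| `restarts` | 5 | k-means++ initializations; best inertia wins |
| `pca_components` | off | exact-SVD projection before clustering |
| `mode` | `top` | pairing: `top` (distance-based) or `all` (naive) |
| `strict_one_to_one` | true | 1:1 candidates need one protein per species |
| `exclude_one_to_one` | true | reference n:m pairs exclude 1:1 groups |

k-means uses Lloyd iterations with tolerance 1e-4 and at most 300
iterations per restart (the toolkit defaults), followed by an exact-mean
polish (below). Increasing `restarts` can only improve (never worsen) the
selected inertia.

## Evaluation conventions

Reference n:m ortholog pairs are all cross-species pairs within each
reference group, excluding groups that are 1:1 (exactly one protein from
every studied species): n:m and 1:1 counts are disjoint notions, and the
package evaluates the two predictions separately. A flag
(`exclude_one_to_one=False` / `--include-1to1-reference`) scores against
all intra-group cross-species pairs instead; the synthetic benchmarks in
the test suite and acceptance script use that inclusive reference, since
"perfect precision" on blob data means every predicted pair lies within a
true group, regardless of the group's copy-number profile.

Proteins without a reference group are each assigned a private singleton
group (and counted in the report as `n_singleton_assigned`): family
completeness divides by the total protein count T, so every protein must
belong to exactly one reference group.

The exact-match percentage divides by the number of predicted clusters;
a reference-group denominator is available (`denominator="groups"`). AMI
uses the permutation-model expectation with arithmetic-mean normalization
(computed via scikit-learn and cross-checked in the tests against a direct
summation over the hypergeometric model). Percent values are rounded
half-even to 3 significant figures only at report-serialization time.

## Numerical choices

* **Lloyd fixed point.** After the library k-means fit, a polish loop
  recomputes each centroid as the exact mean of its members and reassigns
  points (ties toward the lower cluster index) until the labelling is
  stable. This guarantees the documented invariants — centroid = member
  mean to 1e-6, inertia = sum of squared member-to-centroid distances —
  independent of the library's internal stopping rule. Empty clusters
  (possible when duplicate points outnumber distinct locations) are
  repaired by moving in the point farthest from its current centroid.
* **Determinism.** Identical inputs and seed give bit-identical labels;
  all pair and group outputs are canonicalized (lexicographically smaller
  id first, sorted rows), so repeated runs produce byte-identical files.
* **Tie-breaks.** Centroid-distance ties in distance-based pairing break
  toward the lexicographically smaller protein id.
* **PCA.** Exact full SVD (no randomized solver); per-axis sign fixed by
  making the largest-magnitude loading positive; axes beyond the numerical
  rank of the centered data are zero-padded rather than left arbitrary.
* **Degenerate inputs.** Single-block zero-entropy partitions define AMI
  as 1 when the partitions are identical and 0 otherwise. Empty
  predictions leave precision and F1 undefined (`null` in reports) rather
  than zero.

## Synthetic data: what it does and does not emulate

`synth.generate_dataset` draws one isotropic Gaussian blob center per
orthologous group (spread `center_scale`, default 1.0) and places each
member protein at center + N(0, sigma²I). Species membership follows a
per-(group, species) copy-number distribution, default 0/1/2 copies with
probabilities 0.1/0.8/0.1 — mostly single-copy groups with occasional
losses and duplications, the size profile typical of curated
orthologous-group databases; groups drawing zero copies everywhere are
redrawn so every group is populated. Dummy sequences are uniform random
over the 20 amino acids.

This emulates exactly the property the pipeline exploits — groups as
compact blobs — and nothing else: there is no phylogenetic correlation
between species' copies, no anisotropy or cluster-size/variance coupling,
and no relationship between sequence and embedding. Passing tests on this
generator therefore validate the clustering/pairing/evaluation mechanics,
not the geometric quality of any real embedding model.

## Problem sizes

The test suite and acceptance script run at desk scale: zero-noise
recovery uses 2 species × 200 groups (~400 proteins, p = 32); the noise
sweep uses 100 groups × 5 replicate seeds per noise level; oracle
equivalence uses ≥ 100 random instances of ≤ 30 proteins; the brute-force
k-means cross-check enumerates all 2-partitions of 8 points. These sizes
make every check exhaustive or near-exhaustive while keeping the whole
suite in seconds.

## Known limitations

* k-means with k ≈ n/2 produces many singleton clusters, which can emit no
  pairs; sensitivity is intrinsically capped well below 100%.
* The half-the-dataset heuristic is a default, not an optimum for every
  dataset; `sweep-k` exists to tabulate the trade-off on real inputs.
* The default FASTA header dialect (species code before the first `|`) is
  a documented guess at the common database export style and is fully
  configurable (`HeaderDialect` / `--separator`).
* Whether a 1:1 candidate must contain one protein per species or merely
  have size S is genuinely ambiguous in the field's usage; both behaviors
  are provided (`strict_one_to_one`, default strict, matching the 1:1
  definition).
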