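# Methods

## Problem and model

Given n decoy conformations of one protein, each reduced to its ordered
Cα trace (n_res points in Å), the task is to rank decoys by neighbor
density: repeatedly report the decoy A maximising |N_A|, where
N_A = { X : CαRMSD(A, X) ≤ d }, and remove N_A from the pool and from
every remaining neighbor set. The first few reported decoys are the
cluster representatives used for model selection. The package's
guarantee is exactness: the accelerated path (grouping + bounds) yields
the same rounds, representatives and member sets as brute-force
all-pairs clustering, for every input and threshold. This holds because
every pruning branch is one-sided sound under the triangle inequality
(Cα RMSD is a metric on equal-length traces), and is enforced in the
test suite by element-for-element comparison against the brute-force
path across ensembles spanning 50–500 decoys and sparse-to-dense
thresholds.

## Superposition

Kabsch/SVD with determinant sign correction (proper rotations only;
mirror images are considered different structures). The RMSD is
evaluated from the explicit residuals of the rotated coordinates rather
than from the singular-value trace identity: the identity cancels
catastrophically for near-identical structures (errors ~1e-7 Å at
double precision), while residuals give ~1e-15 on rigid copies. The
one-vs-many variant batches the 3×3 SVDs, which is what makes the
brute-force oracle and the reference-distance precomputation fast
enough to test against routinely. Rank-deficient (e.g. collinear)
configurations are handled by the SVD; a zero determinant sign is
resolved to +1.

## Bounds

Per decoy X the pipeline precomputes:

- the signature Sig_X = (‖s_{X,i} − c_X‖)_i, i.e. per-residue distances
  to the centroid, *in residue order* (the lower-bound proof pairs index
  k with index k, so sorting would break it);
- distances to m reference decoys O_1..O_m (default m = 3);
- coordinates centered and rotated onto the first reference (the
  anchor).

The bounds used, all checked as a sandwich property in the tests:

    max( rms(Sig_X − Sig_Y), max_k |d(X,O_k) − d(Y,O_k)| )
      ≤ CαRMSD(X, Y)
      ≤ min( min_k d(X,O_k) + d(Y,O_k), rRMSD(X, Y) )

where rRMSD is the plain Euclidean RMS deviation of the two
anchor-oriented coordinate sets. The signature-distance form
sqrt((1/n) Σ (v_{1,k} − v_{2,k})²) is the RMS of per-residue
centroid-distance differences; since optimal superposition makes the
centroids coincide and each per-residue deviation is at least the
difference of the two centroid distances, it lower-bounds the RMSD.
rRMSD is computed lazily per queried pair from the stored oriented
coordinates; only the orientation pass is precomputed (linear in n) —
materialising all-pairs rRMSD would itself be quadratic and defeat the
point.

Reference decoys are chosen deterministically for spread: the first
decoy, the decoy farthest from it, the decoy farthest from that one
(and max-min selection beyond three). Spread references make the lower
bounds |d(X,O) − d(Y,O)| informative; the count is configurable
(`n_references`).

## Grouping and the neighbor cascade

Leader clustering in input order with radius r = d/2 (factor
configurable): each decoy joins the first existing center within r
(centers scanned in creation order — ties resolved by that order, for
determinism and oracle comparability), else becomes a center.
Member-to-center distances are recorded. r = d/2 is the unique radius
that makes whole-group admission of the query's own group sound (two
members within r of the center are within 2r = d of each other); if the
user raises the factor above 0.5, that shortcut is disabled and
correctness is preserved.

For each query decoy the cascade is: own group wholesale (if 2r ≤ d);
group admission by upper bounds of d(A,C) ≤ d − r; group rejection by
lower bounds > d + r; exact d(A,C) and exact re-tests; then per member
the recorded-distance tests (d(A,C) + d(C,X) ≤ d admits,
|d(A,C) − d(C,X)| > d rejects), pairwise upper bounds (reference, then
rRMSD), pairwise lower bounds (reference, then signature), and finally
the exact RMSD. The bound order is fixed (cheap scalar bounds before
rRMSD before exact) rather than adaptively switched by threshold;
any sound order leaves the output unchanged, so simplicity won.
Ablation switches (`use_groups`, `use_bounds`, `brute_force`) exist for
exactly that reason and are tested to produce identical output.

Per-case tallies (case1..case5, pair_upper/lower/exact) account for
every ordered pair decision — they sum to n·n per run — and can be
dumped as a TSV table to inspect the pruning profile. On a 500-decoy
planted ensemble the profile behaves as the triangle-inequality
reasoning predicts: at a low threshold (1 Å, below the within-cluster
scale) rejections via group lower bounds dominate; at a high threshold
(20 Å, above the largest pairwise distance, the everything-merges
regime) wholesale admissions and upper bounds dominate; in both
regimes over half of all pair decisions resolve without an exact
superposition.

## Greedy extraction

Rounds pick the decoy with the largest remaining neighbor set, ties
broken toward the lowest input index (deterministic; the underlying
criterion treats ties as arbitrary). Removal follows the symmetric
bookkeeping rule: for each removed Y, Y is discarded from N_Z for every
surviving Z ∈ N_Y. Cluster sizes are extraction-time counts and need
not decrease monotonically across rounds. A best-only mode accumulates
per-decoy neighbor *counts* without materialising member lists, giving
the round-1 winner in memory linear in n.

## Threshold discovery

Percentile method (default): per round, sample `sample_size` decoys
without replacement (whole set if smaller), take the x-th percentile
(linear interpolation between order statistics) of all within-sample
pairwise RMSDs; return the median over `n_rounds` rounds. The median
was chosen as the round combiner for robustness; with one round and a
full-set sample the estimator reduces to the exact percentile (tested).
Default x = min(100·n^(−1/4), 10): percentile shrinks as the set grows
so that very large sets cluster at tighter, cheaper thresholds.

Mode-based method (optional): pool the sampled distances, histogram
with Freedman–Diaconis bins (Sturges fallback when the IQR degenerates,
direct value when all distances coincide), take f = densest bin center
and b = minimum sampled distance, return d = c·f + b. The default
c = 2/3 is a package choice; the method is secondary and c is exposed.
Histogram-mode estimates are only precise to a few bin widths, which is
the tolerance the tests use.

## Outlier filter

Decoys farther than 2d from every one of `sample_size` (default 100)
random probes are removed before metric precomputation; probes
themselves always survive (they are within 0 of themselves), so a
sample covering the whole set removes nothing. The 2d radius comes from
the triangle inequality: a probe within d of a well-connected decoy A
is within 2d of everything within d of A. Retention of any decoy near a
decoy with ≥ 10% neighborhood mass is 1 − 0.9^sample_size per the
binomial argument, > 0.9999 at 100; a Monte-Carlo over 1000 probe draws
confirms ≥ 99.9% survival of planted-cluster members. Filtering is
probabilistic, so it sits outside the exactness guarantee; the
brute-force ablation therefore disables it too, and a separate check
confirms the top-ranked clusters are unchanged by filtering on planted
ensembles. Filtered decoys are reported separately and never counted
into cluster sizes.

## Synthetic ensembles

`random_backbone` draws a self-avoiding random walk with the canonical
3.8 Å consecutive-Cα step and a 3.0 Å excluded-volume floor between
non-consecutive residues. `make_ensemble` plants `n_clusters` center
backbones pairwise farther than `separation` in RMSD (rejection
sampling), adds isotropic Gaussian noise (σ = `noise_sigma` per
coordinate) to make members, draws outliers as further backbones also
separated from the centers and from each other, and puts every decoy
into a random rigid pose so that the pipeline's pose invariance is
actually exercised. Defaults (3 clusters × 30 members, 10 outliers, 40
residues, σ = 0.5 Å, separation 8 Å) give unambiguous ground truth:
within-cluster pair distances ≈ σ√6 ≈ 1.2 Å versus cross-cluster
distances ≳ 6 Å. Member-to-center RMSD concentrates near σ√3 (the
superposition absorbs six degrees of freedom, a ~2% correction at 40
residues). Walk lengths set what separations are reachable: ~30-residue
walks support ~6 Å separation, ~40-residue walks 8 Å; the generator
raises with advice rather than looping forever when rejection sampling
cannot meet the request.

What these fixtures do *not* model: Ramachandran statistics, secondary
structure, side chains, or the heavy-tailed, anisotropic error
distributions of real prediction pipelines. Passing tests therefore
demonstrate algorithmic correctness (exactness, bounds, recovery of
planted structure), not biological performance of the density
criterion itself.

## Numerical choices and problem sizes

- "Zero" RMSD tolerance 1e-9 Å; bound-sandwich assertions allow 1e-9
  slack; the triangle-inequality property test allows 1e-7 (batched-SVD
  noise on ~20 Å distances).
- Duplicate decoy names get `#ordinal` suffixes; decoy order is always
  list order, never permuted.
- PDB I/O keeps 3 decimals (standard ATOM fields); round-trips are
  verified at 5.1e-4 Å.
- Test ensembles span 50–500 decoys of 30–40 residues, thresholds from
  below the within-cluster scale to above the ensemble diameter — sizes
  at which the brute-force oracle remains cheap enough to run on every
  configuration while exercising all cascade branches.
- Seeding: a single `random_state` seeds threshold sampling and filter
  probes via spawned `SeedSequence` children; identical seeds give
  byte-identical reports.
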