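# Methods

This note records the models, parameter choices and numerical conventions
behind `barcodebin`, and what the synthetic tests do and do not establish
about real data.

## Distance model

Pairwise distances use the Kimura 2-parameter correction,
d = −½·ln[(1−2P−Q)·√(1−2Q)], with P and Q the transition and transversion
proportions over the sites where *both* sequences carry an unambiguous
A/C/G/T (pairwise deletion). Choices:

* IUPAC ambiguity codes are treated as missing and deleted per pair, not
  probabilistically resolved; this is the common K2P practice for barcode
  data. U is read as T.
* A pair with no comparable sites is *invalid*; a pair whose log argument
  is non-positive is *saturated*. Both are reported as undefined (NaN),
  enumerated, and excluded from all means. Clamping saturated pairs to a
  large value would bias the gap statistics; at barcode-scale divergences
  (≲ 15%) saturation does not occur in practice.
* Distances are kept at full float precision; percent formatting happens
  only in reports. Identical pairs are normalised to +0.0 (the closed form
  produces IEEE −0.0).
* The "> 500 bp" barcode-compliance filter counts unambiguous A/C/G/T
  positions only, strictly greater than 500; gaps and ambiguity codes do
  not count toward length.

## OTU delimitation

Refined single linkage, in two stages:

1. **Seed clusters**: connected components of the graph with an edge where
   d ≤ `seed_threshold`. Undefined distances are non-edges. Default
   0.022 (2.2%), the published operating point for this family of
   delimitation methods.
2. **Markov-cluster refinement**: only seed clusters whose internal
   diameter (max defined pairwise distance) exceeds `refine_threshold`
   (default 0.04, matching the conventional "deep split" marker of > 4%
   divergence) are re-examined. Within such a cluster the similarity
   weight is max(0, 1 − d/`refine_threshold`) with unit self-loops and
   zero weight for undefined pairs; the column-stochastic transition
   matrix is iterated by expansion (matrix power, default 2) then
   inflation (element-wise power, default 2.0, with column
   renormalisation) until the iterate changes by less than `tol` (1e−6,
   max 100 iterations). Clusters are the connected components of the
   support of the limit matrix (threshold 1e−6). Non-convergence keeps the
   seed cluster intact with a warning. Refined clusters never span seed
   boundaries by construction.

The exact edge weighting of the original registry implementation is not
published; the linear similarity transform above is this package's own
documented choice. Cluster ids `OTU.NNNN` are allocated in order of each
cluster's lexicographically smallest member id, making the labelling
invariant under input permutation. They are stable local surrogates; the
live registry's merge/split nomenclature rules are out of scope.

## Neighbour joining

The QC tree uses standard Saitou–Nei agglomeration, implemented in-package
to fix two behaviours the tests rely on: ties in the Q-criterion are broken
by the lexicographically smallest id pair (internal nodes keyed by the
smallest leaf id they subtend), and a negative branch length at a join is
clamped to zero with the excess moved to the sister branch. The Q-matrix
minimum is taken over the upper triangle only, because floating summation
order makes the matrix not bit-symmetric. Requires all pairwise distances
defined; callers must exclude records involved in saturated pairs first.
Correctness is cross-checked in the tests against additive-matrix recovery
and an independent library implementation.

## Concordance and diagnosability

Category algebra per species over its occupied clusters: MATCH (one
cluster, exclusive), SHARE (every occupied cluster shared, or the single
occupied cluster shared), SPLIT (≥ 2 clusters, all exclusive), MIXTURE
(≥ 2 clusters, at least one shared and one exclusive). Dataset-level share
and split percentages double-count mixtures; all reported percentages are
rounded to the nearest whole percent, half away from zero.

"Indistinguishable" sharing is operationalised as minimum interspecific
K2P distance exactly 0 after pairwise deletion — i.e. at least one
identical haplotype across the pair. Diagnosability subtracts each species
involved in at least one identical pair once (a triad member with two
identical partners is not subtracted twice); the range-restricted figure
subtracts only species in identical pairs that are also sympatric.

Regional re-identification keeps the *global* clustering and subsets the
specimens to one region (the region string is authoritative, not
coordinates), then recomputes the occupancy map, MATCH% and diagnostic%
with regional species as denominator. This matches registry practice where
cluster identity is global while checklists are regional; the alternative
(re-clustering per region) is deliberately not used.

## Gap statistics

Per-species rows use all defined pairwise distances: mean and max
intraspecific (undefined below two specimens), nearest-neighbour distance
(minimum to any heterospecific), mean congeneric. Per-taxon summaries
average the per-species statistics unweighted, except the congeneric
column, which is the mean over all congeneric specimen pairs in the group
— the two conventions conventional barcode-gap reports mix. Accumulation curves shuffle
specimens with per-iteration random streams spawned deterministically from
one seed, so increasing the iteration count never reshuffles earlier
iterations; they are validated against the closed-form hypergeometric
expectation.

## Geography

Great-circle distances on a sphere of radius 6371.0 km. Sympatry is
decided on the unrounded minimum cross-pair distance, strictly < 100 km;
reported distances are rounded to 10-km classes (half away from zero),
sharing-pair scatter data additionally binned in 200-km classes. Specimens
without coordinates are excluded from geographic minima (flagged when a
group pair has no coordinate-bearing cross pair) but retained everywhere
else. Whether the original measurements were geodesic is unknowable;
spherical great-circle is adopted.

## Synthetic data generator

The generator is the package's study-conditions instrument, not a general
simulator:

* **Site model**: exact Kimura two-rate (K80) substitution. For a branch of
  length d (expected substitutions/site) the per-site substitution
  probabilities are the closed-form K80 mismatch probabilities, so the K2P
  estimator inverts planted branch lengths exactly in expectation. The
  `ti_tv_ratio` (default 3.0) is the expected transition/transversion
  count ratio at low divergence, i.e. κ = 2 × 3 = 6; it keeps P ≠ Q so the
  correction is non-trivially exercised.
* **Topology**: star phylogenies (family root → genus roots → species
  ancestors → specimen tips). Branch lengths are set so *tip-to-tip*
  expected distances hit the targets: conspecifics 0.7%, congenerics 8.8%,
  intergenerics 15% by default. The analyses consume only pairwise
  distances, so coalescent genealogical detail is unnecessary; this is a
  documented limitation (no rate variation, no recombination of
  haplotypes, nearest-neighbour structure is flatter than in real data).
* **Abundances**: specimens per species follow a truncated power law on
  1..46 whose exponent is solved by bisection to give mean 8.8, allowing
  singletons — the skewed shape of real barcode libraries.
* **Composition**: AT-rich (A .31, T .38, C .16, G .15) to resemble
  lepidopteran COI; downstream analyses are composition-free (K80 is
  doubly stochastic, so planted distances are unaffected).
* **Scenarios** rewrite haplotypes and coordinates: identical sharing
  copies one haplotype across a congeneric pair verbatim (min distance 0
  by construction); diagnosable sharing offsets the partner ancestor by
  0.8% (collisions are detected and nudged by one transition); splits
  place a second within-species cluster at the requested divergence
  (default 5%) in the same region (sympatric) or in a region ≥ 300 km away
  (allopatric); mixtures combine an allopatric split with a diagnosable
  partner in the remote cluster; divergent singletons add one far
  haplotype. Sympatric events share an exact collection site and
  coordinate scatter is clipped at 2.5σ (σ = 0.25°), so planted sympatry
  and allopatry are deterministic, never probabilistic.
* `survey_fixture` assembles 59 species with the package's reference
  discordance proportions: 40 match / 8 share-only / 9 split / 2 mixture (≈ 68/17/19%
  with double counting), three identical sympatric pairs, and 9 of 11
  within-species cluster pairs allopatric (82%).

What passing tests show: the analysis chain recovers exactly what was
planted under the stated conditions. What they do not show: robustness to
alignment error, NUMTs/pseudogenes, contamination, heterogeneous sampling
effort, or intergradation between clusters — real-data phenomena the
generator deliberately omits.

## Problem sizes and determinism

The fixture runs ~460 specimens (59 species); calibration checks use 60
clean species over 8 seeds (~2000 specimens each run set). These sizes make
every Monte-Carlo band (2 SE for calibration, 3 SE for accumulation) tight
enough to be meaningful while keeping the full suite and the acceptance
script in the seconds range. All stochastic stages take explicit seeds;
per-iteration streams are spawned from `numpy.random.SeedSequence`, and
re-running any configuration reproduces outputs byte-for-byte.

## Degenerate inputs

Empty datasets give empty matrices/assignments with warnings; a
single-record dataset yields a 1×1 zero matrix; species→genus inconsistency
and duplicate specimen ids are hard errors; unparseable coordinates become
missing with a logged warning; unequal raw sequence lengths are
right-padded with gaps (COI barcodes are length-conserved, so no aligner is
implemented or needed).
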