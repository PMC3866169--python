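# barcodebin

Confronting traditional species taxonomy with DNA-barcode sequence
clusters: Kimura 2-parameter distances, BIN-style OTU delimitation by
refined single linkage, barcode-gap statistics, species–cluster concordance
classification, and geographic sympatry analysis — with a synthetic
barcode-data generator so the whole chain is testable without downloads.

## Who this is for

Taxonomists and molecular ecologists who assemble COI barcode libraries
(e.g. for a national or continental fauna) and want to ask, reproducibly:
*how well do algorithmically delimited sequence clusters (BIN-style OTUs)
correspond to the morphological species checklist, and how reliable is
molecular re-identification at different geographic scales?*

## The method

**Distances.** For every pair of aligned sequences, positions where either
member lacks an unambiguous nucleotide are removed (*pairwise deletion*).
With *P* the transition proportion (A↔G, C↔T) and *Q* the transversion
proportion over the *n* compared sites, the Kimura 2-parameter distance is

    d = -1/2 ln[(1 - 2P - Q) √(1 - 2Q)]

Saturated pairs (log argument ≤ 0) are reported as undefined, never
clamped. Analyses are restricted to barcode-compliant records (> 500
unambiguous sites).

**OTU delimitation.** A two-stage refined single linkage, the scheme behind
Barcode Index Numbers: stage 1 forms seed clusters as connected components
of the graph linking specimens at d ≤ 2.2%; stage 2 re-examines seed
clusters with internal diameter above 4% by Markov clustering (expansion =
matrix power, inflation = element-wise power with column renormalisation)
on the similarity graph w = max(0, 1 − d/0.04), splitting clusters with
internal divergence structure. Clusters get stable `OTU.NNNN` identifiers.
The clusterer is also exposed as a scikit-learn estimator
(`RefinedSingleLinkage`, precomputed-distance input, `labels_`).

**Concordance.** Each species is classified against the clusters its
specimens occupy: MATCH (one exclusive cluster), SHARE (all occupied
clusters also hold other species), SPLIT (≥ 2 exclusive clusters), MIXTURE
(shares and splits; counted in both the share and split tallies).
Co-clustered species pairs are *identical* (minimum interspecific distance
exactly 0 — a shared haplotype) or *diagnosable*. Re-identification success
follows: a species fails only when it shares an identical barcode, and only
within its range for the range-restricted figure (sympatry = minimum
great-circle distance < 100 km).

**Gap and geography.** Per species: mean/max intraspecific distance,
nearest-neighbour divergence, mean congeneric distance; per taxon:
unweighted means over species plus over-all-pairs congeneric means;
randomised accumulation curves. Great-circle distances (sphere radius
6371 km) drive the sympatry/allopatry classification of cluster-sharing
species pairs and of within-species cluster splits.

**Synthetic data.** `generate()` evolves sequences under an exact Kimura
two-rate site model over star phylogenies calibrated to realistic barcode
structure (658 bp, AT-rich, mean intraspecific divergence 0.7%, congeneric
8.8%, zipf-like specimens-per-species with mean 8.8) and plants discordance
scenarios (identical/diagnosable sharing, sympatric/allopatric splits,
mixtures, divergent singletons) with full ground truth.

## Worked example

```python
from barcodebin import (
    survey_fixture, build_distance_matrix, cluster_dataset,
    build_species_otu_map, classify_species,
)

ds, truth = survey_fixture(seed=1)     # 459 specimens, 59 species
dm = build_distance_matrix(ds)             # pairwise K2P, pairwise deletion
ca = cluster_dataset(dm)                   # refined single linkage OTUs
report = classify_species(build_species_otu_map(ds, ca))
print(len(ca), report.counts, report.match_pct, report.share_pct, report.split_pct)
```

prints

```
65 {'MATCH': 40, 'SHARE': 8, 'SPLIT': 9, 'MIXTURE': 2} 68 17 19
```

i.e. the 59 species map onto 65 OTUs; 40 species (68%) match their cluster
one-to-one, 10 (17%) share a cluster with another species, 11 (19%) are
split over several clusters, with the two mixtures counted in both of the
latter tallies — exactly the structure planted by the generator. The same
run recovers the planted partition with an adjusted Rand index of 1.0 and
classifies 9 of the 11 within-species cluster pairs (82%) as allopatric.

The full pipeline (`barcodebin run --config run.yaml`, or
`run_pipeline(RunConfig(...))`) writes every stage table — distance matrix,
cluster membership, NJ tree, concordance and sharing tables, gap and
regional re-identification summaries — plus a `summary.json`.

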