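"""Species <-> OTU concordance: the confrontation of traditional taxonomy
with sequence-cluster taxonomy.

Each morphological species is classified by its relation to the OTUs its
specimens occupy:

* ``MATCH``   — exactly one cluster, containing only that species (1:1);
* ``SHARE``   — every occupied cluster also holds other species (lumping);
* ``SPLIT``   — two or more clusters, all exclusive to the species;
* ``MIXTURE`` — two or more clusters with at least one shared and at least
  one exclusive (the species both shares and splits).

In dataset-level percentages, mixtures are counted in both the share and the
split tallies. Species pairs co-occupying a cluster are further classified
as ``identical`` (minimum interspecific K2P distance exactly zero, i.e. a
shared haplotype) or ``diagnosable`` (consistent sequence differences
despite co-clustering). Diagnosability and regional re-identification
success follow from these: a species fails molecular re-identification only
when it shares an identical barcode with another species (in range, for the
range-restricted figure).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .distance import DistanceMatrix
from .records import BarcodeDataset

logger = logging.getLogger(__name__)


class Category(str, Enum):
    MATCH = "MATCH"
    SHARE = "SHARE"
    SPLIT = "SPLIT"
    MIXTURE = "MIXTURE"


def round_half_up(x: float) -> int:
    """Nearest whole number, halves away from zero (report convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SpeciesOtuMap:
    """Bipartite species/cluster occupancy with per-cell specimen counts."""

    species_to_clusters: dict[str, frozenset]
    cluster_to_species: dict[str, frozenset]
    cell_counts: dict[tuple, int]

    @property
    def n_species(self) -> int:
        return len(self.species_to_clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_to_species)

    def shared_clusters(self) -> set:
        return {c for c, sp in self.cluster_to_species.items() if len(sp) >= 2}


@dataclass
class ConcordanceReport:
    """Per-species categories plus the dataset-level summary.

    ``share_pct`` counts SHARE and MIXTURE species, ``split_pct`` SPLIT and
    MIXTURE (mixtures double-counted); denominators are the total species
    count and percentages are rounded to the nearest whole percent.
    """

    category_of: dict[str, Category]
    n_species: int
    n_clusters: int
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {
                cat.value: sum(1 for c in self.category_of.values() if c is cat)
                for cat in Category
            }

    @property
    def n_match(self) -> int:
        return self.counts["MATCH"]

    @property
    def n_share(self) -> int:
        """Species sharing a cluster (mixtures included)."""
        return self.counts["SHARE"] + self.counts["MIXTURE"]

    @property
    def n_split(self) -> int:
        """Species split over several clusters (mixtures included)."""
        return self.counts["SPLIT"] + self.counts["MIXTURE"]

    @property
    def match_pct(self) -> int:
        return round_half_up(100.0 * self.n_match / self.n_species)

    @property
    def share_pct(self) -> int:
        return round_half_up(100.0 * self.n_share / self.n_species)

    @property
    def split_pct(self) -> int:
        return round_half_up(100.0 * self.n_split / self.n_species)


def build_species_otu_map(ds: BarcodeDataset, ca: ClusterAssignment) -> SpeciesOtuMap:
    """Cross-tabulate species against clusters for the assigned specimens."""
    species_of = ds.species_of()
    missing = set(ca.cluster_of) - set(species_of)
    if missing:
        raise ValueError(f"specimens in assignment but not dataset: {sorted(missing)[:5]}")
    cells: dict[tuple, int] = {}
    for sid, cid in ca.cluster_of.items():
        cells[(species_of[sid], cid)] = cells.get((species_of[sid], cid), 0) + 1
    sp2c: dict[str, set] = {}
    c2sp: dict[str, set] = {}
    for sp, cid in cells:
        sp2c.setdefault(sp, set()).add(cid)
        c2sp.setdefault(cid, set()).add(sp)
    return SpeciesOtuMap(
        species_to_clusters={s: frozenset(v) for s, v in sp2c.items()},
        cluster_to_species={c: frozenset(v) for c, v in c2sp.items()},
        cell_counts=cells,
    )


def classify_species(m: SpeciesOtuMap) -> ConcordanceReport:
    """Assign each species its match/share/split/mixture category."""
    shared = m.shared_clusters()
    category: dict[str, Category] = {}
    for sp, clusters in m.species_to_clusters.items():
        own_shared = clusters & shared
        own_exclusive = clusters - shared
        if len(clusters) == 1:
            category[sp] = Category.SHARE if own_shared else Category.MATCH
        elif not own_shared:
            category[sp] = Category.SPLIT
        elif own_exclusive:
            category[sp] = Category.MIXTURE
        else:
            category[sp] = Category.SHARE
    return ConcordanceReport(category, m.n_species, m.n_clusters)


def detect_barcode_sharing(
    dm: DistanceMatrix, ds: BarcodeDataset, species_map: SpeciesOtuMap
) -> pd.DataFrame:
    """Sharing table for every species pair co-occupying a cluster.

    Columns: species_a, species_b, cluster_ids, min_distance, witness_a,
    witness_b, sharing_type. ``sharing_type`` is ``identical`` when the
    minimum interspecific K2P distance is exactly zero (a haplotype is
    shared across the pair) and ``diagnosable`` otherwise.
    """
    species_of = ds.species_of()
    specimens_by_species: dict[str, list] = {}
    for sid in dm.ids:
        sp = species_of.get(sid)
        if sp is not None:
            specimens_by_species.setdefault(sp, []).append(sid)

    pair_clusters: dict[tuple, set] = {}
    for cid, species in species_map.cluster_to_species.items():
        for sa in species:
            for sb in species:
                if sa < sb:
                    pair_clusters.setdefault((sa, sb), set()).add(cid)

    rows = []
    for (sa, sb), cids in sorted(pair_clusters.items()):
        ia = [dm.index_of(s) for s in specimens_by_species.get(sa, [])]
        ib = [dm.index_of(s) for s in specimens_by_species.get(sb, [])]
        sub = dm.d[np.ix_(ia, ib)]
        if sub.size == 0 or np.isnan(sub).all():
            logger.warning("no defined interspecific distance for %s / %s", sa, sb)
            continue
        flat = np.nanargmin(sub)
        wi, wj = np.unravel_index(flat, sub.shape)
        min_d = float(sub[wi, wj])
        rows.append(
            {
                "species_a": sa,
                "species_b": sb,
                "cluster_ids": ",".join(sorted(cids)),
                "min_distance": min_d,
                "witness_a": dm.ids[ia[wi]],
                "witness_b": dm.ids[ib[wj]],
                "sharing_type": "identical" if min_d == 0.0 else "diagnosable",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species_a",
            "species_b",
            "cluster_ids",
            "min_distance",
            "witness_a",
            "witness_b",
            "sharing_type",
        ],
    )


def diagnosability_summary(
    sharing: pd.DataFrame, n_species: int, sympatric_pairs: set | None = None
) -> dict:
    """Continental and in-range re-identification success percentages.

    A species is non-diagnostic when it belongs to at least one identical
    sharing pair; in a triad with two identical partners the species is
    subtracted once, not per pair. ``diagnostic_pct`` uses all identical
    pairs; ``range_discriminated_pct`` subtracts only species in identical
    pairs that are also sympatric (``sympatric_pairs`` holds frozensets of
    species binomials). Percentages are rounded to the nearest whole
    percent.
    """
    identical = sharing[sharing["sharing_type"] == "identical"]
    identical_pairs = {
        frozenset((a, b)) for a, b in zip(identical["species_a"], identical["species_b"])
    }
    nondiagnostic = {sp for pair in identical_pairs for sp in pair}
    if sympatric_pairs is None:
        sympatric_identical = identical_pairs
    else:
        sympatric_identical = identical_pairs & set(sympatric_pairs)
    in_range_nondiag = {sp for pair in sympatric_identical for sp in pair}
    return {
        "n_species": n_species,
        "n_identical_pairs": len(identical_pairs),
        "n_identical_sympatric_pairs": len(sympatric_identical),
        "n_nondiagnostic_species": len(nondiagnostic),
        "diagnostic_pct": round_half_up(100.0 * (n_species - len(nondiagnostic)) / n_species)
        if n_species
        else math.nan,
        "range_discriminated_pct": round_half_up(
            100.0 * (n_species - len(in_range_nondiag)) / n_species
        )
        if n_species
        else math.nan,
    }


def regional_reidentification(
    ds: BarcodeDataset,
    region: str,
    ca: ClusterAssignment,
    dm: DistanceMatrix,
) -> dict:
    """Re-identification success for the specimens collected in one region.

    Specimens are restricted to the region while cluster labels are kept
    from the global assignment (registry clusters are global; a regional
    checklist is matched against them). Returns the regional species and
    specimen counts plus diagnostic% (species free of identical barcode
    sharing within the region) and species-cluster MATCH% on the regional
    occupancy map.
    """
    sub = ds.subset_region(region)
    ids = [sid for sid in sub.specimen_ids if sid in ca.cluster_of]
    if not ids:
        logger.warning("region %r has no assigned specimens", region)
        return {
            "region": region,
            "n_species": 0,
            "n_specimens": 0,
            "diagnostic_pct": math.nan,
            "match_pct": math.nan,
        }
    sub = sub.subset(ids)
    sub_ca = ClusterAssignment(
        cluster_of={s: ca.cluster_of[s] for s in ids},
        clusters={
            cid: frozenset(m for m in mem if m in set(ids))
            for cid, mem in ca.clusters.items()
            if any(m in set(ids) for m in mem)
        },
        params=dict(ca.params),
    )
    sub_dm = dm.submatrix(ids)
    m = build_species_otu_map(sub, sub_ca)
    report = classify_species(m)
    sharing = detect_barcode_sharing(sub_dm, sub, m)
    diag = diagnosability_summary(sharing, m.n_species)
    return {
        "region": region,
        "n_species": m.n_species,
        "n_specimens": len(ids),
        "diagnostic_pct": diag["diagnostic_pct"],
        "match_pct": report.match_pct,
    }


def regional_report_table(
    ds: BarcodeDataset, regions: list[str], ca: ClusterAssignment, dm: DistanceMatrix
) -> pd.DataFrame:
    """Per-region re-identification table (diagnostic%, match%, counts)."""
    rows = [regional_reidentification(ds, r, ca, dm) for r in regions]
    return pd.DataFrame(
        rows, columns=["region", "n_species", "n_specimens", "diagnostic_pct", "match_pct"]
    )
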