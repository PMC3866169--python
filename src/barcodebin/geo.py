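"""Geographic analysis: great-circle distances, sympatry/allopatry.

Distances between collection sites are great-circle (haversine) kilometres
on a sphere of radius 6371.0 km. Two groups are sympatric when the minimum
distance between any of their coordinate-bearing members is strictly less
than 100 km (decided on the unrounded value); reported distances are
rounded to the nearest 10-km class, half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .concordance import SpeciesOtuMap
from .distance import DistanceMatrix
from .records import BarcodeDataset

EARTH_RADIUS_KM = 6371.0
SYMPATRY_KM = 100.0


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two WGS84 points; nan if any
    coordinate is missing."""
    if any(math.isnan(v) for v in (lat1, lon1, lat2, lon2)):
        return math.nan
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude out of range: {lon}")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def round_10km(km: float) -> float:
    """Round to the nearest 10-km class, half away from zero."""
    if math.isnan(km):
        return math.nan
    return 10.0 * math.floor(km / 10.0 + 0.5)


@dataclass(frozen=True)
class GeoPair:
    """Minimum geographic separation between two specimen groups."""

    group_a: str
    group_b: str
    min_km: float  # rounded to the 10-km class; nan when undefined
    unrounded_km: float
    witness_a: str | None
    witness_b: str | None
    sympatric: bool | None  # None when no coordinate-bearing cross pair

    @property
    def defined(self) -> bool:
        return self.sympatric is not None


def min_group_distance(
    ds: BarcodeDataset,
    members_a: set,
    members_b: set,
    label_a: str = "A",
    label_b: str = "B",
) -> GeoPair:
    """Minimum great-circle distance over all cross pairs of two groups.

    Specimens lacking coordinates are excluded; if no coordinate-bearing
    cross pair exists the result is flagged undefined. Sympatry is decided
    on the unrounded distance (strictly < 100 km).
    """
    if not members_a or not members_b:
        raise ValueError("both groups must be non-empty")
    rec_a = [ds[sid] for sid in sorted(members_a)]
    rec_b = [ds[sid] for sid in sorted(members_b)]
    best = math.inf
    wa = wb = None
    for ra in rec_a:
        if not ra.has_coordinates:
            continue
        for rb in rec_b:
            if not rb.has_coordinates:
                continue
            km = haversine_km(ra.latitude, ra.longitude, rb.latitude, rb.longitude)
            if km < best:
                best = km
                wa, wb = ra.specimen_id, rb.specimen_id
    if wa is None:
        return GeoPair(label_a, label_b, math.nan, math.nan, None, None, None)
    return GeoPair(
        group_a=label_a,
        group_b=label_b,
        min_km=round_10km(best),
        unrounded_km=best,
        witness_a=wa,
        witness_b=wb,
        sympatric=best < SYMPATRY_KM,
    )


def split_pair_table(
    ds: BarcodeDataset,
    ca: ClusterAssignment,
    species_map: SpeciesOtuMap,
    dm: DistanceMatrix,
) -> pd.DataFrame:
    """Geography and genetics of every within-species cluster pair.

    For each species occupying two or more clusters, every unordered pair of
    its clusters contributes one row: the minimum pairwise K2P distance
    between the species' specimens in the two clusters, the minimum
    geographic separation, the sympatry verdict, cluster sizes and singleton
    flags.
    """
    species_of = ds.species_of()
    rows = []
    for sp in sorted(species_map.species_to_clusters):
        clusters = sorted(species_map.species_to_clusters[sp])
        if len(clusters) < 2:
            continue
        members = {
            cid: sorted(
                m
                for m in ca.clusters[cid]
                if species_of.get(m) == sp
            )
            for cid in clusters
        }
        for a_i in range(len(clusters)):
            for b_i in range(a_i + 1, len(clusters)):
                ca_id, cb_id = clusters[a_i], clusters[b_i]
                ma, mb = members[ca_id], members[cb_id]
                ia = [dm.index_of(m) for m in ma if m in dm._index]
                ib = [dm.index_of(m) for m in mb if m in dm._index]
                sub = dm.d[np.ix_(ia, ib)]
                gen_d = float(np.nanmin(sub)) if sub.size and not np.isnan(sub).all() else math.nan
                geo = min_group_distance(ds, set(ma), set(mb), ca_id, cb_id)
                rows.append(
                    {
                        "species": sp,
                        "cluster_a": ca_id,
                        "cluster_b": cb_id,
                        "min_k2p": gen_d,
                        "min_km": geo.min_km,
                        "unrounded_km": geo.unrounded_km,
                        "sympatric": geo.sympatric,
                        "n_a": len(ma),
                        "n_b": len(mb),
                        "singleton_involved": len(ma) == 1 or len(mb) == 1,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "cluster_a",
            "cluster_b",
            "min_k2p",
            "min_km",
            "unrounded_km",
            "sympatric",
            "n_a",
            "n_b",
            "singleton_involved",
        ],
    )


def sharing_pair_geography(
    ds: BarcodeDataset, sharing: pd.DataFrame, km_class: float = 200.0
) -> pd.DataFrame:
    """Minimum geographic separation for each cluster-sharing species pair.

    Adds the scatter-plot style distance class (default 200-km classes) used
    when plotting sharing pairs against geographic separation.
    """
    by_species: dict[str, set] = {}
    for r in ds.records:
        by_species.setdefault(r.species, set()).add(r.specimen_id)
    rows = []
    for row in sharing.itertuples(index=False):
        geo = min_group_distance(
            ds, by_species[row.species_a], by_species[row.species_b], row.species_a, row.species_b
        )
        rows.append(
            {
                "species_a": row.species_a,
                "species_b": row.species_b,
                "sharing_type": row.sharing_type,
                "min_km": geo.min_km,
                "km_class": math.nan
                if math.isnan(geo.min_km)
                else km_class * math.floor(geo.unrounded_km / km_class),
                "sympatric": geo.sympatric,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species_a", "species_b", "sharing_type", "min_km", "km_class", "sympatric"],
    )
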