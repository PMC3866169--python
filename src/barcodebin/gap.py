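"""Barcode-gap statistics and accumulation curves.

The "barcode gap" is the separation between a species' internal variation
(mean and maximum pairwise intraspecific K2P distance) and its distance to
the nearest heterospecific neighbour. Per-species rows feed per-taxon
summaries (per genus or over the whole dataset): unweighted means over
species-level statistics for intraspecific variation and nearest-neighbour
divergence, and an over-all-pairs mean for congeneric divergence.
Undefined (saturated) distances are excluded from every mean, with the
exclusion counts reported by the distance engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .distance import DistanceMatrix
from .records import BarcodeDataset


def _nan_or(value: float) -> float:
    return float(value) if value == value else math.nan


def species_gap_table(dm: DistanceMatrix, ds: BarcodeDataset) -> pd.DataFrame:
    """One row per species: intraspecific variation and nearest neighbour.

    Columns: species, genus, n_specimens, mean_intra, max_intra (nan when
    fewer than two specimens), nn_distance, nn_species, mean_congeneric
    (nan for species without congeners). A species whose interspecific
    distances are all undefined has nan nn_distance and is flagged.
    """
    species_of = ds.species_of()
    genus_of = {r.species: r.genus for r in ds.records}
    idx_by_species: dict[str, list] = {}
    for sid in dm.ids:
        if sid in species_of:
            idx_by_species.setdefault(species_of[sid], []).append(dm.index_of(sid))

    species_arr = np.array([species_of[s] for s in dm.ids])
    rows = []
    for sp in ds.species_names:
        idx = np.array(idx_by_species.get(sp, []), dtype=int)
        if idx.size == 0:
            continue
        genus = genus_of[sp]
        intra = dm.d[np.ix_(idx, idx)][np.triu_indices(idx.size, k=1)]
        intra = intra[~np.isnan(intra)]
        mean_intra = _nan_or(intra.mean()) if intra.size else math.nan
        max_intra = _nan_or(intra.max()) if intra.size else math.nan

        hetero_mask = species_arr != sp
        inter = dm.d[np.ix_(idx, np.nonzero(hetero_mask)[0])]
        nn_distance = math.nan
        nn_species = ""
        if inter.size and not np.isnan(inter).all():
            flat = np.nanargmin(inter)
            _, jmin = np.unravel_index(flat, inter.shape)
            nn_distance = float(np.nanmin(inter))
            nn_species = str(species_arr[np.nonzero(hetero_mask)[0][jmin]])

        congeneric_mask = hetero_mask & np.array(
            [genus_of[s] == genus for s in species_arr]
        )
        cong = dm.d[np.ix_(idx, np.nonzero(congeneric_mask)[0])]
        cong = cong[~np.isnan(cong)]
        mean_congeneric = _nan_or(cong.mean()) if cong.size else math.nan

        rows.append(
            {
                "species": sp,
                "genus": genus,
                "n_specimens": int(idx.size),
                "mean_intra": mean_intra,
                "max_intra": max_intra,
                "nn_distance": nn_distance,
                "nn_species": nn_species,
                "mean_congeneric": mean_congeneric,
                "all_undefined": bool(inter.size) and bool(np.isnan(inter).all()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "genus",
            "n_specimens",
            "mean_intra",
            "max_intra",
            "nn_distance",
            "nn_species",
            "mean_congeneric",
            "all_undefined",
        ],
    )


def taxon_summary(
    rows: pd.DataFrame,
    dm: DistanceMatrix,
    ds: BarcodeDataset,
    grouping: str = "all",
) -> pd.DataFrame:
    """Per-taxon barcode-gap summary (grouping: ``"genus"`` or ``"all"``).

    Columns per group: species and specimen counts, mean of per-species mean
    intraspecific variation, mean of per-species maximum variation, mean
    pairwise congeneric distance (over all congeneric specimen pairs in the
    group), and mean nearest-neighbour divergence (unweighted over species).
    """
    if grouping not in ("genus", "all"):
        raise ValueError("grouping must be 'genus' or 'all'")
    species_of = ds.species_of()
    genus_of = {r.species: r.genus for r in ds.records}

    def congeneric_pair_mean(group_species: set) -> float:
        idx_sp = [
            (dm.index_of(sid), species_of[sid])
            for sid in dm.ids
            if sid in species_of and species_of[sid] in group_species
        ]
        vals = []
        for a in range(len(idx_sp)):
            ia, sa = idx_sp[a]
            for b in range(a + 1, len(idx_sp)):
                ib, sb = idx_sp[b]
                if sa != sb and genus_of[sa] == genus_of[sb]:
                    v = dm.d[ia, ib]
                    if not math.isnan(v):
                        vals.append(v)
        return float(np.mean(vals)) if vals else math.nan

    groups: dict[str, pd.DataFrame]
    if grouping == "genus":
        groups = {g: sub for g, sub in rows.groupby("genus")}
    else:
        groups = {"all": rows}

    out = []
    for name in sorted(groups):
        sub = groups[name]
        sp_set = set(sub["species"])
        out.append(
            {
                "taxon": name,
                "n_species": len(sp_set),
                "n_specimens": int(sub["n_specimens"].sum()),
                "mean_intra": _nan_or(sub["mean_intra"].mean()),
                "mean_max_intra": _nan_or(sub["max_intra"].mean()),
                "mean_congeneric": congeneric_pair_mean(sp_set),
                "mean_nn": _nan_or(sub["nn_distance"].mean()),
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "taxon",
            "n_species",
            "n_specimens",
            "mean_intra",
            "mean_max_intra",
            "mean_congeneric",
            "mean_nn",
        ],
    )


@dataclass
class ClusterVariationSummary:
    """Internal variation of multi-member clusters."""

    per_cluster: pd.DataFrame
    n_multi_clusters: int
    grand_mean_intra: float
    grand_mean_max: float


def intra_cluster_summary(dm: DistanceMatrix, ca: ClusterAssignment) -> ClusterVariationSummary:
    """Mean/max internal K2P distance per multi-member cluster, plus grand
    means over those clusters (singletons have no internal variation and are
    excluded)."""
    rows = []
    for cid in sorted(ca.clusters):
        members = [m for m in ca.clusters[cid] if m in dm._index]
        if len(members) < 2:
            continue
        idx = np.array([dm.index_of(m) for m in members])
        vals = dm.d[np.ix_(idx, idx)][np.triu_indices(idx.size, k=1)]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        rows.append(
            {
                "cluster_id": cid,
                "n_members": len(members),
                "mean_intra": float(vals.mean()),
                "max_intra": float(vals.max()),
            }
        )
    per_cluster = pd.DataFrame(rows, columns=["cluster_id", "n_members", "mean_intra", "max_intra"])
    return ClusterVariationSummary(
        per_cluster=per_cluster,
        n_multi_clusters=len(per_cluster),
        grand_mean_intra=_nan_or(per_cluster["mean_intra"].mean()) if len(per_cluster) else math.nan,
        grand_mean_max=_nan_or(per_cluster["max_intra"].mean()) if len(per_cluster) else math.nan,
    )


@dataclass
class AccumulationCurve:
    """Randomised accumulation of label richness with specimen count."""

    x: np.ndarray
    mean_richness: np.ndarray
    per_iteration: np.ndarray  # shape (iterations, N)
    iterations: int


def accumulation_curve(
    ds: BarcodeDataset,
    labels: str = "species",
    iterations: int = 100,
    seed: int = 0,
    ca: ClusterAssignment | None = None,
) -> AccumulationCurve:
    """Randomised accumulation curve of species or cluster richness.

    For each iteration the specimens are shuffled by a seeded generator and
    the number of distinct labels seen is recorded after each addition; the
    mean across iterations is the curve. Per-iteration random streams are
    spawned deterministically from the seed, so extending ``iterations``
    does not reshuffle earlier iterations.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if labels == "species":
        lab = [r.species for r in ds.records]
    elif labels == "cluster":
        if ca is None:
            raise ValueError("cluster labels require a ClusterAssignment")
        lab = [ca.cluster_of[r.specimen_id] for r in ds.records if r.specimen_id in ca.cluster_of]
    else:
        raise ValueError("labels must be 'species' or 'cluster'")
    lab_arr = pd.factorize(np.array(lab))[0]
    n = lab_arr.size
    streams = np.random.SeedSequence(seed).spawn(iterations)
    per_iter = np.empty((iterations, n), dtype=np.int64)
    for k, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        order = rng.permutation(n)
        shuffled = lab_arr[order]
        seen = np.zeros(lab_arr.max() + 1, dtype=bool)
        count = 0
        for pos, lv in enumerate(shuffled):
            if not seen[lv]:
                seen[lv] = True
                count += 1
            per_iter[k, pos] = count
    return AccumulationCurve(
        x=np.arange(1, n + 1),
        mean_richness=per_iter.mean(axis=0),
        per_iteration=per_iter,
        iterations=iterations,
    )
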