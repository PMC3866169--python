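import math

import pytest

from barcodebin import (
    BarcodeDataset,
    SpecimenRecord,
    build_distance_matrix,
    build_species_otu_map,
    classify_species,
    cluster_dataset,
    survey_fixture,
)
from barcodebin.cluster import ClusterAssignment


def make_record(
    specimen_id,
    sequence,
    species="Genus01 speciesA",
    genus=None,
    region="DE",
    lat=math.nan,
    lon=math.nan,
    subfamily="Subfamily1",
):
    return SpecimenRecord(
        specimen_id=specimen_id,
        species=species,
        genus=genus or species.split()[0],
        subfamily=subfamily,
        region=region,
        latitude=lat,
        longitude=lon,
        sequence=sequence,
    )


def make_dataset(rows):
    """rows: iterable of kwargs dicts for make_record."""
    return BarcodeDataset(records=[make_record(**r) for r in rows])


def make_assignment(clusters):
    """clusters: dict cluster_id -> iterable of specimen ids."""
    clusters = {cid: frozenset(m) for cid, m in clusters.items()}
    return ClusterAssignment(
        cluster_of={m: cid for cid, mem in clusters.items() for m in mem},
        clusters=clusters,
    )


@pytest.fixture(scope="session")
def fixture_data():
    """The study-shaped synthetic fixture with its full analysis chain."""
    ds, truth = survey_fixture(seed=1)
    dm = build_distance_matrix(ds)
    ca = cluster_dataset(dm)
    smap = build_species_otu_map(ds, ca)
    report = classify_species(smap)
    return {"ds": ds, "truth": truth, "dm": dm, "ca": ca, "map": smap, "report": report}
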