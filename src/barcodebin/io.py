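"""Reading and writing barcode datasets: FASTA sequences + TSV metadata.

The metadata dialect is tab-separated with a mandatory header and fixed
column names: ``specimen_id, species, genus, subfamily, region, lat, lon``.
Missing coordinates are written as empty fields.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import BarcodeDataset, SpecimenRecord

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["specimen_id", "species", "genus", "subfamily", "region", "lat", "lon"]


def _parse_coord(value: object, specimen_id: str, name: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    s = str(value).strip()
    if not s:
        return math.nan
    try:
        return float(s)
    except ValueError:
        logger.warning("specimen %s: unparseable %s %r, treated as missing", specimen_id, name, s)
        return math.nan


def read_dataset(fasta_path: str | Path, metadata_path: str | Path) -> BarcodeDataset:
    """Assemble a dataset from a FASTA file and a TSV metadata table.

    Records present in only one of the two files are reported and dropped;
    duplicate specimen ids in either file are a hard error. Sequence case is
    normalised to upper.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate specimen_id in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing required columns: {sorted(missing_cols)}")
    if meta["specimen_id"].duplicated().any():
        dups = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen_id in metadata: {dups}")

    meta_ids = set(meta["specimen_id"])
    orphan_seqs = sorted(set(seqs) - meta_ids)
    orphan_meta = sorted(meta_ids - set(seqs))
    for sid in orphan_seqs:
        logger.warning("FASTA record %s has no metadata row; dropped", sid)
    for sid in orphan_meta:
        logger.warning("metadata row %s has no FASTA record; dropped", sid)

    records = []
    for row in meta.itertuples(index=False):
        sid = row.specimen_id
        if sid not in seqs:
            continue
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                species=row.species,
                genus=row.genus,
                subfamily=row.subfamily,
                region=row.region,
                latitude=_parse_coord(row.lat, sid, "latitude"),
                longitude=_parse_coord(row.lon, sid, "longitude"),
                sequence=seqs[sid],
            )
        )
    return BarcodeDataset(records=records)


def write_dataset(ds: BarcodeDataset, fasta_path: str | Path, metadata_path: str | Path) -> None:
    """Write a dataset as FASTA + TSV metadata (inverse of :func:`read_dataset`)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.specimen_id, description="") for r in ds.records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")

    rows = []
    for r in ds.records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "genus": r.genus,
                "subfamily": r.subfamily,
                "region": r.region,
                "lat": "" if math.isnan(r.latitude) else repr(r.latitude),
                "lon": "" if math.isnan(r.longitude) else repr(r.longitude),
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(metadata_path, sep="\t", index=False)


def filter_barcode_compliant(ds: BarcodeDataset) -> BarcodeDataset:
    """Retain exactly the records with >500 unambiguous nucleotides.

    Original record order is preserved; the operation is idempotent.
    """
    kept = [r for r in ds.records if r.barcode_compliant]
    n_dropped = len(ds.records) - len(kept)
    if n_dropped:
        logger.info("length filter dropped %d of %d records", n_dropped, len(ds.records))
    return BarcodeDataset(records=kept, alignment_length=ds.alignment_length)


def dataset_manifest(ds: BarcodeDataset) -> dict:
    """JSON-ready summary of a dataset (counts, alignment length)."""
    return {
        "n_records": len(ds),
        "n_species": len(ds.species_names),
        "n_genera": len({r.genus for r in ds.records}),
        "n_regions": len(ds.regions),
        "alignment_length": ds.alignment_length,
        "n_barcode_compliant": sum(1 for r in ds.records if r.barcode_compliant),
        "n_with_coordinates": sum(1 for r in ds.records if r.has_coordinates),
    }
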