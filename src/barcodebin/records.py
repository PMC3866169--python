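"""Core record types: one barcoded voucher specimen and a dataset of them.

A specimen carries an opaque identifier, Linnean taxonomy (species binomial,
genus, subfamily), a sampling region code plus optional WGS84 coordinates,
and an aligned IUPAC nucleotide sequence. A dataset is an ordered collection
of specimens padded to a common alignment length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN-")
UNAMBIGUOUS = frozenset("ACGT")

#: Minimum number of unambiguous (A/C/G/T) positions for formal barcode
#: status; sequences at or below this length are excluded from distance
#: analyses.
BARCODE_MIN_SITES = 500


def comparable_length(sequence: str) -> int:
    """Number of unambiguous A/C/G/T positions in an aligned sequence.

    Gaps and IUPAC ambiguity codes do not count toward barcode length.
    """
    return sum(1 for c in sequence if c in UNAMBIGUOUS)


@dataclass(frozen=True)
class SpecimenRecord:
    """One barcoded voucher specimen.

    Parameters
    ----------
    specimen_id : str
        Opaque identifier, unique within a dataset.
    species : str
        Species binomial (e.g. ``"Idaea seriata"``).
    genus : str
        Genus name; must be consistent with the binomial across a dataset.
    subfamily : str
        Subfamily name.
    region : str
        Country or island code (e.g. ``"IT"``, ``"Sar"`` for Sardinia). The
        region string, not the coordinates, is authoritative for regional
        subsetting.
    latitude, longitude : float
        Decimal degrees WGS84; ``nan`` when the collection site is unknown.
    sequence : str
        Aligned IUPAC nucleotide string, upper case, may contain ``-`` gaps
        and ambiguity codes.
    """

    specimen_id: str
    species: str
    genus: str
    subfamily: str
    region: str
    latitude: float
    longitude: float
    sequence: str

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.specimen_id}: sequence must be non-empty")
        bad = set(self.sequence.upper()) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"{self.specimen_id}: non-IUPAC characters in sequence: {sorted(bad)}"
            )

    @property
    def comparable_length(self) -> int:
        return comparable_length(self.sequence)

    @property
    def barcode_compliant(self) -> bool:
        """True when the sequence has strictly more than 500 A/C/G/T sites."""
        return self.comparable_length > BARCODE_MIN_SITES

    @property
    def has_coordinates(self) -> bool:
        return not (math.isnan(self.latitude) or math.isnan(self.longitude))


@dataclass
class BarcodeDataset:
    """Ordered collection of specimens padded to a common alignment length.

    Sequences shorter than ``alignment_length`` are right-padded with gaps at
    construction; COI barcodes are length-conserved so no aligner is applied.
    """

    records: list[SpecimenRecord] = field(default_factory=list)
    alignment_length: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        genus_of: dict[str, str] = {}
        for r in self.records:
            if r.specimen_id in seen:
                raise ValueError(f"duplicate specimen_id: {r.specimen_id}")
            seen.add(r.specimen_id)
            prev = genus_of.setdefault(r.species, r.genus)
            if prev != r.genus:
                raise ValueError(
                    f"species {r.species!r} mapped to two genera: {prev!r}, {r.genus!r}"
                )
        if self.records:
            max_len = max(len(r.sequence) for r in self.records)
            if self.alignment_length <= 0:
                self.alignment_length = max_len
            elif self.alignment_length < max_len:
                raise ValueError(
                    f"alignment_length {self.alignment_length} < longest sequence {max_len}"
                )
            self.records = [
                replace(r, sequence=r.sequence.upper().ljust(self.alignment_length, "-"))
                for r in self.records
            ]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    def __getitem__(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def species_names(self) -> list[str]:
        """Distinct species in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for r in self.records:
            if r.species not in seen:
                seen.add(r.species)
                out.append(r.species)
        return out

    @property
    def regions(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for r in self.records:
            if r.region not in seen:
                seen.add(r.region)
                out.append(r.region)
        return out

    def species_of(self) -> dict[str, str]:
        """Mapping specimen_id -> species binomial."""
        return {r.specimen_id: r.species for r in self.records}

    def subset(self, specimen_ids: Iterable[str]) -> "BarcodeDataset":
        """Sub-dataset restricted to the given specimens, order preserved."""
        keep = set(specimen_ids)
        return BarcodeDataset(
            records=[r for r in self.records if r.specimen_id in keep],
            alignment_length=self.alignment_length,
        )

    def subset_region(self, region: str) -> "BarcodeDataset":
        return BarcodeDataset(
            records=[r for r in self.records if r.region == region],
            alignment_length=self.alignment_length,
        )
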