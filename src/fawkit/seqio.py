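"""Specimen sequence and metadata I/O.

Field collections arrive as one FASTA file per locus (COIB and Tpi
amplicons, possibly containing IUPAC ambiguity codes for heterozygous
positions read off double-peak chromatographs) plus a CSV table binding
each specimen to a collection site with WGS84 coordinates and a
collection date.  This module reads those inputs into
:class:`SpecimenRecord` / :class:`CollectionSite` objects and validates
sequence alphabets and coordinate ranges.

FASTA dialect: arbitrary line wrapping is accepted on read; writing
emits one unwrapped sequence line per record so that a read/write cycle
is byte-identical for normalized input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "IUPAC_CODES",
    "AMBIGUITY_CODES",
    "SpecimenRecord",
    "CollectionSite",
    "FastaParseError",
    "MetadataError",
    "read_fasta",
    "write_fasta",
    "validate_sequence",
    "read_metadata",
    "load_dataset",
]

#: Full IUPAC nucleotide alphabet (gap excluded; gaps are alignment artifacts).
IUPAC_CODES = frozenset("ACGTRYWKSDMBHVN")

#: Codes representing more than one base (heterozygous/uncertain calls).
AMBIGUITY_CODES = frozenset("RYWKSDMBHVN")


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class MetadataError(ValueError):
    """Schema or row-level problem in the specimen metadata CSV."""


@dataclass(frozen=True)
class CollectionSite:
    """One collection locality (one row of the source-information table)."""

    site_id: str
    name: str
    country: str
    latitude: float
    longitude: float
    date_label: str = ""

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class SpecimenRecord:
    """One field-collected (or simulated) individual.

    ``sequences`` maps locus name ("COIB", "TPI") to the uppercase
    amplicon sequence; a locus that failed amplification is simply
    absent, and per-locus sample sizes are reported separately
    downstream.
    """

    specimen_id: str
    site_id: str
    collection_date: str = ""
    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def year(self) -> int | None:
        """Parsed collection year, if the date label contains one."""
        m = re.search(r"(\d{4})", self.collection_date)
        return int(m.group(1)) if m else None


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs.

    Record order is preserved, sequences are uppercased, and the id is
    the first whitespace-delimited token of the header.  An empty file
    yields an empty list; sequence data before any header raises
    :class:`FastaParseError` naming the offending line.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        "sequence data before any '>' header", lineno
                    )
                chunks.append(line.upper())
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write records as unwrapped FASTA (one sequence line per record)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq.upper()}\n")


def validate_sequence(seq: str) -> list[int]:
    """Return 1-based positions of non-IUPAC characters (empty = valid)."""
    return [
        i for i, c in enumerate(seq.upper(), start=1) if c not in IUPAC_CODES
    ]


_REQUIRED_COLUMNS = ("specimen_id", "site_id", "name", "latitude", "longitude", "date")


def read_metadata(path: str | Path) -> tuple[dict[str, CollectionSite], dict[str, str]]:
    """Read the specimen metadata CSV.

    Returns ``(sites, specimen_to_site)`` where ``sites`` maps site_id
    to :class:`CollectionSite`.  The CSV must carry the columns
    ``specimen_id, site_id, name, latitude, longitude, date`` (a
    ``country`` column is optional).  Coordinate parsing failures and
    out-of-range values are reported with the offending row.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"missing required columns: {', '.join(missing)}")

    sites: dict[str, CollectionSite] = {}
    specimen_to_site: dict[str, str] = {}
    for idx, row in df.iterrows():
        sid = str(row["site_id"])
        try:
            lat = float(row["latitude"])
            lon = float(row["longitude"])
        except (TypeError, ValueError) as exc:
            raise MetadataError(f"row {idx}: unparseable coordinate ({exc})") from exc
        try:
            site = CollectionSite(
                site_id=sid,
                name=str(row["name"]),
                country=str(row.get("country", "")),
                latitude=lat,
                longitude=lon,
                date_label=str(row["date"]),
            )
        except ValueError as exc:
            raise MetadataError(f"row {idx}: {exc}") from exc
        if sid in sites and sites[sid] != site:
            raise MetadataError(f"row {idx}: conflicting definitions for site {sid}")
        sites[sid] = site
        spec_id = str(row["specimen_id"])
        if spec_id and spec_id.lower() != "nan":
            specimen_to_site[spec_id] = sid
    return sites, specimen_to_site


def load_dataset(
    metadata_csv: str | Path,
    fasta_by_locus: Mapping[str, str | Path],
) -> tuple[list[SpecimenRecord], dict[str, CollectionSite]]:
    """Assemble specimen records from per-locus FASTA files + metadata.

    ``fasta_by_locus`` maps a locus name (e.g. "COIB", "TPI") to a FASTA
    path whose record ids are specimen ids.  A specimen referencing an
    unknown site, or a FASTA id absent from the metadata, is an error;
    a specimen missing one locus is kept with that locus absent.
    """
    sites, spec_to_site = read_metadata(metadata_csv)
    records: dict[str, SpecimenRecord] = {}
    for spec_id, sid in spec_to_site.items():
        if sid not in sites:
            raise MetadataError(f"specimen {spec_id} references unknown site {sid}")
        records[spec_id] = SpecimenRecord(
            specimen_id=spec_id,
            site_id=sid,
            collection_date=sites[sid].date_label,
        )
    for locus, path in fasta_by_locus.items():
        for seq_id, seq in read_fasta(path):
            if seq_id not in records:
                raise MetadataError(
                    f"FASTA id {seq_id!r} ({locus}) not present in metadata"
                )
            bad = validate_sequence(seq)
            if bad:
                raise MetadataError(
                    f"specimen {seq_id} ({locus}): non-IUPAC characters at "
                    f"positions {bad[:5]}"
                )
            records[seq_id].sequences[locus] = seq.upper()
    return list(records.values()), sites
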