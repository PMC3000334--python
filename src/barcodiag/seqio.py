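"""Reading, writing and auditing aligned COI barcode libraries.

A *library* is a set of specimen records over a common alignment frame:
each record carries one aligned nucleotide sequence (the ~658-bp barcode
region of the mitochondrial COI gene) plus specimen metadata (species,
optional subspecies, locality, provenance).  Sequences are stored
upper-case; gaps ('-') and IUPAC ambiguity codes are permitted and are
treated as missing data by downstream analyses.

Haplotype collapsing uses overlap identity: two records belong to the same
haplotype when they agree at every column where both carry an unambiguous
base and that shared coverage is at least ``min_overlap`` columns, extended
by transitive closure.  Reported haplotype totals therefore depend on the
``min_overlap`` choice whenever truncated sequences are present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._encoding import IUPAC_CHARS, encode_many

logger = logging.getLogger(__name__)

#: metadata columns recognised in the TSV; `id` and `species` are required
METADATA_COLUMNS = ("id", "species", "subspecies", "country", "locality", "lat", "lon", "source")

DEFAULT_MIN_OVERLAP = 300


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned barcode sequence with its specimen metadata."""

    id: str
    sequence: str
    species: str
    subspecies: Optional[str] = None
    country: Optional[str] = None
    locality: Optional[str] = None
    lat: Optional[float] = None
    lon: Optional[float] = None
    source: str = "reference"

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - IUPAC_CHARS
        if bad:
            raise ValueError(f"record {self.id!r}: non-IUPAC characters {sorted(bad)}")
        if not self.species:
            raise ValueError(f"record {self.id!r}: empty species label")
        object.__setattr__(self, "sequence", seq)

    @property
    def n_unambiguous(self) -> int:
        """Number of columns with a definite base (non-gap, non-N)."""
        return sum(1 for ch in self.sequence if ch not in ("-", "N"))


@dataclass
class Library:
    """Ordered collection of records over a common alignment frame."""

    records: list[SequenceRecord]
    alignment_length: int = field(init=False)

    def __post_init__(self):
        if not self.records:
            raise ValueError("library must contain at least one record")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate record ids: {sorted(dupes)}")
        self.alignment_length = lengths.pop()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species_of(self) -> dict[str, str]:
        return {r.id: r.species for r in self.records}

    @property
    def species(self) -> list[str]:
        """Distinct species labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return list(seen)

    def subset(self, ids: Iterable[str]) -> "Library":
        keep = set(ids)
        return Library([r for r in self.records if r.id in keep])

    def drop(self, ids: Iterable[str]) -> "Library":
        out = set(ids)
        return Library([r for r in self.records if r.id not in out])


@dataclass
class Haplotype:
    """A distinct sequence variant and the specimens carrying it."""

    canonical_sequence: str
    member_ids: list[str]
    species_set: set[str]

    @property
    def shared_between_species(self) -> bool:
        return len(self.species_set) > 1


def _parse_optional(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_metadata(metadata_path) -> pd.DataFrame:
    df = pd.read_csv(metadata_path, sep="\t", comment="#", dtype=str)
    missing = {"id", "species"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    return df


def read_library(fasta_path, metadata_path, assume_5prime_anchored: bool = False) -> Library:
    """Join a FASTA alignment with a specimen-metadata TSV into a Library.

    Every FASTA id must appear in the metadata; metadata rows without a
    sequence are ignored with a warning.  Unequal sequence lengths are
    rejected unless ``assume_5prime_anchored`` is set, in which case shorter
    sequences are right-padded with gaps (appropriate for 5'-anchored COI
    barcodes of varying read length).
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {fasta_path}")
    meta = read_metadata(metadata_path)
    by_id = {row["id"]: row for _, row in meta.iterrows()}

    orphans = sorted(set(seqs) - set(by_id))
    if orphans:
        raise ValueError(f"FASTA ids absent from metadata: {orphans}")
    unused = sorted(set(by_id) - set(seqs))
    if unused:
        logger.warning("metadata rows without sequences ignored: %s", unused)

    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        if not assume_5prime_anchored:
            raise ValueError(
                f"ragged alignment (lengths {sorted(lengths)}); "
                "pass assume_5prime_anchored=True to right-pad"
            )
        frame = max(lengths)
        seqs = {i: s + "-" * (frame - len(s)) for i, s in seqs.items()}

    records = []
    for rid, seq in seqs.items():
        row = by_id[rid]
        lat = _parse_optional(row.get("lat"))
        lon = _parse_optional(row.get("lon"))
        records.append(
            SequenceRecord(
                id=rid,
                sequence=seq,
                species=row["species"],
                subspecies=_parse_optional(row.get("subspecies")),
                country=_parse_optional(row.get("country")),
                locality=_parse_optional(row.get("locality")),
                lat=float(lat) if lat is not None else None,
                lon=float(lon) if lon is not None else None,
                source=_parse_optional(row.get("source")) or "reference",
            )
        )
    return Library(records)


def write_library(lib: Library, fasta_path, metadata_path) -> None:
    """Write FASTA + metadata TSV in the dialect read_library consumes."""
    with open(fasta_path, "w") as fh:
        for r in lib:
            fh.write(f">{r.id}\n{r.sequence}\n")
    rows = []
    for r in lib:
        rows.append(
            {
                "id": r.id,
                "species": r.species,
                "subspecies": r.subspecies or "",
                "country": r.country or "",
                "locality": r.locality or "",
                "lat": "" if r.lat is None else r.lat,
                "lon": "" if r.lon is None else r.lon,
                "source": r.source,
            }
        )
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def filter_by_length(lib: Library, min_unambiguous_bases: int) -> Library:
    """Retain records with strictly more than ``min_unambiguous_bases``
    non-gap, non-N characters, preserving order.

    The >600 bp threshold used for the subspecies analyses excludes the
    short legacy-amplicon sequences (375-378 bp).
    """
    if min_unambiguous_bases < 1:
        raise ValueError("min_unambiguous_bases must be >= 1")
    kept = [r for r in lib if r.n_unambiguous > min_unambiguous_bases]
    if not kept:
        logger.warning("length filter (> %d) removed every record", min_unambiguous_bases)
        return EmptyLibrary()
    if len(kept) < len(lib):
        logger.warning(
            "length filter (> %d) dropped %d of %d records",
            min_unambiguous_bases, len(lib) - len(kept), len(lib),
        )
    return Library(kept)


class EmptyLibrary:
    """Sentinel returned when a filter removes every record."""

    records: list = []
    alignment_length = 0

    def __len__(self):
        return 0

    def __iter__(self):
        return iter(())


def collapse_haplotypes(
    lib: Library, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> tuple[list[Haplotype], list[str]]:
    """Group records into haplotypes by overlap identity with transitive closure.

    Returns ``(haplotypes, excluded_ids)``: records with fewer than
    ``min_overlap`` unambiguous bases cannot be compared reliably and are
    excluded (and reported) rather than forced into a group.
    """
    eligible = [r for r in lib if r.n_unambiguous >= min_overlap]
    excluded = [r.id for r in lib if r.n_unambiguous < min_overlap]
    if excluded:
        logger.warning("haplotype collapsing excluded %d short records: %s",
                       len(excluded), excluded)
    if not eligible:
        return [], excluded

    mat = encode_many([r.sequence for r in eligible])
    valid = mat < 4
    n = len(eligible)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(n):
        vi, si = valid[i], mat[i]
        for j in range(i + 1, n):
            both = vi & valid[j]
            cov = int(both.sum())
            if cov >= min_overlap and np.array_equal(si[both], mat[j][both]):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    haplotypes = []
    for members in groups.values():
        recs = [eligible[i] for i in members]
        canonical = max(recs, key=lambda r: r.n_unambiguous)
        haplotypes.append(
            Haplotype(
                canonical_sequence=canonical.sequence,
                member_ids=[r.id for r in recs],
                species_set={r.species for r in recs},
            )
        )
    haplotypes.sort(key=lambda h: h.member_ids[0])
    return haplotypes, excluded


def haplotype_summary(haplotypes: Sequence[Haplotype]) -> pd.DataFrame:
    """Per-species haplotype counts plus a shared-haplotype flag."""
    rows = []
    species = sorted({s for h in haplotypes for s in h.species_set})
    for sp in species:
        own = [h for h in haplotypes if sp in h.species_set]
        rows.append(
            {
                "species": sp,
                "n_haplotypes": len(own),
                "n_shared": sum(1 for h in own if h.shared_between_species),
            }
        )
    return pd.DataFrame(rows)
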