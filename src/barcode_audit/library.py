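"""Barcode library container and FASTA/TSV input-output.

A barcode library couples an (assumed pre-aligned) set of CO1-style
sequences with per-specimen metadata: a binomial species name, optional
higher taxonomy and locality. All downstream analyses (distances, gap
screening, clustering, identification simulation, networks) consume the
:class:`BarcodeLibrary` built here.

Alignment is an input contract, not a computation: a library whose
sequences differ in length is accepted (``alignment_state == "ragged"``)
but only length filtering may be applied to it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide codes accepted on input (ambiguities are treated as
#: missing data downstream, matching pairwise deletion).
ALLOWED_CHARS = frozenset("ACGTRYSWKMBDHVN-")

METADATA_COLUMNS = ("specimen_id", "species", "taxonomy", "locality")


class LibraryError(ValueError):
    """Raised for malformed or inconsistent library inputs."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One specimen: identifier, species label, sequence and provenance.

    ``taxonomy`` is an ordered list of higher-rank labels (e.g. class,
    order, family); ``locality`` is free text. Both may be empty.
    """

    specimen_id: str
    species: str
    sequence: str
    taxonomy: tuple[str, ...] = ()
    locality: str = ""

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise LibraryError("specimen_id must be non-empty")
        if not self.species or not self.species.strip():
            raise LibraryError(f"record {self.specimen_id!r}: species must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise LibraryError(f"record {self.specimen_id!r}: sequence is empty")
        for pos, ch in enumerate(seq):
            if ch not in ALLOWED_CHARS:
                raise LibraryError(
                    f"record {self.specimen_id!r}: illegal character {ch!r} "
                    f"at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "species", " ".join(self.species.split()))
        object.__setattr__(self, "taxonomy", tuple(self.taxonomy))

    @property
    def informative_length(self) -> int:
        """Number of sites that are neither alignment gaps nor N."""
        return sum(1 for c in self.sequence if c not in "-N")


@dataclass(frozen=True)
class BarcodeLibrary:
    """An ordered collection of :class:`BarcodeRecord` with unique IDs."""

    records: tuple[BarcodeRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.specimen_id in seen:
                raise LibraryError(f"duplicate specimen ID {rec.specimen_id!r}")
            seen.add(rec.specimen_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def species_labels(self) -> list[str]:
        return [r.species for r in self.records]

    @property
    def aligned_length(self) -> int:
        if not self.records:
            return 0
        return len(self.records[0].sequence)

    @property
    def alignment_state(self) -> str:
        lengths = {len(r.sequence) for r in self.records}
        return "aligned" if len(lengths) <= 1 else "ragged"

    @property
    def is_aligned(self) -> bool:
        return self.alignment_state == "aligned"

    def species_index(self) -> dict[str, list[int]]:
        """Map species name -> record positions, in input order."""
        out: dict[str, list[int]] = {}
        for i, rec in enumerate(self.records):
            out.setdefault(rec.species, []).append(i)
        return out

    def singleton_species(self) -> list[str]:
        return [sp for sp, idx in self.species_index().items() if len(idx) == 1]

    def subset(self, specimen_ids) -> "BarcodeLibrary":
        wanted = set(specimen_ids)
        missing = wanted - set(self.ids)
        if missing:
            raise LibraryError(f"unknown specimen IDs: {sorted(missing)}")
        return BarcodeLibrary(tuple(r for r in self.records if r.specimen_id in wanted))

    def subset_species(self, species_names) -> "BarcodeLibrary":
        wanted = {" ".join(s.split()) for s in species_names}
        known = set(self.species_labels)
        missing = wanted - known
        if missing:
            raise LibraryError(f"unknown species: {sorted(missing)}")
        return BarcodeLibrary(tuple(r for r in self.records if r.species in wanted))

    def require_aligned(self, what: str = "this analysis") -> None:
        if not self.is_aligned:
            raise LibraryError(f"{what} requires an aligned (equal-length) library")


def _records_from_fasta(handle) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seqs:
            raise LibraryError(f"duplicate specimen ID {rec.id!r} in FASTA")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise LibraryError("FASTA source contains no records")
    return seqs


def read_metadata(metadata_source) -> pd.DataFrame:
    """Read the specimen metadata TSV (tab-separated specimen export, header required)."""
    df = pd.read_csv(metadata_source, sep="\t", dtype=str, keep_default_na=False)
    for col in ("specimen_id", "species"):
        if col not in df.columns:
            raise LibraryError(f"metadata is missing mandatory column {col!r}")
    dup = df["specimen_id"][df["specimen_id"].duplicated()]
    if len(dup):
        raise LibraryError(f"duplicate specimen ID {dup.iloc[0]!r} in metadata")
    return df


def read_library(fasta_source, metadata_source) -> BarcodeLibrary:
    """Assemble a library from a FASTA file/handle and a metadata TSV.

    FASTA IDs and metadata ``specimen_id`` values must match 1:1; any
    orphan on either side is a hard error listing the offending IDs.
    """
    if isinstance(fasta_source, str):
        with open(fasta_source) as fh:
            seqs = _records_from_fasta(fh)
    else:
        seqs = _records_from_fasta(fasta_source)
    meta = read_metadata(metadata_source)

    fasta_ids = set(seqs)
    meta_ids = set(meta["specimen_id"])
    only_fasta = sorted(fasta_ids - meta_ids)
    only_meta = sorted(meta_ids - fasta_ids)
    if only_fasta or only_meta:
        raise LibraryError(
            "FASTA/metadata specimen ID mismatch; "
            f"FASTA-only: {only_fasta}; metadata-only: {only_meta}"
        )

    records = []
    for row in meta.itertuples(index=False):
        taxonomy = tuple(
            t for t in getattr(row, "taxonomy", "").split(";") if t
        )
        records.append(
            BarcodeRecord(
                specimen_id=row.specimen_id,
                species=row.species,
                sequence=seqs[row.specimen_id],
                taxonomy=taxonomy,
                locality=getattr(row, "locality", ""),
            )
        )
    return BarcodeLibrary(tuple(records))


def write_library(library: BarcodeLibrary, fasta_sink, metadata_sink) -> None:
    """Write FASTA + metadata TSV such that :func:`read_library` round-trips."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
        for r in library
    ]
    if isinstance(fasta_sink, str):
        with open(fasta_sink, "w") as fh:
            SeqIO.write(seq_records, fh, "fasta")
    else:
        SeqIO.write(seq_records, fasta_sink, "fasta")

    meta = pd.DataFrame(
        {
            "specimen_id": library.ids,
            "species": library.species_labels,
            "taxonomy": [";".join(r.taxonomy) for r in library],
            "locality": [r.locality for r in library],
        }
    )
    meta.to_csv(metadata_sink, sep="\t", index=False)


def library_to_strings(library: BarcodeLibrary) -> tuple[str, str]:
    """Serialize to (fasta_text, metadata_tsv_text) without touching disk."""
    fasta_buf, meta_buf = io.StringIO(), io.StringIO()
    write_library(library, fasta_buf, meta_buf)
    return fasta_buf.getvalue(), meta_buf.getvalue()


def length_filter(
    library: BarcodeLibrary, min_len: int = 500
) -> tuple[BarcodeLibrary, list[str]]:
    """Drop records whose ungapped, non-N length is below ``min_len``.

    Returns the filtered library and the list of removed specimen IDs.
    Order of surviving records is preserved; applying the filter twice is
    a no-op.
    """
    if min_len < 0:
        raise LibraryError("min_len must be >= 0")
    kept, removed = [], []
    for rec in library:
        if rec.informative_length < min_len:
            removed.append(rec.specimen_id)
        else:
            kept.append(rec)
    if library.records and not kept:
        raise LibraryError(f"length_filter(min_len={min_len}) removed every record")
    return BarcodeLibrary(tuple(kept)), removed


def trim_terminal_gaps(library: BarcodeLibrary) -> BarcodeLibrary:
    """Replace leading/trailing gap runs by N (per record).

    Terminal gaps usually denote missing data at fragment ends rather than
    indels; converting them to N keeps the alignment length while making
    the missing-data semantics explicit. Exposed as an option because the
    right treatment depends on how the input alignment was produced.
    """
    new = []
    for rec in library:
        s = rec.sequence
        n_lead = len(s) - len(s.lstrip("-"))
        n_trail = len(s) - len(s.rstrip("-"))
        core = s[n_lead : len(s) - n_trail] if n_trail else s[n_lead:]
        new.append(replace(rec, sequence="N" * n_lead + core + "N" * n_trail))
    return BarcodeLibrary(tuple(new))
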