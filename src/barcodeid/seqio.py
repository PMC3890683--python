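"""Reading, writing and validating labelled barcode alignments.

A barcode reference library is a set of aligned, equal-length COI
sequences, each labelled with a specimen identifier, a species binomial,
a genus and optionally a population (geographic or host-plant label).
Labels travel in the FASTA header, delimiter-separated; the field order
is configurable through :class:`HeaderSchema`.

Validation is strict and total: any malformed input raises a diagnostic
error naming the offending record, never a silently truncated dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BarcodeRecord",
    "BarcodeDataset",
    "HeaderSchema",
    "BarcodeValidationError",
    "HeaderParseError",
    "read_labeled_fasta",
    "write_labeled_fasta",
    "check_coding_frame",
    "write_report",
]

#: Nucleotide alphabet accepted on input: the four bases, IUPAC ambiguity
#: codes and the alignment gap character.
ALLOWED_CHARS = frozenset("ACGTRYSWKMBDHVN-")


class BarcodeValidationError(ValueError):
    """Input violates a dataset invariant (lengths, duplicates, alphabet)."""


class HeaderParseError(BarcodeValidationError):
    """A FASTA header does not parse under the configured schema."""


@dataclass(frozen=True)
class HeaderSchema:
    """Field order and delimiter of the structured FASTA header.

    The default ``specimen_id|species|genus|population`` mirrors the
    metadata a BOLD-style reference record carries; ``population`` is
    optional on input.
    """

    fields: tuple[str, ...] = ("specimen_id", "species", "genus", "population")
    delimiter: str = "|"

    def __post_init__(self) -> None:
        required = {"specimen_id", "species", "genus"}
        if not required.issubset(self.fields):
            raise ValueError(f"header schema must include {sorted(required)}")

    def parse(self, header: str) -> dict[str, str | None]:
        parts = header.split(self.delimiter)
        n_required = len([f for f in self.fields if f != "population"])
        if not (n_required <= len(parts) <= len(self.fields)):
            raise HeaderParseError(
                f"header {header!r} has {len(parts)} field(s); "
                f"schema expects {n_required}-{len(self.fields)} "
                f"({self.delimiter.join(self.fields)})"
            )
        out: dict[str, str | None] = {"population": None}
        for name, value in zip(self.fields, parts):
            out[name] = value.strip() or None
        for name in ("specimen_id", "species", "genus"):
            if not out.get(name):
                raise HeaderParseError(f"header {header!r}: empty {name} field")
        return out

    def format(self, record: "BarcodeRecord") -> str:
        values = {
            "specimen_id": record.specimen_id,
            "species": record.species,
            "genus": record.genus,
            "population": record.population or "",
        }
        return self.delimiter.join(values[f] for f in self.fields)


@dataclass(frozen=True)
class BarcodeRecord:
    """One labelled, aligned barcode sequence."""

    specimen_id: str
    species: str
    genus: str
    sequence: str
    population: str | None = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise BarcodeValidationError("specimen_id must be non-empty")
        if not self.species or not self.genus:
            raise BarcodeValidationError(
                f"record {self.specimen_id!r}: species and genus must be non-empty"
            )
        if not self.sequence:
            raise BarcodeValidationError(
                f"record {self.specimen_id!r}: sequence must be non-empty"
            )
        seq = self.sequence.upper()
        bad = set(seq) - ALLOWED_CHARS
        if bad:
            raise BarcodeValidationError(
                f"record {self.specimen_id!r}: disallowed characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass
class BarcodeDataset:
    """An aligned collection of barcode records plus outgroup bookkeeping.

    Invariants (enforced on construction): all sequences share
    ``alignment_length``; specimen ids are unique; every outgroup id is a
    record's id; each species maps to exactly one genus.
    """

    records: list[BarcodeRecord]
    outgroup_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.records:
            raise BarcodeValidationError("dataset must contain at least one record")
        self.records = list(self.records)
        self.outgroup_ids = frozenset(self.outgroup_ids)
        length = len(self.records[0].sequence)
        deviant = [
            f"{r.specimen_id} (len {len(r.sequence)})"
            for r in self.records
            if len(r.sequence) != length
        ]
        if deviant:
            raise BarcodeValidationError(
                f"unequal sequence lengths (expected {length}): {', '.join(deviant)}"
            )
        seen: set[str] = set()
        for r in self.records:
            if r.specimen_id in seen:
                raise BarcodeValidationError(
                    f"duplicate specimen_id {r.specimen_id!r}"
                )
            seen.add(r.specimen_id)
        unknown = self.outgroup_ids - seen
        if unknown:
            raise BarcodeValidationError(
                f"outgroup ids not in dataset: {sorted(unknown)}"
            )
        genus_of: dict[str, str] = {}
        for r in self.records:
            prev = genus_of.setdefault(r.species, r.genus)
            if prev != r.genus:
                raise BarcodeValidationError(
                    f"species {r.species!r} mapped to two genera: {prev!r}, {r.genus!r}"
                )

    # -- convenience views -------------------------------------------------

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def ingroup(self) -> list[BarcodeRecord]:
        return [r for r in self.records if r.specimen_id not in self.outgroup_ids]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, specimen_id: str) -> BarcodeRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    def species_of(self) -> dict[str, str]:
        """specimen_id → species."""
        return {r.specimen_id: r.species for r in self.records}

    def genus_of_species(self) -> dict[str, str]:
        """species → genus (a function by invariant)."""
        return {r.species: r.genus for r in self.records}

    def species_counts(self, ingroup_only: bool = True) -> dict[str, int]:
        counts: dict[str, int] = {}
        pool = self.ingroup if ingroup_only else self.records
        for r in pool:
            counts[r.species] = counts.get(r.species, 0) + 1
        return counts

    def subset(self, keep_ids: Iterable[str]) -> "BarcodeDataset":
        keep = set(keep_ids)
        return BarcodeDataset(
            records=[r for r in self.records if r.specimen_id in keep],
            outgroup_ids=self.outgroup_ids & keep,
        )


def read_labeled_fasta(
    path: str | Path,
    header_schema: HeaderSchema | None = None,
    outgroup_ids: Iterable[str] = (),
) -> BarcodeDataset:
    """Read an aligned, labelled FASTA file into a :class:`BarcodeDataset`.

    Headers must parse under *header_schema* (default
    ``specimen_id|species|genus[|population]``). Input order is preserved.
    Raises :class:`HeaderParseError` or :class:`BarcodeValidationError`
    naming the offending record on any malformed input; an empty file is
    an error, not an empty dataset.
    """
    schema = header_schema or HeaderSchema()
    path = Path(path)
    records: list[BarcodeRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = rec.description
        try:
            fields = schema.parse(header)
        except HeaderParseError as err:
            raise HeaderParseError(f"record {i}: {err}") from None
        records.append(
            BarcodeRecord(
                specimen_id=fields["specimen_id"],
                species=fields["species"],
                genus=fields["genus"],
                population=fields.get("population"),
                sequence=str(rec.seq),
            )
        )
    if not records:
        raise BarcodeValidationError(f"no FASTA records found in {path}")
    return BarcodeDataset(records=records, outgroup_ids=frozenset(outgroup_ids))


def write_labeled_fasta(
    dataset: BarcodeDataset,
    path: str | Path,
    header_schema: HeaderSchema | None = None,
    line_width: int = 70,
) -> Path:
    """Write the dataset back to labelled FASTA (round-trips with read)."""
    schema = header_schema or HeaderSchema()
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=schema.format(r), description="")
        for r in dataset.records
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(seq_records)
    return path


# -- coding-frame QC --------------------------------------------------------

#: Stop codons per supported NCBI translation table. COI barcodes are
#: conventionally checked under the invertebrate mitochondrial code (5),
#: where TGA encodes tryptophan and only TAA/TAG terminate.
_STOP_CODONS: Mapping[int, frozenset[str]] = {
    1: frozenset({"TAA", "TAG", "TGA"}),  # standard
    2: frozenset({"TAA", "TAG", "AGA", "AGG"}),  # vertebrate mito
    5: frozenset({"TAA", "TAG"}),  # invertebrate mito
}


@dataclass(frozen=True)
class CodingQC:
    """Per-record coding-frame quality report."""

    specimen_id: str
    has_internal_stop: bool
    stop_positions: tuple[int, ...]  # 0-based codon start positions
    has_gaps: bool


def check_coding_frame(
    dataset: BarcodeDataset,
    genetic_code: int = 5,
    frame: int = 0,
) -> list[CodingQC]:
    """Report internal stop codons and gap characters per record.

    Pure report — does not mutate or filter the dataset. Codons containing
    a gap or ambiguity character are not translated. The final (possibly
    partial) codon is not counted as internal.
    """
    if genetic_code not in _STOP_CODONS:
        raise ValueError(
            f"unknown genetic code table {genetic_code}; "
            f"supported: {sorted(_STOP_CODONS)}"
        )
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    stops = _STOP_CODONS[genetic_code]
    out: list[CodingQC] = []
    for r in dataset.records:
        seq = r.sequence
        coding = seq[frame:]
        n_codons = len(coding) // 3
        positions = [
            frame + 3 * k
            for k in range(n_codons - 1)  # exclude terminal codon
            if coding[3 * k : 3 * k + 3] in stops
        ]
        out.append(
            CodingQC(
                specimen_id=r.specimen_id,
                has_internal_stop=bool(positions),
                stop_positions=tuple(positions),
                has_gaps="-" in seq,
            )
        )
    return out


# -- tabular report output ---------------------------------------------------


def _render_cell(value, float_precision: int) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return f"{value:.{float_precision}f}"
    return str(value)


def write_report(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    format: str = "tsv",
    columns: Sequence[str] | None = None,
    float_precision: int = 4,
) -> Path:
    """Write a tabular report deterministically (stable column order,
    fixed float precision, UTF-8, LF endings). ``rows`` may be empty, in
    which case ``columns`` must be given and a header-only file results.
    """
    if rows is None:
        raise ValueError("report must not be None")
    if columns is None:
        if not rows:
            raise ValueError("empty report needs explicit columns")
        columns = list(rows[0].keys())
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(columns)]
        for row in rows:
            lines.append(
                "\t".join(_render_cell(row.get(c), float_precision) for c in columns)
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    elif format == "json":
        payload = [
            {
                c: (round(v, float_precision) if isinstance(v, float) else v)
                for c, v in ((c, row.get(c)) for c in columns)
            }
            for row in rows
        ]
        path.write_text(
            json.dumps(payload, indent=2, sort_keys=False) + "\n",
            encoding="utf-8",
            newline="\n",
        )
    else:
        raise ValueError(f"unknown report format {format!r} (tsv|json)")
    return path
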