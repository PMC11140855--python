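"""Sequence, alignment and taxonomy I/O.

FASTA parsing is delegated to Biopython; this module layers the package's
validation rules on top: sequences are uppercased, U is normalised to T,
gaps are legal only inside alignments, and every residue must be a valid
IUPAC nucleotide code. Taxonomy labels travel either in FASTA description
key-values (``species=...;class=...;target=0/1``) or in a separate TSV
table; the TSV wins on conflict.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .iupac import IUPAC_ALPHABET, InvalidBaseError, validate_sequence

ALIGNMENT_ALPHABET = IUPAC_ALPHABET | {"-"}


class FastaParseError(ValueError):
    pass


class DuplicateIdError(ValueError):
    pass


class RaggedAlignmentError(ValueError):
    pass


class UnknownSequenceIdError(KeyError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """One taxonomically labeled, gap-free reference sequence."""

    id: str
    seq: str
    species: str | None = None
    class_name: str | None = None
    is_target: bool | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise InvalidBaseError(f"sequence {self.id!r} is empty")
        for i, c in enumerate(self.seq):
            if c not in IUPAC_ALPHABET:
                raise InvalidBaseError(
                    f"sequence {self.id!r} has non-IUPAC character {c!r} "
                    f"at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Alignment:
    """Gapped FASTA alignment: equal-width rows over IUPAC ∪ {-}."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise RaggedAlignmentError("alignment has no rows")
        widths = {len(s) for _, s in self.records}
        if len(widths) != 1:
            a, b = sorted(widths)[:2]
            raise RaggedAlignmentError(
                f"ragged alignment: rows of length {a} and {b}"
            )
        for rid, s in self.records:
            bad = set(s) - ALIGNMENT_ALPHABET
            if bad:
                raise InvalidBaseError(
                    f"alignment row {rid!r} has non-IUPAC character "
                    f"{sorted(bad)[0]!r}"
                )

    @property
    def width(self) -> int:
        return len(self.records[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def rows(self) -> Iterator[str]:
        for _, s in self.records:
            yield s


@dataclass
class TaxonomyTable:
    """id → (species, class, is_target) lookup."""

    rows: dict[str, tuple[str, str, bool]] = field(default_factory=dict)

    def add(self, seq_id: str, species: str, class_name: str, is_target: bool) -> None:
        if seq_id in self.rows:
            raise DuplicateIdError(f"duplicate taxonomy id {seq_id!r}")
        self.rows[seq_id] = (species, class_name, is_target)

    def lookup(self, seq_id: str) -> tuple[str, str, bool]:
        try:
            return self.rows[seq_id]
        except KeyError:
            raise UnknownSequenceIdError(
                f"sequence id {seq_id!r} not present in the taxonomy table"
            ) from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.rows

    def __len__(self) -> int:
        return len(self.rows)


_DESC_KV = re.compile(r"(species|class|target)\s*=\s*([^;]+)")


def _normalise(raw: str) -> str:
    return raw.upper().replace("U", "T")


def _parse_description(desc: str) -> dict[str, str]:
    return {k: v.strip() for k, v in _DESC_KV.findall(desc)}


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read gap-free FASTA into validated SequenceRecords.

    Uppercases, maps U→T, parses optional ``species=…;class=…;target=0/1``
    key-values from the description. Duplicate ids and non-IUPAC residues
    raise with the offending id and position named.
    """
    path = Path(path)
    try:
        entries = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FastaParseError(f"{path}: {exc}") from exc
    if not entries and path.stat().st_size > 0:
        raise FastaParseError(f"{path}: no FASTA entries found")
    seen: set[str] = set()
    out: list[SequenceRecord] = []
    for entry in entries:
        if entry.id in seen:
            raise DuplicateIdError(f"{path}: duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        kv = _parse_description(entry.description)
        target = kv.get("target")
        out.append(
            SequenceRecord(
                id=entry.id,
                seq=_normalise(str(entry.seq)),
                species=kv.get("species"),
                class_name=kv.get("class"),
                is_target=None if target is None else target not in ("0", "false"),
            )
        )
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records with taxonomy (when set) encoded in the description."""
    bio = []
    for r in records:
        desc = ""
        if r.species is not None or r.class_name is not None or r.is_target is not None:
            parts = []
            if r.species is not None:
                parts.append(f"species={r.species}")
            if r.class_name is not None:
                parts.append(f"class={r.class_name}")
            if r.is_target is not None:
                parts.append(f"target={int(r.is_target)}")
            desc = ";".join(parts)
        bio.append(_BioRecord(Seq(r.seq), id=r.id, description=desc))
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path: str | Path) -> Alignment:
    """Read a gapped FASTA alignment; rows must share one width."""
    path = Path(path)
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise RaggedAlignmentError(f"{path}: empty alignment")
    return Alignment(
        records=tuple((e.id, _normalise(str(e.seq)).replace("U", "T")) for e in entries)
    )


def write_alignment(aln: Alignment, path: str | Path) -> None:
    SeqIO.write(
        [_BioRecord(Seq(s), id=rid, description="") for rid, s in aln.records],
        str(path),
        "fasta",
    )


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read the ``id<TAB>species<TAB>class<TAB>target`` taxonomy TSV."""
    table = TaxonomyTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:4]] != ["id", "species", "class", "target"]:
            raise ValueError(
                f"{path}: expected header id<TAB>species<TAB>class<TAB>target, "
                f"got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            table.add(parts[0], parts[1], parts[2], parts[3] not in ("0", "false"))
    return table


def write_taxonomy(table: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tspecies\tclass\ttarget\n")
        for seq_id, (species, class_name, is_target) in table.rows.items():
            fh.write(f"{seq_id}\t{species}\t{class_name}\t{int(is_target)}\n")


def apply_taxonomy(
    records: Iterable[SequenceRecord], table: TaxonomyTable
) -> list[SequenceRecord]:
    """Overlay a taxonomy table onto records (table wins on conflict)."""
    out = []
    for r in records:
        if r.id in table:
            species, class_name, is_target = table.lookup(r.id)
            out.append(
                replace(r, species=species, class_name=class_name, is_target=is_target)
            )
        else:
            out.append(r)
    return out


def degap(gapped: str) -> str:
    """Remove alignment gaps; explicit step when lifting a row out of an Alignment."""
    return validate_sequence(gapped.replace("-", ""), what="degapped row")
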