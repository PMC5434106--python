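"""Domain types shared by every pipeline stage, plus FASTA/TSV readers and writers.

Sequences are handled in DNA space: RNA ``U`` is normalized to ``T`` on input so
that downstream primer matching (primers are DNA oligos) operates on a single
alphabet.  Taxonomy is an ordered rank path ``domain; phylum; class; order;
family; genus``; the genus slot may be empty for sequences unclassified at
genus rank (common for environmental reference sequences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "IUPAC_DNA",
    "ReferenceSequence",
    "TaxonSet",
    "MultipleAlignment",
    "read_fasta",
    "write_fasta",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "attach_taxonomy",
    "read_primer_table",
    "read_alignment_fasta",
    "write_alignment_fasta",
]

#: Characters permitted in a reference sequence (after U->T normalization).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

#: Number of ranks retained in a taxonomy path (domain..genus); deeper ranks
#: (species, strain) are ignored.
N_RANKS = 6

_FASTA_WRAP = 80


@dataclass(frozen=True)
class ReferenceSequence:
    """A single 16S-like reference sequence.

    ``abundance`` counts how many identical reads/records this entry
    represents; dereplication sums it.  ``is_type_strain`` marks nomenclatural
    anchor sequences used for genus validation.
    """

    id: str
    sequence: str
    taxonomy: tuple[str, ...] = ()
    is_type_strain: bool = False
    abundance: int = 1
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.abundance < 1:
            raise ValueError(f"sequence {self.id!r}: abundance must be positive")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"sequence {self.id!r}: illegal character {self.sequence[pos]!r} "
                f"at position {pos + 1}"
            )

    @property
    def genus(self) -> str:
        """Genus-rank label; empty string when unclassified at genus rank."""
        if not self.taxonomy:
            return ""
        return self.taxonomy[-1]


@dataclass(frozen=True)
class TaxonSet:
    """A named group of reference sequences (here: one validated genus)."""

    name: str
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"taxon {self.name!r} has no members")


@dataclass(frozen=True)
class MultipleAlignment:
    """Fixed-width multiple alignment; gap character ``-``."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids in alignment")
        if self.rows:
            w = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != w:
                    raise ValueError(f"row {rid!r} has length {len(row)} != width {w}")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")


def _normalize_sequence(raw: str, seq_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - IUPAC_DNA
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise ValueError(
            f"sequence {seq_id!r}: illegal character {seq[pos]!r} at position {pos + 1}"
        )
    return seq


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a FASTA file into :class:`ReferenceSequence` records, in file order.

    The id is the header token before the first whitespace; the remainder of
    the header is kept as ``description``.  Lowercase letters and ``U`` are
    normalized.  Duplicate ids raise; an empty file returns ``[]`` with a
    warning.
    """
    path = Path(path)
    records: list[ReferenceSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            ReferenceSequence(
                id=rec.id,
                sequence=_normalize_sequence(str(rec.seq), rec.id),
                description=desc,
            )
        )
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[ReferenceSequence], path: str | Path) -> None:
    """Write records as FASTA with 80-column sequence wrapping."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), _FASTA_WRAP):
                fh.write(rec.sequence[i : i + _FASTA_WRAP] + "\n")


def read_alignment_fasta(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA (rows may contain ``-``) into a MultipleAlignment."""
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace("U", "T"))
    return MultipleAlignment(ids=tuple(ids), rows=tuple(rows))


def write_alignment_fasta(aln: MultipleAlignment, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), _FASTA_WRAP):
                fh.write(row[i : i + _FASTA_WRAP] + "\n")


_TRUE_FLAGS = {"1", "true", "t", "yes", "y"}


def read_taxonomy_table(path: str | Path) -> dict[str, tuple[tuple[str, ...], bool]]:
    """Read a taxonomy TSV: ``id <TAB> domain;...;genus [<TAB> type_strain_flag]``.

    Lines starting with ``#`` are skipped.  A missing flag column defaults to
    ``False``.  Rank paths deeper than genus are truncated to six ranks.
    """
    out: dict[str, tuple[tuple[str, ...], bool]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
            sid = parts[0].strip()
            ranks = tuple(r.strip() for r in parts[1].split(";"))[:N_RANKS]
            flag = len(parts) > 2 and parts[2].strip().lower() in _TRUE_FLAGS
            out[sid] = (ranks, flag)
    return out


def write_taxonomy_table(records: Iterable[ReferenceSequence], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#id\ttaxonomy\ttype_strain\n")
        for rec in records:
            fh.write(
                f"{rec.id}\t{';'.join(rec.taxonomy)}\t{1 if rec.is_type_strain else 0}\n"
            )


def attach_taxonomy(
    records: Sequence[ReferenceSequence],
    taxonomy: Mapping[str, tuple[tuple[str, ...], bool]],
) -> list[ReferenceSequence]:
    """Join FASTA records with a taxonomy table by id.

    Raises if any record id is absent from the table, listing every unmatched
    id so the input mismatch can be fixed in one pass.
    """
    missing = [rec.id for rec in records if rec.id not in taxonomy]
    if missing:
        raise KeyError(
            "ids missing from taxonomy table: " + ", ".join(sorted(missing))
        )
    out = []
    for rec in records:
        ranks, flag = taxonomy[rec.id]
        out.append(replace(rec, taxonomy=ranks, is_type_strain=flag))
    return out


def read_primer_table(path: str | Path):
    """Read a primer-pair TSV: ``pair_id fwd_name fwd_seq rev_name rev_seq``.

    Primer sequences are validated over the IUPAC alphabet; names following
    the standardized ``S-D-Bact-<pos>-<variant>-<S|A>-<len>`` nomenclature get
    positional metadata parsed, other names are accepted without it.
    Returns a list of :class:`hcbprimer.primers.PrimerPair`.
    """
    from .primers import PrimerPair  # local import: primers depends on core_io types

    pairs = []
    seen: set[str] = set()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-separated columns")
            pair_id, fwd_name, fwd_seq, rev_name, rev_seq = parts[:5]
            if pair_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pair_id {pair_id!r}")
            seen.add(pair_id)
            try:
                pairs.append(
                    PrimerPair.from_sequences(pair_id, fwd_name, fwd_seq, rev_name, rev_seq)
                )
            except ValueError as exc:
                raise ValueError(f"primer pair {pair_id!r}: {exc}") from exc
    return pairs
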