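"""Reading, writing and normalizing the sequence formats used by every stage.

FASTA and Clustal parsing are delegated to Biopython; this module adds the
validation the pipeline relies on (unique ids, declared molecule types,
equal-length alignment rows) and the DNA->RNA normalization used before
UTR scanning.

Coordinates are 0-based half-open everywhere inside the package; report
writers convert to 1-based inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import AlignIO, SeqIO

from ptbscan.errors import AlignmentError, FormatError, MoltypeError

Moltype = Literal["nucleotide", "protein"]

GAP = "-"

#: IUPAC nucleotide codes (RNA + DNA + ambiguity).
NT_ALPHABET = frozenset("ACGUTNRYSWKMBDHV")
#: The 20 amino acids plus X (unknown) and * (stop, tolerated on input).
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

#: Unambiguous pyrimidine bases in either RNA or DNA spelling.
PYRIMIDINES = frozenset("CUT")


@dataclass(frozen=True)
class SeqRecord:
    """A single sequence with a declared molecule type.

    Residues are always stored uppercase.  ``id`` is the accession or gene
    identifier; ``description`` is the free-text remainder of the header.
    """

    id: str
    residues: str
    moltype: Moltype = "nucleotide"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        alphabet = NT_ALPHABET if self.moltype == "nucleotide" else AA_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise FormatError(
                f"record {self.id!r}: residues {sorted(bad)} not valid for moltype {self.moltype}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """An ordered multiple sequence alignment with gap character '-'.

    All rows have equal length; ``gap_only_columns`` flags columns that are
    gaps in every row (permitted but usually the sign of an editing artefact).
    """

    records: tuple[SeqRecord, ...]
    gapped: tuple[str, ...]  # gapped row strings, parallel to records

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        lengths = {len(g) for g in self.gapped}
        if len(lengths) != 1:
            ragged = [r.id for r, g in zip(self.records, self.gapped) if len(g) != len(self.gapped[0])]
            raise AlignmentError(f"ragged alignment rows: {ragged}")

    @property
    def length(self) -> int:
        return len(self.gapped[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def row(self, seq_id: str) -> str:
        for r, g in zip(self.records, self.gapped):
            if r.id == seq_id:
                return g
        raise AlignmentError(f"id {seq_id!r} not in alignment")

    @property
    def gap_only_columns(self) -> list[int]:
        return [j for j in range(self.length) if all(g[j] == GAP for g in self.gapped)]


def _check_unique_ids(ids: Iterable[str]) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate sequence id {i!r}")
        seen.add(i)


def guess_moltype(residues: str) -> Moltype:
    """Guess nucleotide vs protein from residue content (ACGTUN-dominated -> nucleotide)."""
    letters = [c for c in residues.upper() if c != GAP]
    if not letters:
        return "nucleotide"
    nt = sum(c in "ACGTUN" for c in letters)
    return "nucleotide" if nt / len(letters) >= 0.95 else "protein"


def read_fasta(path: str | Path, moltype: Moltype | None = None) -> list[SeqRecord]:
    """Read a (possibly wrapped, CRLF-tolerant) multi-record FASTA file.

    ``moltype=None`` guesses per record from residue content.  Raises
    :class:`FormatError` on an empty file or duplicate ids.
    """
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise FormatError(f"{path}: no FASTA records found")
    records = []
    for rec in raw:
        residues = str(rec.seq).upper().replace(".", GAP)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        mt = moltype or guess_moltype(residues)
        records.append(SeqRecord(id=rec.id, residues=residues, moltype=mt, description=desc))
    _check_unique_ids(r.id for r in records)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def normalize_nt(record: SeqRecord) -> SeqRecord:
    """Unify DNA/RNA spelling for UTR scanning: uppercase, T -> U.

    Idempotent and length-preserving.  Protein input raises
    :class:`MoltypeError`.
    """
    if record.moltype != "nucleotide":
        raise MoltypeError(f"normalize_nt expects a nucleotide record, got protein {record.id!r}")
    return SeqRecord(
        id=record.id,
        residues=record.residues.replace("T", "U"),
        moltype="nucleotide",
        description=record.description,
    )


def read_alignment(path: str | Path, dialect: Literal["fasta", "clustal"] = "fasta",
                   moltype: Moltype | None = None) -> Alignment:
    """Read an aligned FASTA or Clustal file into an :class:`Alignment`.

    '.' gaps are converted to '-'.  Ragged FASTA input raises
    :class:`AlignmentError` naming the offending ids.
    """
    path = Path(path)
    if dialect == "fasta":
        raw = list(SeqIO.parse(str(path), "fasta"))
        if not raw:
            raise FormatError(f"{path}: no records found")
        rows = [(rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in raw]
        ref_len = len(rows[0][1])
        ragged = [rid for rid, g in rows if len(g) != ref_len]
        if ragged:
            raise AlignmentError(f"{path}: rows differ in length; offending ids: {ragged}")
    elif dialect == "clustal":
        try:
            msa = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise FormatError(f"{path}: not a Clustal alignment ({exc})") from exc
        rows = [(rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in msa]
    else:
        raise FormatError(f"unknown alignment dialect {dialect!r}")
    _check_unique_ids(rid for rid, _ in rows)
    records = []
    for rid, g in rows:
        ungapped = g.replace(GAP, "")
        mt = moltype or guess_moltype(g)
        records.append(SeqRecord(id=rid, residues=ungapped if ungapped else "N", moltype=mt))
    return Alignment(records=tuple(records), gapped=tuple(g for _, g in rows))


def write_alignment(alignment: Alignment, path: str | Path,
                    dialect: Literal["fasta", "clustal"] = "fasta") -> None:
    """Serialize an alignment as aligned FASTA or Clustal."""
    path = Path(path)
    if dialect == "fasta":
        with path.open("w") as fh:
            for rec, g in zip(alignment.records, alignment.gapped):
                fh.write(f">{rec.id}\n{g}\n")
        return
    if dialect != "clustal":
        raise FormatError(f"unknown alignment dialect {dialect!r}")
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord as BioSeqRecord

    msa = MultipleSeqAlignment(
        [BioSeqRecord(Seq(g), id=rec.id, description="") for rec, g in zip(alignment.records, alignment.gapped)]
    )
    with path.open("w") as fh:
        AlignIO.write(msa, fh, "clustal")


def alignment_from_strings(pairs: Iterable[tuple[str, str]], moltype: Moltype | None = None) -> Alignment:
    """Build an :class:`Alignment` from (id, gapped-row) pairs (test/synthetic helper)."""
    buf = io.StringIO()
    for rid, g in pairs:
        buf.write(f">{rid}\n{g}\n")
    buf.seek(0)
    raw = list(SeqIO.parse(buf, "fasta"))
    rows = [(rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in raw]
    _check_unique_ids(rid for rid, _ in rows)
    records = []
    for rid, g in rows:
        ungapped = g.replace(GAP, "")
        mt = moltype or guess_moltype(g)
        records.append(SeqRecord(id=rid, residues=ungapped if ungapped else "N", moltype=mt))
    return Alignment(records=tuple(records), gapped=tuple(g for _, g in rows))
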