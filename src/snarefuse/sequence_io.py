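"""FASTA protein sequence I/O and PSI-BLAST ASCII PSSM parsing.

Sequences are canonicalized onto the 20-letter amino-acid alphabet in
PSI-BLAST column order (``ARNDCQEGHILKMFPSTWYV``) plus the mask symbol
``X``.  Ambiguity/rare codes (B, Z, U, O, J) are mapped to ``X`` rather
than dropped so that sequence positions stay aligned with PSSM rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical residue ordering (PSI-BLAST PSSM column order), index 0..19.
CANONICAL_ORDER = "ARNDCQEGHILKMFPSTWYV"
#: Mask symbol for ambiguous / non-standard residues, code 20.
MASK = "X"
ALPHABET = CANONICAL_ORDER + MASK
#: Codes remapped to the mask symbol during canonicalization.
_AMBIGUOUS = set("BZUOJX")
#: All letters accepted before canonicalization (IUPAC one-letter amino acids).
_ACCEPTED = set(CANONICAL_ORDER) | _AMBIGUOUS

RESIDUE_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


class PssmFormatError(ValueError):
    """Raised for malformed PSI-BLAST ASCII PSSM input."""


def canonicalize(residues: str, *, record_id: str = "<sequence>") -> str:
    """Uppercase and map non-standard letters (B/Z/U/O/J) to ``X``.

    Idempotent.  Raises :class:`FastaFormatError` naming the record and the
    offending character when a letter outside the IUPAC amino-acid set is
    encountered.
    """
    up = residues.upper()
    out = []
    for ch in up:
        if ch in _AMBIGUOUS:
            out.append(MASK)
        elif ch in _ACCEPTED:
            out.append(ch)
        else:
            raise FastaFormatError(
                f"record {record_id!r}: invalid residue character {ch!r}"
            )
    return "".join(out)


@dataclass
class ProteinSequence:
    """One protein sequence: identifier, residue string, optional label.

    ``label`` is 1 for SNARE, 0 for non-SNARE, ``None`` if unknown.
    """

    id: str
    residues: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        self.residues = canonicalize(self.residues, record_id=self.id)
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PSSMatrix:
    """Position-specific scoring matrix: M rows x 20 canonical columns."""

    sequence_id: str
    scores: np.ndarray
    residue_column_order: str = CANONICAL_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.sequence_id!r} must be M x 20, "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"PSSM for {self.sequence_id!r} has no rows")

    @property
    def m(self) -> int:
        return self.scores.shape[0]


def read_fasta(path, label: Optional[int] = None) -> list[ProteinSequence]:
    """Read a FASTA file into canonicalized :class:`ProteinSequence` records.

    ``label``, if given, is applied to every record.  Input order is
    preserved.  An empty file or a record with an empty body is a
    :class:`FastaFormatError`.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            body = str(rec.seq)
            if not body:
                raise FastaFormatError(f"record {rec.id!r}: empty sequence body")
            records.append(ProteinSequence(id=rec.id, residues=body, label=label))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[ProteinSequence], path) -> Path:
    """Write records as FASTA (60-column wrap); round-trips with read_fasta."""
    if not records:
        raise ValueError("cannot write an empty record list")
    path = Path(path)
    seqs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        # SeqIO's fasta writer wraps at 60 columns.
        SeqIO.write(seqs, fh, "fasta")
    return path


def read_label_table(path) -> dict[str, int]:
    """Read a two-column TSV (id, label in {0,1}) into a dict."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label'")
            if parts[0] == "id" and lineno == 1:
                continue
            try:
                lab = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: label not an integer") from exc
            if lab not in (0, 1):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1")
            labels[parts[0]] = lab
    return labels


def apply_labels(
    records: Iterable[ProteinSequence], labels: dict[str, int]
) -> list[ProteinSequence]:
    """Return records with labels attached from an id->label mapping."""
    out = []
    for rec in records:
        if rec.id not in labels:
            raise KeyError(f"no label for record {rec.id!r}")
        out.append(ProteinSequence(rec.id, rec.residues, labels[rec.id]))
    return out


_FLOAT_RE = re.compile(r"^[+-]?\d+(\.\d+)?$")


def parse_psiblast_pssm(path, sequence_id: Optional[str] = None) -> PSSMatrix:
    """Parse a PSI-BLAST ASCII PSSM file into a :class:`PSSMatrix`.

    The classic layout has two header lines (the second naming 40 residue
    columns), then one row per sequence position::

        <pos> <residue> <20 log-odds ints> <20 percentages> <info> <weight>

    Only the FIRST 20 numeric columns (the log-odds block) are kept; the
    file's stated column order is mapped onto the canonical A..V ordering.
    Rows with fewer than 20 numeric score fields raise
    :class:`PssmFormatError` naming the row.
    """
    path = Path(path)
    column_order: Optional[list[str]] = None
    rows: list[list[float]] = []
    residues: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            parts = raw.split()
            if not parts:
                continue
            # Header naming the score columns: 20 (or 40) residue letters.
            if column_order is None and all(
                len(p) == 1 and p.isalpha() for p in parts
            ) and len(parts) >= 20:
                column_order = [p.upper() for p in parts[:20]]
                continue
            # Position rows start "<int> <letter> ...".
            if len(parts) >= 2 and parts[0].isdigit() and len(parts[1]) == 1 \
                    and parts[1].isalpha():
                res = parts[1].upper()
                if res not in _ACCEPTED:
                    raise PssmFormatError(
                        f"{path}:{lineno}: residue letter {res!r} outside the "
                        "amino-acid alphabet"
                    )
                numeric = [p for p in parts[2:] if _FLOAT_RE.match(p)]
                if len(numeric) < 20:
                    raise PssmFormatError(
                        f"{path}:{lineno}: position row has "
                        f"{len(numeric)} numeric score fields, need 20"
                    )
                rows.append([float(v) for v in numeric[:20]])
                residues.append(res)

    if not rows:
        raise PssmFormatError(f"{path}: no PSSM position rows found")

    scores = np.asarray(rows, dtype=float)
    if column_order is not None:
        if sorted(column_order) != sorted(CANONICAL_ORDER):
            raise PssmFormatError(
                f"{path}: score column header does not name the 20 standard "
                "amino acids"
            )
        perm = [column_order.index(aa) for aa in CANONICAL_ORDER]
        scores = scores[:, perm]

    return PSSMatrix(
        sequence_id=sequence_id or path.stem,
        scores=scores,
    )
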