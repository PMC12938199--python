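"""Readers and writers for the external formats the pipeline touches.

Protein and coding sequences come in as FASTA, per-protein evolutionary
profiles as PSI-BLAST ASCII PSSM files (the ``-out_ascii_pssm`` dialect),
labeled protein pairs and subcellular-localization annotations as
tab-separated tables.  Sequence positions are 1-based in every formula of
the feature layer and 0-based in storage; conversions live in the feature
modules, never here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 proteinogenic residues in fixed alphabetical order.  Every
#: residue-indexed feature block uses this ordering.
AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: The 4 nucleotides in fixed lexicographic order (coding strand).
NUCLEOTIDE_ALPHABET = "ACGT"

#: Labels accepted in pair tables.
LABEL_POSITIVE = 1
LABEL_NEGATIVE = 0
LABEL_UNKNOWN = "unknown"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in AMINO_ALPHABET:
                raise FormatError(
                    f"protein {self.id!r}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneRecord:
    """A coding (CDS) nucleotide sequence over ACGT."""

    id: str
    nucleotides: str

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise FormatError(f"gene {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.nucleotides, start=1):
            if ch not in NUCLEOTIDE_ALPHABET:
                raise FormatError(
                    f"gene {self.id!r}: invalid nucleotide {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass
class Pssm:
    """An L x 20 position-specific scoring matrix of raw log-odds scores.

    ``column_order`` records the residue ordering of the 20 score columns as
    found in the source file; :func:`ppigray.protein_features.evolution_features`
    reindexes to :data:`AMINO_ALPHABET` order.
    """

    protein_id: str
    scores: np.ndarray
    column_order: str = AMINO_ALPHABET

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise FormatError(
                f"PSSM {self.protein_id!r}: expected L x 20 scores, "
                f"got shape {self.scores.shape}"
            )
        if sorted(self.column_order) != sorted(AMINO_ALPHABET):
            raise FormatError(
                f"PSSM {self.protein_id!r}: column order is not a permutation "
                "of the 20 residues"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def in_alphabet_order(self) -> np.ndarray:
        """Scores with columns permuted to :data:`AMINO_ALPHABET` order."""
        perm = [self.column_order.index(r) for r in AMINO_ALPHABET]
        return self.scores[:, perm]


@dataclass(frozen=True)
class Pair:
    id_a: str
    id_b: str
    label: object  # 1, 0 or "unknown"


PairTable = list  # list[Pair]


@dataclass
class LocalizationTable:
    """Mapping from protein id to its set of subcellular compartments."""

    compartments: dict = field(default_factory=dict)

    def __getitem__(self, protein_id: str) -> frozenset:
        return self.compartments[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.compartments

    def __len__(self) -> int:
        return len(self.compartments)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: str = AMINO_ALPHABET) -> list:
    """Read a FASTA file, validating every character against ``alphabet``.

    Lower-case letters are accepted and upper-cased.  Returns
    :class:`ProteinRecord` or :class:`GeneRecord` objects depending on the
    alphabet.  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    cls = ProteinRecord if alphabet == AMINO_ALPHABET else GeneRecord
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if cls is ProteinRecord:
            records.append(ProteinRecord(id=rec.id, residues=seq))
        else:
            records.append(GeneRecord(id=rec.id, nucleotides=seq))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(path, records: Iterable) -> None:
    seqrecords = []
    for rec in records:
        seq = rec.residues if isinstance(rec, ProteinRecord) else rec.nucleotides
        seqrecords.append(SeqRecord(Seq(seq), id=rec.id, description=""))
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_ascii_pssm(path, protein_id: str | None = None) -> Pssm:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first 20-column block (log-odds scores) is kept; the second
    block of weighted observed percentages and the trailing statistics are
    skipped.  The residue-order header line determines ``column_order``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if protein_id is None:
        protein_id = path.stem

    # locate the residue-order line: 40 single-letter fields (two blocks)
    # or 20 for score-only files
    header_idx = None
    column_order = None
    for i, line in enumerate(lines):
        fields = line.split()
        if len(fields) in (20, 40) and all(
            len(f) == 1 and f in AMINO_ALPHABET for f in fields
        ):
            header_idx = i
            column_order = "".join(fields[:20])
            break
    if header_idx is None:
        raise FormatError(f"{path}: residue-order line missing")

    rows = []
    expected_pos = 0
    for line in lines[header_idx + 1:]:
        stripped = line.strip()
        if not stripped:
            break  # blank line ends the matrix block
        fields = stripped.split()
        if not fields[0].isdigit():
            break  # trailing K/Lambda statistics
        expected_pos += 1
        numeric = fields[2:]  # drop position and residue letter
        if len(numeric) not in (20, 40, 42):
            raise FormatError(
                f"{path}: row {expected_pos} has {len(numeric)} numeric fields, "
                "expected 40 (or 20 score-only)"
            )
        try:
            rows.append([float(x) for x in numeric[:20]])
        except ValueError as exc:
            raise FormatError(f"{path}: row {expected_pos}: {exc}") from exc
    if not rows:
        raise FormatError(f"{path}: no score rows found")
    return Pssm(protein_id=protein_id, scores=np.array(rows), column_order=column_order)


def write_ascii_pssm(path, pssm: Pssm, residues: str | None = None) -> None:
    """Write a PSSM in the ASCII dialect :func:`read_ascii_pssm` accepts.

    Used by the synthetic-fixture layer; emits the score block twice (the
    second block stands in for the percentage block) plus the two header
    lines and trailing statistics of the real format.
    """
    path = Path(path)
    letters = " ".join(pssm.column_order)
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted, and gapped",
        f"            {letters}   {letters}",
    ]
    if residues is None:
        residues = "A" * pssm.length
    for i in range(pssm.length):
        row = pssm.scores[i]
        cells = "".join(f"{v:7.0f}" if float(v).is_integer() else f"{v:7.2f}" for v in row)
        pct = "".join(f"{abs(v) * 2:7.0f}" for v in row)
        out.append(f"{i + 1:5d} {residues[i]} {cells} {pct}   0.36   0.09")
    out.append("")
    out.append("                      K         Lambda")
    out.append("Standard Ungapped    0.1337     0.3176")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Pair tables


def _parse_label(token: str):
    token = token.strip()
    if token == "1":
        return LABEL_POSITIVE
    if token == "0":
        return LABEL_NEGATIVE
    if token.lower() == "unknown":
        return LABEL_UNKNOWN
    raise FormatError(f"unknown pair label {token!r} (expected 1, 0 or 'unknown')")


def read_pairs(path) -> list:
    """Read a tab-separated (id_a, id_b, label) table; header row optional."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns"
                )
            if lineno == 1 and fields[2].strip().lower() in ("label", "interaction"):
                continue
            pairs.append(Pair(fields[0], fields[1], _parse_label(fields[2])))
    return pairs


def write_pairs(path, pairs: Sequence[Pair]) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")


# ---------------------------------------------------------------------------
# Localization tables


def read_localizations(path) -> LocalizationTable:
    """Read a tab-separated (protein_id, compartments) table.

    Compartment names are semicolon-joined in the second column; every
    retained protein must have at least one compartment.
    """
    table: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            comps = frozenset(c.strip() for c in fields[1].split(";") if c.strip())
            if not comps:
                raise FormatError(
                    f"{path}: line {lineno}: protein {fields[0]!r} has no compartments"
                )
            table[fields[0]] = comps
    return LocalizationTable(table)


def write_localizations(path, table: LocalizationTable) -> None:
    with open(path, "w") as fh:
        for pid, comps in table.compartments.items():
            fh.write(f"{pid}\t{';'.join(sorted(comps))}\n")
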