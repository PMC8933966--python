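"""Sequence input/output, identifier sanitization, translation and provenance.

FASTA records are held in a small :class:`SequenceRecord` container rather
than Biopython's ``SeqRecord`` so that downstream modules can rely on a fixed,
validated shape (non-empty id without whitespace, uppercase residues, explicit
molecule type). Biopython does the actual FASTA parsing and writing.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "SequenceRecord",
    "NameMap",
    "read_fasta",
    "write_fasta",
    "clean_names",
    "detect_moltype",
    "translate_cds",
    "file_checksum",
]

_NUCLEOTIDE_CHARS = set("ACGTUN")

#: Characters with syntactic meaning in Newick, plus whitespace. These are the
#: characters that break leaf labels in downstream tree files and are replaced
#: by '_' during name cleaning.
FORBIDDEN_NAME_CHARS = set(" \t;:(),[]'\"")

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_CODON_MAP = dict(_STANDARD_TABLE.forward_table)
_CODON_MAP.update({c: "*" for c in _STANDARD_TABLE.stop_codons})


@dataclass(frozen=True)
class SequenceRecord:
    """One named peptide or nucleotide sequence.

    Attributes
    ----------
    id : str
        Non-empty identifier token (no internal whitespace after cleaning).
    description : str
        Free text after the first whitespace of the FASTA header; may be "".
    residues : str
        Uppercase residues; amino acids (incl. X and *) or nucleotides (incl. N).
    moltype : str
        Either ``"peptide"`` or ``"nucleotide"``.
    """

    id: str
    residues: str
    description: str = ""
    moltype: str = "peptide"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        if self.moltype not in ("peptide", "nucleotide"):
            raise ValueError(f"unknown moltype {self.moltype!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class NameMap:
    """Bijective mapping original id -> cleaned id, written to the report."""

    forward: dict[str, str] = field(default_factory=dict)

    def add(self, original: str, cleaned: str) -> None:
        self.forward[original] = cleaned

    def original(self, cleaned: str) -> str:
        for orig, cl in self.forward.items():
            if cl == cleaned:
                return orig
        raise KeyError(cleaned)

    def items(self):
        return self.forward.items()

    def __len__(self) -> int:
        return len(self.forward)


def detect_moltype(residues: str) -> str:
    """Classify residues as nucleotide if >=90% are in {A,C,G,T,U,N}."""
    seq = residues.upper()
    if not seq:
        raise ValueError("empty sequence")
    frac = sum(1 for c in seq if c in _NUCLEOTIDE_CHARS) / len(seq)
    return "nucleotide" if frac >= 0.9 else "peptide"


def read_fasta(path: str | Path, moltype: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into an ordered list of :class:`SequenceRecord`.

    Multi-line bodies are concatenated and residues uppercased. The molecule
    type is auto-detected per record unless ``moltype`` is forced.

    Raises
    ------
    ValueError
        If the file is empty / contains no FASTA header, or if duplicate
        sequence identifiers are present (both name the offending file/ids).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace("-", "")
        # rec.description starts with the id token; strip it off
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        mt = moltype or detect_moltype(residues)
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc, moltype=mt))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"duplicate sequence ids in {path}: {', '.join(dups)}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as multi-line FASTA (fixed wrap width for reproducibility)."""
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i:i + width] + "\n")


def clean_name(name: str) -> str:
    """Replace characters that interfere with Newick/tree tools by '_'."""
    return "".join("_" if c in FORBIDDEN_NAME_CHARS else c for c in name)


def clean_names(records: Sequence[SequenceRecord]) -> tuple[list[SequenceRecord], NameMap]:
    """Sanitize record ids for tree software; resolve collisions with suffixes.

    Every forbidden character (whitespace and Newick-syntax characters) is
    replaced by '_'. If two distinct input ids collide after cleaning, the
    second receives suffix '_2', the third '_3', and so on. Idempotent on
    already-clean id sets.
    """
    name_map = NameMap()
    cleaned_records: list[SequenceRecord] = []
    used: set[str] = set()
    for rec in records:
        base = clean_name(rec.id)
        candidate = base
        k = 2
        while candidate in used:
            candidate = f"{base}_{k}"
            k += 1
        used.add(candidate)
        name_map.add(rec.id, candidate)
        cleaned_records.append(replace(rec, id=candidate))
    return cleaned_records, name_map


def translate_cds(record: SequenceRecord) -> SequenceRecord | None:
    """Translate a coding sequence (frame +1, standard genetic code).

    Trailing bases (length mod 3) are dropped; a single terminal stop is
    removed; internal stops stay '*'; any codon containing an ambiguous base
    becomes 'X'. Returns ``None`` when the resulting peptide is empty (the
    caller logs a warning and skips the record).
    """
    if record.moltype != "nucleotide":
        raise ValueError(f"translate_cds requires a nucleotide record, got {record.id!r}")
    seq = record.residues.replace("U", "T")
    seq = seq[: len(seq) - (len(seq) % 3)]
    peptide = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        peptide.append(_CODON_MAP.get(codon, "X"))
    if peptide and peptide[-1] == "*":
        peptide.pop()
    pep = "".join(peptide)
    if not pep:
        return None
    return SequenceRecord(id=record.id, residues=pep, description=record.description, moltype="peptide")


def file_checksum(path: str | Path) -> str:
    """MD5 hex digest of a file's raw bytes, for provenance logging."""
    path = Path(path)
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
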