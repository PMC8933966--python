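"""Bait collection and annotated reference set handling.

The classifier needs a bait collection with every sequence labeled ingroup
(bona fide MYB) or outgroup (MYB-like non-MYB such as CDC5). The optional
reference set carries functional annotations (e.g. the well characterized
A. thaliana MYB panel) used for ortholog assignment.

``harvest_outgroup`` is the utility used to build outgroup candidates for a
new bait collection: all proteome sequences hitting the MYB baits with a bit
score of at least 100, stripped of known bona fide MYBs, are returned for
manual curation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .candidate_search import run_search
from .sequence_io import SequenceRecord, read_fasta

__all__ = ["BaitCollection", "ReferenceSet", "load_baits", "load_reference", "harvest_outgroup"]

_INGROUP_TOKENS = {"in", "ingroup"}
_OUTGROUP_TOKENS = {"out", "outgroup"}


@dataclass
class BaitCollection:
    """Bait records plus per-id ingroup/outgroup labels."""

    records: list[SequenceRecord]
    labels: dict[str, str]  # id -> "ingroup" | "outgroup"

    def __post_init__(self) -> None:
        ids = {r.id for r in self.records}
        if ids != set(self.labels):
            raise ValueError("bait records and labels must cover the same ids")
        n_in = sum(1 for v in self.labels.values() if v == "ingroup")
        n_out = len(self.labels) - n_in
        if n_in < 1 or n_out < 1:
            raise ValueError(
                "bait collection needs at least one ingroup and one outgroup sequence "
                f"(got {n_in} ingroup, {n_out} outgroup)")

    @property
    def ingroup_ids(self) -> set[str]:
        return {i for i, l in self.labels.items() if l == "ingroup"}

    @property
    def outgroup_ids(self) -> set[str]:
        return {i for i, l in self.labels.items() if l == "outgroup"}


@dataclass
class ReferenceSet:
    """Functionally annotated reference sequences for ortholog assignment."""

    records: list[SequenceRecord]
    annotation: dict[str, dict[str, str]] = field(default_factory=dict)
    # annotation[id] = {"name": ..., "function": ..., "subgroup": ...}

    def __post_init__(self) -> None:
        missing = sorted({r.id for r in self.records} - set(self.annotation))
        if missing:
            raise ValueError(f"reference sequences without annotation: {', '.join(missing)}")

    def annotation_text(self, ref_id: str) -> str:
        ann = self.annotation.get(ref_id, {})
        parts = [ann.get("name", ""), ann.get("function", "")]
        if ann.get("subgroup"):
            parts.append(ann["subgroup"])
        return "; ".join(p for p in parts if p)


def _parse_label(token: str) -> str:
    t = token.strip().lower()
    if t in _INGROUP_TOKENS:
        return "ingroup"
    if t in _OUTGROUP_TOKENS:
        return "outgroup"
    raise ValueError(f"unknown bait label {token!r} (expected in/ingroup or out/outgroup)")


def load_baits(fasta_path: str | Path, info_path: str | Path) -> BaitCollection:
    """Load the bait FASTA and its two-column (id, label) info table.

    The info table is whitespace- or tab-separated; '#' starts a comment;
    labels are case-insensitive "in"/"ingroup"/"out"/"outgroup". Every bait
    sequence must have exactly one label and vice versa.
    """
    records = read_fasta(fasta_path, moltype="peptide")
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(info_path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{info_path}:{lineno}: expected two columns (id, label)")
        labels[parts[0]] = _parse_label(parts[1])
    seq_ids = {r.id for r in records}
    unlabeled = sorted(seq_ids - set(labels))
    orphans = sorted(set(labels) - seq_ids)
    if unlabeled or orphans:
        msgs = []
        if unlabeled:
            msgs.append(f"bait sequences without label: {', '.join(unlabeled)}")
        if orphans:
            msgs.append(f"labels without bait sequence: {', '.join(orphans)}")
        raise ValueError("; ".join(msgs))
    return BaitCollection(records=records, labels=labels)


def load_reference(fasta_path: str | Path, info_path: str | Path) -> ReferenceSet:
    """Load reference FASTA plus tab-separated annotation (id, name, function[, subgroup])."""
    records = read_fasta(fasta_path, moltype="peptide")
    annotation: dict[str, dict[str, str]] = {}
    for lineno, line in enumerate(Path(info_path).read_text().splitlines(), 1):
        raw = line.rstrip("\n")
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{info_path}:{lineno}: expected >=3 tab-separated columns "
                             "(id, name, function[, subgroup])")
        annotation[parts[0]] = {
            "name": parts[1],
            "function": parts[2],
            "subgroup": parts[3] if len(parts) > 3 else "",
        }
    return ReferenceSet(records=records, annotation=annotation)


def harvest_outgroup(bait_myb_seqs: Sequence[SequenceRecord],
                     proteome: Sequence[SequenceRecord],
                     known_mybs: Iterable[str],
                     min_score: float = 100.0,
                     engine: str = "builtin") -> set[str]:
    """Collect outgroup candidates from a proteome.

    Returns ids of proteome sequences with any similarity-search bit score of
    at least ``min_score`` against the MYB baits, minus ``known_mybs``. These
    MYB-like sequences are intended for manual curation before joining a bait
    collection as outgroup.
    """
    known = set(known_mybs)
    if not proteome:
        warnings.warn("harvest_outgroup: empty proteome, returning no candidates")
        return set()
    hits = run_search(bait_myb_seqs, proteome, engine=engine)
    return {h.subject_id for h in hits if h.bit_score >= min_score} - known
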