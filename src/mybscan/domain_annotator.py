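"""MYB repeat detection and repeat-based classification.

A MYB repeat is ~50-53 residues forming three alpha-helices whose structural
core is held by three regularly spaced tryptophans (the first tryptophan of
the R3 repeat is frequently replaced by another hydrophobic residue). The
default motifs encode exactly that spacing pattern as regular expressions and
are configurable, so users can substitute their own patterns:

* R2-like: ``W.{18,22}W.{18,22}W``
* R3-like: ``[FILMW].{17,21}W.{17,21}W``

Repeats found in a peptide are grouped into runs of consecutive repeats
(inter-repeat linker <= 15 residues by default) and the run composition gives
the classical repeat class: R2R3 (the dominant plant class), 3R, 4R, a single
isolated repeat (1R), or none.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "RepeatMatch",
    "DEFAULT_MOTIFS",
    "compile_motifs",
    "detect_repeats",
    "classify_repeats",
]

R2_LIKE = "R2-like"
R3_LIKE = "R3-like"

#: Default repeat motifs; order gives matching priority at equal start positions.
DEFAULT_MOTIFS: dict[str, str] = {
    R2_LIKE: r"W.{18,22}W.{18,22}W",
    R3_LIKE: r"[FILMW].{17,21}W.{17,21}W",
}

CLASS_NONE = "none"
CLASS_1R = "1R"
CLASS_R2R3 = "R2R3"
CLASS_3R = "3R"
CLASS_4R = "4R"


@dataclass(frozen=True)
class RepeatMatch:
    """One located repeat: 0-based half-open coordinates on the peptide."""

    repeat_type: str
    start: int
    end: int
    matched_text: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("invalid repeat coordinates")


def compile_motifs(motifs: Mapping[str, str] | None = None) -> dict[str, re.Pattern]:
    """Compile motif patterns; invalid regex raises ValueError at startup."""
    motifs = dict(motifs) if motifs else dict(DEFAULT_MOTIFS)
    compiled: dict[str, re.Pattern] = {}
    for name, pattern in motifs.items():
        try:
            compiled[name] = re.compile(pattern)
        except re.error as exc:
            raise ValueError(f"invalid motif pattern for {name!r}: {exc}") from exc
    return compiled


def detect_repeats(peptide: str,
                   motif_config: Mapping[str, str] | None = None) -> list[RepeatMatch]:
    """Locate MYB repeats greedily and without overlap, returned in sequence
    order.

    Motifs are applied in config order with decreasing priority: the R2-like
    pattern (strict W initiator) is placed first across the whole peptide,
    then the looser R3-like pattern fills the regions the R2 scan left free.
    Without this priority, the R3 pattern's permissive [FILMW] initiator can
    anchor on a background residue just upstream of a genuine R2 repeat and
    swallow its tryptophan core.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    patterns = compile_motifs(motif_config)
    matches: list[RepeatMatch] = []
    covered: list[tuple[int, int]] = []
    for name, pattern in patterns.items():
        pos = 0
        while pos < len(peptide):
            m = pattern.search(peptide, pos)
            if m is None:
                break
            s, e = m.span()
            if any(s < ce and cs < e for cs, ce in covered):
                pos = s + 1  # overlaps a higher-priority repeat; try later starts
                continue
            matches.append(RepeatMatch(repeat_type=name, start=s, end=e,
                                       matched_text=m.group(0)))
            covered.append((s, e))
            pos = e
    matches.sort(key=lambda r: r.start)
    return matches


def classify_repeats(matches: Sequence[RepeatMatch], max_linker: int = 15) -> str:
    """Derive the repeat class from detected repeats.

    Repeats are grouped into maximal runs whose inter-repeat gap is at most
    ``max_linker`` residues. The longest run decides the class: a run of two
    with an R2-like repeat followed by an R3-like repeat is R2R3; runs of
    three / four (or more) are 3R / 4R; a lone repeat (or a two-repeat run of
    any other composition) counts as 1R; no repeats at all is 'none'.
    """
    if not matches:
        return CLASS_NONE
    runs: list[list[RepeatMatch]] = [[matches[0]]]
    for prev, cur in zip(matches, matches[1:]):
        gap = cur.start - prev.end
        if gap <= max_linker:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    best = max(runs, key=len)
    if len(best) >= 4:
        return CLASS_4R
    if len(best) == 3:
        return CLASS_3R
    if len(best) == 2:
        if best[0].repeat_type == R2_LIKE and best[1].repeat_type == R3_LIKE:
            return CLASS_R2R3
        return CLASS_1R
    return CLASS_1R


def write_domain_table(rows: Sequence[tuple[str, str, list[RepeatMatch]]], path) -> None:
    """Tab-separated domain table: id, repeat_class, n_repeats, coordinates."""
    with open(path, "w") as fh:
        fh.write("id\trepeat_class\tn_repeats\trepeat_coordinates\n")
        for sid, repeat_class, matches in rows:
            coords = ",".join(f"{m.repeat_type}:{m.start}-{m.end}" for m in matches)
            fh.write(f"{sid}\t{repeat_class}\t{len(matches)}\t{coords}\n")
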