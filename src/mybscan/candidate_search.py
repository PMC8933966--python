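"""Initial candidate identification by local similarity search.

Candidates are found by searching all subject sequences with the labeled bait
collection. Three engines are supported:

* ``builtin`` — Smith-Waterman local alignment (BLOSUM62, gap open 11 /
  extend 1) via Biopython's PairwiseAligner; no external binaries needed and
  fully deterministic.
* ``blast``   — external BLAST+ ``blastp`` (tabular output).
* ``hmmer``   — external HMMER: a profile HMM is built from the aligned baits
  and searched against the subjects; profile hits bypass the percent-
  similarity filter (their similarity is reported as 100).

The default filters keep hits with alignment length >= 50 residues and >= 80%
alignment similarity (BLAST "positives"), at most 100 hits per bait query.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import SequenceRecord, write_fasta

__all__ = ["SimilarityHit", "run_search", "filter_hits", "SearchError"]

# Karlin-Altschul parameters for gapped BLOSUM62 with gap open 11 / extend 1,
# used to convert raw Smith-Waterman scores of the built-in engine to bit
# scores comparable with BLAST's.
_KA_LAMBDA = 0.267
_KA_K = 0.041


class SearchError(RuntimeError):
    """Raised when a search engine is unavailable or fails."""


@dataclass(frozen=True)
class SimilarityHit:
    """One local alignment between a bait query and a subject sequence."""

    query_id: str
    subject_id: str
    percent_similarity: float  # 0-100, BLAST-style positives percentage
    alignment_length: int      # aligned columns, gaps included
    bit_score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not 0.0 <= self.percent_similarity <= 100.0:
            raise ValueError("percent_similarity must be in [0, 100]")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _builtin_hit(aligner: Align.PairwiseAligner, matrix, bait: SequenceRecord,
                 subject: SequenceRecord, search_space: float) -> SimilarityHit | None:
    # PairwiseAligner chokes on residues absent from BLOSUM62 ('U', 'O'...);
    # map anything exotic to X, which the matrix does carry.
    alphabet = set(str(matrix.alphabet))
    q = "".join(c if c in alphabet else "X" for c in bait.residues)
    s = "".join(c if c in alphabet else "X" for c in subject.residues)
    try:
        alignments = aligner.align(q, s)
        score = alignments.score
    except Exception:
        return None
    if score <= 0:
        return None
    aln = alignments[0]
    col_q, col_s = aln[0], aln[1]
    length = len(col_q)
    positives = 0
    for a, b in zip(col_q, col_s):
        if a != "-" and b != "-" and matrix[a, b] > 0:
            positives += 1
    bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0)
    evalue = search_space * 2.0 ** (-bits)
    return SimilarityHit(
        query_id=bait.id,
        subject_id=subject.id,
        percent_similarity=100.0 * positives / length,
        alignment_length=length,
        bit_score=bits,
        evalue=evalue,
    )


def _run_builtin(baits: Sequence[SequenceRecord],
                 subjects: Sequence[SequenceRecord]) -> list[SimilarityHit]:
    aligner = _make_aligner()
    matrix = aligner.substitution_matrix
    total_subject_len = float(sum(len(s) for s in subjects)) or 1.0
    hits: list[SimilarityHit] = []
    for bait in baits:
        space = len(bait) * total_subject_len
        for subject in subjects:
            hit = _builtin_hit(aligner, matrix, bait, subject, space)
            if hit is not None:
                hits.append(hit)
    return hits


def _require_exe(name: str, hint: str) -> str:
    path = shutil.which(name)
    if path is None:
        raise SearchError(f"required executable {name!r} not found on PATH; {hint}")
    return path


def _run_blast(baits: Sequence[SequenceRecord],
               subjects: Sequence[SequenceRecord],
               threads: int = 1) -> list[SimilarityHit]:
    _require_exe("makeblastdb", "install NCBI BLAST+ to use the blast engine")
    _require_exe("blastp", "install NCBI BLAST+ to use the blast engine")
    hits: list[SimilarityHit] = []
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        bait_fa, subj_fa = tmp / "baits.fasta", tmp / "subjects.fasta"
        write_fasta(baits, bait_fa)
        write_fasta(subjects, subj_fa)
        subprocess.run(
            ["makeblastdb", "-in", str(subj_fa), "-dbtype", "prot", "-out", str(tmp / "db")],
            check=True, capture_output=True,
        )
        out = tmp / "hits.tsv"
        subprocess.run(
            ["blastp", "-query", str(bait_fa), "-db", str(tmp / "db"), "-out", str(out),
             "-outfmt", "6 qseqid sseqid ppos length evalue bitscore",
             "-num_threads", str(threads)],
            check=True, capture_output=True,
        )
        for line in out.read_text().splitlines():
            if not line.strip():
                continue
            qid, sid, ppos, length, evalue, bits = line.split("\t")
            hits.append(SimilarityHit(
                query_id=qid, subject_id=sid,
                percent_similarity=float(ppos), alignment_length=int(length),
                bit_score=float(bits), evalue=float(evalue),
            ))
    return hits


def _run_hmmer(baits: Sequence[SequenceRecord],
               subjects: Sequence[SequenceRecord],
               threads: int = 1) -> list[SimilarityHit]:
    _require_exe("hmmbuild", "install HMMER to use the hmmer engine")
    _require_exe("hmmsearch", "install HMMER to use the hmmer engine")
    from .phylogeny_engine import align  # deferred: avoids import cycle

    msa = align(baits, backend="builtin")
    hits: list[SimilarityHit] = []
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        aln_fa = tmp / "baits_aln.fasta"
        with open(aln_fa, "w") as fh:
            for rid, row in msa.rows.items():
                fh.write(f">{rid}\n{row}\n")
        subj_fa = tmp / "subjects.fasta"
        write_fasta(subjects, subj_fa)
        hmm = tmp / "baits.hmm"
        subprocess.run(["hmmbuild", "-n", "bait_profile", str(hmm), str(aln_fa)],
                       check=True, capture_output=True)
        table = tmp / "domtbl.txt"
        subprocess.run(
            ["hmmsearch", "--domtblout", str(table), "--cpu", str(threads),
             str(hmm), str(subj_fa)],
            check=True, capture_output=True,
        )
        for line in table.read_text().splitlines():
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            sid = parts[0]
            evalue, bits = float(parts[12]), float(parts[13])  # per-domain
            env_from, env_to = int(parts[19]), int(parts[20])
            hits.append(SimilarityHit(
                query_id="bait_profile", subject_id=sid,
                percent_similarity=100.0,            # profile hits bypass the similarity filter
                alignment_length=env_to - env_from + 1,
                bit_score=bits, evalue=evalue,
            ))
    return hits


def run_search(baits: Sequence[SequenceRecord],
               subjects: Sequence[SequenceRecord],
               engine: str = "builtin",
               threads: int = 1) -> list[SimilarityHit]:
    """Search all subjects with all bait sequences.

    Parameters
    ----------
    engine : {"builtin", "blast", "hmmer"}
        ``builtin`` needs no external binaries; ``blast``/``hmmer`` shell out
        to BLAST+ / HMMER and raise :class:`SearchError` when missing.

    Returns an empty list when there are no subjects.
    """
    if not subjects:
        return []
    if engine == "builtin":
        return _run_builtin(baits, subjects)
    if engine == "blast":
        return _run_blast(baits, subjects, threads=threads)
    if engine == "hmmer":
        return _run_hmmer(baits, subjects, threads=threads)
    raise ValueError(f"unknown search engine {engine!r}")


def filter_hits(hits: Iterable[SimilarityHit],
                min_len: int = 50,
                min_sim: float = 80.0,
                max_hits_per_bait: int = 100) -> set[str]:
    """Apply the default candidate filters and return the candidate id set.

    Hits with ``alignment_length >= min_len`` and ``percent_similarity >=
    min_sim`` survive; per bait query at most ``max_hits_per_bait`` hits are
    kept, ranked by descending bit score (ties: lower e-value, then
    lexicographic subject id). The union of surviving subject ids is returned.
    """
    per_bait: dict[str, list[SimilarityHit]] = {}
    for hit in hits:
        if hit.alignment_length < min_len or hit.percent_similarity < min_sim:
            continue
        per_bait.setdefault(hit.query_id, []).append(hit)
    candidates: set[str] = set()
    for bait_id, bait_hits in per_bait.items():
        bait_hits.sort(key=lambda h: (-h.bit_score, h.evalue, h.subject_id))
        candidates.update(h.subject_id for h in bait_hits[:max_hits_per_bait])
    return candidates
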