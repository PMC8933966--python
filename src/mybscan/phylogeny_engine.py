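"""Multiple alignment and phylogenetic tree construction.

Production-scale runs use the external tools (MAFFT for alignment, FastTree
with ``-wag -nopr -nosupport`` or RAxML for trees). A deterministic built-in
backend — progressive multiple alignment (k-mer UPGMA guide tree, affine-gap
profile-profile merging) plus neighbour joining on p-distances
— makes the full pipeline runnable and testable with no external binaries and
removes the minor run-to-run variation that ML tree search can introduce.

Trees are exchanged as Newick; :class:`PhyloTree` wraps a dendropy tree and
adds the leaf-to-leaf path queries (edge counts, branch-length sums) the
classifier needs. Branch lengths missing from an input Newick default to 1.0
so edge counting works on length-free topologies.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

from .sequence_io import SequenceRecord

__all__ = [
    "MultipleAlignment",
    "PhyloTree",
    "PhylogenyError",
    "align",
    "build_tree",
    "neighbor_joining",
    "p_distance_matrix",
]


class PhylogenyError(RuntimeError):
    """Raised when an alignment/tree backend is missing or fails."""


# ---------------------------------------------------------------------------
# Multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class MultipleAlignment:
    """Gapped rows keyed by sequence id; all rows have equal length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, rid: str) -> str:
        return self.rows[rid].replace("-", "")


def _kmer_profile(seq: str, k: int = 3) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        prof[kmer] = prof.get(kmer, 0) + 1
    return prof


def _kmer_cosine(a: dict[str, int], b: dict[str, int]) -> float:
    shared = set(a) & set(b)
    num = sum(a[k] * b[k] for k in shared)
    na = sum(v * v for v in a.values()) ** 0.5
    nb = sum(v * v for v in b.values()) ** 0.5
    if na == 0 or nb == 0:
        return 0.0
    return num / (na * nb)


_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM.alphabet)          # 24 residues + B/Z/X/*
_GAP_INDEX = len(_ALPHABET)                # gap column scores 0 against anything
_CHAR_INDEX = {c: i for i, c in enumerate(_ALPHABET)}
_SCORES = np.zeros((_GAP_INDEX + 1, _GAP_INDEX + 1))
_SCORES[:_GAP_INDEX, :_GAP_INDEX] = np.asarray(_BLOSUM)


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    """Integer residue counts per column, shape (L, alphabet+gap).

    Counts (not floats) keep the profile independent of row order, so the
    progressive alignment is invariant under input permutations.
    """
    length = len(rows[0])
    counts = np.zeros((length, _GAP_INDEX + 1), dtype=np.int64)
    for row in rows:
        idx = np.fromiter((_CHAR_INDEX.get(c, _CHAR_INDEX["X"]) if c != "-" else _GAP_INDEX
                           for c in row), dtype=np.int64, count=length)
        np.add.at(counts, (np.arange(length), idx), 1)
    return counts


def _profile_align(counts_a: np.ndarray, counts_b: np.ndarray,
                   gap_open: float = -11.0, gap_extend: float = -1.0) -> list[str]:
    """Affine-gap global alignment of two profiles (sum-of-pairs scoring).

    Returns the column operations: 'M' consumes a column of both profiles,
    'X' one of A only, 'Y' one of B only. Ties prefer M, then X, then Y, so
    the traceback is deterministic.
    """
    fa = counts_a / counts_a.sum(axis=1, keepdims=True)
    fb = counts_b / counts_b.sum(axis=1, keepdims=True)
    S = fa @ _SCORES @ fb.T
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)   # gap columns in B (consume A)
    Y = np.full((n + 1, m + 1), NEG)   # gap columns in A (consume B)
    M[0, 0] = 0.0
    X[1:, 0] = gap_open + gap_extend * np.arange(n)
    Y[0, 1:] = gap_open + gap_extend * np.arange(m)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + S[i - 1]
        X[i, 1:] = np.maximum(M[i - 1, 1:] + gap_open, X[i - 1, 1:] + gap_extend)
        # affine within-row recursion for Y via a running maximum:
        # Y[i,j] = max_{k<j} max(M,X)[i,k] + open + ext*(j-k-1)
        base = np.maximum(M[i], X[i])
        t = base + gap_open - gap_extend * np.arange(m + 1)
        run = np.maximum.accumulate(t[:-1])
        Y[i, 1:] = run + gap_extend * np.arange(m)
    ops: list[str] = []
    i, j = n, m
    state = max(("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m]), key=lambda t: t[1])[0]
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            ops.append("M")
            prev = max(("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]),
                       ("Y", Y[i - 1, j - 1]), key=lambda t: t[1])[0]
            i, j, state = i - 1, j - 1, prev
        elif state == "X":
            ops.append("X")
            state = "M" if M[i - 1, j] + gap_open >= X[i - 1, j] + gap_extend - eps else "X"
            i -= 1
        else:
            ops.append("Y")
            came_m = max(M[i, j - 1], X[i, j - 1]) + gap_open
            state = "M" if came_m >= Y[i, j - 1] + gap_extend - eps else "Y"
            if state == "M" and X[i, j - 1] > M[i, j - 1]:
                state = "X"
            j -= 1
        if i == 0 and state == "M" and j > 0:
            state = "Y"
        if j == 0 and state == "M" and i > 0:
            state = "X"
    ops.reverse()
    return ops


def _merge_alignments(rows_a: dict[str, str], rows_b: dict[str, str],
                      ops: Sequence[str]) -> dict[str, str]:
    merged: dict[str, str] = {}
    for rid, row in rows_a.items():
        it = iter(row)
        merged[rid] = "".join(next(it) if op in ("M", "X") else "-" for op in ops)
    for rid, row in rows_b.items():
        it = iter(row)
        merged[rid] = "".join(next(it) if op in ("M", "Y") else "-" for op in ops)
    return merged


def _guide_order(records: Sequence[SequenceRecord]) -> list[tuple]:
    """UPGMA join order on k-mer cosine distances; ties break on the
    lexicographically smallest member label, so the order is independent of
    the input permutation. Returns a nested tuple tree of record indices."""
    n = len(records)
    profiles = [_kmer_profile(r.residues) for r in records]
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = 1.0 - _kmer_cosine(profiles[i], profiles[j])
    clusters: dict[int, tuple] = {i: (i,) for i in range(n)}
    rep: dict[int, str] = {i: records[i].id for i in range(n)}
    size: dict[int, int] = {i: 1 for i in range(n)}
    d = {k: v for k, v in dist.items()}
    active = sorted(clusters)
    nxt = n
    tree: dict[int, tuple] = {i: i for i in range(n)}

    def get(i, j):
        return d[(min(i, j), max(i, j))]

    while len(active) > 1:
        best_key, best_pair = None, None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (get(i, j), tuple(sorted((rep[i], rep[j]))))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        i, j = best_pair
        u = nxt
        nxt += 1
        for k in active:
            if k in (i, j):
                continue
            duk = (get(i, k) * size[i] + get(j, k) * size[j]) / (size[i] + size[j])
            d[(min(u, k), max(u, k))] = duk
        tree[u] = (tree[i], tree[j])
        rep[u] = min(rep[i], rep[j])
        size[u] = size[i] + size[j]
        active = [k for k in active if k not in (i, j)] + [u]
    return tree[active[0]]


def _progressive(records: Sequence[SequenceRecord]) -> MultipleAlignment:
    by_index = {i: rec for i, rec in enumerate(records)}

    def build(node) -> dict[str, str]:
        if isinstance(node, int):
            rec = by_index[node]
            return {rec.id: rec.residues}
        left, right = build(node[0]), build(node[1])
        ops = _profile_align(_profile_counts(list(left.values())),
                             _profile_counts(list(right.values())))
        return _merge_alignments(left, right, ops)

    rows = build(_guide_order(records))
    ordered = {rec.id: rows[rec.id] for rec in records}  # input order for stable files
    return MultipleAlignment(rows=ordered)


def _run_mafft(records: Sequence[SequenceRecord], threads: int = 1) -> MultipleAlignment:
    exe = shutil.which("mafft")
    if exe is None:
        raise PhylogenyError("mafft not found on PATH; install MAFFT or use backend='builtin'")
    from .sequence_io import write_fasta
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        write_fasta(records, infile)
        proc = subprocess.run([exe, "--quiet", "--thread", str(threads), str(infile)],
                              capture_output=True, text=True)
        if proc.returncode != 0:
            raise PhylogenyError(f"mafft failed: {proc.stderr[-500:]}")
    rows: dict[str, str] = {}
    rid = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            rid = line[1:].split()[0]
            rows[rid] = ""
        elif rid is not None:
            rows[rid] += line.strip().upper()
    return MultipleAlignment(rows=rows)


def align(records: Sequence[SequenceRecord], backend: str = "builtin",
          threads: int = 1) -> MultipleAlignment:
    """Align >=2 peptide records with the chosen backend.

    ``builtin`` is the deterministic progressive aligner; ``mafft`` shells out
    to MAFFT with default options.
    """
    if len(records) < 2:
        raise ValueError("alignment requires at least 2 sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in alignment input")
    if backend == "builtin":
        return _progressive(records)
    if backend == "mafft":
        return _run_mafft(records, threads=threads)
    raise ValueError(f"unknown alignment backend {backend!r}")


# ---------------------------------------------------------------------------
# Distances + neighbour joining
# ---------------------------------------------------------------------------

def p_distance_matrix(msa: MultipleAlignment) -> tuple[list[str], np.ndarray]:
    """p-distance (fraction of differing columns) over pairwise-complete
    (both-ungapped) columns; 0.0 when two rows share no ungapped column."""
    labels = list(msa.rows)
    arr = np.array([list(msa.rows[l]) for l in labels])
    n = len(labels)
    gap = arr == "-"
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            total = int(both.sum())
            if total == 0:
                d = 0.0
            else:
                d = float((arr[i][both] != arr[j][both]).sum()) / total
            dist[i, j] = dist[j, i] = d
    return labels, dist


def neighbor_joining(labels: Sequence[str], dist: np.ndarray) -> "PhyloTree":
    """Neighbour joining with deterministic tie-breaking.

    When several pairs attain the minimal Q value, the pair whose clusters
    have the lexicographically smallest (smallest-leaf-label) representatives
    is joined, so the topology is independent of input row order. Negative
    branch-length estimates are clamped to zero. The final three clusters are
    joined at an unresolved (trifurcating) central node, giving an unrooted
    tree.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")

    # each active cluster: (newick subtree string, representative = min leaf label)
    nodes: dict[int, tuple[str, str]] = {i: (_quote(labels[i]), labels[i]) for i in range(n)}
    D = {(i, j): float(dist[i, j]) for i in range(n) for j in range(n) if i != j}
    active = list(range(n))
    next_id = n

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else D[(i, j)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best_pair, best_key = None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                reps = tuple(sorted((nodes[i][1], nodes[j][1])))
                key = (q, reps)
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        i, j = best_pair
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        sub = f"({nodes[i][0]}:{li:.6f},{nodes[j][0]}:{lj:.6f})"
        rep = min(nodes[i][1], nodes[j][1])
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            D[(u, k)] = D[(k, u)] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]
        nodes[u] = (sub, rep)

    i, j, k = sorted(active, key=lambda x: nodes[x][1])
    li = max(0.5 * (d(i, j) + d(i, k) - d(j, k)), 0.0)
    lj = max(0.5 * (d(i, j) + d(j, k) - d(i, k)), 0.0)
    lk = max(0.5 * (d(i, k) + d(j, k) - d(i, j)), 0.0)
    newick = (f"({nodes[i][0]}:{li:.6f},{nodes[j][0]}:{lj:.6f},"
              f"{nodes[k][0]}:{lk:.6f});")
    return PhyloTree.from_newick(newick)


def _quote(label: str) -> str:
    return label  # labels are pre-cleaned; nothing to quote


def build_tree(msa: MultipleAlignment, method: str = "builtin",
               threads: int = 1) -> "PhyloTree":
    """Build a tree over all alignment rows.

    ``builtin`` = NJ on p-distances; ``fasttree`` runs FastTree2 with
    ``-wag -nopr -nosupport``; ``raxml`` runs RAxML under a WAG+GAMMA model.
    """
    if len(msa.rows) < 3:
        raise ValueError("tree building requires at least 3 aligned sequences")
    if method == "builtin":
        labels, dist = p_distance_matrix(msa)
        return neighbor_joining(labels, dist)
    if method == "fasttree":
        return _run_fasttree(msa, threads=threads)
    if method == "raxml":
        return _run_raxml(msa, threads=threads)
    raise ValueError(f"unknown tree method {method!r}")


def _msa_to_fasta(msa: MultipleAlignment, path: Path) -> None:
    with open(path, "w") as fh:
        for rid, row in msa.rows.items():
            fh.write(f">{rid}\n{row}\n")


def _run_fasttree(msa: MultipleAlignment, threads: int = 1) -> "PhyloTree":
    exe = shutil.which("fasttree") or shutil.which("FastTree")
    if exe is None:
        raise PhylogenyError("FastTree not found on PATH; install FastTree2 or use method='builtin'")
    with tempfile.TemporaryDirectory() as tmp:
        aln = Path(tmp) / "aln.fasta"
        _msa_to_fasta(msa, aln)
        proc = subprocess.run([exe, "-wag", "-nopr", "-nosupport", str(aln)],
                              capture_output=True, text=True)
        if proc.returncode != 0:
            raise PhylogenyError(f"FastTree failed: {proc.stderr[-500:]}")
    return PhyloTree.from_newick(proc.stdout.strip())


def _run_raxml(msa: MultipleAlignment, threads: int = 1) -> "PhyloTree":
    exe = (shutil.which("raxmlHPC") or shutil.which("raxmlHPC-PTHREADS-SSE3")
           or shutil.which("raxml"))
    if exe is None:
        raise PhylogenyError(
            "RAxML not found on PATH; install RAxML (e.g. conda install raxml) "
            "or use method='fasttree'/'builtin'")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        aln = tmp / "aln.fasta"
        _msa_to_fasta(msa, aln)
        proc = subprocess.run(
            [exe, "-s", str(aln), "-n", "run", "-m", "PROTGAMMAWAG",
             "-p", "12345", "-w", str(tmp)],
            capture_output=True, text=True)
        if proc.returncode != 0:
            raise PhylogenyError(f"RAxML failed: {proc.stderr[-500:]}")
        best = tmp / "RAxML_bestTree.run"
        return PhyloTree.from_newick(best.read_text().strip())


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted leaf-labeled tree with branch lengths and path queries.

    Wraps a dendropy tree (used for Newick IO) and exposes an adjacency view
    for edge-count / branch-length-sum patristic distances. Branch lengths
    absent from the source Newick are read as 1.0.
    """

    _dtree: dendropy.Tree
    adjacency: dict[int, list[tuple[int, float]]] = field(default_factory=dict)
    leaf_node: dict[str, int] = field(default_factory=dict)
    node_label: dict[int, str | None] = field(default_factory=dict)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick",
                                      preserve_underscores=True,
                                      suppress_internal_node_taxa=True)
        except Exception as exc:
            raise ValueError(f"invalid Newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        tree = cls(_dtree=dtree)
        tree._index()
        return tree

    def _index(self) -> None:
        self.adjacency, self.leaf_node, self.node_label = {}, {}, {}
        ids: dict[int, int] = {}
        for k, node in enumerate(self._dtree.preorder_node_iter()):
            ids[id(node)] = k
            label = node.taxon.label if node.taxon is not None else None
            self.node_label[k] = label
            self.adjacency[k] = []
            if node.is_leaf():
                if label is None:
                    raise ValueError("leaf without a label in tree")
                if label in self.leaf_node:
                    raise ValueError(f"duplicate leaf label in tree: {label!r}")
                self.leaf_node[label] = k
        for node in self._dtree.preorder_node_iter():
            for child in node.child_nodes():
                length = child.edge.length
                length = 1.0 if length is None else float(length)
                u, v = ids[id(node)], ids[id(child)]
                self.adjacency[u].append((v, length))
                self.adjacency[v].append((u, length))

    @property
    def leaf_labels(self) -> set[str]:
        return set(self.leaf_node)

    def to_newick(self) -> str:
        text = self._dtree.as_string(schema="newick", suppress_rooting=True,
                                     unquoted_underscores=True)
        return text.strip() + ("\n" if not text.endswith("\n") else "")

    # -- path queries -------------------------------------------------------

    def _require_leaf(self, label: str) -> int:
        if label not in self.leaf_node:
            raise KeyError(f"leaf {label!r} not in tree")
        return self.leaf_node[label]

    def distances_from(self, label: str, mode: str = "edge_count") -> dict[str, float]:
        """Distances from one leaf to every leaf (including itself: 0)."""
        if mode not in ("edge_count", "branch_length_sum"):
            raise ValueError(f"unknown distance mode {mode!r}")
        start = self._require_leaf(label)
        dist: dict[int, float] = {start: 0.0}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v, length in self.adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + (1.0 if mode == "edge_count" else length)
                    queue.append(v)
        return {lab: dist[node] for lab, node in self.leaf_node.items()}

    def distance(self, a: str, b: str, mode: str = "edge_count") -> float:
        self._require_leaf(b)
        return self.distances_from(a, mode=mode)[b]
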