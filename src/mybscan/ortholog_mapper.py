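"""Ortholog assignment, lineage summary, and transcriptome isoform collapsing.

Each clean MYB candidate is assigned to the reference sequence (e.g. an
annotated A. thaliana MYB) with the minimal edge-count patristic distance in
a joint tree; the reference's functional annotation is copied onto the
candidate as a function hypothesis. Per-reference counts across species
expose lineage expansion and contraction (a reference with zero assigned
candidates in a species signals absence of that lineage).

Isoform collapsing targets transcriptome assemblies: maximal subtrees that
contain only candidate leaves (no bait or reference inside) are treated as
isoform groups of one gene and represented by their longest member. A
tree-free fallback groups sequences by >=99% identity single linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .phylogeny_engine import PhyloTree
from .sequence_io import SequenceRecord

__all__ = [
    "OrthologAssignment",
    "assign_orthologs",
    "summarize_groups",
    "collapse_isoforms",
    "collapse_by_identity",
]


@dataclass(frozen=True)
class OrthologAssignment:
    candidate_id: str
    reference_id: str
    edge_distance: float
    reference_annotation: str


def assign_orthologs(tree: PhyloTree, candidate_ids: Sequence[str],
                     reference_ids: Iterable[str],
                     annotations: Mapping[str, str] | None = None
                     ) -> list[OrthologAssignment]:
    """Assign every candidate to its nearest reference leaf.

    Minimal edge-count distance wins; ties are broken by the smaller
    branch-length-sum distance, then by lexicographic reference id. The
    reference's annotation text is copied into the assignment row.
    """
    reference_ids = sorted(set(reference_ids))
    refs_in_tree = [r for r in reference_ids if r in tree.leaf_labels]
    if not refs_in_tree:
        raise ValueError("no reference leaves present in the tree")
    annotations = annotations or {}
    out: list[OrthologAssignment] = []
    for cid in sorted(candidate_ids):
        edges = tree.distances_from(cid, mode="edge_count")
        lengths = tree.distances_from(cid, mode="branch_length_sum")
        best = min(refs_in_tree, key=lambda r: (edges[r], lengths[r], r))
        out.append(OrthologAssignment(
            candidate_id=cid, reference_id=best, edge_distance=edges[best],
            reference_annotation=annotations.get(best, "")))
    return out


def summarize_groups(assignments: Sequence[OrthologAssignment],
                     reference_ids: Iterable[str]) -> dict[str, int]:
    """Per-reference candidate counts; references without candidates get 0."""
    counts = {r: 0 for r in sorted(set(reference_ids))}
    for a in assignments:
        counts[a.reference_id] = counts.get(a.reference_id, 0) + 1
    return counts


def _candidate_only_components(tree: PhyloTree, candidates: set[str]) -> list[set[str]]:
    """Connected leaf groups left after removing every node that lies on a
    path between two non-candidate leaves (the Steiner tree of the baits/
    references). Each component is a maximal candidate-only subtree."""
    other_nodes = [n for lab, n in tree.leaf_node.items() if lab not in candidates]
    if not other_nodes:
        return [set(candidates)]
    # Steiner tree of non-candidate leaves: a node belongs iff at least two of
    # its neighbouring subtrees (with the node removed) contain non-candidate
    # leaves — equivalently, iff it lies on a path between two of them.
    # Compute per-edge counts by rooting at one non-candidate leaf.
    root = other_nodes[0]
    order: list[int] = []
    parent: dict[int, int | None] = {root: None}
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for v, _ in tree.adjacency[u]:
            if v not in parent:
                parent[v] = u
                stack.append(v)
    non_cand_leaf = set(other_nodes)
    below: dict[int, int] = {n: 0 for n in order}
    for u in reversed(order):
        if u in non_cand_leaf:
            below[u] += 1
        if parent[u] is not None:
            below[parent[u]] += below[u]
    total = len(other_nodes)

    # u lies on a path between two non-candidate leaves iff at least two of
    # its neighbour directions contain one, or u is such a leaf itself.
    def directions_with_others(u: int) -> int:
        cnt = 0
        for v, _ in tree.adjacency[u]:
            if parent.get(v) == u:
                k = below[v]
            else:  # neighbour towards the root: everything not below u
                k = total - below[u]
            if k > 0:
                cnt += 1
        return cnt

    in_steiner = {u for u in order
                  if u in non_cand_leaf or directions_with_others(u) >= 2}
    # components of the remaining forest
    remaining = set(order) - in_steiner
    seen: set[int] = set()
    components: list[set[str]] = []
    label_of = {n: lab for lab, n in tree.leaf_node.items()}
    for start in sorted(remaining):
        if start in seen:
            continue
        comp_nodes = []
        stack = [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            comp_nodes.append(u)
            for v, _ in tree.adjacency[u]:
                if v in remaining and v not in seen:
                    seen.add(v)
                    stack.append(v)
        leaves = {label_of[n] for n in comp_nodes if n in label_of}
        if leaves:
            components.append(leaves)
    return components


def collapse_isoforms(tree: PhyloTree, candidate_ids: Iterable[str],
                      sequences: Mapping[str, SequenceRecord]
                      ) -> tuple[set[str], dict[str, list[str]]]:
    """Collapse candidate-only clades to their longest member.

    Groups are the maximal subtrees whose leaves are all candidates; each is
    represented by its longest sequence (ties: lexicographically smallest
    id). Candidates not inside any such group stay as their own singleton.

    Returns (representative ids, {representative -> sorted group members}).
    """
    candidates = set(candidate_ids)
    in_tree = candidates & tree.leaf_labels
    groups: list[set[str]] = []
    if in_tree:
        groups = _candidate_only_components(tree, in_tree)
    grouped = set().union(*groups) if groups else set()
    for cid in sorted(candidates - grouped):
        groups.append({cid})  # candidates outside the tree or the components
    representatives: set[str] = set()
    table: dict[str, list[str]] = {}
    for group in groups:
        members = sorted(group)
        rep = max(members, key=lambda i: (len(sequences[i].residues), _neg_lex(i)))
        representatives.add(rep)
        table[rep] = members
    return representatives, table


def _neg_lex(s: str):
    """Sort helper: among equal lengths prefer the lexicographically smallest id."""
    return tuple(-ord(c) for c in s)


def collapse_by_identity(records: Sequence[SequenceRecord],
                         min_identity: float = 0.99) -> tuple[set[str], dict[str, list[str]]]:
    """Tree-free fallback: single-linkage groups at >= ``min_identity``
    ungapped identity (shorter-sequence denominator), longest member kept."""
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            shorter = min(len(records[i].residues), len(records[j].residues))
            if shorter == 0:
                continue
            score = aligner.align(records[i].residues, records[j].residues).score
            if score / shorter >= min_identity:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    representatives: set[str] = set()
    table: dict[str, list[str]] = {}
    for members in groups.values():
        ids = sorted(records[i].id for i in members)
        by_id = {records[i].id: records[i] for i in members}
        rep = max(ids, key=lambda i: (len(by_id[i].residues), _neg_lex(i)))
        representatives.add(rep)
        table[rep] = ids
    return representatives, table


def write_ortholog_table(assignments: Sequence[OrthologAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\treference_id\tedge_distance\treference_annotation\n")
        for a in assignments:
            fh.write(f"{a.candidate_id}\t{a.reference_id}\t{a.edge_distance:g}\t{a.reference_annotation}\n")


def write_group_table(table: Mapping[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("representative\tn_members\tmembers\n")
        for rep in sorted(table):
            fh.write(f"{rep}\t{len(table[rep])}\t{','.join(table[rep])}\n")
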