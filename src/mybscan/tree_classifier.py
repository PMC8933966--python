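"""Phylogeny-based separation of MYB candidates from MYB-like sequences.

Each candidate leaf is compared against the labeled bait leaves of a joint
tree. The bait leaves at the minimal edge-count patristic distance "vote":
a majority of ingroup baits makes the candidate a MYB, otherwise it is
MYB-like (a related non-MYB such as CDC5). Before voting, candidates whose
nearest-bait distance exceeds three times the average nearest-bait distance
of all candidates are excluded as outliers — these are typically fragmented
sequences or annotation artifacts that attach to long branches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .phylogeny_engine import PhyloTree

__all__ = [
    "ClassificationOutcome",
    "patristic_distance",
    "nearest_baits",
    "exclude_outliers",
    "exclude_outliers_from_distances",
    "classify_candidate",
    "classify_candidates",
    "STATUS_MYB",
    "STATUS_MYB_LIKE",
    "STATUS_OUTLIER",
]

STATUS_MYB = "MYB"
STATUS_MYB_LIKE = "MYB_like"
STATUS_OUTLIER = "outlier_excluded"

INGROUP = "ingroup"
OUTGROUP = "outgroup"


@dataclass(frozen=True)
class ClassificationOutcome:
    """Status of one candidate with its nearest-bait evidence."""

    candidate_id: str
    status: str
    nearest_bait_ids: frozenset[str]
    nearest_distance: float
    n_ingroup: int
    n_outgroup: int


def patristic_distance(tree: PhyloTree, leaf_a: str, leaf_b: str,
                       mode: str = "edge_count") -> float:
    """Patristic distance between two leaves.

    ``edge_count`` (default) counts the edges on the unique path between the
    leaves; ``branch_length_sum`` sums the branch lengths along that path.
    Symmetric; zero for a leaf against itself.
    """
    return tree.distance(leaf_a, leaf_b, mode=mode)


def nearest_baits(tree: PhyloTree, candidate_id: str,
                  bait_ids: Iterable[str]) -> tuple[set[str], float]:
    """All bait leaves at the minimal edge-count distance from the candidate."""
    bait_ids = set(bait_ids)
    if not bait_ids:
        raise ValueError("bait_ids must not be empty")
    dists = tree.distances_from(candidate_id, mode="edge_count")
    missing = sorted(b for b in bait_ids if b not in dists)
    if missing:
        raise KeyError(f"bait leaves missing from tree: {', '.join(missing)}")
    best = min(dists[b] for b in bait_ids)
    return {b for b in bait_ids if dists[b] == best}, best


def exclude_outliers_from_distances(distances: Mapping[str, float],
                                    factor: float = 3.0) -> tuple[set[str], set[str], float]:
    """Single-pass outlier rule on nearest-bait distances.

    The mean is taken over *all* candidates (outliers included) in a single
    pass; candidate i is excluded iff d_i > factor * mean (strict). Returns
    (surviving ids, excluded ids, mean).
    """
    if not distances:
        return set(), set(), 0.0
    mean = sum(distances.values()) / len(distances)
    threshold = factor * mean
    excluded = {cid for cid, d in distances.items() if d > threshold}
    return set(distances) - excluded, excluded, mean


def exclude_outliers(tree: PhyloTree, candidate_ids: Iterable[str],
                     bait_ids: Iterable[str], factor: float = 3.0
                     ) -> tuple[set[str], list[tuple[str, float, float]]]:
    """Drop candidates whose nearest-bait distance exceeds ``factor`` times
    the average nearest-bait distance of all candidates.

    Returns (surviving candidate ids, exclusion report rows
    (candidate_id, nearest_distance, mean)).
    """
    candidate_ids = list(candidate_ids)
    if not candidate_ids:
        return set(), []
    nearest = {cid: nearest_baits(tree, cid, bait_ids)[1] for cid in candidate_ids}
    survivors, excluded, mean = exclude_outliers_from_distances(nearest, factor=factor)
    report = [(cid, nearest[cid], mean) for cid in sorted(excluded)]
    return survivors, report


def classify_candidate(nearest_bait_ids: Iterable[str],
                       labels: Mapping[str, str],
                       tie_is_myb: bool = False) -> str:
    """Majority vote of the minimal-distance baits.

    Majority ingroup -> MYB; majority outgroup -> MYB-like; an exact tie is
    conservative (MYB-like) unless ``tie_is_myb`` is set.
    """
    nearest_bait_ids = set(nearest_bait_ids)
    if not nearest_bait_ids:
        raise ValueError("nearest_bait_ids must not be empty")
    unlabeled = sorted(b for b in nearest_bait_ids if b not in labels)
    if unlabeled:
        raise KeyError(f"bait ids without ingroup/outgroup label: {', '.join(unlabeled)}")
    n_in = sum(1 for b in nearest_bait_ids if labels[b] == INGROUP)
    n_out = len(nearest_bait_ids) - n_in
    if n_in > n_out:
        return STATUS_MYB
    if n_in == n_out and tie_is_myb:
        return STATUS_MYB
    return STATUS_MYB_LIKE


def classify_candidates(tree: PhyloTree, candidate_ids: Sequence[str],
                        labels: Mapping[str, str], factor: float = 3.0,
                        tie_is_myb: bool = False) -> list[ClassificationOutcome]:
    """Full classification pass: outlier exclusion, then nearest-bait voting.

    ``labels`` maps every bait id present in the tree to ingroup/outgroup.
    Results are sorted by candidate id for reproducible output tables.
    """
    bait_ids = [b for b in labels if b in tree.leaf_labels]
    if not bait_ids:
        raise ValueError("no labeled bait leaves present in the tree")
    outcomes: list[ClassificationOutcome] = []
    info: dict[str, tuple[set[str], float]] = {}
    for cid in candidate_ids:
        info[cid] = nearest_baits(tree, cid, bait_ids)
    nearest_d = {cid: d for cid, (_, d) in info.items()}
    _, excluded, _ = exclude_outliers_from_distances(nearest_d, factor=factor)
    for cid in sorted(candidate_ids):
        near, d = info[cid]
        n_in = sum(1 for b in near if labels[b] == INGROUP)
        n_out = len(near) - n_in
        if cid in excluded:
            status = STATUS_OUTLIER
        else:
            status = classify_candidate(near, labels, tie_is_myb=tie_is_myb)
        outcomes.append(ClassificationOutcome(
            candidate_id=cid, status=status, nearest_bait_ids=frozenset(near),
            nearest_distance=d, n_ingroup=n_in, n_outgroup=n_out))
    return outcomes


def write_classification_table(outcomes: Sequence[ClassificationOutcome], path) -> None:
    """Tab-separated classification table (one row per candidate)."""
    with open(path, "w") as fh:
        fh.write("candidate_id\tstatus\tnearest_distance\tn_ingroup\tn_outgroup\tnearest_bait_ids\n")
        for o in outcomes:
            fh.write(f"{o.candidate_id}\t{o.status}\t{o.nearest_distance:g}\t"
                     f"{o.n_ingroup}\t{o.n_outgroup}\t{','.join(sorted(o.nearest_bait_ids))}\n")
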