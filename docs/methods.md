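# Methods

This note documents the models, rules and numerical choices behind
`mybscan`, in the order the pipeline applies them, together with what the
synthetic test families do and do not demonstrate.

## Inputs and provenance (step 0)

The pipeline consumes a bait collection (peptide FASTA plus a two-column
id/label table marking each bait `in`group — a bona fide MYB — or
`out`group — a MYB-like non-MYB such as CDC5), one subject FASTA per
species, and optionally an annotated reference panel (FASTA plus a
tab-separated id/name/function[/subgroup] table). Every run starts by
writing a `report.txt` with all parameter values and the MD5 checksum of
every input file, so a result can always be traced to its exact inputs.
The report deliberately contains no timestamps: two runs on identical
inputs must produce byte-identical output trees and tables, which is also
what the reproducibility tests assert.

Sequence identifiers are sanitized before any tree is built: whitespace
and the characters with syntactic meaning in Newick
(`; : ( ) , [ ]` and quotes) are replaced by `_`, collisions resolved by
numeric suffixes, and the full original→cleaned map written to
`name_map.tsv`. The forbidden set is exactly the set that breaks leaf
labels in tree files; nothing else is touched.

Subjects may be coding sequences: a file whose records are ≥ 90 %
`{A,C,G,T,U,N}` is treated as nucleotide and translated in frame +1 with
the standard code. Trailing partial codons are dropped, one terminal stop
is removed, internal stops stay `*`, and any codon containing an ambiguous
base becomes `X` (even codons like `GGN` whose product happens to be
unambiguous — the rule is uniform by design). Mixed peptide/nucleotide
files are rejected rather than guessed at.

## Candidate search (step 1)

Default engine is an in-package Smith–Waterman local alignment (BLOSUM62,
gap open 11 / extend 1) applied to every bait × subject pair; BLAST+ and
HMMER are available as drop-in external engines. "Alignment similarity"
means the BLAST-style positives percentage: the fraction of alignment
columns (gaps included) whose residue pair scores > 0 under BLOSUM62.
Raw scores are converted to bit scores with the standard gapped BLOSUM62
Karlin–Altschul parameters (λ = 0.267, K = 0.041), which is what the
outgroup-harvest utility's "bit score ≥ 100" cutoff and the per-bait hit
ranking consume.

Filters (all configurable): alignment length ≥ 50 aa **and** similarity
≥ 80 %, then at most 100 hits per bait query ranked by bit score
(ties: lower e-value, then subject id). Both cutoffs are inclusive; the
candidate set is the union of surviving subject ids. Profile-HMM hits
carry no meaningful positives percentage, so HMMER hits bypass the
similarity filter (reported as 100) and are filtered on envelope length
only.

## Built-in alignment and tree backends (steps 2/5/8)

MAFFT + FastTree2 (`-wag -nopr -nosupport`) or RAxML (WAG+GAMMA) are the
production path. The built-in backend exists so that the complete pipeline
runs deterministically with no external binaries:

* **Progressive alignment** — a UPGMA guide tree on 3-mer cosine distances,
  then profile–profile merging by affine-gap global DP (gap open −11,
  extend −1) with BLOSUM62 sum-of-pairs scoring over column residue
  frequencies. Profiles are integer count vectors, guide-tree ties break on
  the lexicographically smallest member label, and DP traceback prefers
  match over gap states, so the alignment is invariant under input row
  permutations. (A center-star aligner was tried first and rejected: two
  sequences similar to each other but unrelated to the center — exactly the
  outgroup family — receive distorted mutual distances.)
* **Neighbour joining** on p-distances (fraction of differing columns among
  pairwise-complete, i.e. both-ungapped, columns; 0 when two rows share no
  column). Q-matrix ties break on the smallest leaf-label representatives,
  negative branch-length estimates are clamped to 0, and the final three
  clusters join at a trifurcating central node (unrooted tree). On exactly
  additive distances NJ provably recovers the generating topology and
  branch lengths; the tests verify this for n ≤ 6 against enumerated
  bipartitions.

Newick I/O runs through dendropy; branch lengths absent from an input tree
default to 1.0 so edge counting still works on length-free topologies.
Trees are used exactly as parsed (no re-rooting): edge counts are taken on
the tree as written.

## Classification (step 3)

Distances between leaves are **edge-count patristic distances** — the
number of edges on the unique connecting path (branch-length sums are
available as an alternative mode but the classifier votes on edge counts).
For each candidate, *all* bait leaves at the minimal distance vote;
majority ingroup → MYB, majority outgroup → MYB-like, and an exact tie is
conservative (MYB-like; a flag flips this). Using every minimal-distance
bait rather than a fixed k keeps the vote well-defined in polytomies.

Outlier exclusion runs before voting: with dᵢ the nearest-bait distance of
candidate i and m the mean of all dᵢ (a single pass — the mean includes the
outliers, no iterative trimming), candidate i is excluded iff dᵢ > 3·m
(strict inequality at the boundary). This removes fragments and annotation
artifacts that attach to long branches. The factor 3 is configurable.

## Repeat annotation (step 4)

Default motifs encode the canonical repeat architecture — three regularly
spaced tryptophans, with the R3 repeat's first position relaxed to any of
F/I/L/M/W:

```
R2-like:  W.{18,22}W.{18,22}W
R3-like:  [FILMW].{17,21}W.{17,21}W
```

Both are shipped as editable configuration (`--motifs`), so alternative
pattern sets can be substituted verbatim. Matching is greedy and
non-overlapping, with a priority subtlety: the R2 pattern is scanned first
across the whole peptide and the looser R3 pattern only fills the regions
left free. Without this, the R3 initiator class can anchor on a background
hydrophobic residue just upstream of a genuine R2 and swallow its
tryptophan core. Detected repeats are grouped into runs with inter-repeat
linkers ≤ 15 residues (repeats are adjacent in the DNA-binding domain);
the longest run decides the class: R2-then-R3 pair → R2R3, runs of 3/4 →
3R/4R, a lone repeat → 1R. A strict both-repeats-complete match is
required for R2R3; partial repeats do not count.

## Ortholog assignment and isoform collapsing (steps 6–7)

Each clean MYB is assigned to the reference leaf with minimal edge-count
distance in a joint candidates+references tree; ties break by
branch-length sum, then reference id. The reference's annotation text is
copied into the output row as a function hypothesis. Per-reference counts
(including explicit zeros — absence of a lineage is a result) feed the
cross-species summary matrix in batch mode.

Isoform groups are the maximal subtrees whose leaves are all candidates
(equivalently: the components left after removing every tree node that
lies on a path between two bait/reference leaves). Each group is
represented by its longest member, ties broken by the smaller id. Grouping
by tree structure reuses the tree the pipeline has already built; a
sequence-identity fallback (≥ 99 % single-linkage) exists for tree-free
use. Collapsing is idempotent and representatives are always
maximal-length members of their groups.

## Synthetic families

The generator (`mybscan.simulate`) produces everything the pipeline
consumes plus exact truth labels. Ingroup baits derive from one founder
protein carrying an implanted R2+R3 pair (spacings 19/18 residues inside
the motif windows, 5-residue linker) at 15 % divergence; outgroup baits
derive from a separate single-repeat (CDC5-like) founder. Subjects are
ingroup baits mutated at the chosen substitution rate (default 10 %),
MYB-like subjects are mutated outgroup baits, decoys are motif-free random
backgrounds; isoforms are C-terminal truncations that keep the N-terminal
domain. Coding-sequence versions are produced by seeded reverse
translation. Defaults: 30 ingroup / 5 outgroup baits, 10 genes, protein
lengths 160–220 aa.

Two deliberate idealizations: backgrounds are uniform over the 19
non-tryptophan amino acids, and repeat spacers additionally avoid the R3
initiator residues. This reserves the tryptophan spacing pattern for
implants, making truth labels exact — with tryptophan included, a ~200-aa
uniform random protein would spuriously match the repeat motifs ~68 % of
the time and no exact-recovery statement would be possible. Consequently
the fixtures do not probe motif specificity on realistic amino-acid
compositions, nor indels, rate heterogeneity, alignment errors from real
divergence patterns, or incomplete bait coverage of deep lineages. Passing
tests therefore demonstrate the correctness of the *rules* (filters,
distances, votes, collapsing, checkpointing), not field performance on
real assemblies, where the external ML tree path and a curated bait
collection are the intended configuration.

Test and acceptance problem sizes (35 baits, 10–17 subjects, 20 replicate
families, random trees ≤ 32 leaves, additive matrices n ≤ 6) were chosen
as the smallest sizes at which every rule is exercised end to end,
including polytomies and isoform clades.

## Degenerate inputs and edge cases

* Zero candidates after filtering: the run succeeds with empty tables and
  `n_candidates: 0` in the report; no trees are built.
* Fewer than 3 sequences for a tree: tree construction refuses (hard
  error) at the library level; the pipeline skips tree steps that would be
  degenerate.
* A single candidate can never be excluded as an outlier (d > 3d is
  false).
* Translation producing an empty peptide skips the record with a warning
  in the report.
* One failing species in batch mode is recorded in `summary_counts.tsv`
  and does not abort the batch.

## Known limitations

Edge-count distances ignore branch lengths, so very unequal evolutionary
rates among baits can shift votes; the branch-length mode exists but is
not the default because topology-level counting is robust to the built-in
backend's simple p-distances. The built-in NJ/progressive backend is a
testing and reproducibility device, not a substitute for ML trees on real
data. Repeat motifs are heuristic regular expressions, not profile HMMs;
degenerate repeats beyond the allowed spacing windows are reported as
fewer/no repeats. Orthology is nearest-neighbour in a gene tree — no
duplication/loss reconciliation against a species tree.
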