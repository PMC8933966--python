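# mybscan

Automatic identification and annotation of **MYB transcription factor
family members** in plant genome and transcriptome assemblies.

MYBs form one of the largest transcription factor families in plants and
regulate development, stress responses, and specialized metabolism
(flavonols, anthocyanins, proanthocyanidins, glucosinolates, ...). Their
DNA-binding domain consists of up to four imperfect ~50–53-residue repeats
(R1/R2/R3), each stabilized by three regularly spaced tryptophans; the
dominant plant class carries the R2 and R3 repeats (R2R3-MYBs). Because
every new genome or transcriptome assembly triggers another round of manual
MYB cataloguing, `mybscan` packages the whole procedure as a reproducible,
checkpointed pipeline:

1. **Candidate search** — all subject sequences (peptides, or coding
   sequences that are translated first) are compared against a labeled
   *bait collection* by local similarity search. Default filters: alignment
   length ≥ 50 aa, alignment similarity ≥ 80 %, at most 100 hits per bait.
2. **Phylogenetic classification** — a tree is built over candidates plus
   all baits. For each candidate the bait leaves at the minimal *edge-count
   patristic distance* vote: a majority of ingroup baits (bona fide MYBs)
   makes the candidate a **MYB**, a majority of outgroup baits (MYB-like
   non-MYBs such as CDC5) makes it **MYB-like**. Candidates whose nearest
   bait lies further than 3× the mean nearest-bait distance are excluded as
   fragments/artifacts.
3. **Repeat annotation** — configurable regular expressions locate R2-like
   and R3-like repeats and assign the classical repeat class
   (none / 1R / R2R3 / 3R / 4R).
4. **Ortholog assignment** — each clean MYB is assigned to the nearest leaf
   of an annotated reference panel in a joint tree, transferring function
   hypotheses and exposing lineage expansion/contraction.
5. **Isoform collapsing** (for transcriptome assemblies) — candidate-only
   clades are treated as isoform groups of one gene and represented by
   their longest member.

Search, alignment and tree construction can run through the standard
external tools (BLAST+, HMMER, MAFFT, FastTree2 `-wag -nopr -nosupport`,
RAxML) or through fully deterministic built-in backends (Smith–Waterman
search; progressive alignment + neighbour joining), so the complete
pipeline is testable and reproducible with no external binaries.

## Worked example

`mybscan` ships a synthetic-family generator so you can try the full
pipeline without any downloads:

```python
from mybscan import FixtureSpec, generate_family
fx = generate_family(FixtureSpec(seed=11, n_genes=6, isoforms_per_gene=2))
paths = fx.write("demo/fixture")   # bait FASTA+labels, subjects, references
```

```bash
mybscan --baits demo/fixture/baits.fasta --info demo/fixture/baits_info.txt \
        --subject demo/fixture/subjects_pep.fasta \
        --refseqs demo/fixture/references.fasta \
        --refinfo demo/fixture/references_info.txt \
        --collapse --out demo/out
```

prints

```
subjects_pep: 12 MYBs, 2 MYB-like, 14 initial candidates -> demo/out/subjects_pep
```

i.e. of 14 sequences that survived the similarity filters, 12 were placed
next to ingroup baits (the 6 genes × 2 isoforms implanted by the generator)
and 2 next to outgroup baits. The output folder contains the classification
and evidence tables, e.g. `classification.tsv`:

```
candidate_id   status  nearest_distance  n_ingroup  n_outgroup  nearest_bait_ids
gene001_iso1   MYB     3                 1          0           bait_in_001
```

`domains.tsv` (repeat class with match coordinates):

```
id             repeat_class  n_repeats  repeat_coordinates
gene001_iso1   R2R3          2          R2-like:70-111,R3-like:116-155
```

`orthologs.tsv` (function hypotheses copied from the reference panel):

```
candidate_id   reference_id  edge_distance  reference_annotation
gene001_iso1   REF001        3              RefMYB1; flavonol biosynthesis regulator; S1
```

and `isoform_groups.tsv` shows each isoform pair collapsed to its longest
member (12 MYBs → 6 representatives). Newick trees for the candidate,
clean-MYB and final representative sets are written alongside
(`tree_*.nwk`), plus a `report.txt` listing every parameter and the MD5
checksum of every input file. Re-running the same command is a no-op
(checkpoints); deleting an intermediate file re-runs only the affected
steps and reproduces byte-identical outputs.

Batch mode (`--subjectdir FOLDER`) processes every FASTA in a folder and
adds cross-species summary tables (`summary_counts.tsv`,
`summary_groups.tsv`) that compare MYB family sizes and per-reference
lineage counts between species.

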