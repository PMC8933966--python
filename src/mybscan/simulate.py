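"""Synthetic test families: baits, subjects, references, and truth labels.

The generator emulates the structure the pipeline assumes in real data:

* ingroup baits — proteins carrying an R2+R3 repeat implant (two tandem
  repeats with the canonical tryptophan spacing) in a random background,
  derived from a shared ingroup founder so they form a gene family;
* outgroup baits — MYB-like proteins (single degenerate repeat, CDC5-like)
  derived from a separate founder;
* subjects — "new species" sequences: genes mutated off ingroup baits (true
  MYBs), MYB-like sequences mutated off outgroup baits, and motif-free
  background decoys; optional isoform groups made by truncating each gene;
* references — annotated relatives of distinct ingroup baits, standing in
  for a functionally characterized reference MYB panel.

Background residues are drawn uniformly from the 19 non-tryptophan amino
acids and repeat spacers additionally avoid the R3 initiator residues
(F/I/L/M), so that every tryptophan spacing pattern in a fixture sequence is
an implant, never noise — this is what makes truth labels exact.

Everything is driven by one seed; the same spec and seed give byte-identical
output.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .sequence_io import SequenceRecord, write_fasta

__all__ = ["FixtureSpec", "Fixture", "generate_family"]

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_BACKGROUND = AA.replace("W", "")                      # no spurious repeat cores
AA_SPACER = "".join(c for c in AA_BACKGROUND if c not in "FILM")

#: codons used for reverse translation (one unambiguous codon per residue
#: would also work; several choices keep the CDS path non-trivial)
_CODONS = {
    "A": ["GCT", "GCC"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC"], "K": ["AAA", "AAG"],
    "L": ["CTT", "CTG"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCA"], "Q": ["CAA", "CAG"], "R": ["CGT", "CGC"],
    "S": ["TCT", "TCC"], "T": ["ACT", "ACC"], "V": ["GTT", "GTC"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic family."""

    n_ingroup_baits: int = 30
    n_outgroup_baits: int = 5
    n_genes: int = 10
    n_myb_like: int = 2
    n_background: int = 3
    isoforms_per_gene: int = 1
    substitution_rate: float = 0.1
    bait_divergence: float = 0.15
    background_length: tuple[int, int] = (160, 220)
    n_references: int = 5
    seed: int = 0


@dataclass
class Fixture:
    """Generated family with exact truth labels."""

    baits: list[SequenceRecord]
    bait_labels: dict[str, str]                 # id -> ingroup|outgroup
    subjects_pep: list[SequenceRecord]
    subjects_cds: list[SequenceRecord]
    references: list[SequenceRecord]
    reference_annotation: dict[str, dict[str, str]]
    truth: dict[str, dict[str, str]] = field(default_factory=dict)
    # truth[id] = {"true_class": MYB|MYB_like|background,
    #              "source_gene": ..., "isoform_group": ...}

    def true_ids(self, true_class: str) -> set[str]:
        return {i for i, row in self.truth.items() if row["true_class"] == true_class}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the exact file formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "baits": outdir / "baits.fasta",
            "bait_info": outdir / "baits_info.txt",
            "subjects_pep": outdir / "subjects_pep.fasta",
            "subjects_cds": outdir / "subjects_cds.fasta",
            "references": outdir / "references.fasta",
            "reference_info": outdir / "references_info.txt",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.baits, paths["baits"])
        with open(paths["bait_info"], "w") as fh:
            for rec in self.baits:
                fh.write(f"{rec.id}\t{'in' if self.bait_labels[rec.id] == 'ingroup' else 'out'}\n")
        write_fasta(self.subjects_pep, paths["subjects_pep"])
        write_fasta(self.subjects_cds, paths["subjects_cds"])
        write_fasta(self.references, paths["references"])
        with open(paths["reference_info"], "w") as fh:
            for rec in self.references:
                ann = self.reference_annotation[rec.id]
                fh.write(f"{rec.id}\t{ann['name']}\t{ann['function']}\t{ann.get('subgroup','')}\n")
        with open(paths["truth"], "w") as fh:
            fh.write("id\ttrue_class\tsource_gene\tisoform_group\n")
            for sid in sorted(self.truth):
                row = self.truth[sid]
                fh.write(f"{sid}\t{row['true_class']}\t{row['source_gene']}\t{row['isoform_group']}\n")
        return paths


def _rand_seq(rng: random.Random, n: int, alphabet: str = AA_BACKGROUND) -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def make_r2_repeat(rng: random.Random) -> str:
    return "W" + _rand_seq(rng, 19, AA_SPACER) + "W" + _rand_seq(rng, 19, AA_SPACER) + "W"


def make_r3_repeat(rng: random.Random) -> str:
    return "F" + _rand_seq(rng, 18, AA_SPACER) + "W" + _rand_seq(rng, 18, AA_SPACER) + "W"


def implant_domain(rng: random.Random, length: int) -> tuple[str, int, int]:
    """Random background with an R2+R3 pair implanted; returns
    (peptide, domain_start, domain_end)."""
    domain = make_r2_repeat(rng) + _rand_seq(rng, 5, AA_SPACER) + make_r3_repeat(rng)
    flank = max(length - len(domain), 10)
    n_pre = rng.randint(5, flank - 5)
    pre, post = _rand_seq(rng, n_pre), _rand_seq(rng, flank - n_pre)
    return pre + domain + post, len(pre), len(pre) + len(domain)


def mutate(rng: random.Random, residues: str, rate: float,
           protect: tuple[int, int] | None = None) -> str:
    """Random substitutions at the given per-site rate. Tryptophans and
    positions inside ``protect`` (the repeat cores' W/F anchors) are kept so
    the domain stays detectable; all substitutions draw from the W-free
    background alphabet."""
    out = []
    for i, c in enumerate(residues):
        keep_anchor = c in "W" or (protect and protect[0] <= i < protect[1] and c in "WF")
        if not keep_anchor and rng.random() < rate:
            choices = AA_BACKGROUND.replace(c, "") if c in AA_BACKGROUND else AA_BACKGROUND
            out.append(rng.choice(choices))
        else:
            out.append(c)
    return "".join(out)


def reverse_translate(rng: random.Random, peptide: str) -> str:
    cds = "".join(rng.choice(_CODONS[c]) for c in peptide)
    return cds + "TAA"


def generate_family(spec: FixtureSpec) -> Fixture:
    """Generate one complete labeled family from a spec and its seed."""
    if spec.substitution_rate > 0.5:
        warnings.warn("substitution_rate > 0.5: truth recovery is not guaranteed")
    rng = random.Random(spec.seed)

    founder_len = sum(spec.background_length) // 2
    founder_in, dom_start, dom_end = implant_domain(rng, founder_len)
    # MYB-like founder: one degenerate repeat only (CDC5-like)
    single = make_r3_repeat(rng)
    flank = founder_len - len(single)
    founder_out = _rand_seq(rng, flank // 2) + single + _rand_seq(rng, flank - flank // 2)

    baits: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for i in range(spec.n_ingroup_baits):
        residues = mutate(rng, founder_in, spec.bait_divergence, protect=(dom_start, dom_end))
        bid = f"bait_in_{i+1:03d}"
        baits.append(SequenceRecord(bid, residues))
        labels[bid] = "ingroup"
    for i in range(spec.n_outgroup_baits):
        residues = mutate(rng, founder_out, spec.bait_divergence)
        bid = f"bait_out_{i+1:03d}"
        baits.append(SequenceRecord(bid, residues))
        labels[bid] = "outgroup"

    subjects: list[SequenceRecord] = []
    truth: dict[str, dict[str, str]] = {}
    ingroup_baits = [b for b in baits if labels[b.id] == "ingroup"]
    outgroup_baits = [b for b in baits if labels[b.id] == "outgroup"]

    for g in range(spec.n_genes):
        source = ingroup_baits[g % len(ingroup_baits)]
        gene = mutate(rng, source.residues, spec.substitution_rate,
                      protect=(dom_start, dom_end))
        group = f"gene{g+1:03d}"
        for iso in range(spec.isoforms_per_gene):
            if iso == 0:
                residues = gene
            else:
                # C-terminal truncation: keeps the N-terminal domain intact
                cut = len(gene) - 10 * iso - rng.randint(0, 5)
                residues = gene[:max(cut, dom_end + 5)]
            sid = f"{group}_iso{iso+1}"
            subjects.append(SequenceRecord(sid, residues))
            truth[sid] = {"true_class": "MYB", "source_gene": source.id,
                          "isoform_group": group}

    for m in range(spec.n_myb_like):
        source = outgroup_baits[m % len(outgroup_baits)]
        sid = f"myblike{m+1:03d}"
        subjects.append(SequenceRecord(sid, mutate(rng, source.residues, spec.substitution_rate)))
        truth[sid] = {"true_class": "MYB_like", "source_gene": source.id,
                      "isoform_group": ""}

    for d in range(spec.n_background):
        sid = f"decoy{d+1:03d}"
        length = rng.randint(*spec.background_length)
        subjects.append(SequenceRecord(sid, _rand_seq(rng, length)))
        truth[sid] = {"true_class": "background", "source_gene": "",
                      "isoform_group": ""}

    subjects_cds = [
        SequenceRecord(rec.id, reverse_translate(rng, rec.residues), moltype="nucleotide")
        for rec in subjects
    ]

    references: list[SequenceRecord] = []
    reference_annotation: dict[str, dict[str, str]] = {}
    functions = ["flavonol biosynthesis regulator", "anthocyanin biosynthesis regulator",
                 "proanthocyanidin biosynthesis regulator", "root hair patterning",
                 "glucosinolate biosynthesis regulator"]
    for r in range(spec.n_references):
        source = ingroup_baits[(r * 3) % len(ingroup_baits)]
        rid = f"REF{r+1:03d}"
        references.append(SequenceRecord(
            rid, mutate(rng, source.residues, 0.08, protect=(dom_start, dom_end))))
        reference_annotation[rid] = {
            "name": f"RefMYB{r+1}",
            "function": functions[r % len(functions)],
            "subgroup": f"S{r+1}",
        }

    return Fixture(baits=baits, bait_labels=labels, subjects_pep=subjects,
                   subjects_cds=subjects_cds, references=references,
                   reference_annotation=reference_annotation, truth=truth)
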