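"""End-to-end MYB annotation pipeline with checkpoints and provenance.

Steps, in order (all steps write fixed file names into the species folder):

0. provenance + input preparation (report, name cleaning, translation)
1. similarity search against the baits + candidate filtering
2. tree #1 over initial candidates + all baits
3. outlier exclusion and MYB / MYB-like classification
4. repeat (domain) annotation of the clean MYBs
5. tree #2 over clean MYBs + all baits
6. ortholog assignment to the reference set (optional, needs references)
7. isoform collapsing (optional, for transcriptome assemblies)
8. final tree over representatives + references

A step is re-run iff the digests of its inputs (or its parameters) changed or
any of its outputs is missing, so an interrupted analysis resumes at the last
completed checkpoint; in batch mode a finished species is skipped entirely.
With the built-in backends the whole pipeline is deterministic: identical
inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .bait_repository import BaitCollection, ReferenceSet, load_baits, load_reference
from .candidate_search import filter_hits, run_search
from .domain_annotator import (DEFAULT_MOTIFS, classify_repeats, compile_motifs,
                               detect_repeats, write_domain_table)
from .ortholog_mapper import (assign_orthologs, collapse_isoforms, summarize_groups,
                              write_group_table, write_ortholog_table)
from .phylogeny_engine import align, build_tree
from .sequence_io import (SequenceRecord, clean_names, file_checksum, read_fasta,
                          translate_cds, write_fasta)
from .tree_classifier import (STATUS_MYB, STATUS_MYB_LIKE, classify_candidates,
                              write_classification_table)

__all__ = ["PipelineConfig", "run_single", "run_batch", "PipelineError"]

FASTA_SUFFIXES = {".fasta", ".fa", ".faa", ".fna", ".pep", ".cds"}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All tunable parameters; defaults match the documented pipeline defaults."""

    baits: str = ""
    bait_info: str = ""
    subject: str = ""
    subject_dir: str = ""
    refseqs: str = ""
    refinfo: str = ""
    out: str = "mybscan_out"
    search_engine: str = "builtin"      # builtin | blast | hmmer
    tree_method: str = "builtin"        # builtin | fasttree | raxml
    align_backend: str = "auto"         # auto | builtin | mafft
    min_len: int = 50
    min_sim: float = 80.0
    max_hits_per_bait: int = 100
    outlier_factor: float = 3.0
    max_linker: int = 15
    tie_is_myb: bool = False
    collapse: bool = False
    cpu: int = 1
    seed: int = 0
    motifs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))

    def resolved_align_backend(self) -> str:
        if self.align_backend != "auto":
            return self.align_backend
        return "mafft" if self.tree_method in ("fasttree", "raxml") else "builtin"

    def param_lines(self) -> list[str]:
        d = asdict(self)
        d["motifs"] = ";".join(f"{k}={v}" for k, v in sorted(self.motifs.items()))
        return [f"{k}: {d[k]}" for k in sorted(d) if k != "out"]


class _Checkpoints:
    """Per-species ledger of completed steps with input digests."""

    def __init__(self, path: Path):
        self.path = path
        self.state: dict[str, dict] = {}
        if path.exists():
            try:
                self.state = json.loads(path.read_text())
            except json.JSONDecodeError:
                self.state = {}

    def key_for(self, params: str, input_files: list[Path]) -> str:
        h = hashlib.md5(params.encode())
        for f in input_files:
            h.update(file_checksum(f).encode())
        return h.hexdigest()

    def is_done(self, step: str, key: str, outputs: list[Path]) -> bool:
        entry = self.state.get(step)
        return (entry is not None and entry.get("key") == key
                and all(Path(o).exists() for o in outputs))

    def mark(self, step: str, key: str, outputs: list[Path]) -> None:
        self.state[step] = {"key": key, "outputs": [str(o) for o in outputs]}
        self.path.write_text(json.dumps(self.state, indent=1, sort_keys=True))


def _read_tsv_column(path: Path, column: int = 0, skip_header: bool = True) -> list[str]:
    lines = path.read_text().splitlines()
    if skip_header and lines:
        lines = lines[1:]
    return [l.split("\t")[column] for l in lines if l.strip()]


def _prepare_subjects(subject_file: Path, report_lines: list[str]
                      ) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Read, type-check, translate (if coding sequences) and name-clean."""
    raw = read_fasta(subject_file)
    moltypes = {r.moltype for r in raw}
    if len(moltypes) > 1:
        raise PipelineError(
            f"{subject_file}: mixed nucleotide and peptide records; provide one kind")
    if moltypes == {"nucleotide"}:
        peptides = []
        for rec in raw:
            pep = translate_cds(rec)
            if pep is None:
                report_lines.append(f"warning: {rec.id} translated to an empty peptide, skipped")
                continue
            peptides.append(pep)
        report_lines.append(f"input_type: coding sequences (translated {len(peptides)} records)")
        raw = peptides
    else:
        report_lines.append("input_type: peptide sequences")
    cleaned, name_map = _clean_unique(raw)
    return cleaned, dict(name_map.items())


def _clean_unique(records):
    cleaned, name_map = clean_names(records)
    return cleaned, name_map


def run_single(config: PipelineConfig, subject_file: str | Path,
               outdir: str | Path | None = None) -> dict:
    """Run steps 0-8 for one species; returns a result summary dict."""
    subject_file = Path(subject_file)
    outdir = Path(outdir) if outdir else Path(config.out) / subject_file.stem
    outdir.mkdir(parents=True, exist_ok=True)
    cp = _Checkpoints(outdir / "checkpoint.json")
    params = "|".join(param_lines := config.param_lines()) + f"|v{__version__}"

    paths = {
        "report": outdir / "report.txt",
        "name_map": outdir / "name_map.tsv",
        "subjects_clean": outdir / "subjects_clean.fasta",
        "candidates_initial": outdir / "candidates_initial.txt",
        "tree1": outdir / "tree_candidates_baits.nwk",
        "classification": outdir / "classification.tsv",
        "mybs": outdir / "mybs.fasta",
        "myb_like": outdir / "myb_like.txt",
        "domains": outdir / "domains.tsv",
        "tree2": outdir / "tree_clean_baits.nwk",
        "orthologs": outdir / "orthologs.tsv",
        "groups": outdir / "group_counts.tsv",
        "isoform_groups": outdir / "isoform_groups.tsv",
        "representatives": outdir / "representatives.fasta",
        "tree3": outdir / "tree_final.nwk",
    }

    compile_motifs(config.motifs)  # fail fast on malformed motif config

    baits = load_baits(config.baits, config.bait_info)
    bait_records, bait_map = _clean_unique(baits.records)
    bait_labels = {bait_map.forward[rid]: lab for rid, lab in baits.labels.items()}
    baits = BaitCollection(records=bait_records, labels=bait_labels)

    reference: ReferenceSet | None = None
    if config.refseqs:
        if not config.refinfo:
            raise PipelineError("refseqs given without refinfo annotation table")
        reference = load_reference(config.refseqs, config.refinfo)
        ref_records, ref_map = _clean_unique(reference.records)
        ref_ann = {ref_map.forward[rid]: ann for rid, ann in reference.annotation.items()}
        reference = ReferenceSet(records=ref_records, annotation=ref_ann)

    input_files = [subject_file, Path(config.baits), Path(config.bait_info)]
    if reference is not None:
        input_files += [Path(config.refseqs), Path(config.refinfo)]

    # ---- step 0: provenance, cleaning, translation -------------------------
    step0_out = [paths["report"], paths["name_map"], paths["subjects_clean"]]
    key0 = cp.key_for(params + "step0", input_files)
    if not cp.is_done("step0", key0, step0_out):
        report: list[str] = [f"pipeline: mybscan v{__version__}", "step: 0 provenance"]
        report += param_lines
        for f in input_files:
            report.append(f"input_file: {f.resolve()}")
            report.append(f"md5: {file_checksum(f)}")
        report.append(f"backend_versions: python={sys.version.split()[0]} "
                      f"biopython+dendropy (see package metadata)")
        report.append(f"baits_ingroup: {len(baits.ingroup_ids)}")
        report.append(f"baits_outgroup: {len(baits.outgroup_ids)}")
        subjects, name_map = _prepare_subjects(subject_file, report)
        subj_ids = {r.id for r in subjects}
        clash = subj_ids & {r.id for r in baits.records}
        if reference is not None:
            clash |= subj_ids & {r.id for r in reference.records}
        if clash:
            raise PipelineError(f"subject ids collide with bait/reference ids: {sorted(clash)}")
        write_fasta(subjects, paths["subjects_clean"])
        with open(paths["name_map"], "w") as fh:
            fh.write("original_id\tcleaned_id\n")
            for orig, cleaned in name_map.items():
                fh.write(f"{orig}\t{cleaned}\n")
        report.append(f"n_subjects: {len(subjects)}")
        paths["report"].write_text("\n".join(report) + "\n")
        cp.mark("step0", key0, step0_out)
    subjects = read_fasta(paths["subjects_clean"], moltype="peptide") \
        if Path(paths["subjects_clean"]).stat().st_size else []

    def _append_report(line: str) -> None:
        with open(paths["report"], "a") as fh:
            fh.write(line + "\n")

    bait_by_id = {r.id: r for r in baits.records}
    subj_by_id = {r.id: r for r in subjects}

    # ---- step 1: similarity search + filtering -----------------------------
    key1 = cp.key_for(params + "step1", [paths["subjects_clean"]] + input_files[1:3])
    if not cp.is_done("step1", key1, [paths["candidates_initial"]]):
        hits = run_search(baits.records, subjects, engine=config.search_engine,
                          threads=config.cpu)
        candidates = filter_hits(hits, min_len=config.min_len, min_sim=config.min_sim,
                                 max_hits_per_bait=config.max_hits_per_bait)
        paths["candidates_initial"].write_text(
            "".join(f"{c}\n" for c in sorted(candidates)))
        _append_report(f"n_initial_candidates: {len(candidates)}")
        cp.mark("step1", key1, [paths["candidates_initial"]])
    candidates = [c for c in paths["candidates_initial"].read_text().split() if c]

    tree_method = config.tree_method
    aln_backend = config.resolved_align_backend()

    # ---- step 2: tree #1 (initial candidates + baits) ----------------------
    key2 = cp.key_for(params + "step2", [paths["candidates_initial"], paths["subjects_clean"],
                                         Path(config.baits)])
    if not cp.is_done("step2", key2, [paths["tree1"]]):
        if candidates:
            records = baits.records + [subj_by_id[c] for c in candidates]
            msa = align(records, backend=aln_backend, threads=config.cpu)
            tree = build_tree(msa, method=tree_method, threads=config.cpu)
            paths["tree1"].write_text(tree.to_newick())
        else:
            paths["tree1"].write_text("")  # nothing to place
        cp.mark("step2", key2, [paths["tree1"]])

    # ---- step 3: outlier exclusion + classification ------------------------
    step3_out = [paths["classification"], paths["mybs"], paths["myb_like"]]
    key3 = cp.key_for(params + "step3", [paths["tree1"], paths["candidates_initial"]])
    if not cp.is_done("step3", key3, step3_out):
        if candidates:
            from .phylogeny_engine import PhyloTree
            tree = PhyloTree.from_newick(paths["tree1"].read_text())
            outcomes = classify_candidates(tree, candidates, baits.labels,
                                           factor=config.outlier_factor,
                                           tie_is_myb=config.tie_is_myb)
        else:
            outcomes = []
        write_classification_table(outcomes, paths["classification"])
        myb_ids = [o.candidate_id for o in outcomes if o.status == STATUS_MYB]
        write_fasta([subj_by_id[i] for i in myb_ids], paths["mybs"])
        paths["myb_like"].write_text("".join(
            f"{o.candidate_id}\n" for o in outcomes if o.status == STATUS_MYB_LIKE))
        _append_report(f"n_mybs: {len(myb_ids)}")
        _append_report(f"n_myb_like: {sum(1 for o in outcomes if o.status == STATUS_MYB_LIKE)}")
        _append_report(f"n_outliers_excluded: "
                       f"{sum(1 for o in outcomes if o.status not in (STATUS_MYB, STATUS_MYB_LIKE))}")
        cp.mark("step3", key3, step3_out)
    myb_ids = sorted({r.id for r in read_fasta(paths["mybs"], moltype="peptide")}) \
        if paths["mybs"].stat().st_size else []

    # ---- step 4: repeat annotation -----------------------------------------
    key4 = cp.key_for(params + "step4", [paths["mybs"]])
    if not cp.is_done("step4", key4, [paths["domains"]]):
        rows = []
        for mid in myb_ids:
            matches = detect_repeats(subj_by_id[mid].residues, config.motifs)
            rows.append((mid, classify_repeats(matches, max_linker=config.max_linker), matches))
        write_domain_table(rows, paths["domains"])
        n_r2r3 = sum(1 for _, cls, _ in rows if cls == "R2R3")
        _append_report(f"n_r2r3: {n_r2r3}")
        cp.mark("step4", key4, [paths["domains"]])

    # ---- step 5: tree #2 (clean MYBs + baits) -------------------------------
    key5 = cp.key_for(params + "step5", [paths["mybs"], Path(config.baits)])
    if not cp.is_done("step5", key5, [paths["tree2"]]):
        if myb_ids:
            records = baits.records + [subj_by_id[i] for i in myb_ids]
            msa = align(records, backend=aln_backend, threads=config.cpu)
            tree = build_tree(msa, method=tree_method, threads=config.cpu)
            paths["tree2"].write_text(tree.to_newick())
        else:
            paths["tree2"].write_text("")
        cp.mark("step5", key5, [paths["tree2"]])

    # ---- step 6: ortholog assignment (optional) -----------------------------
    if reference is not None:
        key6 = cp.key_for(params + "step6", [paths["mybs"], Path(config.refseqs),
                                             Path(config.refinfo)])
        if not cp.is_done("step6", key6, [paths["orthologs"], paths["groups"]]):
            if myb_ids and len(myb_ids) + len(reference.records) >= 3:
                records = reference.records + [subj_by_id[i] for i in myb_ids]
                msa = align(records, backend=aln_backend, threads=config.cpu)
                rtree = build_tree(msa, method=tree_method, threads=config.cpu)
                annotations = {r.id: reference.annotation_text(r.id)
                               for r in reference.records}
                assignments = assign_orthologs(rtree, myb_ids,
                                               [r.id for r in reference.records],
                                               annotations)
            else:
                assignments = []
            write_ortholog_table(assignments, paths["orthologs"])
            counts = summarize_groups(assignments, [r.id for r in reference.records])
            with open(paths["groups"], "w") as fh:
                fh.write("reference_id\tn_candidates\n")
                for rid in sorted(counts):
                    fh.write(f"{rid}\t{counts[rid]}\n")
            cp.mark("step6", key6, [paths["orthologs"], paths["groups"]])

    # ---- step 7: isoform collapsing (optional) ------------------------------
    rep_ids = myb_ids
    if config.collapse:
        step7_out = [paths["representatives"], paths["isoform_groups"]]
        key7 = cp.key_for(params + "step7", [paths["tree2"], paths["mybs"]])
        if not cp.is_done("step7", key7, step7_out):
            if myb_ids and paths["tree2"].stat().st_size:
                from .phylogeny_engine import PhyloTree
                tree2 = PhyloTree.from_newick(paths["tree2"].read_text())
                reps, table = collapse_isoforms(tree2, myb_ids, subj_by_id)
            else:
                reps, table = set(myb_ids), {i: [i] for i in myb_ids}
            write_fasta([subj_by_id[i] for i in sorted(reps)], paths["representatives"])
            write_group_table(table, paths["isoform_groups"])
            _append_report(f"n_representatives: {len(reps)}")
            cp.mark("step7", key7, step7_out)
        rep_ids = sorted({r.id for r in read_fasta(paths["representatives"], moltype="peptide")}) \
            if paths["representatives"].stat().st_size else []

    # ---- step 8: final tree --------------------------------------------------
    final_refs = reference.records if reference is not None else baits.records
    key8_inputs = [paths["representatives"] if config.collapse else paths["mybs"]]
    key8 = cp.key_for(params + "step8", key8_inputs)
    if not cp.is_done("step8", key8, [paths["tree3"]]):
        if rep_ids and len(rep_ids) + len(final_refs) >= 3:
            records = list(final_refs) + [subj_by_id[i] for i in rep_ids]
            msa = align(records, backend=aln_backend, threads=config.cpu)
            tree = build_tree(msa, method=tree_method, threads=config.cpu)
            paths["tree3"].write_text(tree.to_newick())
        else:
            paths["tree3"].write_text("")
        cp.mark("step8", key8, [paths["tree3"]])

    classification_rows = _read_tsv_column(paths["classification"])
    return {
        "outdir": str(outdir),
        "n_subjects": len(subjects),
        "n_initial_candidates": len(candidates),
        "n_mybs": len(myb_ids),
        "n_myb_like": sum(1 for _ in open(paths["myb_like"])) if paths["myb_like"].exists() else 0,
        "n_classified": len(classification_rows),
        "n_representatives": len(rep_ids),
        "myb_ids": myb_ids,
        "representative_ids": list(rep_ids),
    }


def run_batch(config: PipelineConfig, folder: str | Path) -> dict:
    """Process every FASTA in a folder (lexicographic order); emit summaries.

    One failing species does not abort the batch; its failure is recorded in
    the summary. Resume granularity is the per-species checkpoint ledger.
    """
    folder = Path(folder)
    files = sorted(p for p in folder.iterdir()
                   if p.is_file() and p.suffix.lower() in FASTA_SUFFIXES)
    if not files:
        raise PipelineError(f"no FASTA files found in {folder}")
    out_root = Path(config.out)
    out_root.mkdir(parents=True, exist_ok=True)
    results: dict[str, dict] = {}
    failures: dict[str, str] = {}
    for f in files:
        try:
            results[f.stem] = run_single(config, f, out_root / f.stem)
        except Exception:
            failures[f.stem] = traceback.format_exc(limit=2).strip().splitlines()[-1]

    with open(out_root / "summary_counts.tsv", "w") as fh:
        fh.write("species\tstatus\tn_subjects\tn_initial_candidates\tn_mybs\t"
                 "n_myb_like\tn_representatives\n")
        for species in sorted(set(results) | set(failures)):
            if species in results:
                r = results[species]
                fh.write(f"{species}\tok\t{r['n_subjects']}\t{r['n_initial_candidates']}\t"
                         f"{r['n_mybs']}\t{r['n_myb_like']}\t{r['n_representatives']}\n")
            else:
                fh.write(f"{species}\tfailed: {failures[species]}\t0\t0\t0\t0\t0\n")

    if config.refseqs:
        # species x reference-group matrix from the per-species group counts
        ref_ids: list[str] = []
        matrix: dict[str, dict[str, int]] = {}
        for species, r in sorted(results.items()):
            gpath = Path(r["outdir"]) / "group_counts.tsv"
            if not gpath.exists():
                continue
            counts = {}
            for line in gpath.read_text().splitlines()[1:]:
                rid, n = line.split("\t")
                counts[rid] = int(n)
            matrix[species] = counts
            ref_ids = sorted(set(ref_ids) | set(counts))
        with open(out_root / "summary_groups.tsv", "w") as fh:
            fh.write("species\t" + "\t".join(ref_ids) + "\n")
            for species in sorted(matrix):
                row = "\t".join(str(matrix[species].get(r, 0)) for r in ref_ids)
                fh.write(f"{species}\t{row}\n")
    return {"results": results, "failures": failures}
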