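"""End-to-end orchestration of the comparative analysis.

One call runs: annotation and motif tabulation; per-domain and concatenated
alignments; neighbor-joining trees with bootstrap supports and consensus;
Robinson-Foulds discordance among the Trx, Erv and concatenated trees;
conservation profiling (optionally painted onto a structure); and the
intron-sharing report.  Every output file lands in the configured directory
and is listed, with a SHA-256 checksum, in a JSON manifest that makes the run
reproducible: re-running with the same configuration and seed reproduces all
checksums byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .align import Alignment, progressive_align, read_fasta, write_fasta
from .conservation import (conservation_profile, find_conserved_regions,
                           linker_length_stats, map_profile_to_structure)
from .introns import (GeneModel, IntronPosition, project_to_alignment,
                      protein_intron_positions, read_gene_models,
                      shared_intron_positions, write_sharing_report)
from .motifs import (annotate_family, clade_consensus_motifs, motif_table,
                     write_annotations)
from .patterns import ERV_PATTERN_TEXT, TRX_PATTERN_TEXT, parse_pattern
from .phylo import (bipartition_frequencies, bootstrap_columns, consensus,
                    distance_matrix, nj_tree, rf_distance, concat_alignments)
from .simulate import FamilyConfig, evolve_family, generate_gene_models, write_family

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs and analysis parameters for one pipeline run.

    Exactly one of (fasta, family) must be set: real inputs from files, or a
    synthetic family generated in-run with known truth.
    """

    # real inputs
    fasta: str | None = None
    clades_tsv: str | None = None
    gene_models_tsv: str | None = None
    structure: str | None = None
    structure_ref: str | None = None
    # synthetic input
    family: FamilyConfig | None = None
    introns_per_gene: int = 3
    intron_conserved_fraction: float = 1.0
    # analysis parameters
    trx_pattern_text: str = TRX_PATTERN_TEXT
    erv_pattern_text: str = ERV_PATTERN_TEXT
    model: str = "jtt"
    bootstrap: int = 100
    consensus_rule: str = "majority_extended"
    gap_threshold: float = 0.5
    ic_threshold: float = 3.0
    region_min_len: int = 4
    region_max_gap: int = 1
    intron_tolerance: int = 0
    intron_require_phase: bool = True
    outdir: str = "qsoxphylo_out"
    seed: int = 0

    def validate(self) -> None:
        if (self.fasta is None) == (self.family is None):
            raise ValueError("set exactly one of fasta (real inputs) or "
                             "family (synthetic inputs)")
        if self.bootstrap < 1:
            raise ValueError("bootstrap count must be >= 1")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # not part of the scientific configuration
        if self.family is not None:
            fam = dataclasses.asdict(self.family)
            fam["erv_tree"] = (self.family.erv_tree.newick()
                               if self.family.erv_tree is not None else None)
            d["family"] = fam
        return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_clades(path: str) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                sid, clade = line.rstrip("\n").split("\t")
                out[sid] = clade
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    outputs: list[str] = []
    results: dict = {}
    stage = "setup"

    def out(name: str) -> str:
        path = os.path.join(config.outdir, name)
        outputs.append(name)
        return path

    def fail(exc: Exception):
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_jsonable(),
            "failed_stage": stage,
            "error": str(exc),
            "files": {n: _sha256(os.path.join(config.outdir, n))
                      for n in outputs
                      if os.path.exists(os.path.join(config.outdir, n))},
        }
        with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise PipelineError(stage, exc) from exc

    try:
        seed_root = np.random.SeedSequence(config.seed)

        # ---- inputs ----------------------------------------------------
        stage = "inputs"
        truth = None
        gene_models: dict[str, GeneModel] = {}
        if config.family is not None:
            fam_cfg = dataclasses.replace(config.family, seed=config.seed)
            records, truth = evolve_family(fam_cfg)
            if config.introns_per_gene > 0:
                truth = generate_gene_models(
                    truth, config.introns_per_gene,
                    config.intron_conserved_fraction,
                    seed=int(seed_root.spawn(1)[0].generate_state(1)[0] % (2**31)))
            paths = write_family(records, truth, config.outdir)
            outputs.extend(os.path.basename(p) for p in paths.values())
            clades = dict(truth.clades)
            gene_models = {sid: GeneModel(sid, tuple(t.gene_model))
                           for sid, t in truth.per_seq.items() if t.gene_model}
        else:
            records = read_fasta(config.fasta)
            clades = _read_clades(config.clades_tsv) if config.clades_tsv else {}
            if config.gene_models_tsv:
                gene_models = read_gene_models(config.gene_models_tsv)

        # ---- annotation ------------------------------------------------
        stage = "annotation"
        trx = parse_pattern(config.trx_pattern_text, name="trx",
                            captures={"trx_cxxc": (4, 6), "cx6_8c": (10, 12)})
        erv = parse_pattern(config.erv_pattern_text, name="erv",
                            captures={"erv_cxxc": (5, 7), "ct_cxxc": (14, 16)})
        annotations, failures = annotate_family(records, trx, erv)
        write_annotations(annotations + failures, out("annotations.tsv"),
                          out("annotations.json"))
        results["n_annotated"] = len(annotations)
        results["n_failed"] = len(failures)
        if not annotations:
            raise ValueError("no sequence carries both domains")
        table = motif_table(annotations, clades)
        table.to_csv(out("motif_table.tsv"), sep="\t", index=False)
        with open(out("clade_motifs.json"), "w") as fh:
            json.dump(clade_consensus_motifs(table), fh, indent=1, sort_keys=True)
        stats = linker_length_stats(annotations)
        with open(out("linker_stats.json"), "w") as fh:
            json.dump(stats, fh, indent=1, sort_keys=True)

        # ---- alignments ------------------------------------------------
        stage = "alignment"
        seqs = dict(records)
        trx_recs = [(a.seqid, seqs[a.seqid][a.trx_span[0]:a.trx_span[1]])
                    for a in annotations]
        erv_recs = [(a.seqid, seqs[a.seqid][a.erv_span[0]:a.erv_span[1]])
                    for a in annotations]
        msa_trx = progressive_align(trx_recs)
        msa_erv = progressive_align(erv_recs)
        msa_cat = concat_alignments(msa_trx, msa_erv)
        msa_trx.to_fasta(out("msa_trx.fasta"))
        msa_erv.to_fasta(out("msa_erv.fasta"))
        msa_cat.to_fasta(out("msa_concat.fasta"))
        msa_cat.to_clustal(out("msa_concat.aln"))

        # ---- trees -----------------------------------------------------
        stage = "trees"
        nj_trees = {}
        boot_seeds = seed_root.spawn(3)
        for name, msa, sseq in (("trx", msa_trx, boot_seeds[0]),
                                ("erv", msa_erv, boot_seeds[1]),
                                ("concat", msa_cat, boot_seeds[2])):
            dm = distance_matrix(msa, config.model)
            dm.write_phylip(out(f"dist_{name}.phylip"))
            tree = nj_tree(dm)
            reps = bootstrap_columns(
                msa, config.bootstrap,
                seed=int(sseq.generate_state(1)[0] % (2**31)))
            rep_trees = [nj_tree(distance_matrix(r, config.model)) for r in reps]
            freqs = bipartition_frequencies(rep_trees)
            tree.set_supports({bp: int(np.floor(100 * f + 0.5))
                               for bp, f in freqs.items()})
            cons = consensus(rep_trees, config.consensus_rule)
            with open(out(f"tree_{name}_nj.nwk"), "w") as fh:
                fh.write(tree.newick() + "\n")
            with open(out(f"tree_{name}_consensus.nwk"), "w") as fh:
                fh.write(cons.newick() + "\n")
            with open(out(f"supports_{name}.tsv"), "w") as fh:
                fh.write("bipartition\tfrequency\n")
                for bp in sorted(freqs, key=lambda b: (-freqs[b], sorted(b))):
                    fh.write(",".join(sorted(bp)) + f"\t{freqs[bp]:.4f}\n")
            nj_trees[name] = tree

        stage = "discordance"
        with open(out("rf_discordance.tsv"), "w") as fh:
            fh.write("tree_a\ttree_b\trf\n")
            names = list(nj_trees)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    rf = rf_distance(nj_trees[a], nj_trees[b])
                    results[f"rf_{a}_{b}"] = rf
                    fh.write(f"{a}\t{b}\t{rf}\n")

        # ---- conservation ----------------------------------------------
        stage = "conservation"
        profile = conservation_profile(msa_cat, config.gap_threshold)
        profile.write_tsv(out("conservation.tsv"))
        profile.write_frequency_matrix(out("column_frequencies.tsv"))
        regions = find_conserved_regions(profile, config.ic_threshold,
                                         config.region_min_len,
                                         config.region_max_gap)
        with open(out("conserved_regions.tsv"), "w") as fh:
            fh.write("start\tend\tmean_ic\trank\n")
            for r in regions:
                fh.write(f"{r.start}\t{r.end}\t{r.mean_ic:.4f}\t{r.rank}\n")
        results["n_conserved_regions"] = len(regions)
        if config.structure is not None:
            ref = config.structure_ref or msa_cat.ids[0]
            df = map_profile_to_structure(profile, msa_cat, ref,
                                          config.structure,
                                          out_pdb=out("structure_scores.pdb"))
            df.to_csv(out("structure_scores.tsv"), sep="\t", index=False)

        # ---- introns ---------------------------------------------------
        stage = "introns"
        if gene_models:
            ann_by_id = {a.seqid: a for a in annotations}
            projected: dict[str, list[IntronPosition]] = {}
            unmapped = 0
            for sid, gm in gene_models.items():
                a = ann_by_id.get(sid)
                if a is None:
                    continue
                gm.validate_against(len(seqs[sid]))
                row = msa_cat.row(sid)
                kept = []
                trx_w = msa_trx.width
                for pos in protein_intron_positions(gm):
                    # protein coordinate -> concatenated domain-schema column
                    if a.trx_span[0] <= pos.codon_index < a.trx_span[1]:
                        k = pos.codon_index - a.trx_span[0]
                        dom_row = msa_trx.row(sid)
                        col = [j for j, c in enumerate(dom_row) if c != "-"][k]
                    elif a.erv_span[0] <= pos.codon_index < a.erv_span[1]:
                        k = pos.codon_index - a.erv_span[0]
                        dom_row = msa_erv.row(sid)
                        col = trx_w + [j for j, c in enumerate(dom_row)
                                       if c != "-"][k]
                    else:
                        unmapped += 1
                        continue
                    kept.append(dataclasses.replace(pos, column=col))
                projected[sid] = kept
            results["n_introns_outside_domains"] = unmapped
            clade_names = sorted(set(clades.values()))
            pair_rows = []
            for i, ca in enumerate(clade_names):
                for cb in clade_names[i + 1:]:
                    ga = _dedupe([p for sid in projected for p in projected[sid]
                                  if clades.get(sid) == ca])
                    gb = _dedupe([p for sid in projected for p in projected[sid]
                                  if clades.get(sid) == cb])
                    shared, a_only, b_only = shared_intron_positions(
                        ga, gb, config.intron_tolerance,
                        config.intron_require_phase)
                    write_sharing_report(shared, a_only, b_only,
                                         out(f"introns_{ca}_vs_{cb}.tsv"),
                                         group_names=(ca, cb))
                    pair_rows.append((ca, cb, len(shared), len(a_only),
                                      len(b_only)))
            with open(out("intron_sharing_summary.tsv"), "w") as fh:
                fh.write("clade_a\tclade_b\tshared\ta_only\tb_only\n")
                for row in pair_rows:
                    fh.write("\t".join(map(str, row)) + "\n")

        # ---- manifest --------------------------------------------------
        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_jsonable(),
            "results": results,
            "files": {n: _sha256(os.path.join(config.outdir, n))
                      for n in sorted(set(outputs))},
        }
        with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except PipelineError:
        raise
    except Exception as exc:          # noqa: BLE001 - abort with stage name
        fail(exc)


def _dedupe(positions: list[IntronPosition]) -> list[IntronPosition]:
    """One representative per distinct (column, phase) within a group."""
    seen = {}
    for p in positions:
        key = (p.column, p.phase)
        if key not in seen:
            seen[key] = p
    return [seen[k] for k in sorted(seen)]
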