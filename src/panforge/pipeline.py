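"""End-to-end orchestration.

``run_all`` chains the stages in dependency order over an on-disk panel
(the layout written by :func:`panforge.synth.write_dataset`): consensus
gene calling -> ortholog clustering -> presence/absence matrix and
accumulation curves -> pseudo-assembly and GC profile -> plasmid calls,
trees and CRISPR typing -> gene-trait matching. Every tabular output is
TSV, trees are Newick, and a manifest JSON records parameters, the seed
and a checksum per output file, so a rerun with the same inputs and seed
is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from panforge import (crispr as crispr_mod, genecall, gtm as gtm_mod, io as pio,
                      ortho, panmatrix, plasmids as plasmids_mod, pseudoasm,
                      trees as trees_mod)
from panforge.models import GeneModel

logger = logging.getLogger("panforge")


@dataclasses.dataclass
class GenecallParams:
    min_support_fraction: float = 0.5
    max_overlap: int = 100


@dataclasses.dataclass
class OrthoParams:
    inflation: float = 1.5
    min_score: float = 50.0
    min_identity: float = 0.4
    min_coverage: float = 0.5

    def validate(self) -> list[str]:
        errors = []
        if self.inflation <= 1.0:
            errors.append(f"ortho.inflation must be > 1, got {self.inflation}")
        return errors


@dataclasses.dataclass
class MatrixParams:
    n_permutations: int = 100
    include_singletons: bool = False
    min_run: int = 10
    max_presence: float = 0.9
    cassette_min_fraction: float = 0.8


@dataclasses.dataclass
class PseudoasmParams:
    gc_window: int = 5000
    gc_step: int = 1000


@dataclasses.dataclass
class PlasmidParams:
    min_overlap: int = 50
    chrom_map_cutoff: float = 0.2


@dataclasses.dataclass
class CrisprParamsRun:
    repeat_len_min: int = 23
    repeat_len_max: int = 47
    spacer_len_min: int = 20
    spacer_len_max: int = 50
    min_repeats: int = 3
    max_repeat_mismatch: int = 1


@dataclasses.dataclass
class GtmParams:
    n_trees: int = 1000
    importance_threshold: float = 0.005
    od_threshold: float = 0.8


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of an end-to-end run."""

    dataset_dir: str
    output_dir: str
    seed: int = 0
    linkage: str = "average"
    genecall: GenecallParams = dataclasses.field(default_factory=GenecallParams)
    ortho: OrthoParams = dataclasses.field(default_factory=OrthoParams)
    matrix: MatrixParams = dataclasses.field(default_factory=MatrixParams)
    pseudoasm: PseudoasmParams = dataclasses.field(default_factory=PseudoasmParams)
    plasmids: PlasmidParams = dataclasses.field(default_factory=PlasmidParams)
    crispr: CrisprParamsRun = dataclasses.field(default_factory=CrisprParamsRun)
    gtm: GtmParams = dataclasses.field(default_factory=GtmParams)

    def validate(self) -> list[str]:
        errors = []
        if not Path(self.dataset_dir).is_dir():
            errors.append(f"dataset_dir does not exist: {self.dataset_dir}")
        errors.extend(self.ortho.validate())
        if self.linkage not in ("average", "complete", "single"):
            errors.append(f"unknown linkage {self.linkage!r}")
        if not 0 < self.gtm.importance_threshold < 1:
            errors.append("gtm.importance_threshold must be in (0, 1)")
        return errors


_SECTION_TYPES = {
    "genecall": GenecallParams,
    "ortho": OrthoParams,
    "matrix": MatrixParams,
    "pseudoasm": PseudoasmParams,
    "plasmids": PlasmidParams,
    "crispr": CrisprParamsRun,
    "gtm": GtmParams,
}


def validate_config(path: str | Path) -> RunConfig:
    """Load + validate a YAML run config; unknown keys are rejected by
    name, missing keys take their documented defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    errors: list[str] = []
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in top_fields:
            errors.append(f"unknown config key: {key}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            errors.append(f"section {name} must be a mapping")
            continue
        valid = {f.name for f in dataclasses.fields(cls)}
        for key in section:
            if key not in valid:
                errors.append(f"unknown config key: {name}.{key}")
        kwargs[name] = cls(**{k: v for k, v in section.items() if k in valid})
    for scalar in ("dataset_dir", "output_dir", "seed", "linkage"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    if "dataset_dir" not in kwargs or "output_dir" not in kwargs:
        errors.append("dataset_dir and output_dir are required")
    if errors:
        raise ValueError("; ".join(errors))
    config = RunConfig(**kwargs)
    errors = config.validate()
    if errors:
        raise ValueError("; ".join(errors))
    return config


@dataclasses.dataclass
class RunResult:
    config: RunConfig
    consensus: dict[str, genecall.ConsensusGeneSet]
    ogs: list[ortho.OrthologGroup]
    matrix: pd.DataFrame
    curve: panmatrix.AccumulationCurve
    single_copy_core: list[str]
    assemblies: dict[str, pseudoasm.PseudoAssembly]
    og_ranks: dict[str, int]
    regions: list[panmatrix.VariableRegion]
    plasmid_calls: dict[str, str]
    plasmid_ogs: list[str]
    core_tree_newick: str
    content_tree_newick: str
    crispr_types: dict[str, int]
    gtm_reports: dict[str, gtm_mod.GtmTraitReport]
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage; outputs land in ``config.output_dir``.

    A stage failure aborts with the stage name in the raised error; outputs
    of earlier stages are retained on disk. A missing growth table skips
    the GTM stage with a warning.
    """
    errors = config.validate()
    if errors:
        raise ValueError("; ".join(errors))
    src = Path(config.dataset_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        genomes: dict[str, dict[str, str]] = {}
        tracks: dict[str, dict[str, list[pio.GffFeature]]] = {}
        for fa in sorted((src / "genomes").glob("*.fasta")):
            genomes[fa.stem] = pio.read_fasta(fa)
            tracks[fa.stem] = {}
        for gff in sorted((src / "tracks").glob("*.gff3")):
            strain, pred = gff.stem.rsplit(".", 1)
            tracks[strain][pred] = pio.read_gff3(gff)
        strains = sorted(genomes)
        ref_seq = pio.read_fasta(src / "reference" / "reference.fasta")
        ref_seq = next(iter(ref_seq.values()))
        ref_prot = pio.read_fasta(src / "reference" / "reference.faa")
        ref_genes = [
            GeneModel(gene_id=f.feature_id, strain="REF", contig="REF",
                      start=f.start, end=f.end, strand=f.strand,
                      protein=ref_prot[f.feature_id],
                      annotation=f.attributes.get("product", ""))
            for f in pio.read_gff3(src / "reference" / "reference.gff3")]
        known_plasmids = pio.read_fasta(src / "known_plasmids.fasta")
        od_path = src / "growth_od.tsv"
        logger.info("loaded %d strains, %d reference genes",
                    len(strains), len(ref_genes))

        stage = "genecall"
        consensus: dict[str, genecall.ConsensusGeneSet] = {}
        for s in strains:
            consensus[s] = genecall.call_genes(
                s, tracks[s], genomes[s],
                min_support_fraction=config.genecall.min_support_fraction,
                max_overlap=config.genecall.max_overlap)
            logger.info("genecall %s: %d genes (%d discarded)", s,
                        len(consensus[s].genes), len(consensus[s].discard_log))

        stage = "reference-matching"
        ref_proteins = {g.gene_id: g.protein for g in ref_genes}
        ref_ann = {g.gene_id: g.annotation for g in ref_genes}
        gene_to_ref: dict[str, str] = {}
        for s in strains:
            q = {g.gene_id: g.protein for g in consensus[s].genes}
            gene_to_ref.update(pseudoasm.match_to_reference(
                q, ref_proteins,
                min_score=config.ortho.min_score,
                min_identity=config.ortho.min_identity,
                min_coverage=config.ortho.min_coverage))
        annotation_of_gene = {
            g: ref_ann.get(r, "") for g, r in gene_to_ref.items()}

        stage = "ortho"
        proteins: dict[str, str] = {}
        strain_of: dict[str, str] = {}
        contig_of: dict[str, str] = {}
        all_genes: dict[str, GeneModel] = {}
        for s in strains:
            for g in consensus[s].genes:
                proteins[g.gene_id] = g.protein
                strain_of[g.gene_id] = s
                contig_of[g.gene_id] = g.contig
                all_genes[g.gene_id] = g
        ogs = ortho.cluster_proteins(
            proteins, strain_of, annotation_of=annotation_of_gene,
            inflation=config.ortho.inflation,
            min_score=config.ortho.min_score,
            min_identity=config.ortho.min_identity,
            min_coverage=config.ortho.min_coverage)
        logger.info("ortho: %d OGs from %d proteins", len(ogs), len(proteins))

        stage = "panmatrix"
        matrix = panmatrix.build_matrix(
            ogs, strains, include_singletons=config.matrix.include_singletons)
        curve = panmatrix.accumulation_curves(
            matrix, n_permutations=config.matrix.n_permutations,
            seed=config.seed)
        scc = panmatrix.single_copy_core(matrix, ogs)

        stage = "pseudoasm"
        assemblies: dict[str, pseudoasm.PseudoAssembly] = {}
        ref_rank_of_gene: dict[str, int] = {}
        gc_tracks: dict[str, pd.DataFrame] = {}
        for s in strains:
            pa = pseudoasm.anchor_and_order(
                s, consensus[s].genes, ref_genes, len(ref_seq),
                gene_to_ref=gene_to_ref,
                contig_lengths={c: len(seq) for c, seq in genomes[s].items()},
                contig_input_order=sorted(genomes[s]))
            assemblies[s] = pa
            ref_rank_of_gene = pa.ref_rank_of_gene
            gc_tracks[s] = pseudoasm.gc_profile(
                [(c, genomes[s][c]) for c in pa.all_contigs],
                window=config.pseudoasm.gc_window,
                step=config.pseudoasm.gc_step)
        ranks = pseudoasm.og_ranks(ogs, ref_rank_of_gene, gene_to_ref)
        regions = panmatrix.find_variable_regions(
            matrix, ranks, min_run=config.matrix.min_run,
            max_presence=config.matrix.max_presence)

        stage = "plasmids"
        evidence: list[plasmids_mod.PlasmidEvidence] = []
        for s in strains:
            mapped = {g.gene_id for g in consensus[s].genes
                      if g.gene_id in gene_to_ref}
            gene_ann = [dataclasses.replace(
                g, annotation=annotation_of_gene.get(g.gene_id, ""))
                for g in consensus[s].genes]
            for cid in sorted(genomes[s]):
                evidence.append(plasmids_mod.evaluate_criteria(
                    cid, genomes[s][cid], gene_ann, mapped, known_plasmids,
                    chrom_map_cutoff=config.plasmids.chrom_map_cutoff,
                    min_overlap=config.plasmids.min_overlap))
        plasmid_calls, plasmid_ogs = plasmids_mod.classify(
            evidence, ogs, contig_of)

        stage = "trees"
        og_by_id = {og.og_id: og for og in ogs}
        core_members = {}
        for og_id in scc:
            og = og_by_id[og_id]
            core_members[og_id] = {
                strain_of[m]: proteins[m] for m in og.members}
        if len(strains) >= 3 and core_members:
            dist = trees_mod.core_distance(core_members, strains)
            core_tree = trees_mod.to_newick(trees_mod.neighbor_joining(dist))
        else:
            dist = None
            core_tree = ""
            warnings.warn("core tree skipped: needs >=3 strains and >=1 "
                          "single-copy core OG")
        content = trees_mod.to_newick(
            trees_mod.content_tree(matrix, linkage=config.linkage))

        stage = "crispr"
        arrays_by_strain = {
            s: crispr_mod.find_arrays_in_genome(
                s, genomes[s],
                repeat_len_range=(config.crispr.repeat_len_min,
                                  config.crispr.repeat_len_max),
                spacer_len_range=(config.crispr.spacer_len_min,
                                  config.crispr.spacer_len_max),
                min_repeats=config.crispr.min_repeats,
                max_repeat_mismatch=config.crispr.max_repeat_mismatch)
            for s in strains}
        all_arrays = [a for arrs in arrays_by_strain.values() for a in arrs]
        spacer_matrix, spacer_seqs = crispr_mod.catalog_spacers(all_arrays)
        crispr_types = crispr_mod.assign_types(arrays_by_strain)

        stage = "gtm"
        gtm_reports: dict[str, gtm_mod.GtmTraitReport] = {}
        phenotype_calls = None
        if od_path.exists():
            od_table = pd.read_csv(od_path, sep="\t")
            phenotype_calls = gtm_mod.call_growth(
                od_table, threshold=config.gtm.od_threshold)
            og_ann = {og.og_id: og.annotation for og in ogs}
            gtm_reports = gtm_mod.gtm_all_traits(
                matrix, phenotype_calls, annotation_of=og_ann,
                n_trees=config.gtm.n_trees, seed=config.seed,
                importance_threshold=config.gtm.importance_threshold)
        else:
            warnings.warn("growth table missing; GTM stage skipped")

        stage = "write"
        written = _write_outputs(
            out, config, consensus, ogs, matrix, curve, scc, assemblies,
            ranks, regions, evidence, plasmid_calls, plasmid_ogs, dist,
            core_tree, content, all_arrays, spacer_matrix, spacer_seqs,
            crispr_types, gc_tracks, phenotype_calls, gtm_reports)
    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "n_strains": len(strains),
        "n_ogs": len(ogs),
        "outputs": {name: _sha256(out / name) for name in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return RunResult(
        config=config, consensus=consensus, ogs=ogs, matrix=matrix,
        curve=curve, single_copy_core=scc, assemblies=assemblies,
        og_ranks=ranks, regions=regions, plasmid_calls=plasmid_calls,
        plasmid_ogs=plasmid_ogs, core_tree_newick=core_tree,
        content_tree_newick=content, crispr_types=crispr_types,
        gtm_reports=gtm_reports, manifest=manifest)


def _write_outputs(out, config, consensus, ogs, matrix, curve, scc,
                   assemblies, ranks, regions, evidence, plasmid_calls,
                   plasmid_ogs, dist, core_tree, content, all_arrays,
                   spacer_matrix, spacer_seqs, crispr_types, gc_tracks,
                   phenotype_calls, gtm_reports) -> list[str]:
    written: list[str] = []

    def _tsv(name: str, frame: pd.DataFrame, **kw) -> None:
        frame.to_csv(out / name, sep="\t", **kw)
        written.append(name)

    def _text(name: str, text: str) -> None:
        (out / name).write_text(text)
        written.append(name)

    og_rows = [(og.og_id, s, m)
               for og in ogs for m in og.members
               for s in [m.split("|", 1)[0]]]
    _tsv("og_membership.tsv",
         pd.DataFrame(og_rows, columns=["og", "strain", "gene"]), index=False)
    _tsv("matrix.tsv", matrix, index_label="og")
    _tsv("curves.tsv", curve.to_frame(), index=False)
    _text("single_copy_core.txt", "\n".join(scc) + "\n")
    _tsv("pseudoassembly.tsv",
         pd.concat([a.to_frame() for a in assemblies.values()]), index=False)
    _tsv("og_ranks.tsv",
         pd.DataFrame(sorted(ranks.items()), columns=["og", "rank"]),
         index=False)
    _tsv("variable_regions.tsv", pd.DataFrame(
        [(r.rank_start, r.rank_end, r.n_ogs, round(r.mean_presence, 4),
          ";".join(r.og_ids)) for r in regions],
        columns=["rank_start", "rank_end", "n_ogs", "mean_presence", "ogs"]),
        index=False)
    from panforge.plasmids import evidence_frame
    _tsv("plasmid_evidence.tsv", evidence_frame(evidence), index=False)
    _text("plasmid_ogs.txt", "\n".join(plasmid_ogs) + "\n")
    if dist is not None:
        _tsv("core_distance.tsv", dist)
        _text("core_tree.nwk", core_tree + "\n")
    _text("content_tree.nwk", content + "\n")
    from panforge.crispr import arrays_frame
    _tsv("crispr_arrays.tsv", arrays_frame(all_arrays), index=False)
    _tsv("crispr_spacers.tsv", spacer_matrix, index_label="spacer")
    _tsv("crispr_types.tsv", pd.DataFrame(
        sorted(crispr_types.items()), columns=["strain", "crispr_type"]),
        index=False)
    gc_all = pd.concat(
        [t.assign(strain=s) for s, t in sorted(gc_tracks.items())])
    _tsv("gc_track.tsv", gc_all, index=False)
    discard_rows = [(s, what, why) for s, cs in sorted(consensus.items())
                    for what, why in cs.discard_log]
    _tsv("genecall_discards.tsv", pd.DataFrame(
        discard_rows, columns=["strain", "orf", "reason"]), index=False)
    if phenotype_calls is not None:
        _tsv("growth_calls.tsv", phenotype_calls, index=False)
    if gtm_reports:
        gtm_all = pd.concat(
            [r.table.assign(trait=t, n_positive=r.n_positive,
                            n_negative=r.n_negative)
             for t, r in sorted(gtm_reports.items())])
        _tsv("gtm_report.tsv", gtm_all, index=False)
        from panforge.gtm import report_html
        _text("gtm_report.html", report_html(gtm_reports))
    return written
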