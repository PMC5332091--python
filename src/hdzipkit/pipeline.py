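"""End-to-end orchestration of the family-characterization pipeline.

Stages run in dependency order: identify → classify (tree + architecture)
→ structure/motifs ∥ duplication ∥ cis-elements → expression/qPCR.  A
single :class:`PipelineConfig` carries every threshold, with defaults equal
to the study's stated values; every run writes stage TSVs plus a
:class:`RunManifest` (JSON) recording the config snapshot, input checksums,
per-stage record counts, and warnings.  Coordinates are 0-based half-open
internally; GFF3 is converted on read/write.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (cisreg, domains, duplication, expression, genestruct,
               identify, motifs, phylo, synthetic)

log = logging.getLogger("hdzipkit")


@dataclass
class PipelineConfig:
    """All stage thresholds; defaults are the study's stated values."""

    seed: int = 0
    evalue_threshold: float = 0.01           # dual-domain retention
    null_shuffles: int = 99
    fpkm_threshold: float = 1.0              # expressed iff FPKM > 1
    fold_change_cutoff: float = 2.0          # |FC| > 2 means changed
    fc_pseudocount: float = 0.1
    tandem_window: int = 50_000
    flank: int = 50_000
    min_block_length: int = 200              # chain filter, strict >
    min_block_identity: float = 0.85         # chain filter, strict >
    min_chain_span: int = 2_000
    promoter_length: int = 1500
    bootstrap_replicates: int = 1000
    partial_deletion: float = 0.95
    alpha: float = 0.05                      # Duncan's MRT
    motif_widths: tuple = motifs.DEFAULT_WIDTHS
    max_motifs: int = 15
    output_dir: str = "results/pipeline"
    # optional external inputs; when None the synthetic scenario is used
    proteome_path: str | None = None
    genome_path: str | None = None
    gff_path: str | None = None
    fpkm_path: str | None = None
    ct_path: str | None = None

    def validate(self) -> None:
        positive = ["evalue_threshold", "fpkm_threshold", "fold_change_cutoff",
                    "tandem_window", "flank", "min_block_length",
                    "min_chain_span", "promoter_length",
                    "bootstrap_replicates", "alpha"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if not (0 < self.min_block_identity < 1):
            raise ValueError("config field min_block_identity must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    timestamp: str
    config: dict
    input_checksums: dict[str, str]
    stage_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig,
                 scenario: synthetic.ScenarioConfig | None = None,
                 skip_bootstrap: bool = False,
                 skip_motifs: bool = False) -> RunManifest:
    """Run every stage; returns the manifest (also written to output_dir).

    With no external inputs configured, a synthetic scenario (default:
    study-scale) supplies proteome, genome, annotation, expression, and
    qPCR inputs, and the truth table is written alongside the outputs.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(time.strftime("%Y-%m-%dT%H:%M:%S"),
                           dataclasses.asdict(config), {})

    # ---- inputs -----------------------------------------------------------
    if config.proteome_path:
        proteome = identify.read_fasta(config.proteome_path)
        manifest.input_checksums["proteome"] = _checksum(Path(config.proteome_path))
        genome = gff_text = fpkm = ct_table = None
        truth = None
    else:
        scenario = scenario or synthetic.default_scenario(config.seed)
        log.info("generating synthetic scenario (seed=%d)", scenario.seed)
        proteome, truth_p = synthetic.generate_proteome(
            scenario, outdir / "proteome.faa")
        genome, gff_text, truth_g = synthetic.generate_genome(
            scenario, outdir / "genome.fa", outdir / "genes.gff3")
        fpkm, ct_table, truth_e = synthetic.generate_expression(
            scenario, outdir / "fpkm.tsv", outdir / "qpcr_ct.csv")
        truth = _merge_truth(truth_p, truth_g, truth_e)
        truth.to_json(outdir / "truth.json")
        for name in ("proteome.faa", "genome.fa", "genes.gff3",
                     "fpkm.tsv", "qpcr_ct.csv"):
            manifest.input_checksums[name] = _checksum(outdir / name)

    # ---- identify ---------------------------------------------------------
    log.info("stage identify: %d candidate proteins", len(proteome))
    profiles = identify.default_profiles()
    calls = identify.identify_family(
        proteome, profiles, config.evalue_threshold,
        config.null_shuffles, config.seed)
    _write_identify(calls, dict(proteome), outdir / "family_calls.tsv")
    manifest.stage_counts["identify"] = len(calls)
    retained = [c for c in calls if c.retained]
    manifest.stage_counts["retained"] = len(retained)
    seqs = dict(proteome)

    # ---- architectures + classification -----------------------------------
    log.info("stage classify: %d retained members", len(retained))
    confirm = {d: profiles[d] for d in ("CPSCE", "START", "MEKHLA")}
    architectures = {}
    for call in retained:
        extra = identify.detect_architecture(
            seqs[call.protein_id], confirm, config.evalue_threshold,
            config.null_shuffles, config.seed, call.protein_id)
        architectures[call.protein_id] = {"HD", "LZ"} | extra
    anchors = {f"anchor_{sf}": sf for sf in domains.SUBFAMILIES}
    anchor_seqs = {f"anchor_{sf}": domains.archetype_exemplar(sf)
                   for sf in domains.SUBFAMILIES}
    alignment = phylo.build_domain_alignment(seqs, retained,
                                             anchor_seqs=anchor_seqs)
    if skip_bootstrap:
        dm = phylo.pairwise_distance(alignment,
                                     partial_deletion=config.partial_deletion)
        tree = phylo.nj_tree(dm)
    else:
        tree = phylo.bootstrap_support(
            alignment, config.bootstrap_replicates, config.seed,
            partial_deletion=config.partial_deletion)
    (outdir / "tree.nwk").write_text(tree.to_newick(with_support=True) + "\n")
    assignments = phylo.assign_subfamily(tree, anchors, architectures)
    pd.DataFrame(
        [(a.gene_id, a.subfamily,
          "" if a.tree_support is None else f"{a.tree_support:.0f}",
          a.architecture_agrees) for a in assignments],
        columns=["gene_id", "subfamily", "support", "architecture_agrees"]
    ).to_csv(outdir / "subfamilies.tsv", sep="\t", index=False)
    manifest.stage_counts["classified"] = len(assignments)
    disagree = [a.gene_id for a in assignments if a.architecture_agrees is False]
    if disagree:
        manifest.warnings.append(
            f"architecture disagreement for: {', '.join(disagree)}")
    subfamily_map = {a.gene_id: a.subfamily for a in assignments}

    # ---- properties -------------------------------------------------------
    props = []
    for call in retained:
        mw, pi = identify.protein_properties(seqs[call.protein_id])
        props.append((call.protein_id, len(seqs[call.protein_id]),
                      round(mw, 2), round(pi, 2)))
    pd.DataFrame(props, columns=["protein_id", "length_aa", "mw_da", "pi"]
                 ).to_csv(outdir / "protein_properties.tsv", sep="\t",
                          index=False)

    if genome is None:
        manifest.write(outdir / "manifest.json")
        return manifest

    # ---- gene structure ---------------------------------------------------
    models = genestruct.read_gene_models(gff_text)
    per_gene, summary, missing = genestruct.exon_stats(models, subfamily_map)
    per_gene.to_csv(outdir / "exon_counts.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "exon_summary.tsv", sep="\t", index=False)
    manifest.stage_counts["exon_stats"] = len(per_gene)
    if missing:
        manifest.warnings.append(f"genes missing from GFF3: {missing}")

    # ---- motifs -----------------------------------------------------------
    if not skip_motifs:
        fam_seqs = [(c.protein_id, seqs[c.protein_id]) for c in retained]
        found = motifs.discover_motifs(
            fam_seqs, config.motif_widths, config.max_motifs, config.seed)
        motifs.write_meme_minimal(found, outdir / "motifs.txt")
        pd.DataFrame(
            [(m.motif_id, m.width, sid, off) for m in found
             for sid, off in m.sites],
            columns=["motif_id", "width", "protein_id", "offset"]
        ).to_csv(outdir / "motif_sites.tsv", sep="\t", index=False)
        manifest.stage_counts["motifs"] = len(found)

    # ---- duplication ------------------------------------------------------
    loci = duplication.loci_from_models(models)
    tandem = duplication.find_tandem(loci, window=config.tandem_window)
    segmental, scaffolded = duplication.call_segmental(
        loci, genome, config.flank,
        min_chain_span=config.min_chain_span,
        min_block_length=config.min_block_length,
        min_block_identity=config.min_block_identity,
        prefilter_min_shared=duplication.suggested_prefilter(2 * config.flank))
    rows = [(p.gene_a, p.gene_b, p.kind, p.distance or "", "", "")
            for p in tandem]
    rows += [(p.gene_a, p.gene_b, p.kind, "", p.chain.total_aligned,
              round(p.chain.min_identity, 4)) for p in segmental]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "type", "distance_bp",
                                "chain_total_bp", "min_identity"]
                 ).to_csv(outdir / "duplications.tsv", sep="\t", index=False)
    manifest.stage_counts["tandem_pairs"] = len(tandem)
    manifest.stage_counts["segmental_pairs"] = len(segmental)
    if scaffolded:
        manifest.warnings.append(f"scaffold-located genes excluded: {scaffolded}")

    # ---- cis-elements -----------------------------------------------------
    catalog = cisreg.default_catalog()
    hits_by_gene = {}
    hit_rows = []
    for gid, model in models.items():
        promoter, truncated = cisreg.extract_promoter(
            genome, model, config.promoter_length)
        hits = cisreg.scan_elements(gid, promoter, catalog)
        hits_by_gene[gid] = hits
        hit_rows += [(h.gene_id, h.element, h.offset, h.strand, h.match)
                     for h in hits]
    pd.DataFrame(hit_rows, columns=["gene_id", "element", "offset", "strand",
                                    "match"]
                 ).to_csv(outdir / "element_hits.tsv", sep="\t", index=False)
    enr = cisreg.enrichment_test(hits_by_gene, subfamily_map,
                                 [e.name for e in catalog])
    pd.DataFrame(
        [(r.element, r.subfamily, r.k, r.n, round(r.p0, 4),
          r.p_value, r.q_value) for r in enr],
        columns=["element", "subfamily", "k", "n", "p0", "p_value", "q_value"]
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    manifest.stage_counts["element_hits"] = len(hit_rows)
    manifest.stage_counts["enrichment_tests"] = len(enr)

    # ---- expression -------------------------------------------------------
    scen = scenario or synthetic.default_scenario(config.seed)
    tissue_cols = scen.expression_plan.samples
    classes = expression.classify_expression(
        fpkm[tissue_cols], config.fpkm_threshold,
        scen.expression_plan.tissue_groups)
    pd.DataFrame([(c.gene_id, c.label, ";".join(c.expressed_samples),
                   c.tissue_group or "") for c in classes],
                 columns=["gene_id", "class", "expressed_samples", "group"]
                 ).to_csv(outdir / "expression_classes.tsv", sep="\t",
                          index=False)
    manifest.stage_counts["expression_classes"] = len(classes)
    fc_frames = []
    for tissue in scen.expression_plan.drought_changed:
        fc = expression.fold_change_table(
            fpkm, f"{tissue}_drought", f"{tissue}_ctrl", config.fc_pseudocount)
        fc_frames.append(fc)
        manifest.stage_counts[f"changed_{tissue}"] = int(fc["changed"].sum())
    if fc_frames:
        pd.concat(fc_frames).to_csv(outdir / "fold_changes.tsv", sep="\t",
                                    index=False)

    # ---- qPCR -------------------------------------------------------------
    qres = expression.analyze_qpcr(ct_table, scen.qpcr_plan.calibrator,
                                   config.alpha)
    pd.DataFrame([(r.gene_id, r.sample, r.relative_expression, r.letter)
                  for r in qres],
                 columns=["gene_id", "sample", "rel_expr", "letter"]
                 ).to_csv(outdir / "qpcr_results.tsv", sep="\t", index=False)
    manifest.stage_counts["qpcr_results"] = len(qres)

    manifest.write(outdir / "manifest.json")
    return manifest


def _merge_truth(*tables: synthetic.TruthTable) -> synthetic.TruthTable:
    merged = synthetic.TruthTable()
    for t in tables:
        for f in dataclasses.fields(synthetic.TruthTable):
            src = getattr(t, f.name)
            dst = getattr(merged, f.name)
            if isinstance(src, dict):
                dst.update(src)
            else:
                for item in src:
                    if item not in dst:
                        dst.append(item)
    return merged


def _write_identify(calls, seqs, path) -> None:
    rows = []
    for c in calls:
        mw = pi = ""
        if c.retained:
            mw, pi = (round(x, 2)
                      for x in identify.protein_properties(seqs[c.protein_id]))
        rows.append((
            c.protein_id, c.retained,
            "" if c.hd is None else round(c.hd.score, 2),
            "" if c.hd is None else f"{c.hd.evalue:.3g}",
            "" if c.lz is None else round(c.lz.score, 2),
            "" if c.lz is None else f"{c.lz.evalue:.3g}",
            c.rejection_reason or "", len(seqs[c.protein_id]), mw, pi))
    pd.DataFrame(rows, columns=[
        "protein_id", "retained", "HD_score", "HD_evalue", "LZ_score",
        "LZ_evalue", "reason", "length_aa", "mw_da", "pi"
    ]).to_csv(path, sep="\t", index=False)
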