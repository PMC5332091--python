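"""Exon–intron structure statistics from GFF3 gene models."""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import pandas as pd


@dataclass
class GeneModel:
    """One gene with its exon layout (0-based half-open coordinates)."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]  # sorted, disjoint
    cds_start: int  # translation start (gene start on '+', gene end on '-')

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


def read_gene_models(gff_path_or_text: str) -> dict[str, GeneModel]:
    """Parse a GFF3 file (or literal text) into gene models via gffutils.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Overlapping exons within one gene raise a malformed-annotation error.
    """
    db = gffutils.create_db(gff_path_or_text, ":memory:",
                            from_string="\n" in gff_path_or_text,
                            merge_strategy="create_unique")
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        exons = sorted((e.start - 1, e.end)
                       for e in db.children(gene, featuretype="exon"))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping exons in gene {gene.id}: "
                    f"[{s1},{e1}) and [{s2},{e2})")
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        start, end = gene.start - 1, gene.end
        cds_start = start if gene.strand == "+" else end
        models[gene.id] = GeneModel(gene.id, gene.seqid, gene.strand,
                                    start, end, exons, cds_start)
    return models


def exon_stats(models: dict[str, GeneModel],
               subfamily_map: dict[str, str]
               ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-gene exon/intron counts and per-subfamily summaries.

    Returns (per_gene, per_subfamily, missing): genes named in
    ``subfamily_map`` but absent from the annotation are listed in
    ``missing`` rather than counted; subfamilies with no annotated gene
    are absent from the summary (not reported as zero).
    """
    rows = []
    missing = []
    for gid, sf in subfamily_map.items():
        gm = models.get(gid)
        if gm is None:
            missing.append(gid)
            continue
        rows.append((gid, sf, gm.n_exons, gm.n_introns))
    per_gene = pd.DataFrame(rows, columns=[
        "gene_id", "subfamily", "n_exons", "n_introns"])
    if per_gene.empty:
        summary = pd.DataFrame(columns=["subfamily", "n_genes", "min_exons",
                                        "max_exons", "mean_exons"])
    else:
        summary = (per_gene.groupby("subfamily")["n_exons"]
                   .agg(n_genes="size", min_exons="min", max_exons="max",
                        mean_exons="mean")
                   .reset_index())
    return per_gene, summary, sorted(missing)
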