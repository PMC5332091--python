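#!/usr/bin/env python
"""Scan 1500-bp promoters for cis-elements and test subfamily enrichment.

Extracts the promoter upstream of each translation start, scans it (both
strands) against the packaged IUPAC element catalog, and tests each
(element, subfamily) cell for overrepresentation with an upper-tail exact
binomial test on promoter presence/absence (background = whole-family
proportion; Benjamini-Hochberg within subfamily).  Writes
results/element_hits.tsv and results/enrichment.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from hdzipkit import cisreg, genestruct, identify

SCENARIO = Path("results/scenario")


def main(seed: int = 1) -> None:
    genome = dict(identify.read_fasta(SCENARIO / "genome.fa"))
    models = genestruct.read_gene_models(
        (SCENARIO / "genes.gff3").read_text())
    sf = pd.read_csv("results/subfamilies.tsv", sep="\t")
    sfmap = dict(zip(sf.gene_id, sf.subfamily))
    catalog = cisreg.default_catalog()
    hits_by_gene = {}
    rows = []
    for gid, model in models.items():
        prom, truncated = cisreg.extract_promoter(genome, model)
        hits = cisreg.scan_elements(gid, prom, catalog)
        hits_by_gene[gid] = hits
        rows += [(h.gene_id, h.element, h.offset, h.strand, h.match)
                 for h in hits]
    pd.DataFrame(rows, columns=["gene_id", "element", "offset", "strand",
                                "match"]
                 ).to_csv("results/element_hits.tsv", sep="\t", index=False)
    enr = cisreg.enrichment_test(hits_by_gene, sfmap,
                                 [e.name for e in catalog])
    df = pd.DataFrame([(r.element, r.subfamily, r.k, r.n, round(r.p0, 4),
                        r.p_value, r.q_value) for r in enr],
                      columns=["element", "subfamily", "k", "n", "p0",
                               "p_value", "q_value"])
    df.to_csv("results/enrichment.tsv", sep="\t", index=False)
    print(f"{len(rows)} element occurrences in {len(models)} promoters")
    print("top enrichment per subfamily (smallest p):")
    for subfam, grp in df.groupby("subfamily"):
        top = grp.nsmallest(1, "p_value").iloc[0]
        print(f"  {subfam}: {top.element} (k={top.k}/{top.n}, "
              f"p={top.p_value:.3g}, q={top.q_value:.3g})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
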