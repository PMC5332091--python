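#!/usr/bin/env python
"""Classify expression profiles and count drought-responsive genes.

Classifies every family gene over the tissue panel (expressed iff
FPKM > 1): constitutive / non-expressed / tissue-specific / partial.
Computes log2 treatment-over-control fold changes for the drought
contrasts and counts genes with |fold change| > 2 (study scale: 18 in
leaf, 24 in root).  Writes results/expression_classes.tsv and
results/fold_changes.tsv, plus heatmap-ready log2 matrices.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from hdzipkit import expression, synthetic

SCENARIO = Path("results/scenario")


def main(seed: int = 1) -> None:
    cfg = synthetic.default_scenario(seed)
    plan = cfg.expression_plan
    fpkm = pd.read_csv(SCENARIO / "fpkm.tsv", sep="\t", index_col=0)
    classes = expression.classify_expression(
        fpkm[plan.samples], tissue_groups=plan.tissue_groups)
    pd.DataFrame([(c.gene_id, c.label, ";".join(c.expressed_samples),
                   c.tissue_group or "") for c in classes],
                 columns=["gene_id", "class", "expressed_samples", "group"]
                 ).to_csv("results/expression_classes.tsv", sep="\t",
                          index=False)
    counts = pd.Series([c.label for c in classes]).value_counts().to_dict()
    print("expression classes:", counts)

    frames = []
    for tissue in plan.drought_changed:
        fc = expression.fold_change_table(fpkm, f"{tissue}_drought",
                                          f"{tissue}_ctrl")
        frames.append(fc)
        print(f"{tissue}: {int(fc.changed.sum())} genes with |FC| > 2")
    pd.concat(frames).to_csv("results/fold_changes.tsv", sep="\t",
                             index=False)
    # heatmap-ready exports: log2 FPKM and log2 fold change
    np.log2(fpkm[plan.samples] + 0.1).to_csv(
        "results/heatmap_log2_fpkm.tsv", sep="\t")
    wide = pd.concat(frames).pivot(index="gene_id", columns="contrast",
                                   values="log2_fc")
    wide.to_csv("results/heatmap_log2_fc.tsv", sep="\t")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
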