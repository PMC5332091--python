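"""Expression-profile classification, fold changes, 2^-ΔΔCt, and Duncan's
multiple range test.

Expression calls use the FPKM > 1 convention (strictly greater).  Classes:
constitutive (expressed everywhere), non_expressed (nowhere),
tissue_specific (expressed in exactly one configured tissue group),
partial (anything else).  Treatment/control contrasts use
log2((t + c0)/(c + c0)) with a small pseudocount; a gene is "changed" when
the absolute fold change exceeds 2 (|log2 FC| > 1).

qPCR relative expression is 2^-ΔΔCt with ΔCt = mean target Ct − mean
reference Ct per sample and ΔΔCt relative to a calibrator sample;
between-sample letters come from Duncan's multiple range test at the
chosen protection level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FPKM_THRESHOLD = 1.0
FOLD_CHANGE_PSEUDOCOUNT = 0.1
LOG2_FC_CUTOFF = 1.0  # |fold change| > 2


@dataclass
class ExpressionClass:
    gene_id: str
    label: str  # constitutive | non_expressed | tissue_specific | partial
    expressed_samples: list[str]
    tissue_group: str | None = None


@dataclass
class FoldChangeRecord:
    gene_id: str
    contrast: str
    log2_fc: float
    changed: bool


def classify_expression(matrix: pd.DataFrame,
                        threshold: float = FPKM_THRESHOLD,
                        tissue_groups: dict[str, list[str]] | None = None
                        ) -> list[ExpressionClass]:
    """Classify each gene's expression profile over the matrix columns.

    ``matrix`` is genes × samples of FPKM values (non-negative).  A gene
    is expressed in a sample iff FPKM strictly exceeds ``threshold``.
    """
    if (matrix.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    tissue_groups = tissue_groups or {}
    samples = list(matrix.columns)
    group_sets = {g: set(m) & set(samples) for g, m in tissue_groups.items()}
    out = []
    for gid, row in matrix.iterrows():
        expressed = [s for s in samples if row[s] > threshold]
        eset = set(expressed)
        if len(expressed) == len(samples):
            out.append(ExpressionClass(gid, "constitutive", expressed))
        elif not expressed:
            out.append(ExpressionClass(gid, "non_expressed", expressed))
        else:
            group = next((g for g, m in group_sets.items() if eset == m), None)
            label = "tissue_specific" if group else "partial"
            out.append(ExpressionClass(gid, label, expressed, group))
    return out


def fold_change(treatment: float, control: float,
                pseudocount: float = FOLD_CHANGE_PSEUDOCOUNT,
                gene_id: str = "gene", contrast: str = "treatment/control"
                ) -> FoldChangeRecord:
    """log2 fold change with pseudocount and the |FC| > 2 changed flag."""
    if treatment < 0 or control < 0:
        raise ValueError("FPKM values must be non-negative")
    lfc = math.log2((treatment + pseudocount) / (control + pseudocount))
    return FoldChangeRecord(gene_id, contrast, lfc,
                            abs(lfc) > LOG2_FC_CUTOFF)


def fold_change_table(matrix: pd.DataFrame, treatment_col: str,
                      control_col: str,
                      pseudocount: float = FOLD_CHANGE_PSEUDOCOUNT
                      ) -> pd.DataFrame:
    contrast = f"{treatment_col}/{control_col}"
    recs = [fold_change(row[treatment_col], row[control_col], pseudocount,
                        gid, contrast)
            for gid, row in matrix.iterrows()]
    return pd.DataFrame(
        [(r.gene_id, r.contrast, r.log2_fc, r.changed) for r in recs],
        columns=["gene_id", "contrast", "log2_fc", "changed"])


def ddct(target_ct, ref_ct, calibrator_target_ct, calibrator_ref_ct) -> float:
    """Relative expression 2^-ΔΔCt from replicate Ct lists.

    ΔCt = mean(target) − mean(reference) per sample; ΔΔCt is relative to
    the calibrator sample.  Invariant under any constant Ct shift applied
    to every measurement.
    """
    for reps in (target_ct, ref_ct, calibrator_target_ct, calibrator_ref_ct):
        if len(reps) == 0:
            raise ValueError("replicate sets must be nonempty")
    dct = float(np.mean(target_ct)) - float(np.mean(ref_ct))
    dct_cal = float(np.mean(calibrator_target_ct)) - float(np.mean(calibrator_ref_ct))
    return float(2.0 ** -(dct - dct_cal))


def duncan_q(alpha: float, p: int, df: int) -> float:
    """Duncan's protected studentized-range critical value.

    Protection level α_p = 1 − (1 − α)^(p − 1); the quantile is the
    (1 − α_p) point of the studentized range distribution for p means and
    ``df`` error degrees of freedom.
    """
    if p < 2:
        raise ValueError("range size p must be >= 2")
    return float(stats.studentized_range.ppf((1 - alpha) ** (p - 1), p, df))


def duncan_mrt(groups: list[tuple[str, list[float]]],
               alpha: float = 0.05) -> dict[str, str]:
    """Letter grouping of sample means by Duncan's multiple range test.

    Balanced designs only (equal replicate counts, default study design
    n = 3).  Groups sharing any letter do not differ significantly; with
    zero error variance, unequal means all receive distinct letters.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = {len(v) for _, v in groups}
    if len(ns) != 1:
        raise ValueError("unbalanced designs are not supported")
    n = ns.pop()
    if n < 2:
        raise ValueError("each group needs at least 2 replicates")
    k = len(groups)
    df = k * (n - 1)
    values = [np.asarray(v, dtype=float) for _, v in groups]
    means = np.array([v.mean() for v in values])
    mse = float(np.sum([(v - v.mean()) ** 2 for v in values]).sum()) / df
    order = np.argsort(-means, kind="stable")
    sorted_means = means[order]

    def critical_range(p: int) -> float:
        if mse == 0.0:
            return 0.0
        return duncan_q(alpha, p, df) * math.sqrt(mse / n)

    # maximal homogeneous intervals over the sorted means, with Duncan's
    # containment protection (a non-significant range shields its interior)
    intervals = []
    for i in range(k):
        j_best = i
        for j in range(i + 1, k):
            span = j - i + 1
            if sorted_means[i] - sorted_means[j] <= critical_range(span) \
                    and (mse > 0.0 or sorted_means[i] == sorted_means[j]):
                j_best = j
        intervals.append((i, j_best))
    # drop intervals contained in earlier/larger ones
    maximal = []
    for i, j in intervals:
        if not any(a <= i and j <= b and (a, b) != (i, j)
                   for a, b in intervals):
            maximal.append((i, j))
    letters = {label: "" for label, _ in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for li, (i, j) in enumerate(sorted(set(maximal))):
        letter = alphabet[li % len(alphabet)]
        for idx in range(i, j + 1):
            letters[groups[order[idx]][0]] += letter
    return letters


@dataclass
class QpcrResult:
    gene_id: str
    sample: str
    relative_expression: float
    letter: str


def analyze_qpcr(ct_table: pd.DataFrame, calibrator: str,
                 alpha: float = 0.05) -> list[QpcrResult]:
    """Per-gene 2^-ΔΔCt across samples with Duncan letter groups.

    ``ct_table`` has columns sample,target,reference,replicate,ct; rows
    with ``target == reference`` are the internal-control measurements.
    Letters are computed on per-replicate relative expression (replicate r
    of the target paired with replicate r of the reference).
    """
    results = []
    ref_rows = ct_table[ct_table["target"] == ct_table["reference"]]
    tgt_rows = ct_table[ct_table["target"] != ct_table["reference"]]
    for gene, sub in tgt_rows.groupby("target"):
        ref_gene = sub["reference"].iloc[0]
        samples = list(dict.fromkeys(sub["sample"]))
        if calibrator not in samples:
            raise ValueError(f"calibrator sample {calibrator!r} missing "
                             f"for gene {gene}")

        def cts(frame, sample):
            rows = frame[frame["sample"] == sample].sort_values("replicate")
            return rows["ct"].to_numpy()

        ref_by_sample = {s: cts(ref_rows[ref_rows["target"] == ref_gene], s)
                         for s in samples}
        cal_t = cts(sub, calibrator)
        cal_r = ref_by_sample[calibrator]
        rel = {s: ddct(cts(sub, s), ref_by_sample[s], cal_t, cal_r)
               for s in samples}
        # per-replicate relative expression for the letter test
        dct_cal = cal_t.mean() - cal_r.mean()
        groups = []
        for s in samples:
            t, r = cts(sub, s), ref_by_sample[s]
            reps = 2.0 ** -((t - r) - dct_cal)
            groups.append((s, list(reps)))
        letters = duncan_mrt(groups, alpha)
        for s in samples:
            results.append(QpcrResult(gene, s, rel[s], letters[s]))
    return results
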