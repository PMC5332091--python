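"""Synthetic genomes, proteomes, promoters, and expression data with truth.

The generator emulates the study design the analysis assumes: a
multi-chromosome genome carrying family genes of four architecture
archetypes, segmentally duplicated 100-kb windows, 1500-bp promoters with
planted cis-elements, FPKM matrices with constitutive / tissue-specific /
partial / silent genes, and triplicate qPCR Ct tables with a constant-Ct
reference gene.

Everything is driven by a :class:`ScenarioConfig`; a fixed seed yields
byte-identical output files.  The default scenario
(:func:`default_scenario`) mirrors the published study's scale: 57 true
dual-domain members (23/14/9/11 across subfamilies I–IV) inside a pool of
125 candidates, five segmentally duplicated pairs and no tandem pairs,
three members on unanchored scaffolds, 18 exons in every subfamily-III
gene, and drought contrasts with 18 (leaf) and 24 (root) changed genes.

Background sequence is i.i.d. uniform over residues/bases — the simplest
null for empirical score calibration.  FPKM values are log-normal by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .domains import (ARCHETYPES, AA_ALPHABET, DNA_ALPHABET, SUBFAMILIES,
                      subfamily_consensus)

_AA = np.array(list(AA_ALPHABET))
_NT = np.array(list(DNA_ALPHABET))


# --------------------------------------------------------------------------
# configuration


@dataclass
class DuplicationSpec:
    """One planned segmental duplication.

    ``flank_identity`` is the per-base retention probability applied to the
    copied window; ``duplicated_span`` is how much of the 100-kb window is
    copied (gene-adjacent portion first); ``placement`` optionally pins the
    two genes to chromosomes (0-based indices) — by default they go on
    different chromosomes.
    """

    subfamily: str
    flank_identity: float = 0.9
    duplicated_span: int = 100_000
    placement: tuple[int, int] | None = None


@dataclass
class ExpressionPlan:
    samples: list[str] = field(default_factory=lambda: [
        "leaf", "stem", "ESR", "MSR", "LSR"])
    tissue_groups: dict[str, list[str]] = field(default_factory=lambda: {
        "root": ["ESR", "MSR", "LSR"], "leaf": ["leaf"]})
    class_counts: dict[str, int] = field(default_factory=lambda: {
        "constitutive": 20, "non_expressed": 6,
        "tissue_specific": 16, "partial": 15})
    fpkm_threshold: float = 1.0
    lognormal_mu: float = 1.5
    lognormal_sigma: float = 0.8
    #: drought contrast: tissue -> number of genes with |fold change| > 2
    drought_changed: dict[str, int] = field(default_factory=lambda: {
        "leaf": 18, "root": 24})


@dataclass
class QpcrPlan:
    n_genes: int = 12
    timepoints: list[str] = field(default_factory=lambda: [
        "NTC", "5h", "15h", "48h", "R7d", "R14d"])
    calibrator: str = "NTC"
    ct_sd: float = 0.15
    baseline_ct: float = 24.0
    reference_ct: float = 20.0
    reference_gene: str = "ACT"
    replicates: int = 3


@dataclass
class ScenarioConfig:
    seed: int = 0
    n_chromosomes: int = 18
    chromosome_length: int = 700_000
    archetype_counts: dict[str, int] = field(default_factory=lambda: {
        "I": 23, "II": 14, "III": 9, "IV": 11})
    decoy_counts: dict[str, int] = field(default_factory=lambda: {
        "single_hd": 30, "single_lz": 28, "random": 0, "duplicate": 10})
    duplication_plan: list[DuplicationSpec] = field(default_factory=lambda: [
        DuplicationSpec("II", 0.92), DuplicationSpec("II", 0.90),
        DuplicationSpec("I", 0.93), DuplicationSpec("III", 0.91),
        DuplicationSpec("IV", 0.94)])
    scaffold_genes: int = 3
    domain_mutation_rate: float = 0.05
    #: exons per gene, per subfamily: an int (every gene) or a per-gene list
    exon_counts: dict[str, int | list[int]] = field(default_factory=lambda: {
        "I": 2, "II": 3, "III": 18,
        "IV": [10, 10, 10, 10, 10, 10, 10, 9, 9, 9, 9]})
    #: per-subfamily probability that a promoter carries a given element;
    #: elements not listed fall back to "*".
    promoter_plan: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "I": {"*": 0.3, "ABRE": 0.9, "HSE": 0.8},
        "II": {"*": 0.3, "ABRE": 0.85, "HSE": 0.85},
        "III": {"*": 0.3, "GARE-motif": 0.9},
        "IV": {"*": 0.3, "MBS": 0.9},
    })
    expression_plan: ExpressionPlan = field(default_factory=ExpressionPlan)
    qpcr_plan: QpcrPlan = field(default_factory=QpcrPlan)
    flank: int = 50_000
    promoter_length: int = 1500

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.chromosome_length <= 0:
            raise ValueError("chromosome plan must be positive")
        for d in (self.archetype_counts, self.decoy_counts):
            if any(v < 0 for v in d.values()):
                raise ValueError("counts must be >= 0")
        for v in self.exon_counts.values():
            vals = v if isinstance(v, list) else [v]
            if any(x < 1 for x in vals):
                raise ValueError("exon counts must be >= 1")
        for spec in self.duplication_plan:
            if not (0 < spec.flank_identity <= 1):
                raise ValueError("flank_identity must be in (0, 1]")
            if spec.duplicated_span > 2 * self.flank:
                raise ValueError("duplicated_span exceeds the flank window")
            if spec.subfamily not in SUBFAMILIES:
                raise ValueError(f"unknown subfamily {spec.subfamily!r}")
        if self.qpcr_plan.ct_sd < 0:
            raise ValueError("Ct noise sd must be >= 0")
        if not self.expression_plan.samples:
            raise ValueError("expression plan must name at least one sample")


# --------------------------------------------------------------------------
# truth


@dataclass
class TruthTable:
    """Planted ground truth for one scenario (all slices optional)."""

    true_family_ids: list[str] = field(default_factory=list)
    true_subfamily: dict[str, str] = field(default_factory=dict)
    architectures: dict[str, list[str]] = field(default_factory=dict)
    decoy_ids: dict[str, list[str]] = field(default_factory=dict)
    true_duplications: list[dict] = field(default_factory=list)
    scaffold_gene_ids: list[str] = field(default_factory=list)
    gene_loci: dict[str, dict] = field(default_factory=dict)
    exon_counts: dict[str, int] = field(default_factory=dict)
    planted_elements: dict[str, list[dict]] = field(default_factory=dict)
    true_expression_class: dict[str, str] = field(default_factory=dict)
    true_expression_group: dict[str, str] = field(default_factory=dict)
    true_fold_changed: dict[str, list[str]] = field(default_factory=dict)
    true_qpcr_ratio: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        return cls(**json.loads(Path(path).read_text()))

    def duplication_pairs(self) -> set[frozenset]:
        return {frozenset((d["gene_a"], d["gene_b"]))
                for d in self.true_duplications}


def family_gene_ids(config: ScenarioConfig) -> dict[str, list[str]]:
    """Deterministic family gene ids per subfamily (HDZ01, HDZ02, ...)."""
    out: dict[str, list[str]] = {}
    n = 0
    for sf in SUBFAMILIES:
        ids = []
        for _ in range(config.archetype_counts.get(sf, 0)):
            n += 1
            ids.append(f"HDZ{n:02d}")
        out[sf] = ids
    return out


def _rng(config: ScenarioConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *stream])


def _random_aa(rng, n: int) -> str:
    return "".join(_AA[rng.integers(0, 20, size=n)])


def _random_dna(rng, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n).astype(np.int8)


def _mutate_aa(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        choices = [a for a in AA_ALPHABET if a != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _mutate_dna(rng, arr: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return arr.copy()
    out = arr.copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    # substitute with one of the three other bases
    out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def _dna_str(arr: np.ndarray) -> str:
    return "".join(_NT[arr])


# --------------------------------------------------------------------------
# proteome


def generate_proteome(config: ScenarioConfig,
                      out_fasta: str | Path | None = None
                      ) -> tuple[list[tuple[str, str]], TruthTable]:
    """Family proteins of the four archetypes plus decoys.

    True members embed their archetype's domain blocks (subfamily-signature
    consensus mutated at ``domain_mutation_rate``) in random background.
    Decoys carry exactly one of HD or LZ, pure background, or are exact
    duplicates of a true member (appearing after the original).
    """
    config.validate()
    rng = _rng(config, 1)
    truth = TruthTable()
    records: list[tuple[str, str]] = []
    ids = family_gene_ids(config)
    for sf in SUBFAMILIES:
        for gid in ids[sf]:
            parts = [_random_aa(rng, int(rng.integers(10, 40)))]
            for dom in ARCHETYPES[sf]:
                parts.append(_mutate_aa(rng, subfamily_consensus(sf, dom),
                                        config.domain_mutation_rate))
                parts.append(_random_aa(rng, int(rng.integers(4, 12))))
            parts.append(_random_aa(rng, int(rng.integers(5, 120))))
            seq = "".join(parts)
            records.append((gid, seq))
            truth.true_family_ids.append(gid)
            truth.true_subfamily[gid] = sf
            truth.architectures[gid] = list(ARCHETYPES[sf])
    # decoys with exactly one domain, or none
    single = {"single_hd": "HD", "single_lz": "LZ", "random": None}
    for cls, dom in single.items():
        made = []
        for i in range(config.decoy_counts.get(cls, 0)):
            did = f"{cls}_{i + 1:02d}"
            parts = [_random_aa(rng, int(rng.integers(20, 120)))]
            if dom is not None:
                sf = SUBFAMILIES[int(rng.integers(4))]
                parts.append(_mutate_aa(rng, subfamily_consensus(sf, dom),
                                        config.domain_mutation_rate))
                parts.append(_random_aa(rng, int(rng.integers(20, 120))))
            records.append((did, "".join(parts)))
            made.append(did)
        truth.decoy_ids[cls] = made
    # exact duplicates of true members (redundant transcripts)
    dups = []
    n_dup = config.decoy_counts.get("duplicate", 0)
    if n_dup and truth.true_family_ids:
        pool = truth.true_family_ids
        by_id = dict(records)
        for i in range(n_dup):
            src = pool[int(rng.integers(len(pool)))]
            did = f"duplicate_{i + 1:02d}_{src}"
            records.append((did, by_id[src]))
            dups.append(did)
    truth.decoy_ids["duplicate"] = dups
    if out_fasta is not None:
        write_fasta(records, out_fasta)
    return records, truth


def write_fasta(records: list[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --------------------------------------------------------------------------
# cis-element catalog helpers (shared with the genome generator)


def load_element_catalog() -> list[tuple[str, str, str]]:
    """Packaged (name, IUPAC pattern, functional class) catalog."""
    path = Path(__file__).parent / "data" / "cis_elements.tsv"
    out = []
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        name, pattern, cls = line.split("\t")
        out.append((name, pattern, cls))
    return out


_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
    "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _realize_pattern(rng, pattern: str) -> str:
    return "".join(c[rng.integers(len(c))]
                   for c in (_IUPAC_CHOICES[p] for p in pattern))


# --------------------------------------------------------------------------
# genome


@dataclass
class _Placed:
    gene_id: str
    subfamily: str
    chrom: str
    start: int  # 0-based gene start (= CDS start for '+' genes)
    end: int
    strand: str
    exons: list[tuple[int, int]]  # relative to gene start


def _gene_structure(rng, n_exons: int) -> tuple[list[tuple[int, int]], int]:
    exons = []
    pos = 0
    for i in range(n_exons):
        elen = int(rng.integers(120, 300))
        exons.append((pos, pos + elen))
        pos += elen
        if i < n_exons - 1:
            pos += int(rng.integers(80, 250))
    return exons, pos


def generate_genome(config: ScenarioConfig,
                    out_fasta: str | Path | None = None,
                    out_gff: str | Path | None = None
                    ) -> tuple[dict[str, str], str, TruthTable]:
    """Genome FASTA dict, GFF3 text, and placement/duplication truth.

    Genes are laid out left to right with 50-kb margins so that every
    family gene owns a non-overlapping 100-kb flank window; segmental pairs
    receive a point-mutated copy (rate ``1 - flank_identity``) of the
    source gene's whole window, promoters and gene body included (promoter
    elements are planted before copying).  Inter-gene spacing exceeds the
    50-kb tandem window, so the default layout plants zero tandem pairs.
    """
    config.validate()
    rng = _rng(config, 2)
    truth = TruthTable()
    ids = family_gene_ids(config)
    flank = config.flank
    catalog = load_element_catalog()

    # mark scaffold-located genes: deterministic spread over the family
    all_ids = [g for sf in SUBFAMILIES for g in ids[sf]]
    scaffold_ids = all_ids[:: max(1, len(all_ids) // (config.scaffold_genes or 1))
                           ][: config.scaffold_genes] if config.scaffold_genes else []
    # never place a planned duplication partner on a scaffold
    dup_genes: list[tuple[str, str]] = []  # (gene_a, gene_b) per spec
    used: set[str] = set(scaffold_ids)
    for spec in config.duplication_plan:
        avail = [g for g in ids[spec.subfamily] if g not in used]
        if len(avail) < 2:
            raise ValueError(
                f"not enough subfamily {spec.subfamily} genes for duplication plan")
        a, b = avail[0], avail[1]
        used.update((a, b))
        dup_genes.append((a, b))
    truth.scaffold_gene_ids = list(scaffold_ids)

    # build each gene's region (flank + body + flank) with planted promoter
    regions: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    for sf in SUBFAMILIES:
        plan = config.exon_counts.get(sf, 2)
        for pos, gid in enumerate(ids[sf]):
            n_exons = plan[pos % len(plan)] if isinstance(plan, list) else plan
            exons, body_len = _gene_structure(rng, n_exons)
            strand = "+" if rng.random() < 0.5 else "-"
            region = _random_dna(rng, 2 * flank + body_len)
            planted = _plant_promoter(rng, region, flank, body_len, strand,
                                      config, catalog, sf)
            regions[gid] = region
            meta[gid] = {"subfamily": sf, "exons": exons,
                         "body_len": body_len, "strand": strand}
            truth.planted_elements[gid] = planted
            truth.exon_counts[gid] = n_exons
            truth.true_subfamily[gid] = sf

    # realize segmental copies
    for (a, b), spec in zip(dup_genes, config.duplication_plan):
        src = regions[a]
        span = min(spec.duplicated_span, 2 * flank)
        body_len = meta[a]["body_len"]
        if span >= 2 * flank:
            # full flank span: the whole window (body included) is copied
            copy = _mutate_dna(rng, src, 1 - spec.flank_identity)
        else:
            # copy the gene-adjacent portion of each flank plus the body
            half = max(0, (span - body_len) // 2)
            lo, hi = max(0, flank - half), min(len(src), flank + body_len + half)
            copy = _random_dna(rng, len(src))
            copy[lo:hi] = _mutate_dna(rng, src[lo:hi], 1 - spec.flank_identity)
        regions[b] = copy
        meta[b] = dict(meta[a])  # same structure/strand as the source
        truth.planted_elements[b] = []  # inherited, possibly mutated
        truth.exon_counts[b] = truth.exon_counts[a]
        truth.true_duplications.append({
            "gene_a": a, "gene_b": b, "type": "segmental",
            "flank_identity": spec.flank_identity,
            "duplicated_span": span})

    # place regions onto chromosomes
    chrom_names = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    cursors = {c: 0 for c in chrom_names}
    placed: list[_Placed] = []
    spacing = 10_000
    order = [g for g in all_ids if g not in scaffold_ids]
    # spread duplication partners onto distinct chromosomes by placing
    # round-robin in id order (partners are consecutive ids only within a
    # subfamily; round-robin over 18 chromosomes separates them)
    ci = 0
    chrom_of: dict[str, str] = {}
    for i, (a, b) in enumerate(dup_genes):
        spec = config.duplication_plan[i]
        if spec.placement is not None:
            chrom_of[a] = chrom_names[spec.placement[0] % len(chrom_names)]
            chrom_of[b] = chrom_names[spec.placement[1] % len(chrom_names)]
    for gid in order:
        if gid in chrom_of:
            continue
        chrom_of[gid] = chrom_names[ci % len(chrom_names)]
        ci += 1
    # ensure default-placed partners differ in chromosome
    for a, b in dup_genes:
        if chrom_of[a] == chrom_of[b]:
            alt = [c for c in chrom_names if c != chrom_of[a]]
            chrom_of[b] = alt[0]
    overflow: list[str] = []
    for gid in order:
        chrom = chrom_of[gid]
        region = regions[gid]
        start = cursors[chrom]
        if start + len(region) > config.chromosome_length:
            overflow.append(gid)
            continue
        body_start = start + flank
        m = meta[gid]
        placed.append(_Placed(gid, m["subfamily"], chrom, body_start,
                              body_start + m["body_len"], m["strand"],
                              m["exons"]))
        cursors[chrom] = start + len(region) + spacing
    if overflow:
        raise ValueError(
            "chromosome_length too small; genes do not fit: "
            + ", ".join(overflow))

    # assemble chromosome sequences
    chrom_arrays = {c: _random_dna(_rng(config, 3, i), config.chromosome_length)
                    for i, c in enumerate(chrom_names)}
    for p in placed:
        region = regions[p.gene_id]
        lo = p.start - flank
        chrom_arrays[p.chrom][lo:lo + len(region)] = region
    genome = {c: _dna_str(a) for c, a in chrom_arrays.items()}
    # scaffolds: gene centered with full flanks
    for i, gid in enumerate(scaffold_ids):
        region = regions[gid]
        name = f"scaffold_{i + 1}"
        genome[name] = _dna_str(region)
        m = meta[gid]
        placed.append(_Placed(gid, m["subfamily"], name, flank,
                              flank + m["body_len"], m["strand"], m["exons"]))

    gff = _write_gff(placed)
    for p in placed:
        truth.gene_loci[p.gene_id] = {
            "chromosome": p.chrom, "start": p.start, "end": p.end,
            "strand": p.strand}
    truth.true_family_ids = [p.gene_id for p in placed]
    if out_fasta is not None:
        write_fasta(sorted(genome.items()), out_fasta)
    if out_gff is not None:
        Path(out_gff).write_text(gff)
    return genome, gff, truth


def _plant_promoter(rng, region: np.ndarray, flank: int, body_len: int,
                    strand: str, config: ScenarioConfig, catalog,
                    subfamily: str) -> list[dict]:
    """Overwrite the promoter stretch with fresh background + elements.

    Returns planted (element, offset) records with offsets in promoter
    coordinates (0 = promoter 5' end on the coding strand).
    """
    plen = min(config.promoter_length, flank)
    promoter = _random_dna(rng, plen)
    plan = config.promoter_plan.get(subfamily, {"*": 0.3})
    default_p = plan.get("*", 0.3)
    planted = []
    for name, pattern, _cls in catalog:
        if rng.random() >= plan.get(name, default_p):
            continue
        w = len(pattern)
        if w > plen:
            continue
        offset = int(rng.integers(0, plen - w + 1))
        site = _realize_pattern(rng, pattern)
        promoter[offset:offset + w] = [DNA_ALPHABET.index(c) for c in site]
        planted.append({"element": name, "offset": offset, "site": site})
    if strand == "+":
        region[flank - plen:flank] = promoter
    else:
        # promoter downstream of the body on the reverse strand
        rc = 3 - promoter[::-1]
        region[flank + body_len:flank + body_len + plen] = rc
    return planted


def _write_gff(placed: list[_Placed]) -> str:
    lines = ["##gff-version 3"]
    for p in sorted(placed, key=lambda x: (x.chrom, x.start)):
        g1, g2 = p.start + 1, p.end  # 1-based inclusive
        lines.append("\t".join([
            p.chrom, "hdzipkit", "gene", str(g1), str(g2), ".", p.strand,
            ".", f"ID={p.gene_id};subfamily={p.subfamily}"]))
        mid = f"{p.gene_id}.1"
        lines.append("\t".join([
            p.chrom, "hdzipkit", "mRNA", str(g1), str(g2), ".", p.strand,
            ".", f"ID={mid};Parent={p.gene_id}"]))
        exons = p.exons if p.strand == "+" else \
            [(p.end - p.start - e, p.end - p.start - s) for s, e in reversed(p.exons)]
        for i, (s, e) in enumerate(sorted(exons)):
            a, b = p.start + s + 1, p.start + e
            lines.append("\t".join([
                p.chrom, "hdzipkit", "exon", str(a), str(b), ".", p.strand,
                ".", f"ID={mid}.exon{i + 1};Parent={mid}"]))
            lines.append("\t".join([
                p.chrom, "hdzipkit", "CDS", str(a), str(b), ".", p.strand,
                "0", f"ID={mid}.cds{i + 1};Parent={mid}"]))
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# expression and qPCR


def generate_expression(config: ScenarioConfig,
                        out_fpkm: str | Path | None = None,
                        out_ct: str | Path | None = None
                        ) -> tuple["pd.DataFrame", "pd.DataFrame", TruthTable]:
    """FPKM matrix (tissues + drought contrasts), Ct table, and truth.

    Constitutive genes draw FPKM from 1 + lognormal (support strictly above
    the expressed threshold); non-expressed genes are uniform on
    (0, threshold]; tissue-specific genes are expressed in exactly one
    configured tissue group; partial genes in a random proper subset.
    Drought contrasts add ``{tissue}_ctrl`` / ``{tissue}_drought`` columns
    with the planned number of |fold change| > 2 genes.

    The Ct table has one row per (sample, gene, replicate); reference-gene
    rows carry ``target == reference``.
    """
    import pandas as pd

    config.validate()
    rng = _rng(config, 4)
    plan = config.expression_plan
    ids = family_gene_ids(config)
    genes = [g for sf in SUBFAMILIES for g in ids[sf]]
    truth = TruthTable()
    thr = plan.fpkm_threshold

    classes: list[str] = []
    for cls in ("constitutive", "non_expressed", "tissue_specific", "partial"):
        classes += [cls] * plan.class_counts.get(cls, 0)
    if len(classes) < len(genes):
        classes += ["constitutive"] * (len(genes) - len(classes))
    classes = classes[:len(genes)]
    perm = rng.permutation(len(genes))
    assigned = {genes[i]: classes[k] for k, i in enumerate(perm)}

    group_names = list(plan.tissue_groups) or ["all"]
    samples = plan.samples
    data = np.zeros((len(genes), len(samples)))

    def expressed_value(size):
        return thr + rng.lognormal(plan.lognormal_mu, plan.lognormal_sigma, size)

    def silent_value(size):
        return rng.uniform(0, thr, size)

    for gi, g in enumerate(genes):
        cls = assigned[g]
        truth.true_expression_class[g] = cls
        if cls == "constitutive":
            data[gi] = expressed_value(len(samples))
        elif cls == "non_expressed":
            data[gi] = silent_value(len(samples))
        elif cls == "tissue_specific":
            grp = group_names[gi % len(group_names)]
            truth.true_expression_group[g] = grp
            members = set(plan.tissue_groups.get(grp, samples))
            for si, s in enumerate(samples):
                data[gi, si] = (expressed_value(1)[0] if s in members
                                else silent_value(1)[0])
        else:  # partial: a proper, non-group subset
            while True:
                mask = rng.random(len(samples)) < 0.5
                subset = {s for s, m in zip(samples, mask) if m}
                if (0 < len(subset) < len(samples)
                        and subset not in map(set, plan.tissue_groups.values())):
                    break
            for si, s in enumerate(samples):
                data[gi, si] = (expressed_value(1)[0] if s in subset
                                else silent_value(1)[0])
    fpkm = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"),
                        columns=samples)

    # drought contrasts
    for tissue, n_changed in plan.drought_changed.items():
        ctrl = expressed_value(len(genes))
        treat = ctrl.copy()
        pick = rng.permutation(len(genes))[:n_changed]
        changed_ids = [genes[i] for i in pick]
        for i in pick:
            lfc = rng.uniform(1.5, 4.0) * (1 if rng.random() < 0.5 else -1)
            treat[i] = ctrl[i] * 2.0 ** lfc
        unchanged = np.setdiff1d(np.arange(len(genes)), pick)
        treat[unchanged] = ctrl[unchanged] * 2.0 ** rng.uniform(
            -0.5, 0.5, unchanged.size)
        fpkm[f"{tissue}_ctrl"] = ctrl
        fpkm[f"{tissue}_drought"] = treat
        truth.true_fold_changed[tissue] = sorted(changed_ids)

    # qPCR Ct table
    qp = config.qpcr_plan
    q_genes = genes[:qp.n_genes]
    rows = []
    for g in q_genes:
        ratios = {}
        for tp in qp.timepoints:
            ratio = 1.0 if tp == qp.calibrator else float(
                2.0 ** rng.uniform(-3, 3))
            ratios[tp] = ratio
            for rep in range(1, qp.replicates + 1):
                ct = qp.baseline_ct - np.log2(ratio) + rng.normal(0, qp.ct_sd)
                rows.append((tp, g, qp.reference_gene, rep, round(float(ct), 4)))
        truth.true_qpcr_ratio[g] = ratios
    # internal-control measurements, once per sample
    for tp in qp.timepoints:
        for rep in range(1, qp.replicates + 1):
            ct = qp.reference_ct + rng.normal(0, qp.ct_sd)
            rows.append((tp, qp.reference_gene, qp.reference_gene, rep,
                         round(float(ct), 4)))
    ct_table = pd.DataFrame(rows, columns=[
        "sample", "target", "reference", "replicate", "ct"])

    if out_fpkm is not None:
        fpkm.to_csv(out_fpkm, sep="\t")
    if out_ct is not None:
        ct_table.to_csv(out_ct, index=False)
    return fpkm, ct_table, truth


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The study-scale scenario used throughout the analysis drivers."""
    return ScenarioConfig(seed=seed)
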