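"""Promoter extraction, IUPAC element scanning, and binomial enrichment.

Promoters are the 1500 bp upstream of the translation start (the analysis
equates the transcription start site with the ATG).  Elements are named
IUPAC patterns from a packaged catalog; scanning reports every occurrence,
overlaps included, optionally on both strands.  Per-subfamily
overrepresentation uses an upper-tail exact binomial test on
presence/absence per promoter, with the whole-family promoter proportion
as the background rate, and Benjamini–Hochberg adjustment within each
subfamily.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from scipy import stats

from .genestruct import GeneModel
from .synthetic import load_element_catalog

PROMOTER_LENGTH = 1500

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    pattern: str
    functional_class: str


@dataclass
class ElementHit:
    gene_id: str
    element: str
    offset: int  # 0-based, promoter coordinates (5' end = 0)
    strand: str
    match: str


@dataclass
class EnrichmentResult:
    element: str
    subfamily: str
    k: int        # promoters in subfamily containing the element
    n: int        # subfamily size
    p0: float     # background proportion over all family promoters
    p_value: float
    q_value: float


def default_catalog() -> list[CatalogEntry]:
    return [CatalogEntry(*row) for row in load_element_catalog()]


def validate_catalog(catalog: list[CatalogEntry]) -> None:
    seen = set()
    for entry in catalog:
        bad = set(entry.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"catalog entry {entry.name!r} has invalid IUPAC codes "
                f"{sorted(bad)}")
        if entry.name in seen:
            raise ValueError(f"duplicate catalog entry name {entry.name!r}")
        seen.add(entry.name)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_promoter(genome: dict[str, str], gene: GeneModel,
                     length: int = PROMOTER_LENGTH) -> tuple[str, bool]:
    """Promoter on the coding strand, with a truncation flag.

    Plus strand: bases [cds_start - length, cds_start); minus strand:
    reverse complement of [gene end, gene end + length).  Truncated at
    contig edges.
    """
    seq = genome.get(gene.chromosome)
    if seq is None:
        raise KeyError(f"chromosome {gene.chromosome!r} absent from genome")
    if gene.strand == "+":
        lo = max(0, gene.start - length)
        window = seq[lo:gene.start]
        truncated = lo > gene.start - length
        return window, truncated
    hi = min(len(seq), gene.end + length)
    window = seq[gene.end:hi]
    truncated = hi < gene.end + length
    return revcomp(window), truncated


def _iupac_regex(pattern: str) -> re.Pattern:
    # a sequence N never matches, so classes list explicit bases only
    parts = []
    for code in pattern.upper():
        bases = IUPAC[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(f"(?=({''.join(parts)}))")


def is_palindromic(pattern: str) -> bool:
    return pattern.upper() == revcomp(pattern.upper())


def scan_elements(gene_id: str, promoter: str,
                  catalog: list[CatalogEntry] | None = None,
                  both_strands: bool = True,
                  dedupe_palindromes: bool = True) -> list[ElementHit]:
    """All element occurrences in one promoter (case-insensitive).

    Overlapping occurrences are all reported.  Reverse-strand hits carry
    the forward-coordinate offset of the matched region; for palindromic
    patterns the identical reverse hit is suppressed when
    ``dedupe_palindromes`` is set.
    """
    catalog = catalog if catalog is not None else default_catalog()
    validate_catalog(catalog)
    fwd = promoter.upper()
    rev = revcomp(fwd)
    L = len(fwd)
    hits = []
    for entry in catalog:
        rx = _iupac_regex(entry.pattern)
        w = len(entry.pattern)
        for m in rx.finditer(fwd):
            hits.append(ElementHit(gene_id, entry.name, m.start(), "+",
                                   m.group(1)))
        if both_strands and not (dedupe_palindromes
                                 and is_palindromic(entry.pattern)):
            for m in rx.finditer(rev):
                offset = L - m.start() - w
                hits.append(ElementHit(gene_id, entry.name, offset, "-",
                                       m.group(1)))
    hits.sort(key=lambda h: (h.element, h.offset, h.strand))
    return hits


def exact_binom_upper(k: int, n: int, p0: float) -> float:
    """Upper-tail exact binomial probability P(X >= k), X ~ Bin(n, p0)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def enrichment_test(hits_by_gene: dict[str, list[ElementHit]],
                    subfamily_map: dict[str, str],
                    elements: list[str] | None = None,
                    ) -> list[EnrichmentResult]:
    """Per-(element, subfamily) presence/absence overrepresentation.

    p0 is the proportion of all family promoters containing at least one
    occurrence of the element; for each subfamily of size n with k carrier
    promoters, p = P(X >= k) under Binomial(n, p0); q-values are
    Benjamini–Hochberg within each subfamily.  Empty subfamilies are
    omitted.
    """
    from statsmodels.stats.multitest import multipletests

    genes = list(hits_by_gene)
    if elements is None:
        elements = sorted({h.element for hs in hits_by_gene.values()
                           for h in hs})
    carriers = {e: {g for g in genes
                    if any(h.element == e for h in hits_by_gene[g])}
                for e in elements}
    subfamilies = sorted(set(subfamily_map.values()))
    results: list[EnrichmentResult] = []
    for sf in subfamilies:
        members = [g for g in genes if subfamily_map.get(g) == sf]
        n = len(members)
        if n == 0:
            continue
        block = []
        for e in elements:
            k = sum(1 for g in members if g in carriers[e])
            p0 = len(carriers[e]) / len(genes) if genes else 0.0
            p = exact_binom_upper(k, n, p0)
            block.append(EnrichmentResult(e, sf, k, n, p0, p, p))
        pvals = [r.p_value for r in block]
        if pvals:
            _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
            for r, q in zip(block, qvals):
                r.q_value = float(max(q, r.p_value))
        results.extend(block)
    return results
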