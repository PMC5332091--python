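"""Tandem and segmental duplication calling among family genes.

Tandem: two family genes on the same chromosome whose nearest boundaries
are within 50 kb.  Segmental: the 100-kb flanking windows (50 kb upstream +
50 kb downstream, gene body excluded) of two genes share chained local
alignments, every block longer than 200 bp at above 85% identity, with the
chain's total aligned length at least ``min_chain_span`` (default 2 kb —
well above single-block noise, far below planted spans).

Genes recorded at identical coordinates (alternative transcripts of one
locus) are collapsed before pairing; genes on unanchored scaffolds are
excluded from chromosome-based analyses and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import (AlignmentBlock, ScoringScheme, kmer_index,
                    seeded_local_align)

TANDEM_WINDOW = 50_000
FLANK = 50_000
MIN_BLOCK_LENGTH = 200     # chain filter: length > 200 bp
MIN_BLOCK_IDENTITY = 0.85  # chain filter: identity > 85%
MIN_CHAIN_SPAN = 2_000


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty locus for {self.gene_id}")


@dataclass
class Chain:
    """Strictly collinear chain of filtered alignment blocks."""

    blocks: list[AlignmentBlock] = field(default_factory=list)
    total_aligned: int = 0
    min_identity: float = 1.0

    def __bool__(self):
        return bool(self.blocks)


@dataclass
class DuplicationPair:
    gene_a: str
    gene_b: str
    kind: str  # tandem | segmental
    distance: int | None = None  # tandem evidence
    chain: Chain | None = None   # segmental evidence

    def key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


def find_tandem(loci: list[GeneLocus], family_ids: set[str] | None = None,
                window: int = TANDEM_WINDOW) -> list[DuplicationPair]:
    """Family gene pairs within the tandem window on one chromosome.

    Distance is measured boundary-to-boundary (0 for overlapping loci).
    Symmetric in gene order; pairs are reported with ids sorted.
    """
    eligible = [l for l in loci
                if family_ids is None or l.gene_id in family_ids]
    out = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in eligible:
        by_chrom.setdefault(l.chromosome, []).append(l)
    for chrom_loci in by_chrom.values():
        chrom_loci = sorted(chrom_loci, key=lambda l: (l.start, l.gene_id))
        for i, a in enumerate(chrom_loci):
            for b in chrom_loci[i + 1:]:
                gap = max(0, max(a.start, b.start) - min(a.end, b.end))
                if gap <= window:
                    ga, gb = sorted((a.gene_id, b.gene_id))
                    out.append(DuplicationPair(ga, gb, "tandem", distance=gap))
    return out


@dataclass
class FlankWindow:
    """Concatenated upstream+downstream flank with a genomic coordinate map."""

    sequence: str
    segments: list[tuple[int, int, int]]  # (window offset, genomic start, length)
    truncated: bool

    def to_genomic(self, pos: int) -> int:
        for off, gstart, length in self.segments:
            if off <= pos < off + length:
                return gstart + (pos - off)
        raise IndexError(f"window position {pos} outside mapped segments")


def extract_flanks(genome: dict[str, str], locus: GeneLocus,
                   flank: int = FLANK) -> FlankWindow:
    """Upstream + downstream flank of a locus, gene body excluded.

    Windows are truncated at chromosome edges (flag recorded).
    """
    seq = genome.get(locus.chromosome)
    if seq is None:
        raise KeyError(f"chromosome {locus.chromosome!r} absent from genome")
    if locus.end > len(seq):
        raise ValueError(f"locus {locus.gene_id} extends beyond its chromosome")
    up_start = max(0, locus.start - flank)
    down_end = min(len(seq), locus.end + flank)
    truncated = (up_start > locus.start - flank) or (down_end < locus.end + flank)
    up = seq[up_start:locus.start]
    down = seq[locus.end:down_end]
    segments = []
    if up:
        segments.append((0, up_start, len(up)))
    if down:
        segments.append((len(up), locus.end, len(down)))
    return FlankWindow(up + down, segments, truncated)


def chain_blocks(blocks: list[AlignmentBlock],
                 min_length: int = MIN_BLOCK_LENGTH,
                 min_identity: float = MIN_BLOCK_IDENTITY) -> Chain:
    """Best strictly collinear chain of filtered blocks.

    Blocks failing the length/identity filters (strict inequalities) are
    discarded; the surviving blocks are chained by dynamic programming to
    maximize total aligned length, ties broken by higher minimum identity,
    then by lexicographic block order.
    """
    kept = [b for b in blocks
            if b.length > min_length and b.identity > min_identity]
    if not kept:
        return Chain()
    kept.sort(key=lambda b: (b.qstart, b.sstart, b.qend, b.send))
    n = len(kept)
    # DP value: (total_aligned, min_identity, reverse-lex tiebreak via index)
    best_total = [b.length for b in kept]
    best_minid = [b.identity for b in kept]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if kept[j].qend <= kept[i].qstart and kept[j].send <= kept[i].sstart:
                total = best_total[j] + kept[i].length
                minid = min(best_minid[j], kept[i].identity)
                if (total, minid) > (best_total[i], best_minid[i]):
                    best_total[i], best_minid[i] = total, minid
                    prev[i] = j
    end = max(range(n), key=lambda i: (best_total[i], best_minid[i], -i))
    chain_blocks_ = []
    i = end
    while i != -1:
        chain_blocks_.append(kept[i])
        i = prev[i]
    chain_blocks_.reverse()
    return Chain(chain_blocks_, best_total[end], best_minid[end])


def collapse_same_locus(loci: list[GeneLocus]) -> tuple[list[GeneLocus],
                                                        dict[str, str]]:
    """Collapse genes at identical coordinates to one representative.

    Returns (kept loci, alias map collapsed_id -> representative_id); the
    representative is the lexicographically first gene id at the locus.
    """
    groups: dict[tuple, list[GeneLocus]] = {}
    for l in loci:
        groups.setdefault((l.chromosome, l.start, l.end), []).append(l)
    kept = []
    aliases: dict[str, str] = {}
    for members in groups.values():
        members = sorted(members, key=lambda l: l.gene_id)
        kept.append(members[0])
        for m in members[1:]:
            aliases[m.gene_id] = members[0].gene_id
    return sorted(kept, key=lambda l: (l.chromosome, l.start)), aliases


def call_segmental(loci: list[GeneLocus], genome: dict[str, str],
                   flank: int = FLANK, k: int = 12,
                   min_chain_span: int = MIN_CHAIN_SPAN,
                   min_block_length: int = MIN_BLOCK_LENGTH,
                   min_block_identity: float = MIN_BLOCK_IDENTITY,
                   scheme: ScoringScheme | None = None,
                   exclude_tandem: bool = True,
                   chromosome_prefix: str = "chr",
                   prefilter_min_shared: int = 0
                   ) -> tuple[list[DuplicationPair], list[str]]:
    """All-vs-all segmental duplication calls over family loci.

    Same-coordinate transcript duplicates are collapsed first; loci on
    contigs not matching ``chromosome_prefix`` (unanchored scaffolds) are
    excluded and returned in the second element.  Pairs already within the
    tandem window are skipped when ``exclude_tandem`` is set.

    ``prefilter_min_shared`` > 0 enables a shared-k-mer screen: full
    seed-and-extend alignment runs only for pairs whose windows share at
    least that many distinct k-mers (0 disables the screen).  A chainable
    pair (blocks > 85% identity) shares orders of magnitude more k-mers
    than unrelated windows, so a threshold a few times the random
    expectation (window²/4^k) is conservative;
    :func:`suggested_prefilter` computes one.
    """
    scheme = scheme or ScoringScheme()
    collapsed, _aliases = collapse_same_locus(loci)
    on_chrom = [l for l in collapsed
                if l.chromosome.startswith(chromosome_prefix)]
    excluded = sorted(l.gene_id for l in collapsed if l not in on_chrom)
    tandem_keys = {p.key() for p in find_tandem(on_chrom)} if exclude_tandem else set()
    windows = {l.gene_id: extract_flanks(genome, l, flank) for l in on_chrom}
    indexes = {gid: kmer_index(w.sequence, k) for gid, w in windows.items()}
    kmer_sets = {gid: set(indexes[gid]) for gid in windows}
    out = []
    for i, a in enumerate(on_chrom):
        for b in on_chrom[i + 1:]:
            if frozenset((a.gene_id, b.gene_id)) in tandem_keys:
                continue
            if prefilter_min_shared > 0:
                shared = len(kmer_sets[a.gene_id] & kmer_sets[b.gene_id])
                if shared < prefilter_min_shared:
                    continue
            blocks = seeded_local_align(
                windows[a.gene_id].sequence, windows[b.gene_id].sequence,
                k=k, scheme=scheme, query_id=a.gene_id, subject_id=b.gene_id,
                subject_index=indexes[b.gene_id])
            chain = chain_blocks(blocks, min_block_length, min_block_identity)
            if chain and chain.total_aligned >= min_chain_span:
                ga, gb = sorted((a.gene_id, b.gene_id))
                out.append(DuplicationPair(ga, gb, "segmental", chain=chain))
    return out, excluded


def suggested_prefilter(window_bp: int = 2 * FLANK, k: int = 12,
                        factor: float = 4.0) -> int:
    """Shared-k-mer screen threshold: ``factor`` times the random expectation.

    Two unrelated windows of ``window_bp`` share about window²/4^k distinct
    k-mers; a pair with chainable >85%-identity blocks of even a few kb
    shares thousands.
    """
    expected_random = window_bp * window_bp / 4 ** k
    return int(factor * max(expected_random, 25))


def loci_from_models(models) -> list[GeneLocus]:
    """GeneLocus list from :mod:`hdzipkit.genestruct` gene models."""
    return [GeneLocus(m.gene_id, m.chromosome, m.start, m.end, m.strand)
            for m in models.values()]
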