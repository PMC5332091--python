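"""Shared local-alignment engine.

Two tiers:

* :func:`smith_waterman` — exact affine-gap local alignment for short
  sequences (protein or nucleotide), full dynamic-programming matrix with
  traceback.
* :func:`seeded_local_align` — seed-and-extend alignment for long nucleotide
  windows (the 100-kb duplication flanks): exact k-mer seeds grouped by
  diagonal, X-drop extension into ungapped blocks, overlapping same-diagonal
  blocks merged.  Deterministic; no randomness anywhere.

Blocks feed the duplication caller's chaining step, whose operative filters
(length > 200 bp, identity > 85%) carry the statistical weight; the engine
itself only applies a weak minimum block score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores plus affine gap penalties.

    ``gap_open`` and ``gap_extend`` are non-negative penalties; a gap of
    length k costs ``gap_open + k * gap_extend``.  Protein mode supplies a
    full substitution dict; nucleotide mode supplies match/mismatch
    integers.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: float = 5.0
    gap_extend: float = 1.0
    substitution: dict | None = None

    def __post_init__(self):
        if self.gap_open < self.gap_extend or self.gap_extend < 0:
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.substitution is None and self.match <= 0:
            raise ValueError("match score must be positive in nucleotide mode")

    def score(self, a: str, b: str) -> float:
        if self.substitution is not None:
            return self.substitution[(a, b)]
        if a == "N" or b == "N":
            return self.mismatch
        return self.match if a == b else self.mismatch


#: A compact BLOSUM62-style protein substitution scheme built from
#: Biopython's substitution matrices at first use (see :func:`protein_scheme`).
_PROTEIN_SCHEME_CACHE: ScoringScheme | None = None


def protein_scheme(gap_open: float = 11.0, gap_extend: float = 1.0) -> ScoringScheme:
    """BLOSUM62 protein scoring with BLAST-like affine penalties."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    sub = {
        (a, b): float(m[a][b])
        for a in m.alphabet
        for b in m.alphabet
    }
    return ScoringScheme(match=1, mismatch=-2, gap_open=gap_open,
                         gap_extend=gap_extend, substitution=sub)


@dataclass
class AlignmentBlock:
    """One local alignment between a query and a subject region.

    Coordinates are 0-based half-open.  ``identity * length`` is an integer
    match count; ``length`` counts aligned columns (gaps included for gapped
    alignments).
    """

    query_id: str
    subject_id: str
    qstart: int
    qend: int
    sstart: int
    send: int
    length: int
    identity: float
    score: float

    @property
    def matches(self) -> int:
        return round(self.identity * self.length)

    def is_empty(self) -> bool:
        return self.length == 0


def _empty_block(qid: str, sid: str) -> AlignmentBlock:
    return AlignmentBlock(qid, sid, 0, 0, 0, 0, 0, 0.0, 0.0)


def smith_waterman(a: str, b: str, scheme: ScoringScheme,
                   query_id: str = "query",
                   subject_id: str = "subject") -> AlignmentBlock:
    """Optimal affine-gap local alignment (Smith–Waterman–Gotoh).

    Returns the single best-scoring block; a pair with no positive-scoring
    local alignment yields a zero-score empty block.
    """
    if not a or not b:
        return _empty_block(query_id, subject_id)
    n, m = len(a), len(b)
    NEG = float("-inf")
    # H: best ending in match/mismatch; E: gap in b (consume a); F: gap in a.
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    go, ge = scheme.gap_open, scheme.gap_extend
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - go - ge, E[i - 1][j] - ge)
            F[i][j] = max(H[i][j - 1] - go - ge, F[i][j - 1] - ge)
            diag = H[i - 1][j - 1] + scheme.score(ai, b[j - 1])
            h = max(0.0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h == 0.0:
                ptr[i][j] = 0
            elif h == diag:
                ptr[i][j] = 1
            elif h == E[i][j]:
                ptr[i][j] = 2
            else:
                ptr[i][j] = 3
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0.0:
        return _empty_block(query_id, subject_id)
    # Three-state traceback from the best cell.
    i, j = bi, bj
    cols = 0
    matches = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0.0:
                break
            p = ptr[i][j]
            if p == 1:
                cols += 1
                matches += a[i - 1] == b[j - 1]
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            elif p == 3:
                state = "F"
            else:
                break
        elif state == "E":
            cols += 1
            from_ext = E[i][j] == E[i - 1][j] - ge
            i -= 1
            if not from_ext:
                state = "H"
        else:  # F
            cols += 1
            from_ext = F[i][j] == F[i][j - 1] - ge
            j -= 1
            if not from_ext:
                state = "H"
    return AlignmentBlock(query_id, subject_id, i, bi, j, bj,
                          cols, matches / cols if cols else 0.0, best)


def encode_dna(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 indices; reject other symbols."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN symbols in sequence: {sorted(bad)}")
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """2-bit packed k-mer codes at every position; -1 where a window has N.

    Vectorized; k is limited to 31 so codes fit an int64.
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    arr = encode_dna(seq)
    base = np.full(len(arr), -1, dtype=np.int64)
    for b, v in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        base[arr == np.uint8(ord(b))] = v
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        window = base[j:j + n]
        codes = (codes << 2) | np.where(window >= 0, window, 0)
        invalid |= window < 0
    codes[invalid] = -1
    return codes


def seeded_local_align(query: str, subject: str, k: int = 12,
                       scheme: ScoringScheme | None = None,
                       xdrop: float = 20.0, min_block_score: float = 30.0,
                       query_id: str = "query", subject_id: str = "subject",
                       subject_index: dict | None = None) -> list[AlignmentBlock]:
    """Seed-and-extend ungapped local alignment of two nucleotide sequences.

    Exact k-mer matches define candidate diagonals; each seeded diagonal is
    scanned once and split into maximal X-drop segments under the
    match/mismatch scores of ``scheme``.  Segments scoring below
    ``min_block_score`` are dropped.  Suited to point-mutation divergence
    (the synthetic duplication model); indel-bearing homology is out of
    scope for this tier.

    ``subject_index`` allows reusing a precomputed :func:`kmer_index` of the
    subject across many queries.
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8 for nucleotide mode")
    scheme = scheme or ScoringScheme()
    qa = encode_dna(query)
    sa = encode_dna(subject)
    if len(qa) < k or len(sa) < k:
        return []
    index = subject_index if subject_index is not None else kmer_index(subject, k)
    qcodes = encode_kmers(query, k)
    # Collect seeded diagonals: diag = qpos - spos.
    diag_hits: dict[int, list[int]] = {}
    for i, code in enumerate(qcodes):
        if code < 0:
            continue
        for j in index.get(int(code), ()):
            diag_hits.setdefault(i - j, []).append(i)
    blocks: list[AlignmentBlock] = []
    margin = 400  # scan this far beyond the outermost seeds on a diagonal
    nmask_q = qa == _N
    nmask_s = sa == _N
    for d, qpos in diag_hits.items():
        qlo = max(0, min(qpos) - margin, d)
        qhi = min(len(qa), max(qpos) + k + margin, len(sa) + d)
        if qhi <= qlo:
            continue
        qseg = qa[qlo:qhi]
        sseg = sa[qlo - d:qhi - d]
        match = (qseg == sseg) & ~nmask_q[qlo:qhi] & ~nmask_s[qlo - d:qhi - d]
        for a0, a1, score, matches in _xdrop_segments(
                match, scheme.match, scheme.mismatch, xdrop, min_block_score):
            blocks.append(AlignmentBlock(
                query_id, subject_id,
                qlo + a0, qlo + a1,
                qlo + a0 - d, qlo + a1 - d,
                a1 - a0, matches / (a1 - a0), score))
    blocks.sort(key=lambda b: (b.qstart, b.sstart, -b.length))
    return blocks


_N = np.uint8(ord("N"))


def kmer_index(subject: str, k: int) -> dict[int, list[int]]:
    """Positions of every N-free k-mer of ``subject``, keyed by 2-bit code."""
    index: dict[int, list[int]] = {}
    for j, code in enumerate(encode_kmers(subject, k)):
        if code < 0:
            continue
        index.setdefault(int(code), []).append(j)
    return index


def _xdrop_segments(match: np.ndarray, sm: float, sx: float,
                    xdrop: float, min_score: float):
    """Maximal positive-scoring segments of a boolean match track.

    Greedy left-to-right scan: a segment starts at the first match, grows
    while the running score stays within ``xdrop`` of its maximum, and is
    emitted trimmed to its score-maximizing prefix.
    """
    out = []
    n = len(match)
    i = 0
    while i < n:
        if not match[i]:
            i += 1
            continue
        start = i
        score = 0.0
        best_score = 0.0
        best_end = i
        matches = 0
        best_matches = 0
        j = i
        while j < n:
            score += sm if match[j] else sx
            if match[j]:
                matches += 1
            if score > best_score:
                best_score, best_end, best_matches = score, j + 1, matches
            if best_score - score > xdrop:
                break
            j += 1
        if best_score >= min_score:
            out.append((start, best_end, best_score, best_matches))
        i = max(best_end, start + 1)
    return out
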