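"""Family identification by dual-domain profile scanning.

A family member must carry both the homeodomain (HD) and the leucine zipper
(LZ).  Each domain is modelled as an ungapped position-specific scoring
matrix (log-odds bits over the 20 residues) built from a small packaged seed
alignment; a protein's domain score is the best sliding-window sum.

Significance is calibrated empirically per protein: the protein is shuffled
``null_shuffles`` times and rescored.  The counting estimate
``(1 + #null >= observed) / (null_shuffles + 1)`` is reported as
``empirical_p``; when the observed score beats every shuffle the tail is
extrapolated with a Gumbel fit (method of moments on the null max-scores),
so that strong hits are not floored at ``1/(n+1)``.  The E-value is the
per-protein tail probability scaled by the database size.

Retention mirrors the classic gene-family workflow: both domains below the
E-value threshold (default 0.01), then exact-duplicate removal with the
first occurrence in input order winning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .domains import AA_ALPHABET, seed_alignment

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_EULER_GAMMA = 0.5772156649015329


@dataclass
class Profile:
    """Ungapped log-odds scoring matrix for one domain.

    ``matrix[j, r]`` is the bit score of residue ``r`` at position ``j``;
    columns derive from pseudocount-smoothed frequencies over the seed
    alignment against ``background``.
    """

    name: str
    matrix: np.ndarray  # (width, 20) bits
    width: int
    background: np.ndarray  # (20,)

    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        """Score of the consensus sequence (sum of per-column maxima)."""
        return float(self.matrix.max(axis=1).sum())

    def gathering_threshold(self, fraction: float = 0.25) -> float:
        """Minimum bit score for a credible domain instance.

        Shuffle-null E-values alone cannot separate a genuine domain from
        a merely order-unusual window (e.g. one coiled-coil scoring on
        another coiled-coil's profile); requiring a fixed fraction of the
        profile's maximum attainable score plays the role of a per-family
        gathering cutoff.
        """
        return fraction * self.max_score


@dataclass
class DomainHit:
    protein_id: str
    domain: str
    start: int  # 0-based half-open residue coordinates
    end: int
    score: float  # bits
    evalue: float
    empirical_p: float  # counting estimate (1+k)/(n+1)


@dataclass
class FamilyCall:
    protein_id: str
    hd: DomainHit | None
    lz: DomainHit | None
    retained: bool
    rejection_reason: str | None = None  # missing_HD, missing_LZ, redundant, low_score


def build_profile(seqs: list[str], pseudocount: float = 1.0,
                  background: np.ndarray | None = None,
                  name: str = "profile") -> Profile:
    """Log-odds profile from a gapless, equal-width seed alignment.

    score(r) = log2(((count_r + pseudocount*bg_r) / (N + pseudocount)) / bg_r)
    """
    if not seqs:
        raise ValueError("seed alignment must contain at least one sequence")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("ragged seed alignment")
    if width < 1:
        raise ValueError("profile width must be >= 1")
    bg = (np.full(20, 1 / 20) if background is None
          else np.asarray(background, dtype=float))
    counts = np.zeros((width, 20))
    for s in seqs:
        for j, r in enumerate(s):
            counts[j, _AA_INDEX[r]] += 1
    n = len(seqs)
    freq = (counts + pseudocount * bg) / (n + pseudocount)
    return Profile(name, np.log2(freq / bg), width, bg)


def default_profiles() -> dict[str, Profile]:
    """Profiles for all five packaged domains."""
    return {d: build_profile(seed_alignment(d), name=d)
            for d in ("HD", "LZ", "CPSCE", "START", "MEKHLA")}


def _encode(seq: str) -> np.ndarray:
    idx = np.empty(len(seq), dtype=np.intp)
    for i, r in enumerate(seq):
        j = _AA_INDEX.get(r)
        if j is None:
            raise ValueError(f"non-standard residue {r!r} at position {i}")
        idx[i] = j
    return idx


def _window_scores(encoded: np.ndarray, profile: Profile) -> np.ndarray:
    """Score of every window — vectorized over windows, loop over width."""
    nw = len(encoded) - profile.width + 1
    total = np.zeros(nw)
    for j in range(profile.width):
        total += profile.matrix[j, encoded[j:j + nw]]
    return total


def evalue_from_null(score: float, null_scores: np.ndarray,
                     db_size: int = 1) -> tuple[float, float]:
    """(E-value, counting p) for an observed max-score against a shuffle null.

    Counting: p = (1 + #null >= score) / (n + 1).  When no null score
    reaches the observation, a Gumbel right tail fitted to the null
    max-scores by the method of moments extrapolates beyond the sampled
    range; the E-value uses min(counting, Gumbel), keeping E monotone
    non-increasing in score.
    """
    null_scores = np.asarray(null_scores, dtype=float)
    n = len(null_scores)
    k = int(np.sum(null_scores >= score))
    p_count = (1 + k) / (n + 1)
    p = p_count
    if k == 0 and n >= 10:
        beta = null_scores.std(ddof=1) * math.sqrt(6) / math.pi
        if beta > 0:
            mu = null_scores.mean() - _EULER_GAMMA * beta
            z = (score - mu) / beta
            # P(max > score) = 1 - exp(-exp(-z))
            p_gumbel = -math.expm1(-math.exp(-z))
            p = min(p_count, p_gumbel)
    return db_size * p, p_count


def scan_profile(protein_id: str, sequence: str, profile: Profile,
                 null_shuffles: int = 99, seed: int = 0,
                 db_size: int = 1) -> DomainHit | None:
    """Best ungapped window hit of ``profile`` in one protein.

    Proteins shorter than the profile width yield no hit (``None``),
    not an error.
    """
    if len(sequence) < profile.width:
        return None
    enc = _encode(sequence)
    scores = _window_scores(enc, profile)
    best = int(scores.argmax())
    obs = float(scores[best])
    rng = np.random.default_rng([seed & 0x7FFFFFFF, profile.width,
                                 len(sequence), _hash32(protein_id)])
    nulls = np.empty(null_shuffles)
    for i in range(null_shuffles):
        nulls[i] = _window_scores(rng.permutation(enc), profile).max()
    evalue, p_count = evalue_from_null(obs, nulls, db_size)
    return DomainHit(protein_id, profile.name, best, best + profile.width,
                     obs, evalue, p_count)


def _hash32(s: str) -> int:
    h = 0
    for c in s:
        h = (h * 131 + ord(c)) & 0x7FFFFFFF
    return h


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file via Biopython."""
    from Bio import SeqIO

    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq)
        if not seq:
            raise IOError(f"unreadable/empty FASTA record at index {i}")
        out.append((rec.id, seq))
    return out


def identify_family(proteome: list[tuple[str, str]],
                    profiles: dict[str, Profile] | None = None,
                    evalue_threshold: float = 0.01,
                    null_shuffles: int = 99, seed: int = 0,
                    redundancy_identity: float = 1.0,
                    gathering_fraction: float = 0.25) -> list[FamilyCall]:
    """Dual-domain family calls over an ordered proteome.

    Retained iff the HD and the LZ hit both pass ``evalue_threshold`` and
    the per-profile gathering score cutoff, and the sequence is not
    redundant with an already-retained one (exact identity by default;
    ``redundancy_identity < 1`` switches to an edit-distance identity
    threshold).  Every rejection carries a reason.
    """
    profiles = profiles or default_profiles()
    if "HD" not in profiles or "LZ" not in profiles:
        raise ValueError("both HD and LZ profiles are required")
    db_size = max(1, len(proteome))
    ga_hd = profiles["HD"].gathering_threshold(gathering_fraction)
    ga_lz = profiles["LZ"].gathering_threshold(gathering_fraction)
    calls: list[FamilyCall] = []
    retained_seqs: list[str] = []
    retained_exact: set[str] = set()
    for pid, seq in proteome:
        hd = scan_profile(pid, seq, profiles["HD"], null_shuffles, seed, db_size)
        lz = scan_profile(pid, seq, profiles["LZ"], null_shuffles, seed, db_size)
        hd_ok = hd is not None and hd.evalue < evalue_threshold and hd.score >= ga_hd
        lz_ok = lz is not None and lz.evalue < evalue_threshold and lz.score >= ga_lz
        if not hd_ok:
            reason = "missing_HD" if hd is None else "low_score"
            if hd is not None and hd.empirical_p > 0.5:
                reason = "missing_HD"
            calls.append(FamilyCall(pid, hd, lz, False, reason))
            continue
        if not lz_ok:
            reason = "missing_LZ" if lz is None else "low_score"
            if lz is not None and lz.empirical_p > 0.5:
                reason = "missing_LZ"
            calls.append(FamilyCall(pid, hd, lz, False, reason))
            continue
        if _is_redundant(seq, retained_seqs, retained_exact, redundancy_identity):
            calls.append(FamilyCall(pid, hd, lz, False, "redundant"))
            continue
        retained_seqs.append(seq)
        retained_exact.add(seq)
        calls.append(FamilyCall(pid, hd, lz, True))
    return calls


def _is_redundant(seq: str, retained: list[str], exact: set[str],
                  threshold: float) -> bool:
    if seq in exact:
        return True
    if threshold >= 1.0:
        return False
    import edlib

    for other in retained:
        d = edlib.align(seq, other, task="distance")["editDistance"]
        if 1 - d / max(len(seq), len(other)) >= threshold:
            return True
    return False


def detect_architecture(sequence: str, profiles: dict[str, Profile],
                        evalue_threshold: float = 0.01,
                        null_shuffles: int = 99, seed: int = 0,
                        protein_id: str = "protein",
                        gathering_fraction: float = 0.25) -> set[str]:
    """Set of domains confidently present in one protein."""
    present = set()
    for name, prof in profiles.items():
        hit = scan_profile(protein_id, sequence, prof, null_shuffles, seed)
        if (hit is not None and hit.evalue < evalue_threshold
                and hit.score >= prof.gathering_threshold(gathering_fraction)):
            present.add(name)
    return present


# --- protein physical properties ------------------------------------------

#: Average residue masses (Da), monomer minus water.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

#: Bjellqvist-style pK set used for net-charge/pI calculations.
PK_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PK_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


def _net_charge(counts: dict[str, int], ph: float) -> float:
    q = 0.0
    for grp, pk in PK_POSITIVE.items():
        n = 1 if grp == "Nterm" else counts.get(grp, 0)
        q += n * 10 ** pk / (10 ** ph + 10 ** pk)
    for grp, pk in PK_NEGATIVE.items():
        n = 1 if grp == "Cterm" else counts.get(grp, 0)
        q -= n * 10 ** ph / (10 ** ph + 10 ** pk)
    return q


def protein_properties(sequence: str) -> tuple[float, float]:
    """(molecular weight in Da, isoelectric point in pH units).

    MW sums average residue masses plus one water; pI is the pH at which
    the Henderson–Hasselbalch net charge crosses zero, found by bisection
    to |charge| < 1e-4.
    """
    if not sequence:
        raise ValueError("empty sequence")
    mw = WATER_MASS
    counts: dict[str, int] = {}
    for i, r in enumerate(sequence):
        m = RESIDUE_MASS.get(r)
        if m is None:
            raise ValueError(f"non-standard residue {r!r} at position {i}")
        mw += m
        counts[r] = counts.get(r, 0) + 1
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2
        q = _net_charge(counts, mid)
        if abs(q) < 1e-4:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mw, (lo + hi) / 2
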