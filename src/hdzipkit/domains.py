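"""Packaged domain consensus fixtures for the dual-domain family.

The family is defined by a DNA-binding homeodomain (HD) immediately followed
by a leucine-zipper (LZ) dimerization motif.  Subfamily architectures add
further blocks: CPSCE (subfamily II), START (III and IV) and the C-terminal
MEKHLA block (III only).

The consensus strings below are hand-written, information-rich fixtures for
synthetic-data generation and profile construction — they are this package's
own models, not copies of any curated profile database.  Because the HD and
LZ blocks are shared by all four subfamilies, each subfamily carries a
deterministic "signature" variant of those two blocks (a fixed substitution
pattern applied at import time); the between-subfamily divergence is what
lets distance-based tree building separate the four clades.
"""

from __future__ import annotations

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

SUBFAMILIES = ("I", "II", "III", "IV")

# ~60-residue homeodomain-flavored consensus (helix-turn-helix character).
HD_CONSENSUS = "KRKLSDEQVRMLELSFGQEHKLESERKDRLAQELGLDPRQVAVWFQNRRARWKSKQLEHD"

# ~35-residue leucine zipper: leucines on a heptad repeat.
LZ_CONSENSUS = "LENEVSRLKKLLSEELDRLQKENEQLREELARLNS"

# Short conserved block characteristic of subfamily II.
CPSCE_CONSENSUS = "NCPSCEREVGSSESAVDCFA"

# Putative lipid-binding block shared by subfamilies III and IV.
START_CONSENSUS = (
    "VSDVAGRVMEELLSNAVTFEPAGWKVVQDRETGDIFLMDSATSSLFPAEPMGTVRFFTVL"
    "EDGTLVVYPLWLPFLHGRMPRDLVNQYISSGLLQHAELGGAIEVIHHEQLEPHSPLPRVM"
)

# C-terminal block found only in subfamily III.
MEKHLA_CONSENSUS = (
    "MEKHLAEILCSGDLDSIPTRSVEALRKRPGWSSVIDEVAHTFDGQSVMLIRSFMDPAEYM"
    "EVLSPMFQAY"
)

DOMAIN_CONSENSUS = {
    "HD": HD_CONSENSUS,
    "LZ": LZ_CONSENSUS,
    "CPSCE": CPSCE_CONSENSUS,
    "START": START_CONSENSUS,
    "MEKHLA": MEKHLA_CONSENSUS,
}

#: Domain blocks present in each subfamily's archetype, N- to C-terminal.
ARCHETYPES = {
    "I": ("HD", "LZ"),
    "II": ("HD", "LZ", "CPSCE"),
    "III": ("HD", "LZ", "START", "MEKHLA"),
    "IV": ("HD", "LZ", "START"),
}

_SIGNATURE_RATE = 0.18
_SIGNATURE_SEEDS = {"I": 101, "II": 202, "III": 303, "IV": 404}


def _signature_variant(consensus: str, subfamily: str, domain: str) -> str:
    """Deterministic subfamily-specific variant of a consensus block."""
    rng = np.random.default_rng(
        [_SIGNATURE_SEEDS[subfamily], sum(map(ord, domain))]
    )
    chars = list(consensus)
    for i in range(len(chars)):
        if rng.random() < _SIGNATURE_RATE:
            choices = [a for a in AA_ALPHABET if a != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def subfamily_consensus(subfamily: str, domain: str) -> str:
    """Consensus block for one subfamily.

    HD and LZ carry the per-subfamily signature; the architecture-defining
    blocks (CPSCE, START, MEKHLA) are shared verbatim.
    """
    if subfamily not in SUBFAMILIES:
        raise ValueError(f"unknown subfamily: {subfamily!r}")
    base = DOMAIN_CONSENSUS[domain]
    if domain in ("HD", "LZ"):
        return _signature_variant(base, subfamily, domain)
    return base


def seed_alignment(domain: str) -> list[str]:
    """Gapless seed alignment for profile construction.

    For HD and LZ this is the base consensus plus the four subfamily
    signature variants, so one profile scores members of every subfamily
    well; the remaining domains have a single-sequence alignment.
    """
    base = DOMAIN_CONSENSUS[domain]
    if domain in ("HD", "LZ"):
        return [base] + [subfamily_consensus(s, domain) for s in SUBFAMILIES]
    return [base]


def archetype_exemplar(subfamily: str, linker: str = "GSGSG") -> str:
    """Unmutated full-length exemplar of a subfamily archetype.

    Used as the anchor taxon for that subfamily in tree-based
    classification.
    """
    blocks = [subfamily_consensus(subfamily, d) for d in ARCHETYPES[subfamily]]
    return linker.join(blocks)
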