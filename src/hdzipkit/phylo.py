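"""Distance-based subfamily classification.

Family members are classified into subfamilies I–IV by neighbor-joining on
Poisson-corrected pairwise distances with bootstrap support, anchored by one
reference exemplar per subfamily, and cross-checked against the
domain-architecture rule table (HD+LZ only → I; +CPSCE → II;
+START+MEKHLA → III; +START without MEKHLA → IV).

The alignment consumed here is pre-computed (this package does not provide
a progressive aligner); for synthetic cohorts the natural choice is the
gapless concatenation of the profile-matched HD and LZ regions, which is
equal-length by construction (:func:`build_domain_alignment`).

"Partial deletion" site filtering keeps alignment columns whose non-gap
coverage is at least a configurable cutoff (default 95%) before any
pairwise comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_GAP_CHARS = set("-.")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix must be finite")
        np.fill_diagonal(self.d, 0.0)


class Node:
    """Tree node; children stored as (child, branch_length) pairs."""

    __slots__ = ("taxon", "children", "clamped")

    def __init__(self, taxon: str | None = None):
        self.taxon = taxon
        self.children: list[tuple["Node", float]] = []
        self.clamped = False  # negative NJ branch length clamped to zero

    def leaves(self) -> list[str]:
        if self.taxon is not None:
            return [self.taxon]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree represented with a trifurcating root node.

    ``support`` maps canonical splits (frozenset of the leaf side not
    containing the reference taxon) to bootstrap percentages.
    """

    root: Node
    taxa: list[str]
    support: dict[frozenset, float] = field(default_factory=dict)

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, canonicalized."""
        ref = min(self.taxa)
        all_taxa = frozenset(self.taxa)
        out = set()

        def visit(node: Node):
            for child, _ in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(self.taxa) - 1:
                    out.add(side if ref not in side
                            else all_taxa - side)
                visit(child)

        visit(self.root)
        return out

    def split_support(self, side) -> float | None:
        """Bootstrap support of a bipartition given either of its sides."""
        side = frozenset(side)
        ref = min(self.taxa)
        key = side if ref not in side else frozenset(self.taxa) - side
        return self.support.get(key)

    def clades(self) -> list[frozenset]:
        """Leaf sets of both sides of every edge (candidate anchored clades)."""
        all_taxa = frozenset(self.taxa)
        sides = []

        def visit(node: Node):
            for child, _ in node.children:
                side = frozenset(child.leaves())
                if 0 < len(side) < len(self.taxa):
                    sides.append(side)
                    sides.append(all_taxa - side)
                visit(child)

        visit(self.root)
        return sides

    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node: Node, length: float | None) -> str:
            if node.taxon is not None:
                s = node.taxon
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = ""
                if with_support and length is not None:
                    side = frozenset(node.leaves())
                    ref = min(self.taxa)
                    key = side if ref not in side else frozenset(self.taxa) - side
                    if key in self.support:
                        label = f"{self.support[key]:.0f}"
                s = f"({inner}){label}"
            if length is not None:
                s += f":{length:.6f}"
            return s

        return fmt(self.root, None) + ";"


def _encode_alignment(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    taxa = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must be equal length")
    L = lengths.pop()
    mat = np.zeros((len(taxa), L), dtype=np.int16)
    for i, t in enumerate(taxa):
        for j, c in enumerate(seqs[t].upper()):
            mat[i, j] = -1 if c in _GAP_CHARS else ord(c)
    return taxa, mat


def _distances_from_matrix(mat: np.ndarray, cols: np.ndarray,
                           correction: str, taxa: list[str]) -> np.ndarray:
    sub = mat[:, cols]
    valid = sub >= 0
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        comp = both.sum(axis=1)
        if np.any(comp == 0):
            j = i + 1 + int(np.argmax(comp == 0))
            raise ValueError(
                f"no comparable columns for pair ({taxa[i]}, {taxa[j]})")
        mism = ((sub[i] != sub[i + 1:]) & both).sum(axis=1)
        p = mism / comp
        if correction == "p":
            row = p
        elif correction == "poisson":
            if np.any(p >= 1.0):
                raise ValueError("saturated pair: p-distance of 1")
            row = -np.log1p(-p)
        else:
            raise ValueError(f"unknown correction {correction!r}")
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return d


def pairwise_distance(seqs: dict[str, str], correction: str = "poisson",
                      partial_deletion: float = 0.95) -> DistanceMatrix:
    """Pairwise distances under partial-deletion site filtering.

    Columns with non-gap coverage below ``partial_deletion`` are dropped
    globally; within the kept columns each pair is compared over sites
    where neither sequence is gapped.  ``correction='p'`` returns the raw
    p-distance; ``'poisson'`` applies d = -ln(1 - p).
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    taxa, mat = _encode_alignment(seqs)
    coverage = (mat >= 0).mean(axis=0)
    cols = np.flatnonzero(coverage >= partial_deletion)
    if cols.size == 0:
        raise ValueError("no columns survive partial deletion")
    return DistanceMatrix(taxa, _distances_from_matrix(mat, cols, correction, taxa))


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Canonical neighbor-joining agglomeration.

    Ties broken by first (row-major) minimal Q entry; negative branch
    length estimates are clamped to zero with a per-node flag.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [Node(t) for t in dm.taxa]
    D = dm.d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        idx = int(Q.argmin())
        i, j = divmod(idx, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        for child, ln in ((nodes[ai], li), (nodes[aj], lj)):
            if ln < 0:
                parent.clamped = True
                ln = 0.0
            parent.children.append((child, ln))
        # distances from new node
        new_d = 0.5 * (sub[i, :] + sub[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k, ak in enumerate(active):
            D[-1, ak] = D[ak, -1] = new_d[k]
        nodes.append(parent)
        new_index = D.shape[0] - 1
        active = [a for a in active if a not in (ai, aj)] + [new_index]
    # join final three at a trifurcating root
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = Node()
    for child, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        if ln < 0:
            root.clamped = True
            ln = 0.0
        root.children.append((child, ln))
    return Tree(root, list(dm.taxa))


def bootstrap_support(seqs: dict[str, str], n_replicates: int = 1000,
                      seed: int = 0, correction: str = "poisson",
                      partial_deletion: float = 0.95) -> Tree:
    """NJ tree on the full alignment with bootstrap split support.

    Columns are resampled with replacement per replicate; an edge's support
    is the percentage of replicate trees containing the same bipartition.
    Replicates whose resampled columns leave some pair with no comparable
    sites are redrawn.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    taxa, mat = _encode_alignment(seqs)
    coverage = (mat >= 0).mean(axis=0)
    cols = np.flatnonzero(coverage >= partial_deletion)
    if cols.size == 0:
        raise ValueError("no columns survive partial deletion")
    base = nj_tree(DistanceMatrix(
        taxa, _distances_from_matrix(mat, cols, correction, taxa)))
    counts: dict[frozenset, int] = {s: 0 for s in base.splits()}
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    done = 0
    while done < n_replicates:
        pick = cols[rng.integers(0, cols.size, size=cols.size)]
        try:
            d = _distances_from_matrix(mat, pick, correction, taxa)
        except ValueError:
            continue
        rep = nj_tree(DistanceMatrix(taxa, d))
        for s in rep.splits():
            if s in counts:
                counts[s] += 1
        done += 1
    base.support = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    return base


@dataclass
class SubfamilyAssignment:
    gene_id: str
    subfamily: str  # I, II, III, IV or "ambiguous"
    tree_support: float | None
    architecture_agrees: bool | None


def architecture_subfamily(domains: set[str]) -> str | None:
    """Rule table mapping a domain architecture to a subfamily.

    Requires HD and LZ; START+MEKHLA → III, START alone → IV, CPSCE → II,
    bare HD+LZ → I.  Total over the four archetypes; non-family
    architectures map to None.
    """
    if "HD" not in domains or "LZ" not in domains:
        return None
    if "START" in domains:
        return "III" if "MEKHLA" in domains else "IV"
    if "CPSCE" in domains:
        return "II"
    return "I"


def assign_subfamily(tree: Tree, anchors: dict[str, str],
                     architectures: dict[str, set[str]] | None = None
                     ) -> list[SubfamilyAssignment]:
    """Subfamily of each non-anchor leaf via the smallest anchored clade.

    For each gene the candidate clades are the edge sides containing it;
    the smallest side that also contains at least one anchor determines
    the call.  Mixed anchor subfamilies in that side yield "ambiguous".
    Architecture agreement (when architectures are supplied) is recorded,
    never silently overriding the tree call.
    """
    missing = set(anchors) - set(tree.taxa)
    if missing:
        raise ValueError(f"anchors absent from tree: {sorted(missing)}")
    present = {anchors[a] for a in anchors}
    for sf in ("I", "II", "III", "IV"):
        if sf not in present:
            raise ValueError(f"no anchor supplied for subfamily {sf}")
    sides = sorted(tree.clades(), key=len)
    out = []
    for gene in tree.taxa:
        if gene in anchors:
            continue
        call = "ambiguous"
        support = None
        for side in sides:
            if gene not in side:
                continue
            anchor_sfs = {anchors[a] for a in anchors if a in side}
            if not anchor_sfs:
                continue
            if len(anchor_sfs) == 1:
                call = anchor_sfs.pop()
                ref = min(tree.taxa)
                key = side if ref not in side else frozenset(tree.taxa) - side
                support = tree.support.get(key)
            break
        agrees = None
        if architectures is not None and gene in architectures:
            agrees = architecture_subfamily(architectures[gene]) == call
        out.append(SubfamilyAssignment(gene, call, support, agrees))
    return out


def build_domain_alignment(proteome: dict[str, str], calls,
                           anchors: dict[str, str] | None = None,
                           anchor_seqs: dict[str, str] | None = None) -> dict[str, str]:
    """Gapless alignment of concatenated HD+LZ profile-hit regions.

    ``calls`` are retained :class:`~hdzipkit.identify.FamilyCall` objects;
    anchor sequences (exemplars) are scanned with the default profiles to
    locate their domain regions.  Equal length holds by construction since
    every row is one HD window plus one LZ window.
    """
    from .identify import default_profiles, scan_profile

    rows: dict[str, str] = {}
    for call in calls:
        if not call.retained:
            continue
        seq = proteome[call.protein_id]
        rows[call.protein_id] = (seq[call.hd.start:call.hd.end]
                                 + seq[call.lz.start:call.lz.end])
    if anchor_seqs:
        profs = default_profiles()
        for aid, seq in anchor_seqs.items():
            hd = scan_profile(aid, seq, profs["HD"], null_shuffles=0)
            lz = scan_profile(aid, seq, profs["LZ"], null_shuffles=0)
            rows[aid] = seq[hd.start:hd.end] + seq[lz.start:lz.end]
    return rows
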