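# Methods

`hdzipkit` re-implements, as a tested pipeline over synthetic genomes with
planted ground truth, the standard genome-wide characterization workflow
for a dual-domain plant transcription-factor family (homeodomain + leucine
zipper, subfamilies I–IV): identification, subfamily classification, gene
structure and motif analysis, duplication calling, promoter element
enrichment, and expression/qPCR statistics.  This note records the models,
the parameter choices, and the places where a design was genuinely open.

## Synthetic scenarios

A `ScenarioConfig` fully determines a scenario; a fixed seed yields
byte-identical files.  The default scenario mirrors the scale of a typical
published family survey in a crop genome:

| quantity | default | note |
|---|---|---|
| true members (I/II/III/IV) | 23/14/9/11 = 57 | four archetypes |
| decoys | 30 HD-only, 28 LZ-only, 10 exact duplicates | pool of 125 |
| chromosomes | 18 × 700 kb | plus 3 scaffold-located genes |
| segmental duplications | 5 pairs (2×II, I, III, IV) | flank identity 0.90–0.94, full 100-kb window |
| tandem pairs | 0 | layout spacing > 50 kb |
| exons per gene | I: 2, II: 3, III: 18, IV: 9.6 mean | per-gene lists supported |
| promoter elements | per-subfamily planting probabilities | ABRE/HSE ↑ in I–II, GARE ↑ in III, MBS ↑ in IV |
| expression classes | 20 constitutive, 6 silent, 16 tissue-specific, 15 partial | FPKM = 1 + lognormal(1.5, 0.8) when expressed |
| drought contrasts | 18 changed in leaf, 24 in root | planted |fold| up to 16 |
| qPCR | 12 genes × 6 timepoints × 3 replicates | Ct noise SD 0.15, constant-Ct reference |

Domain blocks are hand-written, information-rich consensus fixtures.  HD
and LZ carry a deterministic per-subfamily *signature* (a fixed ~18%
substitution pattern applied at import); without between-subfamily
divergence of the shared domains, no distance-based tree could separate
four clades.  Member proteins embed the signature consensus mutated at a
per-position rate (default 0.05) in i.i.d.-uniform background — the
simplest null for empirical score calibration.

What the generator does **not** emulate: indels (duplicated windows
diverge by point mutation only, so the flank aligner is ungapped),
sequencing noise, genome assembly artifacts, codon structure
(protein sequences are not translations of the gene models), and
library-size effects in FPKM.  Passing tests therefore demonstrate
correctness of the decision rules and statistics at study scale, not
robustness to alignment-breaking indel divergence or quantification noise.

## Identification

Each domain is an ungapped position-specific scoring matrix (bits) built
from the packaged seed alignment with pseudocount smoothing:
`score(r) = log2(((n_r + τ·bg_r)/(N + τ))/bg_r)`, τ = 1.  A protein's
domain score is the maximum sliding-window sum.  Significance is
calibrated per protein by shuffling its residues (default 99 shuffles):
the counting estimate `(1+k)/(n+1)` is reported, and when the observed
score exceeds every shuffle a Gumbel right tail (method-of-moments fit to
the null maxima) extrapolates beyond the sampled range.  The E-value is
the tail probability times the database size; retention requires both
domains at E < 0.01.

A score floor accompanies the E-value: a hit must reach 25% of its
profile's maximum attainable score (the analog of a curated gathering
cutoff).  The shuffle null preserves composition but not local order, so
a window can be order-unusual relative to its own shuffles while being a
terrible absolute match — e.g. one coiled-coil region scoring
"significantly" on another coiled-coil's profile at −6 bits.  At the
default mutation rate true domains score ≥ 80% of the profile maximum and
background windows ≤ 16%, so the floor is far from both.

Redundancy removal is exact sequence identity with first-in-input
priority (a configurable edit-distance identity threshold is provided;
the workflow's "redundant" is otherwise undefined).  Molecular weight
sums average residue masses plus one water; pI solves the
Henderson–Hasselbalch net charge for zero by bisection with a packaged
Bjellqvist-style pK set (N-term 7.5, C-term 3.55; D 4.05, E 4.45, H 5.98,
C 9.0, Y 10.0, K 10.0, R 12.0).

## Alignment engine

Short sequences: exact Smith–Waterman–Gotoh with affine gaps (a k-long
gap costs `gap_open + k·gap_extend`), verified against an independent
full-matrix oracle.  Long nucleotide windows: exact k-mer seeds (k = 12,
2-bit packed) grouped by diagonal; each seeded diagonal is scanned once
and cut into maximal X-drop segments (match +1, mismatch −2, X = 20,
minimum segment score 30).  This tier is deliberately ungapped: the
generator's duplication model is point mutation, and the operative
filters are applied downstream at chaining.  The all-vs-all caller
optionally screens pairs by shared distinct k-mers before alignment
(threshold ≈ 4× the random expectation `window²/4^k`); a chainable pair
shares two orders of magnitude more.

## Subfamily classification

The tree alignment is the gapless concatenation of each retained
protein's HD and LZ profile-hit windows plus one unmutated archetype
exemplar per subfamily as anchor (equal length by construction; no
progressive aligner is bundled).  Distances are Poisson-corrected
p-distances, d = −ln(1−p), under partial-deletion site filtering (columns
with ≥ 95% non-gap coverage; the cutoff is configurable because the
upstream convention leaves it open).  Trees are canonical neighbor
joining with row-major tie-breaking; negative branch-length estimates are
clamped to zero with a per-node flag.  Bootstrap resamples columns with
replacement (default 1000 replicates); support is the percentage of
replicate trees containing the same bipartition.

A gene's tree subfamily is the subfamily of the anchors in the smallest
edge-side containing the gene and at least one anchor; mixed anchors in
that side yield "ambiguous", never an exception.  The architecture rule
table (HD+LZ → I; +CPSCE → II; +START+MEKHLA → III; +START alone → IV) is
evaluated independently and disagreement is recorded per gene — the tree
call stands, nothing is silently overwritten.

## Gene structure and motifs

Exon statistics come from the GFF3 (1-based inclusive, converted to
0-based half-open on read, gffutils-backed); intron count is exon count
minus one; empty subfamilies are omitted from summaries rather than
reported as zero.

Motif discovery is greedy multi-motif ZOOPS EM: per motif, many
subsequence seeds are probed briefly and the best few run to convergence
at each candidate width (default grid {11, 15, 21, 29, 41, 50}; the full
11–50 range is configurable), with a register-shift refinement step
because EM can lock onto an off-register local optimum.  Accepted motifs
must contain at least two sites and exceed a per-width empirical-null
baseline — the same EM run on residue-shuffled sequences — by at least
0.5 bits/column.  A raw information-content floor cannot work here:
ZOOPS EM on i.i.d. random sequences produces 1.3–2.7 bits/column of
apparent information purely by overfitting, so the floor is applied to
the *excess* over the shuffled baseline.  Among candidates, ranking is by
total excess information `w·(IC/col − null_w)`: per-column ranking
cherry-picks narrow sub-windows of a wider true motif, and raw total IC
pads motifs with background columns; the null baseline is precisely the
per-column cost of adding a column.  Accepted sites are masked before the
next motif, so no position is claimed twice.  The smoothed (MAP-style)
M-step makes the raw log-likelihood non-decreasing only to numerical
tolerance (~1e-6 relative), which the tests assert.

## Duplication calling

Tandem: same chromosome and boundary-to-boundary gap ≤ 50 kb (the
convention measures nearest edges; the 50-kb rule's reference points are
otherwise unstated).  Segmental: the 100-kb flank window (50 kb up +
50 kb down, gene body excluded, truncation flagged at contig edges) of
each gene pair is aligned; blocks are filtered (length > 200 bp, identity
> 85%, both strict) and chained by dynamic programming maximizing total
aligned length under strict collinearity, ties broken by higher minimum
identity then lexicographic order.  A pair is called when the best
chain's total aligned length reaches 2 kb — well above single-block
noise, far below planted spans; the "confirmation" criterion is not
otherwise quantified upstream, so it is exposed as config.  Same-
coordinate gene records (alternative transcripts of one locus) are
collapsed to one representative first; scaffold-located genes are
excluded from chromosome-based analyses and listed.  The chain is
computed over the concatenated window, so duplication of either flank
suffices.

## Promoter elements and enrichment

Promoters are the 1500 bp upstream of the translation start — the
workflow's operational equation of transcription start with ATG is kept,
and flagged here as a known approximation.  Scanning is IUPAC-class
matching (sequence N never matches), all overlapping occurrences, both
strands, with palindromic patterns de-duplicated by default.  Enrichment
is per (element × subfamily) on promoter presence/absence: with n genes
in the subfamily and k carriers, p = P(X ≥ k) for X ~ Binomial(n, p0),
where p0 is the whole-family carrier proportion (the family, not the
genome, is the implied reference set); Benjamini–Hochberg within each
subfamily, raw and adjusted values both reported.  Presence/absence
rather than occurrence counts keeps the Bernoulli-per-gene model exact.
Short patterns are common by chance in 1.5-kb windows, so power at
subfamily sizes 9–23 is limited; the planted cells still attain the
smallest p-values in their subfamilies.

## Expression and qPCR

Expressed means FPKM strictly above 1.  Constitutive = expressed in all
samples; non-expressed = in none; tissue-specific = expressed in exactly
one configured tissue group; partial otherwise (the strict group rule is
this package's operationalization of qualitative descriptions).  Fold
changes use log2((t + 0.1)/(c + 0.1)); the 0.1-FPKM pseudocount handles
zeros and is configurable (excluding zero-FPKM genes instead is supported
by setting the pseudocount to 0 and filtering).  Changed means
|fold change| > 2, strictly.

2^-ΔΔCt aggregates replicates by the arithmetic mean of Ct; ΔCt = target
− reference per sample, ΔΔCt relative to the calibrator, making the
result invariant under any constant Ct shift.  Duncan's multiple range
test assumes a balanced design (n = 3 replicates; unbalanced input is
rejected, not approximated): pooled within-group mean square, critical
ranges `R_p = q(α_p, p, df)·√(MSE/n)` with protection level
α_p = 1 − (1−α)^(p−1), studentized-range quantiles from scipy's
integrated range distribution (they match Duncan's published
significant-range table to two decimals), letters assigned to maximal
homogeneous intervals with containment protection.  Zero error variance
with unequal means yields all-distinct letters, not an exception.

## Problem sizes

The bundled study-scale scenario (57 members / 125 candidates, 18 × 700-kb
chromosomes, 1000-replicate bootstrap available but 300 used in the
reproduction script, 12 qPCR genes) runs end-to-end in about a minute on
one core; the full 15-motif discovery adds ~3 minutes and is run by
`analysis/04_structure_motifs.py`.  The test suite uses smaller cohorts
(e.g. 11–21 proteins, 2 duplications) chosen to exercise every decision
rule exactly.

## Known limitations

- Ungapped profile scanning and flank alignment: indel-divergent domains
  or duplications would be fragmented or missed; the generator does not
  produce them.
- The empirical E-value is calibrated per protein; cross-protein score
  comparison relies on the shared profiles, not on a unified null.
- The NJ/Poisson classification stands in for likelihood-based tree
  inference; adequate for four well-separated clades, not for fine
  within-subfamily branching.
- Planted-element truth is recorded only for originally-constructed
  promoters; a segmental copy inherits its source's (possibly mutated)
  promoter and contributes no planted-element truth rows.
- Duncan letters are computed on per-replicate relative expression with
  replicate-index pairing of target and reference wells.
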