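# Methods

This note records the models, rules, and numerical conventions behind each
stage, the choices made where the design was genuinely open, and what the
synthetic data generator does and does not emulate.

## Sequence model and coordinates

Proteins are upper-case strings over the 20 standard residues plus `X`
(unknown).  `X` is excluded from the numerator *and* denominator of every
composition fraction, so fractions stay well defined on partially determined
sequences.  Every externally visible coordinate is 1-based inclusive.
Coding sequences are in-frame on the coding strand; residue *i* owns
nucleotides 3i−2..3i, an optional trailing stop codon is tolerated, and `N`
bases are excluded from GC numerators and denominators.  Metadata
(organism, family label, phylogenetic rank) lives in a sidecar TSV keyed by
sequence id; the rank is the integer x-coordinate of the trend regressions.

## Tripartite segmentation

The core/arm boundary is not knowable from one sequence alone, so the
partition is anchored to a single reference: the user names a reference
sequence and its core interval, the interval is mapped to alignment
columns, and every row's core is the set of its own ungapped positions
covered by those columns.  When a boundary column is gapped in a target
row, the core start snaps inward to the next ungapped position and the core
end snaps inward to the previous one — the core is maximal-inside, the arms
maximal-outside.  Rows that are all-gap across the core columns are flagged
unsegmentable and excluded downstream; rows whose projected core is shorter
than a configurable fraction (default 0.5) of the reference core are
flagged partial and excluded from per-region statistics.  The configuration
accepts one reference per family when families were aligned separately.
Empty arms have length 0 in the length tables but report *missing* (not
zero) composition and disorder fractions, so family means run over
non-empty regions only.

## Charged stretches

Charged residues are K/R (positive) and D/E (negative); histidine is
treated as uncharged throughout.  A stretch is a maximal span of same-sign
charged residues, in two variants:

- **strict** (default): uninterrupted runs of ≥ 3, plus spans with exactly
  one uncharged interior position in the CCXCC/CXCCCC style, admitted from
  span 5 (≥ 4 charged).  The interior gap must be uncharged — an
  opposite-sign residue never bridges a stretch.
- **lenient**: additionally admits span-4 one-gap forms (CCXC/CXCC, e.g.
  DEGE).  Strict hits are always a subset of lenient hits.

Only maximal spans are reported; a run contained in a valid gapped span is
subsumed by it.  Two interior gaps are never admitted.  The two modes exist
because the span-4 single-gap form appears in practice as a named stretch
while the formal rule requires span 5; neither behaviour is silently merged
into the other.

## Motifs, phospho sites, tandem repeats

Patterns are ordered element lists (residue class, min-repeat, max-repeat)
parsed from PROSITE-like strings.  The scanner enumerates every repeat
combination and reports each distinct (start, end) extent once, overlapping
matches included; `x` spacers match any residue including `X`, explicit
classes do not match `X`.  Built-ins: NES `L-x(2,3)-[LIVFM]-x(2,3)-L-x-[LI]`
(no fuzzy matching — real export signals that deviate from the consensus
are out of scope for a literal scanner), NLS `RKKRKD` (scanning reduces to
exact substring search), CK2 `(S/T)-x-x-(D/E)` with the acceptor at the
S/T.  Per-region presence tables collapse hits to booleans, so they are
insensitive to how overlapping matches are counted.

Phospho sites come from the CK2 scanner and/or external tracks.  Distance
to a stretch is 0 inside it, otherwise the coordinate difference to the
nearest stretch boundary; *near* means distance ≤ W, default W = 5 residues
(the notion of "near" is not quantified in the field; W is configurable).

Tandem repeats: for each candidate period ≥ `min_unit` (default 10) and
start, copies are extended while every copy keeps identity ≥ `min_identity`
(default 0.9) to the column-majority consensus (ties broken by the first
copy).  Candidates are ranked longest-span first, then highest minimum
identity; a candidate sharing more than half its span with an accepted
repeat is suppressed.  The half-overlap rule removes both nested
sub-repeats and the ±1-phase shifts of an exact repeat, which otherwise
pass the identity threshold at (unit−1)/unit.

## GC content, isochores, trends

GC fractions are computed over A/C/G/T only.  gc_full is exactly the
codon-count-weighted mean of gc1/gc2/gc3, and the length-weighted mean of
the per-region values — both identities are tested.  Isochore classes use
half-open upward boundaries extended to a total classification:
[0, 41) → L (GC-poor, covering the L1/L2 range), [41, 46) → H1,
[46, 100] → H (very GC-rich, H2/H3).  The published ranges leave values
below 34% and the boundary points unassigned; extending L to zero and using
half-open boundaries makes the classifier total, deterministic, and
monotone.  Gene-vs-band concordance is simply equality of class labels.

Trends are unweighted ordinary least squares of GC% on rank (scipy's
linregress behind the `fit_trend` surface), per family and per part
(full/N/core/C).  No phylogenetic generalised least squares is attempted.
When one organism contributes several sequences the default is one point
per sequence; an organism-mean aggregation is available since either
reading of "one point per organism" is defensible.  Slope comparisons use
z = (a₁−a₂)/√(se₁²+se₂²) on all pairs, ordered by slope.

## Phylogenies per scope

Distances are p-distances (mismatches over pairwise-comparable, mutually
gap-free columns) — the minimal-assumption choice; model-corrected
distances are deliberate non-goals, as the downstream contracts (topology
recovery, class regrouping) are robust to the distance model at this scale.
Scope column sets are everything left (N) or right (C) of the reference
core's projected column span.  Pairs with fewer than 10 comparable columns
are missing by default; the bootstrap path instead saturates such pairs at
distance 1.0, the convention for arm blocks that are not mutually
alignable.

Neighbor joining is the classical Q-criterion agglomeration, exact on
additive matrices (verified against path-length matrices of random trees to
1e-9).  Q is evaluated on the upper triangle only, because floating-point
addition order makes the broadcast Q matrix asymmetric in the last bit;
ties are broken toward the lexicographically smallest cluster-key pair
(a cluster's key is its smallest leaf id), making the tree independent of
input order.  Negative branch-length estimates are clamped to zero with the
total deficit logged on the tree.  Bootstrap resamples columns with
replacement, B replicates under an explicit seed; an internal edge's
support is the percentage of replicate trees containing the same canonical
leaf bipartition.

**Class partitions.**  Reading "the classes" off a tree requires choosing a
level of its hierarchy, which no support threshold alone can do (every
monophyletic family is separated from everything else by its own
well-supported edge).  The partition is therefore computed as single-linkage
clustering of families on mean leaf-to-leaf patristic distance, with the
class level set by the largest gap in the merge heights; the gap must
exceed a relative factor (default 1.2), otherwise no class structure is
declared.  A split between two classes is kept only when some internal edge
with bootstrap support ≥ k_cut (default 70) separates their families by
majority side; unsupported splits are merged back.  Purity reports, per
family, the smallest majority fraction over class-separating edges — 1.0
for families whose leaves never straddle a class boundary.

## Synthetic data generator

The generator emulates the study design, not any real dataset:

- **Cores** (default 240 residues) evolve by substitutions only along a
  known class → family → taxon hierarchy (defaults 0.35 / 0.12 / 0.04
  expected replacements), so the true alignment is trivial.
- **Arms** evolve the same way from one root arm per side (class divergence
  0.30, family 0.15, taxon 0.05).  A taxon's N arm is a suffix, and its C
  arm a prefix, of its family ancestor — junction-anchored coordinates are
  column-consistent across taxa.  Arm lengths are Gaussian per family
  (means follow the emulated family portrait: N arms 31–170, C arms 0–240,
  none for families 4/5).  Composition is controlled exactly: disorder-
  promoting residues (positive TOP-IDP propensity) make up 0.80 of arm and
  0.38 of core positions, the two levels that make the windowed proxy
  reproduce the arm-vs-core disorder contrast.
- **The emitted alignment** carries one column block per arm class; a row is
  all-gap in other classes' blocks.  Arms with separate histories are not
  mutually alignable, so cross-class arm pairs share no columns and
  full-length distances stay core-driven, while within-class arm columns
  carry the planted N/C class signal.  The planted class maps default to
  the regrouping phenomenon: full {F1,F2,F3}|{F4}|{F5}|{F6,F7}, N-arm
  {F1}|{F2}|{F3}|{F6,F7}|{F4,F5}, C-arm {F1,F6,F7}|{F2,F3}.
- **Planted features** (stretches, NES/NLS, CK2 acceptors beside negative
  stretches, a 7 × 15-residue tandem repeat in family 1's C arm) are
  written at recorded junction-anchored coordinates with neutral flanks.
  Families sharing an arm class share a layout offset so planted columns
  align within, and only within, the class.  The literal NLS embeds a
  positive charged run; that run is registered in the manifest as a planted
  stretch.
- **Sanitisation**: after planting, the background (cores and arms) is
  point-mutated to neutral residues until the stretch (lenient), NES, NLS,
  and tandem-repeat detectors report planted features and nothing else.
  This is what makes "precision = recall = 1.0 at zero noise" a
  well-defined oracle.  Two consequences: at zero substitution rate, family
  cores are identical only up to these isolated sanitisation edits; and the
  CK2 consensus, too permissive to remove from background without
  distorting composition, is scored by recall only.
- **Coding sequences** fix a canonical codon prefix per residue and choose
  third bases (GC-rich vs AT) by exact count to hit a per-sequence GC3
  target of intercept + slope × rank + Gaussian noise (default sd 2
  percentage points), clipped to the feasible interval; a configured line
  outside the feasible interval (floored by the forced Met/Trp third bases)
  is an error.  GC1/GC2 follow from the amino-acid sequence.
- **Corruption** applies substitution noise to arm positions and records,
  per planted feature, whether its detector still fires at the original
  coordinates.

What the generator does **not** emulate: insertions/deletions (real arms
vary by indels, not only terminal truncation), codon substitution models,
rate heterogeneity across sites, alignment error, or the composition of any
real protein family.  Passing tests therefore demonstrate that the
detectors, regressions, and tree machinery recover what was planted under
clean conditions and degrade gracefully under substitution noise — not that
the pipeline's biological conclusions transfer to any particular real
dataset.

## Problem sizes and determinism

The study-scale configuration is 7 families × 50 taxa (350 sequences,
alignment ≈ 1300 columns) with 100 bootstrap replicates per scope; the
trend-recovery experiment uses 40 ranks × 50 replicates at slope 1.5 and
noise sd 2.  These sizes keep a complete run in the minutes range on one
CPU.  All randomness flows from explicit seeds through
`numpy.random.default_rng`; reruns with identical configuration and seed
produce byte-identical report bundles (logs carry no timestamps, floats are
formatted with a fixed precision).

## Known limitations

- The stretch rule reports maximal spans only; counting conventions that
  split a long gapped span into sub-stretches would need a different
  maximality rule.
- The NES scanner is literal; sensitivity to divergent export signals is
  explicitly out of scope.
- The class-partition gap criterion declares "no structure" on trees whose
  family distances are smoothly graded; it is designed for data with a
  genuine two-level hierarchy.
- p-distances saturate for unalignable arm pairs, which compresses deep
  arm-tree branch lengths; supports and partitions are unaffected, but arm
  branch lengths should not be read as evolutionary distances across
  classes.
- The packaged disordered/ordered reference frequency table is a synthetic
  stand-in for closed-box runs; real analyses should supply measured
  database frequencies via `disorder_enrichment`'s table argument.
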