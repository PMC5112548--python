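# Methods

## Domain model and scanner

A WRKY domain is modelled as two coupled signatures. The heptapeptide is a
4-residue tetramer slot (canonically WRKY) followed by a 3-residue tail slot
(canonically GQK). The tetramer must match either the canonical string or
one of the 28 catalogued variants (WRRY, WSKY, WKRY, WVKY, WKKY, WRIY, WRKN,
WRKD, WHQY, WRIS, WRQV, GRKY, WLKY, WREY, ARKM, WWKN, WRMY, WRKR, WIKY,
WQKY, WHKC, WRCI, FRKY, RSQY, WTKY, WKKC, WRKC, WWKS); the tail must be
within Hamming distance `tail_mismatch` (default 1) of GQK. The zinc finger
is matched as `C-x(4..7)-C-x(21..26)-H-x(1..2)-[H|C]`, the earliest match at
or after the heptapeptide within a 120-residue window, with lazy spacers so
the shortest consistent spacing is reported. Reported spacings for the
family differ between single-domain (x5 or x7 / x23 or x26) and
double-domain (x4–x5 / x22–x23) proteins, so the ranges are configuration
parameters rather than constants.

Decision rules the sources leave open, fixed here:

- **Variant gating.** A non-canonical tetramer is only called when both its
  GQK-like tail and a downstream zinc finger corroborate it. A canonical
  tetramer is retained even without an intact finger (the finger is recorded
  as absent), since truncated family members occur. Rationale: a 4-mer alone
  matches by chance roughly once per 10^4 residues; the two corroborating
  features push the false-positive rate to negligible levels while keeping
  recall at 1 on clean sequence.
- **Domain extent.** From 10 residues upstream of the heptapeptide (covering
  the conserved D-G-Y-N/R context) to the last zinc-finger residue,
  truncated at sequence bounds; without a finger, 50 residues from the
  heptapeptide start (~60 aa total).
- **Overlap resolution.** Among overlapping candidates: canonical tetramer
  first, then smaller tail mismatch, then leftmost start. Deterministic.
- **Terminal labels.** One accepted domain → SINGLE_C; two → N_TERMINAL and
  C_TERMINAL in sequence order; three or more → first/last terminal, middle
  INTERNAL.
- **X** is a legal residue but never matches any motif position.

## Architecture classification

WRKY calls and accessory-domain intervals are ordered by start coordinate,
run-length encoded, and matched against a closed template set covering the
known chimeric forms (three WRKY + ZF_SBP; WRKY + 3×CBS; kinase before one
or two WRKY; two WRKY before kinase; PAH + 2 WRKY + kinase; ULP protease,
TIR, ATP-GRASP or B3 before WRKY; TIR + LRR repeats + WRKY; LRR repeats +
NAC + 2 WRKY; WRKY + ZF_SBP). LRR blocks match "two or more" repeats — the
published exemplar has seven, but repeat counts are scanner-brittle, so the
observed count lives in the domain string, not the template. The longest
matching template wins; remaining ties fall to a fixed template order.
Proteins matching no template are labelled by WRKY count (1–4), or
CHIMERIC_OTHER if they carry accessory domains in an unrecognized
arrangement (or more than four WRKY domains, which no published survey
reports). Accessory domains are consumed as an interval table rather than
detected de novo: detection of kinase/TIR/etc. belongs to general-purpose
profile scanners, and consuming intervals keeps this classifier testable
and scanner-agnostic.

Species summaries report single/double/novel/total counts without forcing
the first three to sum to the total: published census tables allow one
protein to satisfy more than one column, and their rows do not always sum.

## Nomenclature

Prefix: genus initial (upper) + epithet initial (lower). On collision the
epithet contribution grows to the epithet's **first syllable** — first vowel
group plus the following consonant cluster minus the onset consonant of the
next syllable, minimum two letters — then letter by letter, capped at four
epithet letters. This reproduces the published abbreviation pairs (Pv/Pvul,
Cr/Crein, Pp/Pper, Cs/Csa) deterministically. One published abbreviation is
not reachable by any letter-count rule: "Csub" for *C. subellipsoidea*
follows the morpheme "sub-", while "Csa" for *C. sativus* truncates after
one vowel; the syllable rule sides with the majority and yields "Csu"
(still unique). Collision resolution is order-dependent; species are
processed in the user-supplied order.

Reference assignment scores the query's C-terminal domain against each
reference domain by global alignment (BLOSUM62, gap open −10, extend −0.5).
Rice references serve monocot queries; Arabidopsis references serve dicots
and all other lineages. Ties break by higher identity, then lower reference
number, so results are invariant to reference order. The packaged reference
panel is synthetic (generated domain sequences; see the data section).
Paralogs sharing (prefix, number) are suffixed "-1", "-2", … ordered by
genomic coordinate when a coordinate map is supplied, else by query id;
numbering is idempotent.

## Distances, trees and grouping

Columns failing a 95% site-coverage filter are removed (partial deletion);
pairwise p-distance is mismatches over mutually ungapped retained sites;
the Poisson correction −ln(1−p) is the default model and is undefined at
p ≥ 1 (raised as an error naming the pair). Neighbor joining is the
classical algorithm with lowest-index tie-breaking and negative branch
lengths clamped to zero; it is exact on additive matrices, which the tests
verify on all 15 five-taxon topologies and 100 random additive matrices.
NJ stands in for likelihood tree search deliberately: the grouping
conclusions this package supports are topology-level, and NJ is exact in
the regime the synthetic families occupy.

Group propagation is split-based and therefore rooting-invariant: a query
leaf receives the label of the smallest split side containing it whose
labelled reference members are non-empty and unanimous; if every such side
mixes labels the leaf is UNASSIGNED and flagged. The overlap report lists
every WRKY family number whose members land in two or more groups — the
operational signature of a grouping scheme that mixes lineages.

Consensus extraction reports the per-column plurality residue (gaps never
count as consensus) with HIGH (≥ 0.90 of rows) and LOW (≥ 0.50) tiers,
matching the multiple-alignment consensus thresholds used in family-wide
alignments; contiguous HIGH runs are exported as motif strings and recover
WRKYGQK on conserved families.

Discrete-gamma categories use the equal-probability discretization with
**category means** (not medians): for shape α and k categories, the rate of
category i is k·[F(α+1, α·b_{i+1}) − F(α+1, α·b_i)] with quantile bounds
b_i, which guarantees the rates average to exactly 1. Mean-based rates are
what mainstream phylogenetics packages print, and a 1-D search over α
(bounded scalar minimization of the max per-category deviation) reproduces
each published 5-category set to within 0.004. The large-α limit approaches
rates of 1 like ~1.4/√α in the outer categories (normal limit), so "all
rates ≈ 1 within 10⁻³" requires α ≳ 2×10⁶.

## Relative rate test

For an aligned triplet with designated outgroup C, columns containing a gap
or missing residue in any row are excluded (complete deletion; a pairwise-
deletion option exists but is non-default, matching how published triplet
analyses eliminate gapped positions). Retained columns partition into five
categories: all identical, all distinct, and unique differences in A, B or
C. The statistic is X² = (m_A − m_B)²/(m_A + m_B) with 1 df (0 when
m_A + m_B = 0, with p = 1), and the upper tail is computed in closed form
as p = erfc(√(X²/2)) — this matches published tables to all five printed
decimals. The continuity-uncorrected statistic is the default; a Yates-
corrected variant is available behind a flag but does not reproduce the
printed values.

The size/power simulator draws an ancestor uniformly over 20 states and
evolves A, B and C along branches of given expected substitutions per site
under the equal-rate 20-state model, using the closed-form identity
probability 1/20 + (19/20)e^(−20t/19) rather than event simulation. At
equal rates (500 sites, 2000 replicates) the empirical rejection rate at
α = 0.05 lies within 3 Monte-Carlo standard errors of 0.05; power is
monotone in rate asymmetry and sites under paired seeds.

## Synthetic data: what it emulates, and what it does not

`generate_proteome` plants domains with the exact structure the scanner
models: 6 background residues + the D-G-Y-N (N-terminal context) or
D-G-Y-R (C-terminal/single context) block, the heptapeptide, a 3-residue
linker, and a C-x4-C-x23-H-x-H finger. Zinc-finger spacer positions avoid
C and H so the planted coordinating residues are the ones a scanner finds;
after assembly, any background window that happens to spell a catalogued
heptapeptide signature is re-drawn (seeded), so at zero mutation the
planted set is recovered with precision and recall exactly 1 — that is a
designed property, not an empirical accident. Within-domain mutation (per
site, uniform replacement) degrades recall monotonically. Chimera layouts
place accessory spans at realistic lengths (kinase 250 aa, TIR 150, LRR 24,
…) and record them as the interval table the classifier consumes. Default
conditions: 10 species × 50 families × 1 paralog = 500 proteins, 25%
double-domain, 5% chimeric, 10% variant injection, uniform background
composition (configurable), mutation rate 0.

`generate_labeled_families` builds groups as clades by construction: group
ancestors diverge from a common root at `between_group_divergence`, members
from their ancestor at `per_group_divergence`, indel-free so rows are
pre-aligned. Note that because members always cluster around their own
ancestor, *any* positive between-group divergence leaves the clade
structure recoverable — even equal to the within-group rate. "No
separation" is therefore modelled as between-group divergence 0 (all
members exchangeable around one ancestor), which reliably produces
non-empty overlap reports and assignment conflicts.

What the generator does **not** emulate: indels and alignment error, codon
structure, non-uniform exchangeabilities (no JTT/WAG matrix), compositional
heterogeneity across sites or lineages, and domain families other than the
planted signatures. Passing the recovery tests therefore demonstrates
correctness of the calling, classification and grouping logic under the
model's own assumptions — not scanner sensitivity on real, noisy proteomes.

The packaged nomenclature reference panel
(`data/synthetic_reference_domains.tsv`) is likewise synthetic: 75
generated domain sequences per lineage, fixed seed, standing in for the
Arabidopsis/rice reference sets, which live in external databases. At 10%
query divergence, reference recovery against this panel exceeds 95%.

## Numerical and interface conventions

Internal coordinates are 0-based half-open; all rendered tables are 1-based
inclusive with a header note. All randomized operations take explicit
seeds; the CLI logs its resolved configuration and a config hash. Problem
sizes in the test suite (500-protein proteomes, 2000-replicate simulations,
100-matrix NJ sweeps, 100-family recovery) were chosen to give stable
pass/fail behaviour at interactive runtimes.

## Known limitations

- The scanner is a pattern matcher, not a profile HMM; weak or degenerate
  domains beyond the configured spacer ranges are missed by design.
- Maximum-likelihood tree search, bootstrap support values and empirical
  substitution matrices are out of scope; the NJ trees support grouping
  logic, not branch-length inference under a realistic model.
- Accessory domains must be supplied as intervals; the package does not
  detect them.
- Prefix collision resolution depends on processing order, as does any
  scheme consistent with the published abbreviations.
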