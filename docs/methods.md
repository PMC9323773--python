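# Methods

## Overview

`hervtrace` re-creates, at desk scale, a four-stage analysis of endogenous
retrovirus (ERV) evolution across primates: (1) discovery of full-length
proviruses in genome sequence, (2) inference and dating of
vertical-transmission events from orthologous insertions, (3) detection of
LTR-discordant element pairs as candidates for inter-element recombination,
and (4) identification of ncRNA co-option by strand-aware containment.
Because the original survey scale (dozens of primate assemblies) is out of
reach for a reproducible test suite, every stage is exercised against a
synthetic multi-species cohort with known ground truth; the ncRNA stage is
additionally exercised on a packaged 107-row human annotation table.

## Alignment core

All stages consume the same currency: identity, query/subject coverage,
raw score, bit score and e-value of local alignments.  The dynamic
programming is Biopython's `PairwiseAligner` (exact Smith–Waterman, affine
gaps).  Conventions:

- Nucleotide scoring: match +1, mismatch −2, gap open 2.5, gap extend 2.5
  (a gap of length L costs `open + (L−1)·extend`); Karlin–Altschul
  constants λ = 1.28 nats, K = 0.46 (megablast-like).  `N` aligns as a
  mismatch against everything and never counts as an identity.
- Translated (protein vs six-frame) and protein–protein scoring: BLOSUM62
  with gap open 11 / extend 1 and ungapped constants λ = 0.3176,
  K = 0.134.  Stop codons score −10⁴ against everything, so alignments
  never cross a stop; gapped alignment happens within one frame only
  (no frameshifts).
- `bits = (λS − ln K)/ln 2`; `E = K·m·n·e^{−λS}` with m, n the full
  query/subject lengths in the units of the comparison.  Hits with
  E above the cutoff (default 10⁻⁵) are discarded.

For pairs whose DP matrix exceeds 3×10⁷ cells the engine seeds candidate
subject windows with shared k-mers (12-mers for DNA, 4-mers for protein),
clusters seeds by diagonal, and runs the exact aligner inside each window,
so every reported score is the true score of a concrete alignment path.
Within a window, additional hits are surfaced by masking the best hit's
subject span and re-aligning, up to a hit cap.

Among co-optimal alignments the engine prefers the path with the most
identities.  This tie-break runs the path retrieval under a substitution
matrix whose identity cells are nudged up by 2⁻¹³ — dyadic, so perturbed
sums stay exact in doubles, and far below the 0.5 score granularity, so
the set of optimal paths cannot change for alignments shorter than ~4 kb.
The returned path's score is recomputed under the true scoring and checked
against the exact optimum; on any disagreement the unperturbed aligner's
path is used instead.  A plain quadratic-space DP implementation
(`hervtrace.swdp`, numba-jitted, same conventions, same identity-favouring
tie-break) serves as the reference the engine is validated against in the
test suite; the pipeline itself never calls it.

An adapter that parses external BLAST-family `-outfmt 6` tables into the
same hit type exists (`parse_blast_tabular`) but nothing in the pipeline
invokes an external binary.

## Provirus discovery

The discovery funnel on one genome:

1. **RT screen.** Translated search of a reverse-transcriptase (RT)
   protein panel against all six frames, e ≤ 10⁻⁵; hit footprints are
   reported in forward-strand nucleotide coordinates and deduplicated.
2. **Merging.** Footprints on one contig closer than 1000 bp (strictly
   less) are merged; merging is order-invariant.
3. **Competitive filter.** Each merged candidate is re-searched against
   ERV, host and (non-retroviral) virus panels and labelled by the
   highest-bit-score panel.  Ties retain the candidate (ERV > other virus
   > host) — losing a true ERV is costlier than carrying a false candidate
   one stage further.
4. **LTR detection.** The candidate is extended 10,000 bp on each side
   (clipped at contig edges) and the best pair of same-orientation direct
   repeats with one repeat per side is taken as the LTR pair, subject to
   length bounds (100–3000 bp), a 2× length-ratio cap and ≥80% identity.
5. **Boundary refinement.** Local alignment ends are biased: terminal
   mismatch runs get clipped, and occasional lucky gapped extensions
   overshoot into flank.  Each repeat end is therefore re-anchored 25 bp
   inside the repeat, the pairing offset re-estimated by a best-matching
   20 bp window over ±6 bp shifts, and the boundary placed at the argmax
   of an ungapped outward walk.  The walk's mismatch penalty is the
   likelihood-ratio optimum for the observed repeat identity p against a
   25%-match background, `−ln((1−p)/0.75)/ln(p/0.25)` (≈2.0 at p = 0.95,
   ≈1.3 at p = 0.85), clamped to [1.0, 2.5].  In simulation this places
   ≥95% of boundaries within ±5 bp of truth at the ≥90% twin-LTR identity
   regime; residual error is the intrinsic changepoint ambiguity of a
   mutated boundary.
6. **Gene annotation.** The inter-LTR region is searched against per-gene
   panels (gag, pro, pol, env); per-gene footprints are merged with the
   same 1000 bp rule and annotations shorter than 100 aa are discarded.
   RT-domain hits inside the pol footprint are attached to the pol
   annotation.
7. **Full-length call.** True iff an RT-bearing pol exists and the genes
   present, read along the element strand (the strand of the RT hit), form
   a subsequence of gag–pro–pol–env.  Elements failing the call are kept
   in the output flagged `is_full_length = False` for auditability.
8. **Classification.** Nearest-reference by RT identity: label of the
   highest-identity RT reference when ≥60% identity, else `Unknown`; ties
   break by bit score then lexicographic label.  Tree-placement
   classification is deliberately not implemented; similarity to reference
   RTs is the operative definition here.

## Vertical transmission

Full-length elements are extracted with up to 2000 bp of flanking host
sequence per side ("~2 kb" is implemented as exactly 2000 with clipping at
contig edges; a clipped flank under 250 bp auto-fails the coverage
condition).  A cross-species pair is accepted as orthologous iff all three
conditions hold:

1. element identity ≥90% and coverage ≥90% of the shorter element;
2. both flank pairs (upstream↔upstream, downstream↔downstream) align at
   >90% identity — flanks alone, not flank+LTR;
3. both flank coverages >25% with at least one ≥80%.

Coverage denominators are always the shorter sequence of the pair — the
symmetric reading of an unspecified denominator.  The test canonicalises
pair order internally, so it is exactly symmetric.  Same-species pairs are
refused: within-genome similarity is paralogy or recombination signal.
For all-vs-all screening, pairs sharing almost no 16-mers between element
sequences (fewer than 5 sampled hits) are skipped — such pairs cannot
reach the 90/90 condition.

Accepted pairs form an undirected graph; connected components (not
cliques — robust to one failed comparison inside a true orthology group)
of size ≥2 are transmission events.  Each event maps to the most recent
common ancestor of its species set on a time-calibrated, ultrametric
species tree; the node age is a **minimum** integration age.  The packaged
6-leaf fixture tree carries splits at 6.7, 9.1, 15.8, 20.2 and 29.4 MYA
(human–chimp through Old World monkey depths).

A consequence the simulator reproduces: with substitution rate
0.002/site/MY, flank identity at a split of age T is ≈ 1 − 2·T·0.002, so
the 90% identity floor makes events older than ~25 MY undetectable — the
deepest fixture split (29.4 MYA) sits below the horizon by design.

## LTR recombination

Within one (species × classification) stratum, each element contributes
its 5′ and 3′ LTR (element-sense sides).  An all-vs-all best-local-hit bit
score matrix (both strands, score-only) supports two calls:

- **Non-clustered flag** — a score surrogate for "the element's LTRs are
  not siblings on an LTR tree": flagged iff some foreign LTR strictly
  outscores the element's own partner LTR against either of its LTRs.  On
  small strata this agrees with a neighbour-joining sibling-pairing oracle
  in ≥95% of elements (checked in the test suite with scikit-bio NJ over
  reference-DP alignment distances).
- **Recombination call** — the reciprocal two-sided pattern: for *both*
  elements of a pair, each LTR scores strictly higher against some LTR of
  the other element than against its own partner, and the two LTRs map to
  the other element's two *distinct* LTRs.  Ties never flag.  Calls are
  deduplicated as unordered pairs.  The weaker one-sided variant (only one
  element's own-pair comparison exceeded) was considered and rejected as
  less conservative.

Cross-species LTR comparisons are excluded by construction of the strata.

## ncRNA co-option

A provirus/transcript pair is reported iff same contig, same strand,
overlap ≥1 bp, and at least one feature's overlap coverage is exactly
100% (full containment).  Coordinates are 0-based half-open internally;
the packaged human table is 1-based inclusive and converted on read.
Containment is evaluated on full genomic spans, not exon structure.  The
packaged table's element names carry provirus coordinates and the
supergroup as a suffix; 26 of the 107 printed rows have transcript and
provirus intervals that cannot satisfy the containment contract (some do
not even overlap).  These rows are retained for the per-chromosome and
per-supergroup summaries — fidelity to the printed annotation — but
flagged by a validator; the intersection operation itself reports only the
81 self-consistent rows.

## Synthetic cohort

The generator emulates the evolutionary structure the orthology test
assumes, not primate genome composition.

- **Loci.** Each insertion occupies its own contig: up to 2600 bp of
  random flank (GC 0.41), the element, and another flank.  The locus
  exists in every species; the element appears in all and only the
  descendants of its assigned tree node (configurable per-species losses
  create e.g. a Homo+Gorilla-only orthology group via loss in Pan).
- **Elements.** Two initially identical LTRs (350 bp, a 2%-mutated variant
  of a per-supergroup consensus) flanking back-translated gag (140 aa),
  pro (110 aa), pol (340 aa, with a central 180 aa RT slice) and env
  (130 aa) proteins separated by 30 bp spacers; ~25% of insertions are
  planted on the minus strand.  Supergroup consensus proteins and LTRs are
  derived deterministically from the seed for all 11 supergroup labels, so
  the emitted reference panels (RT, per-gene, host and viral decoys) are
  consistent whether or not a supergroup is planted.
- **Evolution.** Jukes–Cantor per-site substitution at 0.002
  substitutions/site/MY down each branch (optional transition bias;
  indels available but off by default), applied independently to flanks,
  LTRs and internal sequence, giving expected leaf-pair divergence
  2·rate·split-age and independently diverging twin LTRs.  The rate is a
  mammalian-neutral-scale choice that places the fixture tree's deepest
  split just beyond the orthology detectability horizon.
- **Recombination.** Swaps exchange the 5′ LTRs of two same-species,
  same-supergroup leaf elements after evolution; a lighter per-stratum
  simulator (`simulate_ltr_stratum`) generates LTR-only strata with
  element divergence 6%, twin divergence 1% per copy and 0.5% post-swap
  mutation for the recombination analyses.
- **ncRNA.** For elements of a designated species, annotations are placed
  fully containing the element on the same strand for a set fraction,
  plus partial-overlap, opposite-strand and background decoys.
- **Determinism.** All randomness flows from `numpy` generators keyed by
  `(seed, stage, index)`, so identical configurations produce
  byte-identical FASTA and truth tables.

What passing on this cohort does *not* show: robustness to repeats and
segmental duplications, solo-LTR formation, indel-rich divergence,
assembly gaps, or GC/isochore structure of real primate genomes.  The
pipeline's behaviour on real assemblies is bounded, not established, by
these tests.

## Problem sizes and numerical choices

The shipped analyses use a 6-species cohort with 13 insertions (including
two single-species and one below-horizon insertion), a 50-element
single-genome discovery benchmark with an element-free control of equal
size, a 50-element recombination stratum with 5 planted swaps plus 100
swap-free 10-element replicates, 200 random pairs (≤400 nt) for
engine-vs-reference-DP score agreement, and 500×500 random feature sets
for the containment oracle — sizes chosen so the full suite completes on
a single CPU in well under half an hour while every stage is exercised at
a scale where its failure modes (boundary noise, near-threshold identity,
component merging) actually occur.

Degenerate inputs: empty sequences, non-IUPAC symbols and empty reference
panels raise input errors naming the offence; a missing flank fails the
orthology coverage condition rather than raising; elements missing an LTR
are skipped with a warning in recombination strata; unparseable element
names count as `Unknown` in summaries.

## Known limitations

- Classification is nearest-RT-reference, not phylogenetic placement;
  labels are only as good as the reference panel.
- The LTR detector assumes exactly one provirus per extension window; a
  tandem pair of elements within 10 kb would confuse the repeat search.
- Recombination detection presumes both LTRs present; solo LTRs and
  internal-region breakpoints are out of scope.
- E-values use a simple m×n search space without length corrections, so
  absolute e-values for very short queries are optimistic; all thresholds
  in the pipeline operate far from that regime.
- The event count per node is a lower bound tied to the detectability
  horizon; deep events surface, if at all, at too-recent nodes (their
  MRCA age remains a valid minimum age).
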