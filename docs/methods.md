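# Methods

## The model

`satevo` studies tandem satellite arrays — ordered copies ("monomers",
~120 bp here) of a repeated unit on one molecule — under the three
processes that dominate satellite evolution:

* **Point substitution.** Per generation each array receives
  Poisson(`mu`·sites) substitutions; the site is uniform and the new base
  is uniform over the three alternatives. This is exactly the Jukes–Cantor
  (JC69) process, so mutation-only runs are checkable against the closed
  form `p_diff = ¾(1 − e^(−4d/3))` with `d = 2·mu·T` for two lineages
  separated by `T` generations each. Branch-specific multipliers
  (`rate_multipliers`, keyed by leaf or internal-node label) scale `mu` on
  a named branch and nothing else.
* **Gene conversion.** Poisson(`gc_rate`) events per array per generation;
  donor and recipient units uniform and distinct; tract start uniform in
  the monomer; tract length geometric with mean `gc_tract_mean` (support
  ≥ 1 bp, clipped at the monomer end); the donor tract overwrites the
  recipient non-reciprocally.
* **Unequal crossover.** Poisson(`uxo_rate`) events per array per
  generation. The array recombines with a copy of itself misaligned by
  `k` monomers (`k` geometric with mean `uxo_offset_mean`, support ≥ 1);
  a uniform breakpoint is drawn and the longer (n+k) or shorter (n−k)
  product is kept with equal probability. Offsets whose product would
  leave `[min_copies, max_copies]` are resampled (up to 100 draws, then
  the event is dropped), so arrays neither go extinct nor explode.

Within a generation the order is fixed — substitutions, then conversions,
then crossovers — so the event log is replayable: applying the log to the
ancestral array reproduces each leaf bit-exactly, which is both the
simulator's correctness oracle and the ground truth for benchmarking the
analysis stack. Crossovers act on monomer boundaries only and there are no
indel mutations, so every unit keeps the ancestral monomer length and
remains traceable to an ancestral monomer. One RNG stream per `evolve()`
call, with a fixed preorder branch traversal, makes runs fully determined
by the seed. Branch lengths are interpreted as integer generation counts.

What the simulator deliberately does not model: mid-monomer crossover
breakpoints, indel mutations (real satellite units vary in length; here
length variation enters only through partial units at contig ends),
paired-end read structure or indel sequencing errors, selection on repeat
content, and exchange between arrays on different chromosomes. Passing
tests therefore show that the analysis stack recovers truth under this
idealized generative process — not that it is robust to assembly artifacts
or length-variant-rich real data.

## Alignment and identity

All identity statistics rest on one pairwise aligner (Gotoh three-state
DP, numba-compiled): Needleman–Wunsch and Smith–Waterman with affine gaps,
where a gap of length L costs `gap_open + L·gap_extend`. Default scoring
is +1/−2 with gaps −4/−1 — BLAST-like, tuned for the 55–100 % identity
range satellite families span. `N` never matches anything, a conservative
choice for low-support consensus columns. Traceback ties break
deterministically (diagonal, then up, then left; gap closure preferred
over extension), and the implementation is checked against an exhaustive
alignment-enumeration oracle at short lengths and against an independent
aligner's scores at random lengths.

Percent identity defaults to the **count-gaps** policy (identical columns
over all alignment columns, single-gap columns non-identical); the
exclude-gap-columns policy is available as a flag since published
identity values do not always state their gap treatment.

## Homology search and capture

Searches run full Smith–Waterman per query/subject pair, report the best
local hit, split the subject at the hit, and recurse into the flanks —
yielding all non-overlapping significant alignments, the natural output on
tandem arrays. Significance is Karlin–Altschul `E = K·m·n·e^(−λS)` with λ
solved from the scoring scheme and background composition and `K` fixed at
0.1; this applies ungapped theory to gapped scores, which is the classic
approximation and adequate because the thresholds themselves (exclude
E > 0.1 or span < 30 bp; review-flag E > 0.001 and span < 50 bp) are
operating points, not physical constants. Hits in the review window are
kept and machine-flagged rather than silently dropped. Iterative capture
re-queries with everything captured so far (after strand-aware exact
duplicate/substring removal) until a round adds nothing new; the per-round
trace records hit and capture counts.

## Unit extraction, merging, classification

Contigs are tiled by maximal non-overlapping consensus matches on both
strands; units shorter than 90 % of the consensus are flagged partial and
excluded from trees and identity summaries (but counted in extraction
accounting). Identical-sequence length variants merge when they share an
exact overlap and each member's overhang is < 50 % of the merged (union)
length; the member's-own-length denominator is available as a flag. The
union rule as stated is permissive — any equal-length pair with a 1-bp
terminal overlap would satisfy it — so merging additionally requires the
overlap to cover at least half of the shorter fragment, i.e. the pieces
must plausibly be length variants of the same repeat. Merging applies to
closure in deterministic order (longest, then lexicographic) and is
idempotent.

Consensus building is center-star progressive alignment on the identity
medoid with majority-rule columns (alphabetical on ties; columns > 50 %
gapped dropped) — deterministic and adequate for unit sets above ~70 %
identity, not a general MSA. Classification scores each unit against the
Left and Right canonical consensuses (global, count-gaps): best ≥ 90 % →
canonical Left/Right (argmax, ties to Left); 79.5–90 % → variant;
55–79.5 % → family-divergent; below → unknown. The band edges are
configurable constants with those defaults.

Dimer detection computes mean unit identity at lags 1–4 along the array.
Because a true period-p structure peaks at every multiple of p, the period
estimate is the smallest lag within one identity point of the maximum
(a strict arg-max would flip between lag 2 and lag 4 under drift noise);
the array is called dimeric when the period is 2 and lag-2 identity
exceeds lag-1 by ≥ 5 points.

## Statistics

Identity summaries report the mean of all pairwise identities and an
empirical 95 % interval — the 2.5th/97.5th percentiles (type-7 linear
interpolation) of the pairwise-identity distribution, not a normal-theory
CI, so the upper bound can sit exactly at 100 when identical pairs exist.

The permutation homology test shuffles the nucleotides of both sequences
each replicate (a single-side mode exists for sensitivity checks),
re-aligns globally, and reports `p = (#{null ≥ observed} + 1)/(B + 1)`;
the add-one convention gives the exact floor `1/(B+1)` — with the default
B = 10,000 the strongest reportable result is p < 10⁻⁴. Type-I error is
verified by calibration on independent composition-matched sequences.

The concerted-evolution score is Δ = mean within-group %ID − mean
between-group %ID over labelled units, with a group-label permutation
null (pairwise identities computed once and reused across permutations).
Δ > 0 with small p is the homogenization signature.

## Trees

Distances on aligned units code each maximal run of columns gapped in
exactly one of the two rows as a single fifth-state "indel event":
distance = (mismatches + events)/(compared sites + events). Coding is
pairwise rather than column-global, and a gap run of any length counts
once (run-length invariance is property-tested). Trees are classic
Saitou–Nei neighbor joining with deterministic Q-matrix tie-breaking
(label order) and negative branch estimates clamped to zero with the
deficit moved to the sister branch; NJ's exactness on additive matrices is
the central oracle (100 random additive matrices, Robinson–Foulds 0 and
patristic distances to 1e-9). Bootstrap resamples alignment columns,
recomputes distance + NJ, and reports per-edge bipartition frequencies.
Monophyly uses unrooted semantics: a leaf set is monophyletic iff some
edge separates exactly that set. Trees are unrooted throughout, with an
explicit root-on-outgroup-ancestor operation.

## Study conditions (scenario defaults)

No field-calibrated per-generation rates exist for these processes, so the
scenarios fix desk-scale conditions in which each mechanism's signature is
theoretically expected, chosen once at design time:

* **Monomer and dimer.** 120-bp monomers; Left/Right seeds at ~84 %
  identity (19/120 sites), matching the canonical dimer divergence.
* **Concerted scenario** (`concerted_scenario`): 16 identical ancestral
  copies, `mu` = 5×10⁻⁵, `uxo_rate` = 0.1 (offset mean 2),
  `gc_rate` = 0.2 (tract mean 80 bp), bounds [4, 64], tree
  `((A:600,B:600):300,C:900)`. Rationale: each unit is overwritten by
  conversion roughly once per 80 generations — fast against the
  per-branch drift of `mu·T` = 0.03/site — which is the "turnover beats
  drift" regime in which within-species identity should stay above
  between-species identity.
* **Null scenario**: identical except `uxo_rate = gc_rate = 0`; units then
  drift independently and within- and between-species identity share one
  expectation, giving the score's null calibration.
* **JC scenario**: two species, mutation only, `T` chosen so `2·mu·T`
  equals the target divergence.
* **Accelerated scenario** (`accelerated_scenario`): 16 copies,
  `mu` = 10⁻⁵, `uxo_rate` = 0.3 (offset mean 3), `gc_rate` = 0.3 (tract
  mean 110 bp ≈ full monomer), bounds [4, 48], tree
  `((A:800,B:800):400,C:1200)`, substitution multiplier 5 on leaf A.
  Turnover here is strong enough that each lineage homogenizes within its
  terminal branch, and the accelerated branch accumulates ~5× the shared
  stem substitutions of its sisters.

Benchmark problem sizes (100 additive matrices; 200 calibration
repetitions at B = 999; 50 simulation replicates for recovery rates; 20
replicates for JC; 1000 random fragment sets) are the package's documented
evaluation conditions.

## Known limitation: what a substitution multiplier can and cannot do

In this model, whether a species' units form a monophyletic NJ clade is
governed primarily by exchange-mediated homogenization: unit lineages (and
unit sequences, via conversion) must coalesce within the species' terminal
branch. The substitution multiplier scales the shared stem signal of the
focal lineage — but it scales that lineage's within-species polymorphism
by the same factor, and it does not speed up lineage sorting at all.
Exploration across the parameter space showed a correspondingly sharp
knife edge: under conditions where the accelerated lineage is reliably
monophyletic (≥ 90 % of replicates), the unaccelerated control is itself
monophyletic in well over half of replicates; under conditions where the
control interleaves reliably (< 50 %), incomplete sorting also caps the
accelerated lineage near 80 %. The defaults favour the first regime — the
accelerated-lineage clade is the pattern of interest — and the benchmark
reports both rates (typically ~90–95 % vs ~75 %). A sharper contrast would
require acceleration of the exchange processes themselves on the focal
branch, which the model intentionally keeps lineage-uniform.

## Numerical and degenerate-input choices

* Geometric laws ("1 + geometric" offsets/tracts) are implemented as
  numpy's geometric distribution — support ≥ 1, mean equal to the stated
  parameter.
* Identity percentiles use numpy's default type-7 interpolation.
* The NJ Q-matrix tolerance for ties is 1e-12; bipartitions are
  canonicalized by the smaller side.
* Empty local alignments (no positive-scoring pair) carry score 0 and
  raise on percent-identity; empty sequence inputs raise everywhere.
* Arrays at the copy-number bounds resample crossover offsets
  (reflection); an array of fewer than 2 units receives no conversions.
* PHRED qualities encode the read error rate as a constant
  `Q = −10·log₁₀(e)` clamped to [2, 40]; error-free reads carry Q40.
* Reads are single-end and forward-strand so that error-free reads are
  literal substrings of the array — a deliberate simplification for
  testability.
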