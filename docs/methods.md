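# Methods

## The data model

A larva of a "thummi"-complex chironomid carries four chromosomes (arm
combination AB CD EF G, haploid n = 4). Each of the seven arms A–G is
scored as a *genotypic combination*: an unordered pair of named banding
sequences (e.g. `A1.2`). Banding sequences therefore behave as alleles at
seven loci. A population sample is a set of larvae from one locality,
optionally pooled over collection dates; B chromosomes are recorded as a
per-larva count, and population-level B-chromosome "frequency" is the
*carrier* fraction (larvae with ≥ 1 B chromosome), since per-cell counts of
supernumeraries are not stable enough to treat them as segregating alleles.

## Rearrangement algebra

A banding sequence's order is a **signed permutation** of band segments:
the mapping notation in which a region is written right-to-left (e.g.
`15c-12v`) encodes a reversed reading, so orientation is part of the data.
One segment represents one maximal region shared by all sequences of an
arm, not an individual band — region-level granularity keeps exact search
tractable and matches how inversions are actually scored under the
microscope.

- An inversion is a **reversal** of a contiguous interval: the segment
  order flips and every segment's orientation flips. A reversal is an
  involution. It is *pericentric* when the reversed interval spans the
  centromere boundary (`centromere_index`, a boundary position with the
  centromere mapped at a defined end of the arm), *paracentric* otherwise.
- The **breakpoint count** b(x, y) is the number of segment adjacencies of
  x (two end caps included) absent from y in either reading direction with
  signs. Whole-order reflection (reverse + negate) is treated as identity
  everywhere: a squashed chromosome has no intrinsic left–right. Both the
  signed (default) and unsigned variants are computed; signed is the
  faithful model of oriented regions.
- **Minimal inversion steps** is the length of the shortest reversal series
  connecting two orders, found by bidirectional breadth-first search over
  canonical forms (minimum of an order and its reflection). Each reversal
  breaks/creates at most two adjacencies, giving the working bounds
  ceil(b/2) ≤ steps ≤ b. Exact search is limited to 12 segments and a step
  budget (default 16); beyond it the breakpoint lower bound is returned
  with an `exact=False` flag rather than a guess.
- **Hypothetical sequences** are the unobserved orders interior to at least
  one minimal reversal path between two observed sequences, enumerated by
  meeting forward and backward BFS layers; they are emitted in a
  deterministic order (sorted canonical forms) and labelled class
  `hypothetical`. Reported intermediates are canonical forms, so a printed
  order may be the mirror reading of the form a cytologist would draw —
  the two are the same chromosome under the reflection convention.
- The **derivation graph** attaches every non-main sequence to its
  minimal-steps ancestor among registry members, ties broken toward the
  arm's root and then lexicographically. Translocation-derived sequences
  cannot arise by reversals, so they are attached only through their
  annotated parent and flagged `kind=translocation`. Registry entries
  without transcribed orders fall back to their annotated parent/steps/kind;
  unattachable sequences are reported per arm as orphans, not silently
  dropped.

The packaged registry carries the 40 named banding sequences of
*Chironomus borokensis* with classes and derivation annotations (including
the three-step complex origin of `p'borA5` and the single-step derivations
of `p'borA8`/`p'borA9` from it). The literature records one sequence under
both `p'borA2` and `h'borA2`; the registry uses `h'borA2`, consistent with
its Holarctic, alternative-class status. Band-by-band orders for the 40
sequences exist only in unpublished mapping material, so the registry marks
them as stubs; the rearrangement engine is validated on synthetic orders
with known generation history instead.

## Polymorphism statistics

A larva is *heterozygous* if at least one arm carries two different
sequences; its *heterozygous inversions* count is the number of
heterozygous arms. Species-level figures are unweighted across populations
(populations, not larvae, are the sampling unit), reported as mean ± SE
with the SD alongside, and populations below `min_n` larvae (default 10)
are excluded and listed.

**Hardy–Weinberg.** The default test is the exact conditional test on
genotype counts given allele counts (Levene's distribution): full
enumeration for two alleles, seeded Monte Carlo permutation of the allele
vector (Guo–Thompson style) for more. Exact conditional tests on discrete
data are conservative — their size is strictly below the nominal level — so
a **mid-p** variant (tables exactly as probable as the observed one counted
with weight 1/2) is provided; mid-p is the variant whose simulated type-I
error sits on the nominal 0.05, while the plain exact p guarantees validity
(size ≤ α). A chi-square test with expected counts from allele frequencies
is available for comparison. The direction of deviation compares observed
and expected heterozygote totals.

**Pooling.** Samples taken in different years at one locality are combined
when no banding sequence shows a significant frequency difference:
per-sequence 2×2 allele-count tables (focal vs rest) under Fisher's exact
test, Bonferroni-corrected over all tested sequences. The classical angular
φ-transformation z-test (φ = 2·arcsin√p), the textbook tool of Russian
biometry for this task, is offered as `method="phi"`; Fisher's exact test
is the modern default. With Bonferroni correction the family-wise error is
conservative, so under the null same-locality samples pool in ≥ 95 % of
cases at α = 0.05.

## Classification and cytogenetic types

Main sequences are **designated a priori** as serial 1 of each arm (the
naming convention numbers the main sequence first); they remain "main" even
where they are not dominant, which is exactly what the type system
describes. For the rest the precedence is: *unique* (exactly one carrier
larva in the whole data set), then *alternative* (seen in both homo- and
heterozygous state, present in at least `min_populations` populations,
default 2, and dominant — frequency > 0.5 — in at least one), then *rare*.
The published verbal definitions do not cover every profile (a het-only
sequence at frequency 0.3 satisfies neither the rare low-frequency clause
nor the alternative clause), so *rare is the residual class*: this keeps
the guarantee that classification is a partition of everything observed.
The `rare_threshold` (default 0.10) and dominance threshold (0.5) are
exposed as parameters.

A population's **cytogenetic structure type** is the concatenation, in
A→G order, of the letters of arms whose main-sequence frequency is ≤ 0.5
("0" if none). A frequency of exactly 0.5 counts as *not* dominant, since
dominance is defined as "higher than 0.5". Typing is monotone: lowering a
main frequency can only add letters.

## Distances and trees

The default metric is **Nei's (1972) standard genetic distance** with gene
identities summed over all arms (arms as loci, sequences as alleles):
D = −ln(J_ab / √(J_a·J_b)). This choice matches the scale of published
between-population cytogenetic distances (order 0.001–0.5 within species,
~0.7 between the closest sibling species); the per-locus-averaged Nei
distance and the Cavalli-Sforza & Edwards chord distance are provided
behind a `metric` flag so a user can calibrate against a specific published
matrix. No pseudo-count smoothing is applied: a zero cross-population
identity yields an explicit `+inf` flag rather than a silently shrunken
value.

**Neighbor joining** is the standard Saitou–Nei agglomeration on the
Q-criterion. Ties in Q are broken by the lexicographic order of the
smallest leaf labels under the candidate pair, making output deterministic.
Negative branch-length estimates (possible on non-additive input) are
clamped to zero and logged. On additive matrices the algorithm recovers the
generating topology exactly. Trees are written as Newick with the final
trifurcation as root; matrices as square PHYLIP with names truncated/padded
to 10 characters (duplicate truncations are an error, not a silent rename).

## Synthetic data

The generator emulates the statistical structure of a multi-population
karyological survey; every draw flows through one seeded
`numpy.random.Generator`.

- **Genotypes** per arm follow a Hardy–Weinberg distribution with a single
  deviation knob F: P(hom ii) = p_i² + F·p_i(1−p_i),
  P(het ij) = 2·p_i·p_j·(1−F). F = 0 is the null; F > 0 gives heterozygote
  deficit; F < 0 (allowed down to −min_i p_i/(1−p_i)) models heterozygote
  excess of the kind occasionally reported in single arms.
- **B chromosomes** are Bernoulli carriers at the configured frequency.
- **Reversal series** derive an order from the identity by k random
  reversals. With `non_overlapping` set the intervals are pairwise disjoint
  and non-adjacent, which forces 2k breakpoints and hence minimal distance
  exactly k (checked at generation time) — ground truth for the search
  engine.
- The built-in **"paper-like" scenario** has 21 populations with the
  locality codes, sample sizes (10–734 larvae) and regional structure of a
  published Palearctic survey design: Europe/Ural/East-Siberia profiles
  with every main sequence dominant (type 0), West-Siberian profiles with
  the arm-G alternative near fixation (type G, plus DG/FG/DFG variants and
  elevated arm-D/arm-F alternatives), and Far-East ADG and F profiles —
  seven types in total. Frequency profiles were fixed once from that
  qualitative description (main sequences 0.75–0.95 where dominant,
  displaced mains 0.1–0.45, alternatives carrying the remainder); the
  statistics computed from the simulation (e.g. ~80 % heterozygous larvae,
  ~13 sequences per population, Nei distances up to ~0.27) are outputs of
  those choices, not calibration targets. B-carrier frequencies up to 0.30
  are placed in 13 of the 21 populations.

What the generator does **not** emulate: real surveys have many
singleton/unique sequences (a frequency-parameterized generator cannot make
"exactly one larva ever" a design property), linkage between arms,
temporal frequency change between collection dates, drift/migration
structure within regions, and scoring ambiguity between similar sequences.
Passing end-to-end tests therefore demonstrates correct recovery of
frequencies, types, classes and regional clustering under clean sampling —
not robustness to cytological misscoring.

## Numerical and testing choices

- Exact reversal search: BFS over canonical (reflection-minimal) forms; the
  test suite checks it against an independent iterative-deepening search on
  500 random instances (≤ 8 segments, ≤ 3 reversals) plus breakpoint-bound
  and involution invariants.
- HW exact p-values are computed in log-space with a 1e-12 tie window and
  are checked against full enumeration in exact rational arithmetic for
  N ≤ 50; the mid-p type-I rate is simulated at 2,000 replicates (N = 50,
  p = 0.5) and must sit inside the binomial 95 % band around 0.05, while
  the plain exact rate must stay below the band's upper edge (it is
  conservative by construction, so a two-sided band around the nominal
  level is not an attainable property for it). Power is checked at F = 0.3,
  N = 100.
- End-to-end recovery runs the 21-population scenario at N = 500 per
  population and requires mean absolute frequency error < 0.02 per
  population. (A *per-cell* 0.02 bound is not statistically attainable at
  N = 500: the binomial SE of a 0.45 frequency is ≈ 0.016, so among ~250
  estimated frequencies several exceed 0.02 error with near certainty; the
  MAE form is the meaningful reading of the same tolerance.) Types and
  class labels must be recovered exactly, and the NJ tree must contain the
  type-0 group and the West-Siberian group as clades.
- NJ is validated by exact topology recovery on 100 random additive trees
  (4–10 leaves, branch lengths ≥ 0.1) and cross-checked against an
  independent reference implementation; Newick output is round-tripped
  through an independent parser.
- Problem sizes in tests and in `scripts/acceptance.py` (500 search
  instances, 2,000 HW replicates, 100 NJ trees, N = 500 recovery) were
  chosen to make sampling noise negligible relative to the asserted
  tolerances while keeping the default run fast on one CPU.

## Known limitations

- Reversal distances use exact search only (no Hannenhalli–Pevzner closed
  form); orders above 12 segments get a flagged lower bound.
- The exact HW test for > 2 alleles is Monte Carlo, so its p-values carry
  simulation error (~1/√n_mc); the seed is explicit.
- Pericentric inversions are modelled within a single arm's order via the
  centromere boundary; full two-arm concatenated modelling is supported by
  the data structures (`source_arm` tags) but the packaged registry does
  not yet carry transcribed two-arm orders.
- Cytogenetic distances depend on which sequences were scored; tables are
  compared over shared arms with unobserved serials imputed as frequency 0,
  which is only sensible for surveys scored against a common registry.
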