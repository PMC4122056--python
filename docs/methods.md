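# Methods

## Problem and model

`rnajoint` predicts the joint secondary structure of two interacting
RNA strands R′ and R″: a set S of nested intramolecular base pairs in
each strand plus a set H of intermolecular (hybrid) pairs. Hybrid
pairs are allowed to cross intramolecular pairs — that is the
kissing-hairpin geometry this class of interactions is known for — but
each intramolecular set must be nested within its strand, and the
hybrid set must be antiparallel-consistent (positions ascending on R′
pair with positions descending on R″). Every base joins at most one
pair, and no pair is "lonely" (each pair has a stacked neighbor).

The search space is derived from a complementarity dot matrix over the
concatenation R = R′ N R″: cell (i, j) is 1 iff r_i can pair with
r_{l−j+1} under Watson-Crick (A-U, C-G) or wobble (G-U) rules.
Maximal anti-diagonal runs of 1s — *sub-diagonals* — are candidate
helices. Enumeration applies four exclusions: canonicalization (only
pairs a < b, so each biological pair appears once although the matrix
is mirror-symmetric), the separator position never pairs,
intramolecular pairs must enclose at least `min_hairpin_loop` unpaired
bases, and runs shorter than `min_pairs` are dropped. Runs are
homogeneous in kind (stem of R′, stem of R″, or hybrid) because any
run crossing the separator hits a zero cell.

Wobble filtering: a sub-diagonal whose G-U fraction strictly exceeds
`gu_threshold` has its G-U pairs removed and the remains re-segmented
into maximal runs; shorter-than-`min_pairs` fragments are discarded.
The threshold default of 0.14 is the wobble-pair frequency observed in
curated interacting sRNA–mRNA pairs; it is a dataset statistic, not a
tuned constant, and both the threshold and the strict-inequality
reading are configurable.

## Phenotype construction

A genotype is a bit-tuple over the deterministically ordered
sub-diagonal set (stems of R′, stems of R″, hybrids; within a
category, by first pair ascending). The phenotype walks active
sub-diagonals in that order; for sub-diagonal k the surviving set C_k
is its pairs minus (a) pairs sharing a base with anything accepted
earlier and (b) pairs crossing an accepted pair of the same class.
C_k is then pruned of lonely pairs *to fixpoint* (one removal can
isolate another pair; a single pass would not restore the invariant).
Empty C_k are dropped. First-come-wins crossing removal is the
minimal extension of base-sharing conflict resolution that keeps every
individual renderable in bracket notation and evaluable by any
nested-structure energy backend; it is applied per class so hybrids
can still cross stems.

The construction is order-dependent by design: the same bits with the
same sub-diagonal order are bit-for-bit reproducible.

## Energy model

Fitness(P) = MFE(S) + MFE(H), evaluated separately: the intramolecular
energy of each strand plus the hybrid energy, summed. Energy backends
are pluggable; two are provided.

The built-in model is a deliberately small nearest-neighbor scheme
with an embedded 6×6 ordered stack table (Turner-style magnitudes,
kcal/mol, symmetric under strand flip so a helix scores the same read
from either end) and the following loop terms:

| term | form | default |
|---|---|---|
| hairpin loop | a + b·ln(size), size ≥ 3 | a = 3.5, b = 1.1 |
| bulge/internal loop | a + b·ln(size), size ≥ 1 | a = 1.7, b = 1.1 |
| multiloop | init + per-branch | 3.4 + 0.4·branches |
| hybrid region initiation | per maximal region | 4.1 |
| terminal wobble | per G-U helix/region end | 0.5 |

All Watson-Crick/Watson-Crick stacks are stabilizing, and loop
penalties are non-negative and non-decreasing in size, so extending a
helix by a Watson-Crick stack never raises the energy. Hybrid energy
is computed per maximal region (initiation + stacks), with an
internal-loop penalty for the unpaired bases between consecutive
regions. Dangling ends and coaxial stacking are omitted; the model is
meant to rank candidate structures plausibly and keep every documented
example computable by hand, not to reproduce a full thermodynamic
parameter set.

The external backend renders each component in dot-bracket form and
shells out to a structure evaluator (`RNAeval`; the two-strand `&`
dialect is used for H). It is an alternative backend and a
cross-check, never required by the tests.

## Genetic algorithm

Defaults: population h = 40, at most I = 20 generations, crossover
rate 0.9, mutation rate 0.1, initialization cap of max(n, m) active
helices per individual, stagnation patience 5.

- **Initialization**: the number of active bits is drawn uniformly from
  [1, min(|D^R|, cap)], then that many sub-diagonals are chosen
  uniformly without replacement.
- **Selection/elitism**: populations are kept sorted by fitness
  (ascending); the top ⌈(1 − crossover_rate)·h⌉ individuals transfer
  unchanged. This guarantees the best fitness is monotone
  non-increasing, which the stagnation-based termination presumes.
- **Crossover**: the remainder is refilled by single-point crossover of
  consecutive fitness-ranked parents (1st×2nd, 3rd×4th, …, cycling),
  cut position uniform in [1, |D^R|].
- **Mutation**: ⌈mutation_rate·h⌉ randomly chosen *non-elite*
  individuals swap one active bit for an inactive one; if the newly
  activated helix is fully conflicted away (contributes no pairs),
  another inactive bit is tried, up to |D^R| attempts (a finite bound
  covering all candidates). Restricting mutation to non-elite ranks
  preserves the monotonicity guarantee.
- **Termination**: best fitness unchanged for `patience` generations
  (converged) or the generation cap.

A single seeded RNG stream is consumed in documented order
(initialization → per-generation crossover cuts → mutation choices), so
identical configuration, seed and inputs give bit-identical results.

## Synthetic fixtures

The generator plants a known joint structure: each strand gets one or
more perfect hairpins, and the loop of the first hairpin of each strand
holds one hybrid site — a kissing-hairpin interaction with all planted
pairs Watson-Crick. Defaults (n = m = 30, one 4-pair stem per strand,
one 8-pair hybrid) are sized so that the planted hybrid is the dominant
element of the search space.

Backgrounds: `LOW_COMPLEMENT` draws background positions as A and
planted element sequences from {G, C} — U never occurs, so background
bases cannot pair at all and the only complementarity is among the
strong G:C planted elements (plus short accidental G:C runs between
them). `RANDOM` draws everything uniformly over A/C/G/U, adding
realistic spurious complementarity and weaker planted helices.

What passing fixture tests shows — and what it does not: recovery of a
planted dominant hybrid demonstrates that the search machinery and the
energy ranking work together as designed, at the problem sizes stated
above. Real sRNA–mRNA pairs are longer, have many energetically
comparable competing helices, non-uniform base composition and
non-Watson-Crick structure; accuracy on such data depends on the
energy backend and is not established by these tests.

## Numerical and degenerate-input choices

- Coordinates are 1-based and inclusive everywhere in the public API.
- T is silently read as U; other IUPAC ambiguity codes are rejected.
- Metric denominators of zero (no predicted or no reference pairs)
  yield 0 with a logged warning, matching how empty predictions are
  scored in the published benchmark tables.
- Comparisons against printed table values round half-up to the
  table's own number of decimals. Recomputing every printed F from
  its printed Sn/PPV flags five rows, three of which (SgrS-ptsG,
  DsrA-Rpos, MicA-lamB) are exact *truncated* renderings of the
  recomputed value — the table evidently truncated rather than rounded
  some entries — and two of which (IncRNA54-RepZ by 0.42, GcvB-livK by
  2.99) are genuine discrepancies. The consistency report flags and
  classifies them; it never adjusts them.
- Fitness ties are resolved by Python's stable sort, keeping runs
  deterministic.
- Mutation on a genotype with no active or no inactive bit is the
  identity.

## Known limitations

- The built-in energy model is simplified; absolute energies are not
  comparable to full thermodynamic evaluators, only rankings are
  meaningful.
- Pseudoknots beyond the stem/hybrid crossing inherent to kissing
  hairpins are not representable (one bracket alphabet per kind).
- Exactly two strands; no alignments, no partition functions, no
  suboptimal-structure enumeration, no temperature dependence.
- The GA is a heuristic: it offers no optimality guarantee, and on
  landscapes with many near-degenerate optima different seeds can
  return different structures of similar energy.
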