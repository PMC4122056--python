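# rnajoint

Joint secondary-structure prediction for two interacting RNAs with a
genetic algorithm.

Antisense RNAs, bacterial sRNAs and siRNAs regulate their targets by
base-pairing with them. Predicting such an interaction means finding
the *joint* secondary structure: the stems inside each RNA **and** the
hybrid regions between the two strands — including kissing-hairpin
geometries, where loop bases of one hairpin pair with loop bases of the
other. Exact thermodynamic treatments of this problem are expensive
(the general problem is NP-complete), so `rnajoint` searches the
structure space heuristically:

1. The strands R′ (length *n*) and R″ (length *m*) are concatenated into
   R = R′ N R″ (*l* = *n* + *m* + 1; the separator N never pairs).
2. A complementarity dot matrix of R against reverse R is built; every
   maximal anti-diagonal run of pairable positions (A-U, C-G, G-U) is a
   *sub-diagonal*: a candidate stem or hybrid region. Sub-diagonals
   over-rich in G-U wobble pairs (> 14 %) have the wobbles stripped and
   are re-segmented. The resulting set D^R is the search space.
3. An individual is a bit-tuple over D^R. Its phenotype is built by
   visiting active sub-diagonals in a fixed order and keeping the pairs
   that neither reuse a base nor cross a same-class pair accepted
   earlier; isolated (lonely) pairs are pruned. Fitness is
   Fitness(P) = MFE(S) + MFE(H): the nearest-neighbor free energy of
   the two intramolecular structures plus that of the hybrid regions
   (kcal/mol, lower is better).
4. An elitist GA (population *h* = 40, ≤ 20 generations, crossover
   rate 0.9, mutation rate 0.1) evolves the population: the top 10 % are
   transferred unchanged, the rest are refilled by single-point
   crossover of consecutive fitness-ranked parents, and a few non-elite
   individuals undergo a bit-swap mutation with retries. The run stops
   on stagnation or at the generation cap.

Predictions are scored against references at base-pair resolution:
Sn = TP/(TP+FN), PPV = TP/(TP+FP), F = 2·Sn·PPV/(Sn+PPV),
MCC = √(Sn·PPV), on the 0–100 scale, over the whole joint structure or
over binding-site (hybrid) pairs only.

## Worked example

```sh
printf ">R1\nCGGUUUGAGGUCCG\n>R2\nACUACCGAAAAGUU\n" > pair.fasta
rnajoint predict pair.fasta --seed 1 --output-dir out
```

prints one log line per generation and then the prediction:

```
generation=0 best=-3.80 mean=3.99 distinct=38
...
generation=5 best=-3.80 mean=0.73 distinct=31
CGGUUUGAGGUCCG
[[[[..........
ACUACCGAAAAGUU
...]]]].......
fitness_kcal_mol	-3.80
generations	5	stop	converged
```

The two bracket lines are the joint dot-bracket notation: `(`/`)` are
intramolecular pairs, `[` on the first strand pairs with `]` on the
second (the *i*-th `[` 5′→3′ matches the *i*-th `]` from the 3′ end —
the antiparallel convention). Here the best individual under the
built-in energy model is a single 4-pair hybrid binding CGGU of R1 to
ACCG of R2 at −3.8 kcal/mol; `out/structure.dbn` and `out/pairs.tsv`
hold the same structure in file form. Scoring a structure against a
reference:

```sh
rnajoint evaluate out/structure.dbn reference.dbn --mode binding-sites
```

emits a TSV line with TP, FP, FN, Sn, PPV, F and MCC.

`rnajoint fixtures --seed 3 --out fx/` generates a synthetic
interacting pair with a planted kissing-hairpin ground truth
(`fx/pair.fasta`, `fx/truth.dbn`), and `rnajoint tables` checks the
embedded published benchmark tables for internal consistency,
recomputing every F from its printed Sn/PPV and all column means.

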