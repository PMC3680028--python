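# Methods

## Model and assumptions

A PPI network is a simple undirected graph G = (V, E) over opaque,
case-sensitive protein-ID strings; a protein complex is modelled as a
dense subgraph. The package assumes the input graph is simple: duplicate
edge lines and reversed duplicates collapse (last weight wins, logged) and
self-loops are dropped with a logged count. Protein IDs are never
normalised or mapped — two spellings of one accession are two proteins.

### PE-measure

Every observed interaction starts with prior reliability p⁰ = 0.5, read as
"an observed edge is a coin flip until corroborated". A common neighbour
l of (i, j) supports the edge with probability p_il · p_jl, and supports
are treated as independent, so the updated reliability is one minus the
probability that no common neighbour supports it:

    p_ij ← 1 − ∏_{l ∈ N_i ∩ N_j} (1 − p_il · p_jl).

Updates are synchronous (Jacobi-style): every right-hand value is read
from the previous iteration's matrix, so the result does not depend on
edge enumeration order. Pairs that do not interact carry probability 0 and
are never stored. Consequences used as test invariants: values stay in
[0, 1]; the map is symmetric; an edge in no triangle is 0 after one
iteration and forever after.

Filtering computes each node's mean incident reliability on the scored
network first, then removes — all at once — every edge scoring strictly
below the average at *either* endpoint. Strictness means uniform-weight
networks lose nothing; computing averages before any removal makes the
filter order-independent. The either-endpoint reading follows from the
per-protein scan phrasing of the removal rule; a both-endpoint variant
would remove strictly fewer edges and is not what the worked example
implies. Filtering runs once, after the final scoring iteration, never
inside the loop. Nodes are never removed and may become isolated.

The alternative scorers CD-distance, AdjstCD and iterated AdjstCD are
included for ablation-style comparisons. In the iterated scheme w⁰ is the
adjacency indicator and one update step reproduces AdjstCD exactly, with
the network-wide mean weight as the degree floor; the normalising count in
that mean is taken to be the node count (the only dimensionally sensible
reading). AdjstCD-based filtering reuses the same per-node-average removal
rule, since no dedicated threshold exists for it.

### Weighted-clustering-coefficient peeling

For a seed protein with neighbourhood members N_i (seed excluded) and
N_3cliques triangles through the seed,

    c = 2 · N_3cliques / (N_i² · (N_i − 1)).

N_3cliques equals the edge count of the member-induced subgraph: a member
edge plus the two seed edges is exactly one triangle through the seed.
This is the only reading consistent with the fixture's printed trace
(7 → 5 → 3 member edges giving c = 0.14 → 0.21 → 0.33). Note c ≤ 1/N_i
(at most N_i(N_i−1)/2 member edges), so smaller subgraphs can always win;
this bound is asserted at every peel step in the tests. On a fully
connected 3-member remainder c is 1/3, not 1 — the formula's value, which
is what the implementation returns, even though a density reading of such
a triangle would be 1.

Peeling removes the member of minimum degree *within the member subgraph*
(the seed edge never counts — required for the fixture's node 5 to be the
unique minimum), rescoring after each removal, down to 3 members. The
pre-peeling state is eligible as the maximum; argmax ties prefer the
earliest (largest) member set, keeping more proteins at equal density.
Minimum-degree ties default to the lexicographically smallest member
(reproducible runs); `tie_break="random"` with a seeded RNG reproduces
randomized behaviour. Seeds of degree < 3 are skipped — the stop condition
presumes at least 3 members, which is also why complexes of ≤ 3 proteins
are out of reach of this method.

Rejoin is a single pass over the *original* neighbourhood members outside
the core: a candidate joins iff its network neighbours cover strictly more
than fraction t of the core, seed included in the denominator. Judging
every candidate against the pre-rejoin core prevents admission cascades.
Detection runs on the filtered, unweighted topology; reliability weights
never enter c, which is a pure count ratio.

Duplicate predictions are removed by exact set equality only (first seed
in sorted order wins); overlapping complexes are deliberately left
untouched — no merge step exists in this method.

### Evaluation metrics

MatchScore is the Jaccard index; a prediction matches a reference when it
reaches a threshold α ∈ (0, 1]. Rec/Prec count matched reference and
predicted complexes; F1 is their harmonic mean. Sn, PPV and Acc = √(Sn·PPV)
follow the standard clustering-wise definitions on the reference ×
prediction confusion matrix t_ij (shared-protein counts); predictions
overlapping no reference contribute zero to both PPV sums, and a wholly
non-overlapping comparison yields PPV = Acc = 0 with a logged warning.
MMR solves a maximum-*weight* (not merely maximal) one-to-one assignment
on the complete bipartite refs × preds graph weighted by Jaccard scores —
via the Hungarian algorithm — and divides the matched weight by the
reference count. Empty predicted catalogs give 0; an empty reference
catalog is a domain error.

Size filtering (default minimum 4, matching the detector) is exposed as
an explicit pre-evaluation flag, not applied inside the metric functions,
so the evaluation API stays a pure metric library.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 2 | scoring iterations; further iterations change little because supported edges saturate quickly |
| t | 0.3 | rejoin threshold, fraction of core (strict); higher t admits fewer proteins and trades recall for precision |
| min_size | 4 | smallest reported complex; the peeling floor makes 3-member cores degenerate |
| α | 0.25 | Jaccard match threshold for Rec/Prec/F1 |
| tie_break | lex | peel tie policy; `random` + rng_seed for randomized replicates |

## Synthetic benchmarks

The planted-complex generator emulates the one property the method
exploits — complexes are locally dense, noise is locally sparse. Defaults:
10 disjoint planted groups of 5–8 proteins with within-group edge
probability 0.9, 40 background proteins, background edge probability 0.01
between all remaining pairs, plus optional uniformly random extra edges
("noise") among existing nodes only. Everything is a pure function of
(params, seed). Deliberately absent features of real screens: scale-free
degree distributions, shared subunits between complexes, bait–prey
sampling bias, and systematically missing edges. Passing robustness tests
therefore show that reliability filtering rescues density-based detection
from *uniform random* edge noise, not that it corrects experiment-specific
artefacts.

The noise-robustness experiment adds 2× and 4× the clean edge count as
random pairs and compares F1 (α = 0.5, truth catalog as reference) of
PE-filtered vs unfiltered detection over 10 generator seeds; the filtered
variant must win in at least 7. These problem sizes (~105 nodes, up to
~1100 edges) keep the whole experiment in seconds while leaving the noise
regime harsh enough that unfiltered detection visibly degrades.

## Numerical choices and degenerate inputs

- All probability arithmetic is plain float; products over common
  neighbours are short, so no log-space accumulation is needed.
- Empty common-neighbour products are 1 (score 0); empty networks, empty
  catalogs and isolated nodes are handled per the contracts above rather
  than raising, except where a quantity is genuinely undefined (c with
  < 2 members, CD-distance between two isolated proteins, MatchScore of
  an empty set, MMR without references).
- Output determinism: seeds are visited in sorted order, complexes are
  written sorted by (size descending, lexicographic members), and edge
  lists are written with lexicographic endpoints and sorted lines, so
  identical configurations reproduce byte-identical files even with the
  random tie-break (via its seed).
- Weights are serialised with six decimals; round-tripping preserves them
  to that precision.

## Known limitations

- Complexes with ≤ 3 proteins cannot be detected (peeling floor).
- Exact-duplicate deduplication only; heavily overlapping predictions are
  all reported, which depresses Prec and PPV on redundant seeds.
- The filter can remove true edges of hub proteins whose incident
  reliabilities are heterogeneous (either-endpoint rule is aggressive by
  construction).
- Evaluation retains predicted proteins absent from every reference; they
  affect no sum, but they also go unrewarded — semantic (e.g. GO-based)
  evaluation is out of scope.
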