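# Methods

`dyncomplex` detects protein complexes from a protein–protein interaction
(PPI) network by combining three evidence sources — GO annotations, tandem
affinity purification (TAP) scores, and time-course gene expression — in
four phases.  This note documents the model in each phase, the tunable
parameters, the numerical choices, and the parts of the procedure that are
reconstructions rather than published formulas.

## Phase 1 — TAP-aware edge weighting

Every PPI edge (P₁, P₂) receives

* a GO weight `W_GO ∈ [0,1]`: the mean of per-aspect SimGIC similarities
  over Biological Process, Cellular Component and Molecular Function.
  SimGIC for one aspect is the information-content-weighted Jaccard of the
  two proteins' ancestral annotation closures,
  `Σ ic(t), t ∈ cl(a)∩cl(b) / Σ ic(t), t ∈ cl(a)∪cl(b)`, with
  `ic(t) = −ln p(t)` estimated from annotation frequency over the input
  protein set.  Closures follow `is_a` edges only; `part_of` is ignored
  (the simplest well-defined closure).  The log base cancels in the ratio,
  so natural log is an arbitrary but irrelevant choice (asserted by a
  property test).  When a protein carries no annotation in an aspect, the
  mean runs over the aspects where both proteins are annotated, and is 0
  if there are none — this avoids penalising sparsely annotated proteins
  with arbitrary zeros.
* a TAP weight `W_TAP ∈ [0,1]`: purification scores from the LCMS and
  MALDI experiments are min–max normalised per source and averaged; a pair
  present in one source uses that score alone, and a pair absent from both
  gets the neutral value 0.5.  Normalisation is per source over all its
  pairs (the natural reading of "normalised between 0 and 1"); pairs not
  in the PPI network never create edges.

TAP acts multiplicatively: `alpha_tap = 1 + (W_TAP − 0.5)·γ` and
`W = alpha_tap · W_GO`.  `γ ∈ [0,1]` is the TAP impact factor; published
per-dataset tunings are γ=0.4 (BioGrid profile, α ∈ [0.8, 1.2]) and γ=0.3
(DIP profile, α ∈ [0.85, 1.15]).  γ=0 or the TAP-off switch reduces `W` to
`W_GO` exactly.

## Phase 2 — expression binarisation and memetic biclustering

Each protein's time course is binarised against its own row statistics:
cell (i, j) is *active* iff `GE[i][j] ≥ |μ[i] − σ[i]·ε|`, with μ the row
mean and σ the population standard deviation (divide by n).  ε ≥ 0
(default 0.6) shifts the threshold below the mean; ties count as active.
The rule is per-row and affine-equivariant, so an optional per-row min–max
pre-scaling (off by default) provably cannot change the binary result —
also asserted by a property test.  A consequence worth knowing: for a
two-level row the threshold separates the levels only when the active
fraction f satisfies `√(f/(1−f)) > ε` (f > ε²/(1+ε²) ≈ 0.26 at ε=0.6);
rows with almost all cells at one level binarise degenerately because
σ → 0.

Biclusters — submatrices whose selected proteins are predominantly active
in the selected time points — are found by a steady-state Lamarckian
memetic algorithm.  A chromosome is a binary vector of m protein bits and
n time-point bits; its fitness is the active fraction of the selected
submatrix (0 when either part is empty).  Operators per iteration:

* binary tournament selection (two distinct contestants, fitter wins,
  ties to the first drawn);
* two-point crossover on the protein part only, probability 0.9;
* independent bit mutation: 0.001 per protein bit, 0.1 per time bit (the
  time part is never crossed over, so it mutates faster);
* local search on each child: one pass over the bits, each tested with
  probability 0.8, a flip kept only if fitness strictly increases.  The
  improved child re-enters the population (Lamarckian write-back), so the
  population's best fitness never decreases;
* insert both children, remove the two worst.

Three implementation decisions deserve explanation because the operator
descriptions alone underdetermine them:

1. **Tie-breaking by area.**  The fitness of a perfectly active sub-block
   equals that of the full block (both are 1), and single-time-point
   selections reach fitness 1 trivially.  Wherever individuals are ordered
   by fitness — worst-removal, the final sort, the returned top-k — ties
   are broken by the selected area |I|·|J|, so the search prefers maximal
   biclusters among equally pure ones.
2. **Local-search scan order.**  Bits are visited in a random permutation
   drawn per pass from the run's generator.  A fixed left-to-right order
   systematically favours low-index proteins and early time points,
   because flips are easiest to accept while the running fitness is still
   low; the permutation keeps the pass deterministic under a seed while
   removing the positional bias (measured directly on planted data).
3. **Restarts.**  A single steady-state population without niching
   ultimately converges on one attractor, so one run cannot return several
   distinct biclusters reliably.  The search is restarted
   `restarts_per_bicluster` times (default 3) per requested bicluster with
   sub-seeds spawned deterministically from the master seed; the final
   populations are pooled and the top `n_biclusters` distinct solutions
   are returned, skipping near-duplicates (protein-set Jaccard > 0.8, the
   same redundancy notion used by the detector and the aggregator).

A run stops at `max_iterations` (default 2000) or when *every* individual
reaches `fitness_goal` (default 0.95) — the population has converged;
stopping as soon as the single best individual reaches the goal would end
the search almost immediately, since tiny all-active submatrices reach
fitness 1 early.  Population size defaults to 100.  These three defaults
are implementation choices, not published values.

Each returned bicluster induces one *dynamic subnetwork*: the weighted PPI
restricted to the bicluster's proteins (isolated nodes retained).

## Phase 3 — core–attachment detection

On each subnetwork, four deterministic steps:

1. **Seeding.**  Every protein is scored with the weighted local
   clustering coefficient `WCC(v) = Σ_{e∈L} W(e) / (|L|·(|L|−1))`, L its
   incident edge set in the graph under consideration; degree ≤ 1 scores 0
   since the formula is undefined there.  Seeds are the proteins at or
   above the `alpha_seed` quantile of the nonzero scores — a scale-free
   rule, so the same `alpha_seed` is meaningful whatever the weight scale.
   Lower `alpha_seed` ⇒ more seeds.
2. **Core growth.**  From each seed, greedily add the outside neighbour
   with the largest summed edge weight into the core, accepted only if the
   core's weighted edge density (Σ intra-core W over member pairs) does
   not decrease; stop at the first rejection.  Density, not WCC, is the
   acceptance score: a unit-weight k-clique node has WCC 1/(k−2), which
   *falls* as a clique grows, so a WCC-based acceptance rule could never
   grow past a triangle, while density is clique-size invariant.
3. **Attachments.**  A neighbour u of the core joins the complex iff
   `|edges(u, core)| / |core| ≥ β`; candidates are judged against the
   original core, so the result is order-independent.  Higher β ⇒ smaller
   complexes.
4. **Redundancy filter.**  Complexes sorted by (WCC, size, members) are
   kept greedily so that every kept pair has Jaccard < 0.8.

**Reconstruction notice.**  The seeding threshold (step 1's quantile), the
core acceptance rule (step 2's density), and the attachment normalisation
(step 3's division by |core|) are reconstructions: the four-step outline
and the WCC formulas are published, but the detector's original internal
criteria are not, and these choices are the simplest ones consistent with
the published parameter behaviour (more seeds at low α, smaller complexes
at high β).  Published per-dataset tunings: (α, β) = (0.3, 0.5) for the
BioGrid profile and (0.55, 0.7) for the DIP profile.

## Phase 4 — analysis and aggregation

All per-subnetwork detections are pooled.  Complexes with fewer than 3
proteins are dropped; sizes 3–5 pass directly to the final result; sizes
≥ 6 are grouped greedily (largest first) into categories in which every
pair exceeds Jaccard 0.8.  (The size-5 boundary is genuinely contradictory
in the source description — size 5 is claimed both to pass through and to
be categorised; pass-through wins here because it is stated first and
unconditionally.)  Each category is reduced in three steps: (a) the
intersection of all members becomes the `CommonPart`; (b) every residual
protein present in at least half the members is moved into it, and the
augmented CommonPart joins the final result; (c) each remaining residual
protein is tried alone on a copy of the CommonPart and the enlarged
complex is emitted iff its complex WCC strictly increases.  Phase-(c)
candidates never accumulate, so their processing order is irrelevant; the
WCC is computed on the full weighted network because categories mix
complexes from different subnetworks.  The final set is de-duplicated on
exact protein-set equality.  With post-processing off, aggregation is the
identity up to exact duplicates (the ablation mode).

## Evaluation

A detected complex is a true positive if some benchmark complex matches
it with Jaccard ≥ th (default 0.25, the conventional threshold); a
benchmark complex is recovered if some detection matches it.  Matching is
many-to-many — both definitions are existential — and precision, recall,
and F-1 follow.  An empty benchmark is an error.

## Synthetic data

The generator plants consistent ground truth across all inputs so every
stage is testable offline:

* **PPI**: six complexes (sizes 5–12, near-cliques with internal edge
  probability 0.95–1.0; adjacent complexes share one protein) over an
  Erdős–Rényi background at density 0.005 on 300 proteins.  Real yeast
  interaction networks have density ≈ 0.002; early drafts at 0.02 were an
  order of magnitude too dense and generated spurious weighted triangles
  that dominated precision.
* **TAP**: per-edge scores ~N(0.8, 0.08) for intra-complex pairs and
  ~N(0.3, 0.08) otherwise, with 70 % of pairs missing per source — TAP is
  sparse complementary evidence by design.
* **GO**: three aspects, each a root with function-group terms beneath it.
  Complex members are annotated to a marker term below their complex's
  group (so co-complex SimGIC ≈ 1), background proteins to one of ~21
  10-protein groups (so cross-group SimGIC = 0 and same-group SimGIC is
  high but rarely coincides with an interaction).  The MF aspect annotates
  only even-indexed proteins, exercising the missing-aspect averaging.
* **Expression**: a continuous matrix built backwards from a target binary
  pattern — active cells at 1.0, inactive at 0.05, Gaussian jitter 0.01 —
  so that binarisation at ε=0.6 recovers the pattern exactly (verified
  post-hoc; the bundle records the agreement).  The pattern holds three
  disjoint 60-protein × 4-time-point blocks (the planted biclusters; each
  contains two planted complexes, i.e. complexes sit inside larger
  co-expression modules) over background rows whose active counts are
  clamped binomial draws at rate 1/3, the feasibility floor of the ε=0.6
  threshold.

The block geometry is deliberate: the planted blocks are the *maximum-area
perfect biclusters* of the pattern (area 240 versus ≤ ~150 for any
column-subset competitor), and the within-block growth ladder is monotone
in area, so the fitness-plus-area-tie-break search has the planted blocks
as its true optima.  With overlapping time blocks or denser background
activity, wide one-column submatrices out-rank the planted blocks and no
faithful implementation of this fitness could prefer them — a useful
reminder that the fitness rewards purity, not biological signal.

What the fixture does *not* emulate: realistic degree distributions
(hubs), annotation depth and evidence codes, dynamic expression trends
within a block, measurement-specific noise in TAP scores.  Passing tests
on this fixture therefore show the machinery is implemented correctly and
that planted structure at realistic sparsity is recovered; they do not
certify performance on real interactome data.

## Problem sizes and determinism

The reference test configuration runs the default bundle (300 proteins,
12 time points) with 10 requested biclusters × 3 restarts (population
100); biclustering takes a few seconds and the whole pipeline well under
a minute on one core.  All stochastic stages draw from generators seeded
from a single master seed (restart sub-seeds are spawned from it), so a
(config, seed) pair reproduces outputs bit-for-bit; phase 3, phase 4 and
all file writers are deterministic by construction, with stated tie-break
orders everywhere an ordering matters.

## Known limitations

* The detector's internal rules are reconstructions (above); absolute
  complex counts on real data will differ from the original tool even
  where directional parameter behaviour matches.
* The memetic fitness admits trivially perfect tiny biclusters; the area
  tie-break mitigates this but a principled size-aware fitness would be a
  better search criterion.
* Protein identifiers are matched as exact strings; cross-database ID
  reconciliation is out of scope.
* The GO weighting re-implements SimGIC directly; the optional
  local-search refinement some external semantic-similarity tools apply
  after scoring is not reproduced (no published algorithm to follow).
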