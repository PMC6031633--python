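# Methods

This note records the modeling choices behind `fwalign`: what is
computed, which knobs matter, what the synthetic generators do and do
not emulate, and where the design was genuinely open.

## Roles and role similarity

Species roles are motif-position counts over the connected directed
motifs on 2 and 3 nodes.  Exhaustive enumeration and canonicalization
give 2 dyadic motifs (single link, mutual link) with 3
automorphism-distinct positions, and 13 triadic motifs with 30
positions, so role vectors have 33 slots by default.  Whether dyads
belong in the role vector is a convention; we include them (they carry
degree-like information) and expose `min_n=3` to drop them, which
leaves the 30-slot variant.

Self-loops (cannibalism) are retained in storage but stripped before
motif counting and alignment: the 2-/3-node position catalog is defined
on loop-free graphs, and a cannibalistic link would otherwise create
positions outside the catalog.

Role similarity is the Pearson correlation of two role vectors.
Pearson is undefined for a constant vector (σ = 0, e.g. a species
isolated from all motifs); by convention such a pair scores 1 when the
two vectors are elementwise equal and 0 otherwise, so degenerate but
identical roles align freely while non-matching ones are neutral.
Identical vectors short-circuit to exactly 1.0 to keep self-alignment
costs at exactly zero.

## Alignment costs

Two costs are implemented over pairings λ with unpaired markers:

* **simple** — Σ (1 − ρ(a, b)) over matched pairs plus ε per unpaired
  species.  The penalty is charged directly as ε (not as 1 − ε): read
  as "the cost contribution of an unpaired species is ε", which keeps
  the cost monotone in ε and makes ε = 0 mean "unpairing is free".
* **neighborhood** (default) — for each pairing x = (a, b), the sum of
  (1 − ρ) over pairings joining a neighbor of a to a neighbor of b,
  plus ξ_x = ε·(u_a + u_b), where u_a counts neighbors of a not paired
  to any neighbor of b and u_b symmetrically.  An unpaired species
  contributes ε per neighbor.  "Neighbor" pools prey and predators;
  a direction-respecting variant (prey pair with prey, predators with
  predators) is available via `directional_neighbors=True`.  Direction
  still enters the pooled variant through the role vectors themselves.

ε defaults to 1.0, the midpoint of the per-pair cost range [0, 2]:
unpairing a species is then cost-neutral against pairing it with an
uncorrelated partner (ρ = 0) and favored against anticorrelated ones.

Alignment **quality** ê is the mean of (1 − ρ) over real–real matches
only; unpaired species contribute nothing (their ρ is taken as 1) and
do not enter the divisor N.  A degenerate alignment with no real
matches scores 2, the maximal dissimilarity, so it can never look good.

## Optimization

The state space is the set of bijections between the two species sets
after padding the smaller web with dummy species (a dummy partner means
unpaired).  Moves swap the partners of two uniformly chosen elements.
Cost changes are evaluated incrementally from the affected pairings
only; the full recomputation is kept as a cross-check in the tests.

Schedule: geometric cooling (×0.95 per stage), stage length
50·max(|A|, |B|) proposals by default, stop after 20 stages without
improvement (10 in the ensemble preset) or T < 1e−6, best-ever state
returned.  The initial temperature is calibrated so that a typical
uphill move from the start state is accepted with probability ~0.8.

Restarts: the first restart starts from the optimal role-only
assignment (a linear-assignment solve on the 1 − ρ matrix) and is
refined with a *cold* quench (T0 = 1e−4) — heating a greedy start to
the calibrated temperature would erase the information it carries.
Remaining restarts start from random bijections at the calibrated
temperature.  All randomness flows from one seeded generator per
restart (seed + restart index).  Identical webs terminate early once
cost 0 is found.

`AlignConfig.ensemble_preset` (3 restarts, early stop after 10 stale
stages) is the schedule used for all-pairs sweeps; it was chosen as the
cheapest schedule that still recovers isomorphisms and planted
structure reliably on webs of the sizes used in the experiments
(10–50 species).  The exhaustive oracle scans all padded bijections
and is limited to |A| + |B| ≤ 14.

## Ensemble analyses

* The all-pairs dissimilarity matrix stores ê for every unordered pair;
  n webs require n(n−1)/2 optimizations.  Per-pair results can be
  cached as JSON keyed by web content and configuration.
* Species are ranked by their mean ρ across all real pairings; unpaired
  pairings are excluded from every mean rather than counted as 0, so
  rarely-paired species are not penalized.
* Alignment transitivity of species a: over unordered pairs of other
  webs (B, C) where a has real partners b and c, the fraction where
  (b, c) is itself a pairing of the B–C alignment.  Species with no
  valid (B, C) pair report missing, not 0.  The null shuffles partners
  within each alignment while keeping the number of real pairings, and
  reports the mean and a 95% Monte-Carlo interval.
* Path connectedness of a species subset is the fraction of subset
  pairs joined by an undirected path *within the induced subweb* —
  paths through non-subset species do not count, matching the question
  "do these species form a connected component of their own".  The
  path-likelihood test draws equal-size uniform random subsets and uses
  the +1-smoothed one-sided p-value.  The "best-aligned" candidate set
  defaults to the top quartile of species by mean ρ (no canonical
  cutoff exists; the fraction is a parameter).

## Backbones

Link overlap counts, for each link (a, a′) of a web, the alignments in
which the partners (b, b′) of both endpoints exist and b → b′ is a link
of the partner web *in the same energy-flow direction* — directionality
is central to the method, so an inverted link does not count.  The
k-link backbone takes the top-k links by overlap weight, breaking ties
by weight-descending then lexicographic order; determinism was
preferred over faithfulness to an unspecified original rule.  Requests
for k above a web's link count are refused (such webs are dropped from
a sweep, shrinking the retained fraction as k grows).

E_k entries are the raw optimal alignment *cost* between backbones (all
share k links, so size normalization is moot); a flag switches to ê.
Cluster counts are chosen by a majority vote of three indices (average
silhouette width, Calinski–Harabasz on the PCoA embedding, Dunn) over
seeded k-medoids runs, ties to the smallest count; this replaces a
5-index/8-method ensemble vote with a smaller, dependency-free variant
of the same majority rule.  Consensus structures align every member to
its cluster medoid; member links map into the medoid's species space,
and a consensus link's likelihood l is the exact fraction of members
whose image contains it (the medoid itself counts as a member).  Member
nodes without a medoid counterpart are pooled under an auxiliary label.
Links with l below the threshold (default 0.01) are dropped.

The strength test compares the mean interaction strength of backbone
links against equal-size uniformly drawn link sets (one-sided,
+1-smoothed).

## PERMANOVA and PCoA

The one-way pseudo-F partitions squared dissimilarities:
SS_total = (1/n)Σ_{i<j} d²; SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²;
F = ((SS_total − SS_within)/(g − 1)) / (SS_within/(n − g)); the
p-value permutes group labels (default 9999 permutations, seeded,
+1-smoothed so p = 0 is never reported).  Degrees of freedom are
reported as (g − 1, n − g).  Pairwise tests run per group pair on the
submatrix with Holm adjustment by default.  PCoA Gower-centers −½d²,
eigendecomposes, keeps axes with eigenvalue > 1e−10, and drops
negative-eigenvalue axes with a log note; distances are reproduced
exactly when the input is Euclidean-embeddable.  Both routines are
checked against scikit-bio in the tests.

## Synthetic generators

The niche model draws niche values uniformly, diet-range widths from a
Beta(1, 1/(2C) − 1) so that the expected directed connectance is C, and
diet centers uniformly below each species' niche value; the lowest-niche
species is forced basal, and self-loops are stripped.  No
connected-web or duplicate-species rejection step is applied.

Planted-backbone ensembles embed one fixed subgraph verbatim in every
web and add fresh periphery per web: periphery–periphery links at
directed density 0.10 (niche-web-like) and periphery–core attachments
at probability 0.01 per ordered pair and direction.  The attachment
default keeps the expected number of periphery links per core species
well below one (≈ 0.3 with 15 periphery species): the planted core
must remain the dominant structure *of its own species* for the
ensemble to emulate "a shared backbone with varying periphery" at all.
During harness validation two other regimes were mapped and rejected
for cause: dense attachment (≈ 0.15+) makes periphery links dominate
every core species' degree, so core roles are noise and even exhaustive
optimization maps cores to periphery — the planted structure is
unidentifiable in principle, not merely hard; and a star-shaped core
fails for a different reason — its satellite leaves are exchangeable
with any periphery consumer of the hub.  The default planted core
(`motif_rich_backbone`) is therefore a four-level chain with maximal
omnivory: 4 species, 6 links, every member with a unique in/out-degree
signature and within-core degree 3.

What these generators do **not** emulate: sampling error and taxonomic
aggregation in empirical webs, interaction strengths (weights are only
synthesized in tests that need them), body-size correlations,
modularity/compartments, and webs larger than ~50 species.  Passing
recovery tests therefore demonstrates correctness of the machinery and
detectability under controlled noise, not performance on field data.

The three-web toy fixture (`fig_toy_triple`) hand-builds the two
canonical transitivity patterns — one species whose partners in the two
other webs are themselves paired (transitivity 1) and one whose
partners never are (transitivity 0) — with reference alignments stored
alongside the webs.  It instantiates the described pairing structure
minimally; it is not a tracing of any particular published figure.

## Numerical choices and experiment sizes

Costs are compared with absolute tolerance 1e−12 inside the annealer
and 1e−9 in tests (role similarities enter through floating Pearson
computations).  The validation experiments run at: 50 seeded pairs of
≤ 6-species webs for the exhaustive-oracle check; 20 niche webs of
10–50 species for self/isomorph recovery; 10 ensembles of 20 webs
(4-species core + 15 periphery species) for planted-backbone recovery;
1000 simulations (n = 40, two groups, 199 permutations each) for the
PERMANOVA type-I calibration.  These sizes give stable Monte-Carlo
estimates while keeping the full suite comfortably runnable on one CPU.

## Known limitations

* The annealer is heuristic: on ambiguous webs different seeds can
  return different near-optimal alignments; only the ≤ 14-species
  oracle is exact.
* Bipartite networks are detected and warned about but not excluded;
  the alignment model targets unipartite webs and gives no guarantees
  on bipartite ones (no canonical detection rule exists, so exclusion
  is left to the user).
* Role vectors stop at 3-species motifs; species differing only in
  ≥ 4-species structure are indistinguishable.
* E_k clustering assumes the backbones at a given k are comparable;
  for k larger than many webs' link counts the retained subset shrinks
  and the cluster-count vote loses power.
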