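# Methods

## Model and assumptions

The package assumes the core–attachment view of protein complexes: a
densely interacting core plus peripheral proteins with fewer links into it.
Detection therefore runs in two phases — deterministic density-based core
mining, then a stochastic discrete search that assigns peripheral proteins
(pollen) to cores (plants). Both phases operate on *dynamic* subnetworks:
the static PPI network restricted to proteins whose expression clears a
per-gene activity threshold at each of 12 timestamps. The underlying
assumptions are that (a) complex members are co-expressed, so an expression
time course separates transient from co-occurring interactions, and (b)
edge reliability information (essentiality, localization, GO overlap,
local clustering) is additive on a common [0, 1] scale.

## Activity thresholds and the cycle question

The activity threshold is `μ + 3σ(1 − F)` with `F = 1/(1 + σ²)`; σ is the
population (divide-by-n) standard deviation, a convention fixed here
because the formula itself carries no Bessel correction. Expression data
are expected as three cycles of twelve timestamps. The reduction from 36
columns to 12 timestamps is genuinely open; this implementation computes μ
and σ over all 36 raw values and judges activity on the cycle-averaged
value of each timestamp, which keeps the threshold estimate as stable as
possible while producing exactly 12 subnetworks. "Not less than" is read
inclusively (≥). Proteins without an expression record are never active
and drop out of every subnetwork (logged).

## Edge relations

Four symmetric relations per edge, each provably in [0, 1]:

* **co-essentiality** — as printed, the essential-edge weight normalizes
  by a single endpoint's incident essential-edge count and is therefore
  asymmetric; an undirected weighted graph needs symmetric weights, so the
  implementation averages the two orientations:
  `(1/colsum_i + 1/colsum_j)/2`. Column sums are computed over the edges of
  the *current* subnetwork (weighting is applied per timestamp). Edges with
  a non-essential endpoint score 0 but are **not** removed — deleting them
  would disconnect most of the graph and contradict the additive weight.
* **co-localization / co-annotation** — squared overlap over the size
  product; an empty term set on either side gives 0.
* **co-cluster** — edge clustering coefficient, triangles over
  `min(deg−1)`; 0 for non-edges or a degenerate denominator (an endpoint of
  degree 1).

`NW` divides the relation sum by the constant 4 (the number of relations).
With no annotations at all, `NW = co_cluster/4` exactly — a property the
tests pin down.

## Core mining

Seeds are proteins with weighted degree strictly above the network mean,
in descending order. The neighbor scan order (descending NW to the seed,
lexicographic tie-break) and the strict `>` comparisons make the procedure
canonical: output is invariant to input edge ordering and carries no
randomness. A rejected neighbor is not reconsidered (single ordered pass).
Density of a singleton is undefined; the first admission is judged on the
two-node density. Default `DT = 0.25`; `0.15` is documented as the better
choice for sparser networks, and the flag is exposed. Note the admission
rule judges only the *post-addition density of the whole core*, so a large
dense core can absorb a weakly linked neighbor of the seed when DT is low —
this is the faithful reading of the rule, not a defect.

## Pollination search

Pollen positions are core indices, so the continuous pollination updates
with Lévy-flight steps that motivate the metaphor have no meaning on this
domain; only the discrete update is implemented. Each pollen keeps its
core when its priority (sum of edge clustering coefficients to core
members, computed on the subnetwork topology) exceeds `Thr = 0.2`, else it
jumps to a uniformly random core. Priorities depend only on fixed topology
and fixed core membership, so the full pollen × core table is precomputed
once. A pollen that lands on a satisfying core never moves again; the loop
stops when every pollen is satisfied or after `max_iter` (default 100)
iterations. Pollen that satisfy no core would resample forever, so they are
discarded at the end — attaching them would inject noise. One seeded
generator drives initialization and all jumps; the seed is recorded in the
run manifest, making full runs byte-reproducible.

With `max_iter` large, a pollen with any satisfying core finds one with
probability `1 − ((Num−1)/Num)^max_iter`; at the defaults this failure
probability is negligible, and the test suite checks agreement with an
exhaustive search oracle over 200 seeded instances.

Merging pools the complexes of all 12 timestamps, collapses identical
member sets, ranks by size descending (lexicographic ties) and keeps a
complex iff its overlap score with every kept complex is `< 0.8`. Keeping
the larger complex is a choice: "filter highly overlapping" does not say
which survives, and size-descending retention favors complete cores over
fragments.

## Evaluation

Matching counts each predicted complex once in TP even when it overlaps
several reference complexes (and symmetrically for matched-known counts).
`0/0` in Sn or Sp is reported as 0 with a warning, so degenerate catalogs
do not crash reporting. A perfect match (OS = 1) holds iff the member sets
are identical, so it is tested with set equality rather than float
comparison. Enrichment uses the exact hypergeometric upper tail
(`scipy.stats.hypergeom.sf`) over a user-supplied protein→group table; no
ontology propagation is performed, and N (the network size) defaults to
the static network but is a parameter. p < 0.01 is the conventional
significance bar.

## Synthetic benchmark

The generator plants `n_complexes` (default 10) node-disjoint complexes:
clique-by-default cores of 3–6 proteins and 2 attachments per complex, each
attachment wired to at least two core members so its triangle counts — and
hence its pollination priority — are nonzero by construction. Complexes are
assigned timestamps round-robin; members are expressed at 10.0 exactly at
their timestamp (all cycles) and near 0.5 elsewhere, which the three-sigma
rule marks active exactly once. The 50 background proteins receive uniform
high-variance noise on [0, 10]: the high variance keeps F small and the
threshold near μ + 3σ ≈ 12, above every cycle-averaged value, so
background genes are never active. The generator re-derives each gene's
activity pattern at generation time and raises if calibration ever fails.
Noise knobs: `background_edge_prob` adds spurious edges between proteins
of different complexes (and background), `annotation_overlap` dilutes the
shared localization/GO terms, `essential_fraction` controls essential
marking of core members.

What the benchmark does **not** emulate: scale-free degree structure,
overlapping complexes, expression imputation gaps, or annotation bias
toward well-studied proteins. Passing the planted-recovery tests shows the
pipeline is internally consistent and recovers the structure it models; it
does not certify performance on real interactome data, where false-positive
rates, catalog incompleteness and identifier mismatches dominate.

## Problem sizes and numerics

Tests and the acceptance script run on networks of roughly 100–130
proteins with 10 planted complexes — large enough that all twelve
subnetworks, the weighting, mining and attachment phases are exercised,
small enough to keep oracle cross-checks (triangle enumeration, exhaustive
attachment search, 10⁵-draw sampling) exact and fast. Strict inequalities
are used exactly where defined (`> DT`, `> Thr`, `> mean`); all
tie-breaking is lexicographic on protein IDs; floating-point comparisons in
tests use absolute tolerances of 1e-9 or tighter where closed forms exist.

## Known limitations

* One attachment per pollen per subnetwork; overlapping predictions arise
  only across timestamps.
* No GO semantic similarity — raw term overlap only.
* The per-subnetwork essential-edge normalization is an interpretation
  (static-network normalization is the alternative); it is localized in
  `build_essential_index` if a user wants the other convention.
* Real-data runs (DIP-scale networks) work through the same CLI but are
  untested here; memory and time grow with the subnetwork triangle counts.
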