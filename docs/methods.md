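# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Species delimitation model

The phylogenetic species concept is operationalised as a conjunction of
two kinds of evidence over one specimen sample:

* a **metric boundary** — a partition of specimens cut from a UPGMA
  dendrogram whose held-out discriminant accuracy reaches 0.90, and
* a **character boundary** — at least one discrete character whose state
  is fixed (a single non-missing state) within each side and different
  across sides.

Only the conjunction delimits species.  Either signal alone is read as
intraspecific structure: a metric split without fixed characters is
dimensional variation (sexual dimorphism, regional or temporal trends);
fixed characters without a validated metric split never arise in the
workflow because character reconciliation is applied to validated
partitions.  One deliberate exception: a single-specimen morphogroup
(a unique, holotype-like specimen) cannot enter a discriminant analysis
and is delimited on fixed differential states alone.

### Character criteria

`filter_characters` removes, in order: characters flagged unscorable;
characters polymorphic *within* a specimen (e.g. a premolar present on
one side of the skull and absent on the other) — under the PSC such a
feature is a trait, not a character; continuous characters lacking a
natural gap; invariant characters; and characters that are not
parsimony-informative (fewer than two states carried by at least two
specimens each).  Natural-gap coding places a state boundary at every
adjacent gap at least `min_gap_ratio` (default 3.0, a design choice —
no published quantification of "natural gap" exists) times the median
adjacent gap of the sorted values.  The rule is deliberately
conservative: evenly spaced values are rejected outright, and data
needing more than the five-state alphabet are rejected rather than
truncated.

### Imputation

Missing measurement cells are completed under a joint multivariate
normal by data augmentation: the I-step draws each specimen's missing
block from its conditional normal given the observed entries and the
current parameters; the P-step draws the covariance from an
inverse-Wishart (df = n-1, scale = centred cross-product) and the mean
from N(x̄, Σ/n) — the posterior under the noninformative Jeffreys prior
|Σ|^-(p+1)/2, which the referenced R implementation also uses.  The
chain runs 100 steps by default and returns one completed dataset after
a final I-step; EM (pattern-wise sufficient statistics, observed-data
log-likelihood asserted non-decreasing) supplies the start.  Multiple
imputation with Rubin pooling is out of scope: downstream clustering
and discriminant analysis consume a single completed table.

Numerical guards: the start covariance receives a relative 1e-10 ridge;
conditional covariances are symmetrised and ridged at 1e-10 of their
trace before Cholesky; a non-positive-definite posterior draw is
retried with geometrically growing ridge inflation, logged.  Observed
cells are never altered (asserted).  A conditional draw can leave the
positive orthant for variables whose coefficient of variation is large;
such draws are kept (they are what the model says) and counted in the
result log, and completed matrices relax the strict-positivity
validation that raw measurement tables must satisfy.

Variables observed in fewer than two specimens are an error; the
`prune_missing` helper drops variables observed in under 50% of
specimens and then specimens observed in under 50% of the remaining
variables (both thresholds configurable — no numeric rule is published,
so the defaults are ours and every removal is logged).

The normality check is Mardia's kurtosis test (b2p = mean squared
Mahalanobis distance to the centroid with the ML covariance;
z = (b2p - p(p+2)) / sqrt(8p(p+2)/n), two-sided normal p).  The
software used in the source workflow tests "normality based on
kurtosis" without publishing its formula or values; Mardia's statistic
is the documented stand-in.

### Clustering and validation

Distances are raw-scale Euclidean by default (a `standardize` flag
z-scores columns first); the choice of metric is unpublished, and raw
Euclidean matches the defaults of the clustering software of the era.
UPGMA uses size-weighted average linkage; a merge at distance d sits at
height d/2, so the dendrogram is ultrametric with leaves at height 0.
Exact distance ties are broken by the lowest-index pair, row-major —
the whole procedure is deterministic — and ties are logged.  Cutting k
groups removes the k-1 highest (= last) merges.

Discriminant validation uses the full Gaussian rule (pooled within-group
covariance with n-k divisor, equal priors by default to neutralise
unequal group sizes; observed-frequency priors behind a flag).
Stratified 50/50 splits keep each group's proportion, giving the extra
member of odd groups to training (any fixed rule suffices; training
gets it for model stability).  Groups too small to split (fewer than 4
members in auto mode) fall back to leave-one-out jackknife.  A pooled
covariance with more variables than spare cases is singular and raises
an error advising variable reduction — the same constraint that forced
the dentary-only variable subset in the source workflow.  The
end-to-end driver sets single-specimen groups aside before validation
and deepens the cut until two multi-member groups exist.

The 0.90 accuracy cutoff is exposed as a pure predicate
(`meets_support_cutoff`); it marks morphometric *support*, not species
status.

## Parsimony

Characters are unordered; tree length is the Fitch minimum-mutation
count, computed on uint8 state-set bitmasks vectorised across
characters.  Polytomies are scored exactly with Hartigan's multi-child
rule (keep the states carried by the most children; cost = children -
maximum), which reduces to Fitch on binary nodes; a left-fold of binary
combines is *not* exact on polytomies with missing data, which is why
Hartigan is used.  Missing and inapplicable cells carry the full state
set — the two codes are stored distinctly for provenance but treated
identically, as the source matrix conventions do.

**Exact search** is branch and bound over stepwise addition (insertion
cost via the junction rule below, children explored best-first, pruned
at the incumbent), limited to 14 taxa, returning every minimum-length
tree.  **Heuristic search** runs random-addition-sequence starts
followed by TBR branch swapping.  TBR neighbourhoods are scored exactly
and cheaply: bisecting at an edge and rejoining subtrees A and B at
edges eA, eB gives length L(A) + L(B) + (number of characters whose
edge state sets are disjoint), where the edge state set is the Fitch
preliminary set of the subtree rooted at a virtual node on that edge.
Every accepted tree is nevertheless re-scored from scratch and the
equality asserted.  A global buffer holds up to `hold` distinct trees
(keyed by their bipartition sets) at the best length; a closure pass
then swaps through equal-length TBR neighbours of every held tree,
recovering the TBR-connected island(s) of most parsimonious trees.
Separate islands not visited by any replicate can be missed — MPT
counts are therefore lower bounds capped at `hold`.

MPT counting needs a tree-identity convention.  Binary mode counts
distinct fully-resolved bipartition sets; collapse mode first contracts
every internal edge whose contraction leaves the length unchanged and
counts the resulting (possibly polytomous) topologies.  Published MPT
counts are sensitive to this convention, so both are reported.

Consensus retains clades with frequency strictly above the cutoff
(cutoff 1.0 = strict, frequency 100%); retained clades are checked for
mutual compatibility (guaranteed at cutoff >= 0.5).  Support values are
computed on unrooted bipartitions, canonically keyed by the side not
containing the first taxon; rooting (on the outgroup edge, or the
outgroup's pendant edge when the outgroup is not monophyletic in a
given tree) is applied only at export.

**Bremer decay** per clade = best length of a tree lacking the clade
minus the optimum.  A window sweep retains every tree visited within
`max_suboptimal` (default 10) extra steps; clades never lost there are
probed by a constrained hill-climb that penalises trees containing the
clade, and a clade that still never disappears reports ">10" — window
retention alone can underestimate decay, hence the re-search.
**Character jackknife** deletes each character independently with
probability e^-1 ~= 0.3679 per replicate (the conventional removal
probability; the source settings do not state one), re-searches at
reduced effort, and scores a clade by the fraction of replicate
majority-rule consensus trees containing it.  A replicate left with
zero characters is redrawn and logged.

Ordered (Wagner) scoring is deliberately not implemented: the only
analysis that orders characters in the source workflow is the Bayesian
tip-dated run, which is out of scope (its stratigraphic calibration
table ships as a data fixture only).

## Synthetic data

`simulate_measurements` draws per-species multivariate normals, adds an
optional sexual-dimorphism location shift to a random half of each
species (fixed 50/50 mixture — no published ratio exists), clips at a
positive floor, and deletes cells independently at the requested MCAR
rate (the imputation model assumes ignorable missingness; nothing is
known about the real mechanism, and MCAR is the only one implemented).
Masks that would silence an entire variable or specimen are redrawn.
`simulate_characters` evolves unordered characters (2-5 states) along a
branch-length tree under the symmetric Mk model from a uniform root.
Identical seeds give bit-identical datasets.

`nimravid_fixture` bundles a study-shaped dataset: an 85-specimen x
15-variable measurement table built from four species profiles whose
basilar lengths and other craniodental means follow the published
per-species summaries (roughly 138-187 mm means, 7% coefficient of
variation, correlated size axes, mild dimorphism in the most abundant
species) with 41.18% MCAR deletion — the published missingness of the
largest genus table; a 27-taxon x 33-character matrix evolved on a
fixed reference topology (nine outgroup genera; ingroup clades for the
conical-toothed genera, the European genera, and the saber-toothed
Hoplophoneini on a long stem) with the Mk rate calibrated so the
matrix's ensemble CI lands near 0.5, the moderate homoplasy typical of
craniodental matrices; and the published first/last appearance ages
verbatim.

What passing tests on these data do **not** show: real measurement
tables are not multivariate normal within species (allometry, age
structure), their missingness is anatomically structured (a crushed
skull loses all cranial variables together), and real character
conflict is concentrated — a handful of clean synapomorphies support
deep clades.  The Mk process spreads homoplasy uniformly instead, so
the fixture's deep clade shows moderate jackknife support (roughly
40-80% depending on seed) even where its Bremer decay is substantial,
whereas comparable real clades can jackknife near 100%.  Conclusions
about the pipeline's behaviour on real data should lean on the exact
oracles and contracts, not on the fixture's particular support values.

## Problem sizes

The test suite and the acceptance script run everything at sizes chosen
to keep a complete from-scratch run at a few minutes on one CPU:
heuristic searches use 100 random-addition replicates (20 for the
cross-seed stability check), jackknife uses 150-600 replicates at one
addition sequence each, Bremer probing uses 8-10 sweep replicates,
discriminant properties use 25-50 planted seeds, and the delimitation
contrast uses 20 seeded replicates per scenario.  These sizes are the
package's defaults for its own validation; all of them are parameters.

## Known limitations

* Heuristic MPT sets are TBR-island lower bounds (see above).
* Bremer values above the suboptimal window depend on the constrained
  re-search finding the best counterexample tree; for pathological
  matrices the reported decay is an upper bound.
* The delimitation reconciler requires nested (hierarchical) candidate
  partitions; genuinely conflicting partitions are an error by design.
* Strict fixation is brittle to a single misassigned specimen; with
  heavy missingness the morphometric track can misplace its most
  incomplete specimens, which is a property of single-MVN imputation of
  a mixture, not of the reconciliation logic.
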