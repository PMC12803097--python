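# Methods

## The model

`paleorealms` reconstructs how marine biodiversity accumulated across a
small set of biogeographic realms (by default the nine global marine realms
NC, CI, CP, EA, EP, SC, WA, WI, NP). A species' geographic range is a
subset of realms, encoded as a bitmask whose bit order is fixed by the
`RealmSet`. Range evolution along a dated phylogeny follows the
dispersal–extinction–cladogenesis (DEC) model family:

* **Anagenetic** (along branches): a continuous-time Markov chain over
  realm subsets. A range R gains realm k at rate `d · Σ_{i∈R} M[i,k]`,
  where M is the epoch's dispersal multiplier matrix, and loses an occupied
  realm at rate `e`. The empty range is absorbing (a lineage extinct in
  every realm never recovers).
* **Cladogenetic** (at nodes): daughter ranges are drawn from a
  model-specific event table. DEC allows narrow sympatry, subset sympatry
  and narrow vicariance (one single-realm daughter); DIVALIKE allows
  narrow sympatry and vicariance of any split; BAYAREALIKE only copies the
  ancestral range. The `+J` variants add founder-event speciation: one
  daughter jumps to a realm outside the ancestral range, weighted by
  `j` times the mean dispersal multiplier from the occupied realms to the
  destination. Event weights y (narrow sympatry), s (subset sympatry) and
  v (vicariance) are fixed at 1, the family's convention; only d, e and j
  are estimated (k = 2 for base models, 3 for +J).

Likelihoods use Felsenstein pruning with dense matrix exponentials per
branch segment. Branches are split at the stratified-DMM epoch boundaries
(piecewise-constant Q); the cladogenetic table at a node uses the epoch
containing the node's age. The root prior is flat over non-empty ranges.
Conditional likelihoods are rescaled at every node, so clades of a few
hundred tips pose no underflow risk.

### Survival conditioning

Under the forward DEC process a non-trivial fraction of lineages is
absorbed into the empty range; observed datasets contain only survivors.
The synthetic-data generator therefore offers three sampling schemes:

* `sim_ranges(..., resample_scope="clade")` — resample the whole clade
  until no tip is empty (exact, but only feasible for small clades);
* `resample_scope="branch"` — retry only the offending branch path, a
  local conditioning with a small downward bias on realized extirpations;
* `sim_ranges_conditional` — exact sampling from
  P(history | all tips non-empty) using the stochastic-mapping machinery
  with "any non-empty range" constraint vectors at the tips. This is the
  same distribution clade-level resampling targets, but remains feasible
  at any tree size.

Fitting data generated this way with the plain likelihood biases ê toward
zero, because the probability of full survival itself depends strongly on
e. `loglikelihood`/`fit_model` therefore accept `condition_survival=True`,
which divides the likelihood by P(no tip empty) — computed by a second
pruning pass — making the estimator consistent with the generator. On
150-tip, 4-realm clades simulated at d = 0.1, e = 0.03, the conditioned
DEC MLEs recover d within roughly 20% and e within roughly 50% per fit;
because single-fit ê has large sampling spread at this size, recovery is
reported as the geometric mean over 12 replicate simulations.

## Dispersal multiplier matrices

Per stratum: paleo-rotated realm seed points (an input; tectonic rotation
itself is out of scope) are extrapolated over the water mask by
nearest-seed assignment on the sphere; realm centroids are spherical means
of labeled cells; shortest over-water paths between centroids are computed
by Dijkstra on the 8-connected water lattice with great-circle edge
weights and longitude wraparound; and the distance matrix is min–max
normalized and subtracted from one, giving multipliers in [0, 1] with unit
diagonal. Numerical policies:

* unreachable pairs get 1.5 × the largest finite distance before
  normalization (near-zero multiplier, finite likelihood);
* an all-equal off-diagonal distance matrix carries no contrast and
  defaults to all-ones multipliers (no information → no penalty), with a
  warning;
* an optional ε floor (default 0) lifts the farthest pair off exactly 0;
* normalization is per-epoch by default; a global-across-epochs switch is
  provided since either reading of "normalized between zero and one" is
  defensible.

Two stratification presets are provided: 5-Myr strata to 45 Ma for
cetaceans and 10-Myr strata to 140 Ma for the other groups, each closed by
a stratum reaching 360 Ma so the stack is older than any root age (10 and
15 intervals respectively).

## Stochastic mapping and event accounting

Histories are sampled conditional on the fitted model: node states from
the downpass conditional likelihoods, one cladogenetic event per node, and
anagenetic paths conditioned on both branch endpoints by uniformization
(states at epoch boundaries are sampled first, then each homogeneous piece
is filled in). Replaying any sampled log reproduces its endpoint states
exactly, which the tests assert for every map they draw.

Classification follows the six process types of the accounting layer:
anagenetic gains are dispersal (destination = gained realm, source split
1/|R| over the occupied realms), losses are extinction in the lost realm;
narrow sympatry and BAYAREALIKE copying are in-situ speciation spread
1/|R| over the range; subset sympatry is attributed to the nested
single-realm daughter; vicariance is allopatry; founder events record the
jump realm as destination. Every dispersal or founder event contributes
exactly one immigration and one emigration after attribution, so the
interchange matrix's off-diagonal total equals the dispersal + founder
count. Fractional 1/|R| attribution is the default; "largest multiplier"
and "random realm" alternatives exist for sensitivity checks.

Downstream products: realm × type tables (mean/median/2.5–97.5% quantiles
over maps, summed over clades), source/sink interchange matrices with
percentage margins, richness standardization (realms with ≤ 1 extant
species excluded; scale factor configurable, default 1000 per-species
rates), 1-Myr binned series smoothed with a centered 3-bin rolling mean
over a 65-Myr span, per-realm lineages-through-time in 0.1-Myr bins with
quantile envelopes, and top-quantile edge extraction (linear-interpolation
quantiles, ties at the threshold kept).

## Predictors and statistics

Per-realm predictors: Faith's PD; Rosauer phylogenetic endemism with
branch realm membership taken as the union of descendant species' realms;
weighted endemism; fair-proportion evolutionary distinctiveness summarized
by median and (sample) standard deviation over member species; mean range
size; centroid isolation (great-circle by default, chord optionally);
continental shelf area as the 0 to −200 m depth band (boundary included);
and realm area. The collinearity screen iteratively removes, from the
worst pair exceeding |r| > 0.7, the member with the larger mean |r| to all
other retained variables (ties to the later column) — a deterministic
substitute for a judgment-based choice.

The statistical battery: paired Wilcoxon signed-rank tests (zero
differences dropped; exact p for n ≤ 25, else normal approximation with
continuity correction); GLS with AR1 errors fit by profile maximum
likelihood over ρ with exact AR1 whitening, a timebin × epoch design split
at the Miocene onset (23.03 Ma), an optional triple interaction with a
realm factor, and an independent-errors fallback on optimization failure;
and linear mixed models (REML) with z-scored predictors, random intercepts
for the primary grouping, an optional crossed grouping as a variance
component, and Wald 95% intervals.

## What the synthetic data do and do not emulate

Birth–death clades (default λ = 0.15, μ = 0.05 per Myr, clade sizes in the
study's 10–100 tip window) with ranges evolved forward under known
parameters reproduce the statistical structure the pipeline assumes:
ultrametric trees, realm-subset ranges, epoch-stratified dispersal, and
fully logged ground-truth events. They do not emulate real coastline
geometry, range-size heterogeneity from niche differences, diversification
rate variation among lineages, or sampling artifacts in published
supertrees — so green tests certify the machinery and its statistical
calibration, not empirical conclusions about real clades.
Benchmark problem sizes (150-tip recovery clades, 30-tip model-selection
clades, 10–50-tip bundles) were chosen so the full suite runs on a single
CPU in minutes while leaving each check statistically informative.

## Known limitations

* DEC's extirpation rate is weakly identified from extant ranges; even
  with matched conditioning its MLE has ~40% sampling spread at 150 tips.
* The survival-conditioned likelihood matches clade-level conditioning
  exactly but only approximates the survivor-pruning process that shapes
  real supertrees.
* Mixed-model inference uses Wald intervals; no profile or bootstrap
  alternatives.
* Uncapped 9-realm state spaces (512 states) are supported but slow in
  fitting loops; `max_range_size` trades completeness for speed.
* The grid machinery works on regular lon/lat lattices with cell-center
  great-circle distances; no equal-area projection is attempted.
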