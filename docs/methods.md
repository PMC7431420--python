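# Methods

This note documents the models and procedures implemented in
`plovernet`, the assumptions behind them, the parameters that matter,
and the design decisions taken where conventions genuinely differ.

## Social network construction

Associations are inferred from spatio-temporal co-occurrence ("gambit
of the group"): all birds sighted in the same 10-min sampling period
whose positions are connected by a chain of pairwise distances each at
most 20 m form one group, and every within-group dyad is scored as
associating in that period. Grouping is the connected-components
problem on the ≤-20 m proximity graph; the implementation (KD-tree
pairs + union-find) is tested for exact agreement with a brute-force
oracle.

Conventions the literature leaves open, fixed here as defaults:

- **Chain boundary is inclusive** (distance ≤ 20 m joins). The
  exclusive variant is available (`inclusive=False`) and the dyad
  counts under both conventions are reported side by side where they
  matter, since edge counts can differ at exact-boundary distances.
- **Repeat sightings of a bird within one period are averaged** to a
  single position before grouping; a bird recorded under two sexes is
  an error, not a silent fix.
- Coordinates are planar metres (projected); no geodesic arithmetic.
  Appropriate for study extents of a few kilometres.

Edges carry the simple ratio index `SRI = x / (x + y_AB + y_A + y_B)`,
computed per dyad from period tallies (`x` together, `y_AB` both seen
apart, `y_A`/`y_B` one seen). A dyad never observed has SRI 0; edges
exist only for SRI > 0, and node degree counts such edges ("number of
associates"), strength sums their weights. Networks are year-specific;
no cross-year edges.

Pre-breeding filtering keeps sightings strictly earlier than the
season start minus an exclusion window (default 14 days; 30 days and
a drop-May variant are the sensitivity settings).

## Breeding structure

Two nests overlap temporally when the closed intervals from clutch
laying to incubation end share at least one calendar day — day
resolution, boundary inclusive, per the "at least 1 day" criterion.
Per-nest context excludes the focal pair's own nests (either partner
shared) from neighbour counts; the 100 m neighbourhood radius is
boundary-inclusive. Julian laying dates are day-of-year, variance
standardised over the analysis table before entering models with
linear-plus-quadratic date terms (avoids collinearity between the two
terms). Dispersal records pair each individual's earliest nest per
year across consecutive years only; `first_only` keeps each
individual's first transition, the subset used by the fixed-effects
dispersal models.

## Permutation inference

Three measure-preserving randomisation schemes:

| scheme     | what moves                            | what is conserved                                  |
|------------|---------------------------------------|----------------------------------------------------|
| datastream | identities across group slots, per period | group count and sizes per period; each period's individual set; per-bird sighting frequency |
| mate       | female identities among pairs, per stratum (year or year × habitat) | male identities; pair count and female multiset per stratum |
| nest       | (x, y, laid, incubation-end) tuples among nests, per year × habitat | pair identities and success flags; within-stratum location/timing multisets |

Permuting female rather than male identities is an arbitrary,
documented choice; results are invariant to which sex is permuted.

Two-tailed p-values use the add-one convention (the observed value
counts as one realisation of its own null): `p_up = (1 + #{null ≥
obs})/(n+1)`, `p_down` analogous, and `p = min(1, 2·min(p_up,
p_down))` — the "double the smaller tail" rule. The alternative
extremity measure (absolute deviation from the null mean) is available
via `method="deviation"`. p-values are never 0, and with the observed
statistic drawn from the null itself they are super-uniform (tested).

`run_permutation_test` gives each replicate its own RNG substream of
the master seed, so results are independent of execution order and
reproducible replicate-by-replicate. Replicates whose statistic fails
(non-convergence, non-finite value) are dropped with a logged count;
more than 10% failures aborts the test rather than reporting an
unreliable null.

## Regression models

Families follow the response type: binomial/logit for binary and
proportion responses, Poisson/log for counts, gaussian with identity
or log link for continuous responses. All fits are maximum likelihood
so nested models compare by likelihood-ratio test (`chi² = 2·ΔLL`,
floored at 0, df = parameter-count difference).

Random intercepts are supported where the fitting machinery allows ML
estimation: gaussian-identity responses use `MixedLM` (ML, crossed
intercepts as variance components). For binomial and Poisson responses
with random terms the fit is downgraded to a fixed-effects GLM and
flagged (`downgraded=True`); the permutation tests are unaffected
because observed and null statistics come from the same model, but
reported LRT statistics for those specifications are fixed-effects
likelihoods, a documented limitation. Grouping factors with fewer than
two levels are dropped with a logged downgrade. Separation and
singular fits are flagged, never silent; a constant response yields a
degenerate fit with zero slopes.

Gaussian log-link models of distances add a +1 m offset
(`DISTANCE_OFFSET_M`, configurable) so zero distances (a bird reusing
its exact nest site) stay inside the model's support.

VIFs are `1/(1 − R²_j)` from regressing each design column on the
others (intercept included); perfectly collinear terms report `inf`.
Categorical reference levels are alphabetical (patsy default);
habitats and years enter as categorical fixed effects or random
intercepts exactly as each registry entry declares.

## Analysis registry

Each entry couples a model specification to its dataset builder and
null scheme:

| key | response (family) | focal term | random terms | null |
|-----|-------------------|------------|--------------|------|
| A1_degree / A1_strength / A1_prop | degree (Poisson) / strength (gaussian) / prop. male associates (binomial) | sex | individual | datastream |
| A2_pairing, A2_pairing_habitat | pair formed (binomial) | SRI | male, female (crossed) | mate, year (or year × habitat) |
| A3_success_sri (+ `_habitat` GLM, first records) | nest success (binomial) | SRI | male, female | — |
| A4_overlap_degree / strength | n concurrent nests (Poisson) | degree / strength | individual, nest | nest |
| A5_distance_degree / strength | mean distance to concurrent nests (gaussian, log) | degree / strength | individual, nest | nest |
| A6_dyad_overlap / distance | dyad nests concurrent (binomial) / distance (gaussian, log) | dyad SRI | both ids, both nests | nest |
| A7_success_structure | nest success (binomial) | n overlapping (+ mean/min distance, habitat, date, date²; VIF-checked) | year | — |
| A8_success_density100 | nest success (binomial) | n overlapping within 100 m | year | — |
| A9_stay_prev_success | stayed in habitat (binomial) | previous success | individual, year | — |
| A10_distance_prev_success | dispersal distance (gaussian, log) | previous success | individual, year | — |
| A11_distance_neighbour_success | dispersal distance (gaussian, log; GLM, first records) | prop. neighbours successful | — | — |

The pairing dataset (A2) is literal: *all* male × female combinations
with both social and breeding information in a year, not only
co-observed dyads. A6 excludes actual breeding pairs and uses each
bird's earliest nest of the year. A7 is restricted to nests with at
least one concurrent nest (its distance covariates are undefined
otherwise).

## The synthetic-data generator

The generator emulates the features the analyses rely on, with one
global seed expanded into per-stage/per-year/per-survey substreams so
identical configurations reproduce identical tables byte for byte.

What it emulates:

- ~80% of adults colour-ringed (only ringed birds are sightable);
  three rectangular habitats, two of them surveyed outside the
  breeding season.
- Home ranges cluster around a few foraging hotspots per habitat
  (isotropic Gaussian noise around hotspot-anchored centres). The
  observer covers one local area per 10-min period, so a bird's
  sampling period tracks its hotspot with probability
  `period_locality`. These two mechanisms produce the chance
  associations that make networks sparse but not empty: at defaults,
  yearly density ≈ 0.01–0.02 and mean degree ≈ 1, matching the sparse
  regime such survey data show.
- Pair sociality is the ground-truth effect: a pair both detected in
  a survey shares a period with probability q
  (`pair_bond_attraction`), and given a shared period co-locates
  within the chain distance with probability q — so the co-location
  fraction among shared periods is exactly q. q = 0 removes the
  social signal of pairing; the default q = 0.5 is a strong effect.
- Breeding: one attempt per pair-year with probability `breed_prob`,
  laying dates ~ Normal(day 259, 18 d) clipped to Aug–Nov, ~30 d from
  laying to incubation end, success ~ Bernoulli(`nest_success_prob` =
  0.6). The first attempt sits in the pair's home habitat with
  probability `habitat_fidelity` (0.9); after a previous attempt the
  pair stays with probability 0.9 (success) or 0.6 (failure) —
  encoded ground truth that the dispersal analyses recover.

What it does not emulate: movement realism (no correlated walks,
tides, weather), observer effort gradients, divorce and re-mating
within seasons, floaters, age structure, or detection heterogeneity
among individuals. Passing tests therefore show the estimators and
nulls are correct under the stated sampling structure, not that any
particular field system satisfies that structure.

Key defaults: 120 individuals, 4 years, 22 surveys/year of six 10-min
periods, detection 0.35/survey, position noise SD 30 m, hotspot SD
40 m, chain distance 20 m, neighbourhood radius 100 m, season start
1 August, exclusion 14 d.

## Calibration of the pairing test

Type-I error and power of the A2 pairing test are measured on
simulated datasets (`plovernet.calibration`): 100 null datasets
(q = 0) and 50 strong-effect datasets (q = 0.6), 500 randomisations
each, α = 0.05, with the habitat-stratified mate null. Measured on
these conditions: type-I ≈ 0.03, power ≈ 0.98.

Calibration datasets are constructed so the permutation null — pairing
random among pairs nesting in the same habitat and season — actually
holds when q = 0. Two features of the general-purpose defaults violate
that exchangeability for reasons unrelated to any social effect, and
are therefore switched off for calibration:

- **One survey season per dataset.** Pairs persist across years and
  hotspot-driven SRI is correlated across years, a dyad-level repeated
  measure that only the crossed random effects of the full model
  absorb; pooling seasons around a fixed-effects statistic inflates
  its variance relative to season-wise randomisation.
- **Full habitat fidelity.** With fidelity < 1, home and nest habitat
  diverge, and pairing still tracks home habitat (where sociality is
  measured) even at q = 0, so the stated null is false.

The calibration population (60 individuals, full survey effort) keeps
the male × female grid dense enough that the permuted slope
distribution is effectively continuous; much smaller grids leave a
large atom (replicates with no SRI-positive pair), and because tied
values count in both tails, the doubled p-value then cannot reach the
nominal level — the test becomes over-conservative rather than
invalid.

## Problem sizes and runtime

Default simulated datasets (120 birds × 4 years) build and analyse in
under a second per network; the registered permutation analyses use a
fast path for A2 (the design matrix is fixed under mate randomisation,
only the response changes) at roughly 1–10 ms per replicate. The test
suite's calibration checks (100 × 500 + 50 × 500 model refits) are the
dominant cost at a few minutes; the acceptance script mirrors those
sizes. The 10,000-randomisation default of `run_permutation_test`
reflects the analysis standard; tests and examples pass smaller
`n_perm` explicitly.

## Known limitations

- No ML-fitted GLMM for binomial/Poisson families: LRTs for those
  mixed specifications use the fixed-effects likelihood (flagged).
- The gaussian/log-link distance models are a convenience for
  right-skewed distances, not a mechanistic dispersal kernel.
- Mate randomisation treats the female multiset per stratum as
  exchangeable; it does not preserve individual females' multi-year
  pair fidelity (see the calibration section).
- The generator's hotspot mechanism is the sole source of non-pair
  social structure; there is no true gregariousness variation among
  individuals.
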