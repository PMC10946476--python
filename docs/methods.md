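# Methods

## Data model

The pipeline's raw input is a table of blood-meal records: one row per
(study, site, habitat class, Diptera taxon, host taxon) with a count of
blood meals. Habitat is one of three anthropogenic-modification classes
(`Agricultural`, `NearNatural`, `VillageUrban`) supplied as a label —
no habitat inference is performed. Latitude is signed decimal degrees;
all modelling uses |latitude| so hemispheres pool.

### Taxon resolution

Taxa unidentified at species level carry their rank (`genus` or
`family`). Resolution applies three rules, per `study_id` (co-occurrence
is a property of the study location, so the same genus may be safe in
one study and ambiguous in another):

1. a single unidentified species in a genus becomes a `"<Genus> spp."`
   node;
2. several unidentified species in one genus are collapsed to a single
   node only when the user-supplied sympatry table reports that no
   congeneric/confamilial species co-occur there (entry = 1); an entry
   ≥ 2, or a missing entry, removes those rows — a missing entry is
   never silently treated as safe;
3. rows whose rank is above family are removed.

The resolution log reconciles exactly: input rows = output rows +
removed rows. Collapsed rows are *not* re-aggregated at this stage (so
the reconciliation holds); matrix construction sums them anyway. The
sympatry table is a plain CSV rather than a live taxonomic-database
query, for reproducibility.

### Networks

One network per (study, habitat): a study sampling several habitats
yields several networks; several sites of one study in one habitat are
pooled (conflicting site latitudes are an error by default,
`latitude_policy="mean"` opts into averaging). Networks with fewer than
two Diptera taxa are excluded — a single-consumer matrix is a host list,
not a network. Rows and columns are sorted lexicographically, making
every downstream number independent of input order.

## Metrics

All logarithms are natural.

**Interaction evenness.** IE = H / ln(denominator), H the Shannon
entropy of link-weight proportions. The printed formula of the source
literature divides by ln L with L the number of links, but the widely
used R implementation defaults to the number of matrix cells; which one
produced any given published value is often undecidable. Both are
implemented (`realized_links`, the default, and `all_cells`); the mode
is recorded in every output row, and the acceptance machinery reports
both. When all positive cells are equal, H is returned as ln L exactly
so that IE is exactly 1.

**H2′.** H2′ = (H2max − H2) / (H2max − H2min), where the extrema are
over nonnegative *integer* matrices sharing the observed marginals:

* *H2max* (entropy maximum = minimum of Σ n ln n, a convex
  transportation problem): start from the floored proportional table
  ⌊r_i c_j / m⌋, complete the marginals greedily by the cheapest unit
  increments, then push single units along alternating cycles while any
  push lowers the objective. 2×2 cycles are always searched; length-6
  cycles are searched when the matrix is small (≤ 6×6 with both
  dimensions ≥ 3). Since a transportation polytope whose smaller
  dimension is ≤ 3 has no residual cycle longer than 6, local optimality
  is global optimality there.
* *H2min* (entropy minimum = maximum of the same convex objective,
  attained at a polytope vertex): greedy packing that repeatedly pairs
  the largest remaining row marginal with the largest remaining column
  marginal, restarted from every feasible first pairing (when the matrix
  has ≤ 144 cells), then maximal pushes along cycles (the objective is
  convex along a cycle direction, so the optimum step is a full push).

Both extrema are achievable arrangements, so error can only shrink the
interval; if the observed entropy escapes it the offending bound is
clamped to the observed value with a warning. The test suite proves the
heuristics equal exhaustive enumeration on hundreds of random matrices
up to 3×3 / m ≤ 12 (and spot-checks 4×4), with zero clamp events.
Degenerate geometries (H2max = H2min, e.g. single-row matrices whose
marginals fix every cell) return H2′ = 0 with a flag instead of NaN;
flagged networks are excluded from the modelling stage and counted.

## Null model

For each network, the domestic host set (human, chicken, dog, cat, goat,
cattle, horse, pig, sheep; case-insensitive, with a user-editable
synonym map for scientific names) is removed; Diptera rows left with no
meals are dropped; IE is recomputed. Each of 100 replicates removes the
same number k of host species drawn uniformly (not abundance-weighted)
from all hosts. z = (IE_targeted − mean) / sd over replicates
(sample sd; spreads below 1e−12 are treated as zero variance, which with
an equal targeted value gives z = 0 — a genuinely host-symmetric network
yields exactly that). Replicates whose remaining network cannot support
IE (fewer than two links) are redrawn, capped at 10× the replicate
count, after which the network is skipped. Networks with no domestic
host, or where all hosts are domestic (random = targeted), are skipped
with a recorded reason rather than scored. Everything is reproducible
from a single seed.

## Rarefaction

One blood meal = one incidence sampling unit, so the incidence frequency
of a taxon is the number of meals involving it and that of an
interaction is its link weight (which makes interaction richness curves
well defined). Interpolation uses the hypergeometric expectation
S(t) = S_obs − Σ_i C(T−Y_i, t)/C(T, t), computed with log-gamma
differences; extrapolation uses the Chao2-based exponential approach to
the asymptote; Chao2 uses the (T−1)/T small-sample factor and the
bias-corrected form when no doubletons exist. Curves run on a 40-knot
grid from 1 to 2T (the conventional doubling endpoint) and are exactly
continuous at t = T. Bootstrap confidence bands are out of scope; the
curves support a qualitative completeness statement
(S_obs / Chao2 is reported as a completeness ratio).

## Statistical stage

Gaussian GLMs are fitted as OLS (identical by definition; deviance =
residual sum of squares). The full metric model is
`metric ~ habitat + |latitude| + S + log(m) + family + family:|latitude|
+ family:habitat`. Rank-deficient designs (e.g. a family observed in one
habitat only) are fitted on the estimable subspace via the
pseudoinverse, with effective degrees of freedom taken from the
design-matrix rank — this reproduces the reduced interaction df seen
with sparse family×habitat occupancy.

Term tests compare nested models, respecting marginality (main effects
against the main-effects model; each interaction added to it). The raw
deviance change is reported as the X² statistic — on a response bounded
in [0, 1] these are small numbers, which is expected. The p-value uses
the dispersion-scaled change: with Gaussian errors and estimated
dispersion the exactly calibrated reference is F(df, df_resid), so that
is the primary p-value; the chi-square variant of the same scaled
statistic (its large-sample equivalent, and mildly liberal at these
sample sizes) is reported alongside as `p_chisq`. Measured calibration
at n = 60 networks over 500 null replicates: type-I error 0.058 for F
vs 0.074 for chi-square at nominal 0.05.

Tukey HSD habitat contrasts are computed, by default, between
covariate-adjusted habitat means (contrasts of the fitted main-effects
model with covariates at their sample means, p from the studentized
range with k = 3); a raw-group-means mode delegates to statsmodels and
serves as an independent cross-check, to which the adjusted mode
provably reduces when covariates do not vary.

Richness models are OLS `richness ~ |latitude| + n_bloodmeals`, the
blood-meal count serving as a sampling-effort proxy.

## Synthetic data generator

The generator is Dirichlet-multinomial, per network: (1) a host
community — headline expected shares for cattle and humans per habitat,
a Dirichlet spread (concentration = the habitat's `dominance`) over the
remaining domestic and wild hosts, jittered so networks differ;
(2) per-fly host preferences, Dirichlet draws centred on the community
with concentration `preference_strength` (small = host-specific flies =
high H2′); (3) fly activity shares, Dirichlet with per-habitat
concentration (small = a few dominant fly species); (4) one multinomial
draw of the network's meals over (fly, host) cells. Every sampled taxon
is guaranteed at least one meal by moving single meals from the largest
cell: a compiled network contains exactly the observed taxa, and this
makes realized richness S independent of habitat, so the habitat effect
on evenness remains identifiable with S and log m in the model — as in
the compiled data, where it persists under those controls. Without this,
the habitat signal is entirely mediated by node loss and the adjusted
test cannot see it.

Default scenario (the study conditions): 14/18/15 networks per habitat,
120–260 meals each (≈9 100 total), domestic meal shares 0.81/0.63/0.63
with cattle at 0.51 absolute in Agricultural and humans at 0.26 in
Village/Urban, five Diptera families drawn at the observed 24/12/4/4/2
network frequencies, latitudes uniform on [−34°, 60°] with no structural
effect (an optional `latitude_effect` knob injects one for power
studies). The dominance/preference/activity concentrations (0.4/2.5/2.5,
6.0, 0.25/0.6/0.6) were set once so the emergent metric levels mirror
the compiled data: mean H2′ ≈ 0.39, an agricultural evenness deficit of
≈ 0.09–0.12 against both other habitats (in either IE mode), and hosts
near sampling completeness while interactions remain undersampled.

What the generator does not emulate: absolute richness scale (its taxon
pools are tens of species, not the hundreds of a global compilation, so
aggregated totals and host-completeness ratios are flatter than real
ones); between-study methodological heterogeneity; spatial/climatic
autocorrelation; and it couples habitat weakly to H2′ (a by-product of
the activity asymmetry), whereas the compiled data showed no habitat
effect on H2′. Passing tests therefore demonstrate the pipeline's
correctness and calibration under a faithful-but-idealised generative
model, not conclusions about any real landscape.

## Problem sizes and determinism

Calibration experiments run at the sizes that make their claims
meaningful while staying desk-scale: 500 null replicates (n = 60
networks) for type-I error, 200 replicates for power, 100 seeds for the
end-to-end habitat-ordering check; these run in a few minutes total.
All randomness flows from numpy `SeedSequence` spawns of a single seed;
identical seeds give byte-identical record files and bit-identical
z-scores across runs.
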