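# Methods

This note documents the models and procedures implemented in `pollinet`,
their assumptions, the defaults and why, and what the synthetic-data tests
do and do not demonstrate about real visitation data.

## Network construction

Visitation records (plant, pollinator, site, date, count) are pooled across
sites and dates into a single count matrix `α_ik`. Pooling is deliberate:
the analyses address the aggregate community, not site- or time-resolved
structure. Species labels are sorted lexicographically at construction so
that every seeded downstream computation is reproducible regardless of the
order records arrive in. A species enters the network only through at least
one interaction; all-zero rows/columns are invalid by construction.
Unidentified taxa (genus- or family-level labels) are treated as ordinary
labels with no rank-aware merging, and species absent from the annotation
tables fall into a functional group `"unknown"`. Percentages in summary
tables are rounded to two decimals, matching standard reporting style in
the visitation literature.

## Bray–Curtis composition and PERMANOVA

Dissimilarity between two plants' pollinator faunas is Bray–Curtis on raw
pooled counts, `1 − 2Σmin/(Σx+Σy)` (computed via
`scipy.spatial.distance`). Counts are not relativized first: whether to
transform before Bray–Curtis is genuinely open in this design; raw counts
are the default of the standard ecology tooling and keep the null model
(which operates on event counts) on the same scale. The pairwise matrix is
returned as a `skbio.DistanceMatrix` and can be fed to any external
ordination (NMDS is intentionally not implemented here).

The PERMANOVA is the one-way McArdle–Anderson partitioning computed
directly from the distance matrix: `SS_total = Σ_{i<j} d²_ij/N`, within-
group sums divided by group size, `F = (SS_between/(g−1))/(SS_within/(N−g))`.
The permutation p-value uses the +1 convention, `p = (1+#{F_perm ≥ F_obs})/
(1+n_perm)`, so p is never exactly zero; the default is 999 permutations
and a seed is always required. Degenerate inputs: a group containing every
object is an error; if all within-group distances are zero the pseudo-F is
reported as +inf and permutations still yield a valid p. An exhaustive-
enumeration variant exists for small N. Multi-factor and nested designs are
out of scope.

## Abundance-resampling null for sharing with a focal plant

The question the null isolates: does plant j resemble the focal plant more
than expected if every plant sampled pollinators proportionally to their
community-wide abundance? Each replicate redraws, for every plant
independently, `R_i` events from the categorical distribution
`p_k = C_k/F` (a multinomial per row; row totals preserved exactly, column
totals stochastic). "Number of pollinators seen on each plant" is
interpreted as the number of interaction events `R_i`, not distinct taxa,
because Bray–Curtis operates on event counts; the distinct-taxa reading is
available via the `row-multinomial`/`patefield` switch used for role
thresholds but is not the envelope default. The focal plant's own row is
randomized too, so the envelope reflects joint sampling noise. Per plant
the 1000-replicate distribution yields the mean and the 2.5/97.5
percentiles (a percentile interval, not a normal approximation); the
observed distance is classified by strict comparison, with ties counting
as within the null — ties favour the null hypothesis. Replicate seeds are
derived from the master seed by a counter scheme (BLAKE2b of
`"{seed}:{tag}:{i}"`), making envelopes bit-identical across reruns.

## Modularity

Barber's bipartite Q compares in-module interaction weight with the
margins-based expectation `R_i C_k/F`; it is 0 for any margin-random
structure and 1 only in the limit of many equal, perfectly separated
blocks. The optimizer is weighted bipartite label propagation with
modularity-gain acceptance: species are visited in seed-shuffled order;
each species considers the modules of its interaction partners and moves
only if Q strictly increases (ties on gain go to the lowest module id);
sweeps repeat until no move improves Q, then a greedy refinement merges
module pairs while Q increases. After convergence, zero-gain merges are
applied so that Q-equivalent splits collapse to the fewest modules (a
structureless matrix yields a single module at Q = 0). This
label-propagation-plus-merging design trades the exhaustiveness of
simulated-annealing optimizers for speed and per-seed determinism; the
meta-optimizer reruns it with N derived seeds (default 10) and keeps the
best Q, breaking ties toward fewer modules, then first found. Because the
optimizer differs from other published module-detection heuristics, Q on
any given empirical matrix may differ slightly from values obtained with
other tools; recovery tests against planted structure are the relevant
check.

## Species roles

Degrees for c and z are binary (distinct partners), following the
Olesen-style role tradition; weighted variants are out of scope. z
standardizes the within-module degree over the *same-trophic-level* members
of the species' module using the population standard deviation; modules
with a single same-level member, or uniform within-module degrees, give
z = 0, keeping those species classifiable rather than undefined.
c = 1 − Σ_t (k_st/k_s)² measures how evenly a species' partners spread
over modules (0 = all partners in one module).

Thresholds are not fixed literature constants: they are the 95% quantiles
of c and z pooled per trophic level over species of 1000 (default)
margin-preserving null networks, each given a single label-propagation run
(one run, not meta restarts, keeps 1000 nulls tractable and only adds
noise that the quantile absorbs). The null family is Patefield's
fixed-margins algorithm (via `scipy.stats.random_table`), with a
row-multinomial alternative behind a config switch. Quantiles are pooled
per level rather than across levels; with strongly skewed margins both
levels tend to land near c ≈ 0.83 anyway, which is why per-level and
pooled thresholds are hard to distinguish in practice. Classification is
strict: a value exactly at its threshold is low.

## Müller influence index

`d_ij = Σ_k (α_ik/R_i)(α_jk/C_k)` for same-level species, computed in one
matrix product; rows (targets) sum to 1 by construction and the diagonal
(self-influence) is included in the per-acting-species sums and means —
the mean divides by the total number of same-level species, including the
acting species itself. The orientation (rows = targets, columns = acting)
is stated in every output header because transposition is the classic bug
with asymmetric indices. The index quantifies *potential* influence via
shared partners; no pollen-transport or fitness interpretation is
computed.

## Synthetic communities

The generator emulates the statistical features the analyses rely on:
strongly skewed visitation (species weights i.i.d. lognormal(0, σ), σ = 1
by default — with ~20–40 plants this routinely concentrates half the
visits in two or three species, the regime where abundance-driven sharing
is plausible), multinomial sampling of a fixed total of visitation events
(2000 by default, matching a realistic single-season survey effort at
desk scale), and optionally planted trait-affinity blocks: round-robin
module assignment (balanced sizes keep NMI-based recovery stable) with
each visit staying in the plant's module with probability `affinity`
(default 0.95, a strong but not perfect trait signal). Species sampled
zero times are dropped, mirroring the network invariant, and reported in
the ground truth.

What the generator does *not* emulate: phenology, spatial structure, site
effects, sampling-method biases, or continuous trait matching. Passing the
calibration tests therefore shows the null model is correctly calibrated
*under its own assumptions*, and that planted discrete modules are
recoverable — not that real visitation data satisfy those assumptions.

## Problem sizes and numerical choices

Reference study conditions used by the test suite and the acceptance
script: neutral 20 plants × 30 pollinators × 2000 visits with 1000 null
replicates (envelope coverage ≥ 90% expected at the nominal 95% level);
modular 40 × 60 × 2000 at affinity 0.95 with 4 modules (NMI ≥ 0.9
recovery); role thresholds at 200 Patefield nulls for calibration runs
and 1000 for full analyses. Move/merge acceptance uses a 1e-12 gain
tolerance; percentiles use numpy's default linear interpolation; the
optimizer's determinism is per (matrix, seed).

## Known limitations

* The label-propagation optimizer finds local optima; meta restarts
  mitigate but do not guarantee the global maximum on large networks.
* Null-model thresholds inherit Monte-Carlo noise of order a few
  hundredths at 200 nulls; use 1000 for reportable thresholds.
* Bray–Curtis on raw counts is sensitive to total visitation per plant;
  rare plants have noisy compositions and wide envelopes.
* The envelope test is per-plant marginal; no multiplicity correction is
  applied across plants, matching standard practice for envelope plots.
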