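# Methods

## Data model and conventions

All model code consumes **branching times**: the ordered internal-node
ages `x_2 ≥ x_3 ≥ … ≥ x_n` of a rooted, binary, ultrametric tree,
measured backward from the present in the tree's time units (Myr for a
dated phylogeny).  `x_2` is the crown age; the interval on which the
reconstructed tree holds `i` lineages has duration `d_i = x_i − x_{i+1}`
(`x_{n+1} ≡ 0`).  Trees are validated rather than repaired:
ultrametricity is checked at a relative tolerance of 1e-6 × crown age
(dated trees should be exactly ultrametric; deviation signals an input
error), polytomies are rejected with an explicit error (silently
resolving them would change the branching times), and tied node ages
are allowed — a zero-duration interval contributes nothing to the
interval sums while its event term is retained.

## Likelihoods

All pure-birth-type models share one kernel.  With per-interval
speciation rates `λ_i`,

```
lnL = Σ_{i=2}^{n−1} ln(i λ_i) − Σ_{i=2}^{n} i λ_i d_i .
```

The five models instantiate it (or extend it) as:

* **pureBirth** — `λ_i = λ` (1 parameter).  Closed-form MLE
  `λ̂ = (n−2) / Σ i d_i`.
* **BD** — constant-rate birth–death in the (net rate `r`, extinction
  fraction `a`) parameterization, via the Nee-style reconstructed-process
  closed form
  `(n−2) ln r + r Σ_{i=3}^{n} x_i + n ln(1−a) − 2 Σ_{i=2}^{n} ln(e^{r x_i} − a)`.
* **DDL** — `λ_i = r1 (1 − i/k)`, `k ∈ (n, 10^7]`.
* **DDX** — `λ_i = r1 · i^(−x)`, `x ∈ [−5, 5]` (negative `x` means
  rates increase with standing diversity).
* **yule2rate** — `λ = r1` at ages older than the shift time `st`,
  `r2` at younger ages (3 parameters).

**Orderings constant.**  The kernel contains `Σ_{i=2}^{n−1} ln i =
ln (n−1)!`; the BD closed form traditionally omits it.  The same
constant is added to the BD likelihood so all five models share one
additive convention.  Absolute log-likelihoods therefore may differ
from other software by a data-independent constant, which cancels in
every AIC difference and in the rate-constancy statistic.  Comparisons
against published absolute `Ln(L)` values are for this reason not a
meaningful check; AIC *differences* are.

## Optimization

* BD: the net rate has a unique score-equation root bracketed on
  (0, ∞) for each fixed `a`, solved by vectorized safeguarded
  Newton/bisection; `a` is profiled on a deterministic grid over
  [0, 1) refined by successive bracket subdivision.  The `a = 0`
  boundary always competes via the exact pure-birth closed form, and a
  boundary optimum is reported with `r1 = λ̂` and log-likelihood
  *identical* to pure birth.  The profile approach is a stronger global
  search than a handful of quasi-Newton starts and, in testing, matched
  or exceeded a 5-start L-BFGS-B baseline on every tree (the only
  discrepancies were trees on the degenerate `r→0, a→1` ridge, where
  the profile found the higher optimum).
* DDL / DDX: for fixed shape parameter the rate scale has the closed
  form `r1̂ = (n−2)/Σ i c_i d_i`, so both are one-dimensional profile
  problems, solved on a coarse grid plus bounded scalar refinement.
  The supremum of the DDL profile over `k ∈ (n, ∞)` is exactly the
  pure-birth likelihood; when the bounded profile falls below that
  limit the fit reports the limit value with `k` at the cap and a
  `collapsed_to_pure_birth` flag.  This keeps the nesting identity
  `lnL(DDL) ≥ lnL(pureBirth)` exact and reproduces the published
  "huge k, ΔAIC = −2" collapse pattern; the value forgone by the cap
  is below 1e-4 log-units at these tree sizes.
* yule2rate: the likelihood is piecewise in `st`, so candidates are
  the internal branching times plus midpoints of adjacent branching
  intervals; each candidate has closed-form segment MLEs
  (events / lineage-weighted duration).  Candidates leaving zero
  events on one side are inadmissible (the supremum there is not
  attained); ties break toward the older candidate.  Events exactly at
  the shift belong to the older regime.
* Nesting sanity: any rate-variable optimum below the pure-birth
  optimum (beyond 1e-8) raises an error rather than returning a
  silent best-effort value.

## AIC conventions

`standard` is `−2 lnL + 2k`.  The `table5` compatibility convention is
`−(2 lnL + 2k)` — the parameter penalty enters with inverted sign — and
is provided because published diversification tables in this literature
print AIC values satisfying that identity.  Both are always carried;
`aic_standard − aic_table5 = 4k` for every fit.  Under `table5`, a
nested model with an extra parameter and identical likelihood shows
ΔAIC = −2 relative to its parent, which is the boundary pattern the
acceptance script recomputes.

## Rate-constancy test

`ΔAIC_RC = AIC(best of {pureBirth, BD}) − AIC(best of {DDL, DDX,
yule2rate})` under the chosen convention; positive values favour rate
variability.  Significance is one-sided (upper tail) against the same
statistic computed on pure-birth trees simulated with the observed tip
count and pure-birth rate estimate, 9000 replicates by default; the
p-value uses the add-one estimator `(1 + #{null ≥ obs})/(R + 1)`.
The statistic is exactly invariant to time rescaling (all rates scale
by 1/c, log-likelihoods shift by the common Jacobian `(n−2) ln(1/c)`),
so the null conditions on tip count only, not on crown age.
Replicates whose fit fails are resampled and counted; more than 1%
failures aborts the run.

## Distances, alignment summaries, clock LRT

Pairwise distances use pairwise deletion (sites where either sequence
carries a gap or ambiguity are dropped for that pair only), matching
mixed-coverage matrices where some specimens lack genes.  The ML
distance is plain HKY85 — empirical base frequencies per pair,
transition/transversion parameter estimated jointly with the distance
by bounded ML (both can be fixed; with equal frequencies and κ = 1 the
estimate equals the Jukes–Cantor closed form).  A per-pair Γ shape is
not identifiable and is deliberately not estimated.  Pairs with no
finite optimum (saturation, cap at 10 substitutions/site) are reported
as NaN, never as a fabricated number.  Group summaries are arithmetic
means over unordered pairs, in percent; singleton groups have an
undefined (not zero) within-group mean.  Variable sites are columns
with ≥ 2 distinct unambiguous states; parsimony-informative sites have
≥ 2 states each in ≥ 2 sequences.  The molecular-clock LRT consumes
externally computed tree log-likelihoods (clock enforced / free) and a
required degrees-of-freedom input — tools differ in how they count
clock constraints, so no default is assumed — and refers
`2(lnL_free − lnL_clock)` to the χ² upper tail.

## Synthetic data

Simulated trees are crown-conditioned (the process starts with two
lineages at the crown) and conditioned on an exact tip count `n`,
matching the branching-time convention.  For constant or
diversity-dependent rates, the stage with `i` lineages lasts
`Exp(i λ_i)`; a final full waiting time with `n` lineages places the
present strictly after the last branching event (memoryless overshoot).
The two-rate model has an age-dependent rate, so it is sampled exactly
by backward inverse-cumulative-rate transformation (stage `i`, walked
backward from the present, advances the cumulative rate
`Λ(age) = ∫ λ` by `Exp(1)/i`); this reduces to the forward scheme when
the two rates coincide.  Topology is assembled by uniform lineage
splitting at each event.  The birth–death simulator is a forward
Gillespie run with rejection until exactly `n` survivors, extinct
lineages pruned; events during the final overshoot window are ignored —
a small, documented approximation of exact `N(present) = n`
conditioning, adequate at desk scale but mildly biased for extreme
`μ/λ`.  Under this generator the `n = 3` age ratio `x_3/x_2` has the
exact law `F(u) = 3u/(2+u)` (not uniform — uniformity holds only in a
vanishing-rate limit), and the test suite checks that exact law.

Alignments evolve site-independently under HKY85 (optionally with
Gamma rate multipliers of mean 1) along the tree, with the root drawn
from the stationary frequencies; branch lengths in expected
substitutions per site are `rate_per_unit × branch length × site
multiplier`.  What the generator does **not** emulate: indels and
alignment error, codon structure, among-gene partition heterogeneity,
selection, sampling biases of real taxon sets.  Passing tests
therefore demonstrate correctness of the estimators under the models'
own assumptions, not robustness to real-data violations of them.

## Problem sizes and defaults

Default study conditions mirror small dated radiations: trees of
10–60 tips, net rates 0.1–0.2 per Myr, null sample of 9000 replicates.
The test suite exercises the same machinery at desk scale — e.g. the
size/uniformity calibration of the rate-constancy test uses 200
simulated datasets with 200-replicate nulls (n = 20, λ = 0.15), and
parameter-recovery suites use 100–200 replicates — sizes chosen to
make the Monte-Carlo checks sharp while keeping a full run of the
suite in the minutes range.

## Known limitations

* No incomplete-sampling correction (none is applied by the analysis
  the package mirrors); estimates on undersampled clades inherit the
  usual pull-of-the-present biases.
* The BD likelihood surface has the classic `r→0, a→1` ridge; on small
  trees the global optimum occasionally sits there, and the profile
  fit will faithfully report it (with `a` near 1).  This is a property
  of the likelihood, not of the optimizer.
* yule2rate's shift-time grid bounds the error of a piecewise-constant
  search; `st` is only ever identified up to the branching interval
  containing it.
* The clock LRT consumes external log-likelihoods; it does not compute
  tree likelihoods itself.
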