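# Methods

This note documents the models implemented in jellytroph, the assumptions
behind them, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that a user
extending or auditing the package should know about. It describes procedures
only; every empirical number the package claims is computed by the test suite
or by `scripts/acceptance.py` at run time.

## Data model

All inputs are UTF-8 CSV with `.` decimals. Publication-derived glyphs are
normalized on parse: Unicode minus/en-dash/em-dash → ASCII hyphen, µ/μ → `u`
(so `−18.2` parses as −18.2 and `200–1000 µm` matches the canonical size
class `200-1000 um`). The month calendar is an ordered categorical supplied
in config; the default is the eight-month field sequence
Nov, Dec, Feb, Apr, May, Jun, Jul, Sep (no date arithmetic is ever done).
Missing prey-count cells are structural zeros — a taxon not found in a
stomach is a true zero, and taxon vocabularies are unioned across rows.
Missing δ or FA cells are errors, never imputed. Validation collects *all*
offending cells before raising, so one pass yields a complete report
(exposed as JSON via `jellytroph validate`).

## Prey electivity

For each focal taxon and month a 2×2 table is built: pooled stomach counts
(focal vs all other taxa) against environment counts derived from net-haul
densities. Pearre's C is the signed square root of the ordinary 2×2
chi-square scaled by the grand total, `χ² = n·C²`, tested at df = 1 with no
continuity correction and no multiple-testing adjustment by default (a Holm
option exists but is off, matching the per-cell flag convention of field
tables); direction flags are "+"/"−" when p ≤ α.

Two decisions deserve emphasis:

- **Pooling.** Counts are pooled per month across predators before testing.
  Individual medusae carry a handful of prey, far too few for a per-stomach
  chi-square; monthly pooling is what makes the test defensible. A
  per-sample mode (`per_sample_selectivity`) exists behind a flag for
  sensitivity analysis.
- **Environment pseudo-counts.** Densities (ind m⁻³) are not counts, and a
  chi-square needs counts. Policies: `volume` (densities × sampled volume
  when the table carries one, falling back to `match`), `match` (density
  proportions × the month's pooled diet total, keeping power comparable
  across months), `raw` (round densities as-is, half-up), or a fixed integer
  pseudo-n. The default is `volume`. The choice changes power, not the sign
  of C.

Interpretation caveat: electivity is *relative*. If one abundant taxon is
strongly selected, every other taxon's diet share shrinks below its
environment share, and neutral taxa can flag "−" legitimately. At large n
the flag sign for taxon t converges to sign(w_t − w̄), where w̄ is the
availability-weighted mean selection weight — worth remembering when reading
recovery tests against generator weights.

Cells where the focal taxon is absent from both margins, or where a margin
is entirely zero, are reported "not testable" rather than C = 0.

## Trophic level

`TL = (δ¹⁵N_f − δ¹⁵N_ref)/3.2 + 2` with the baseline fixed at calanoid
copepods (TL 2) and 3.2 ‰ enrichment per level; both are configurable. The
baseline δ¹⁵N_ref is a per-month input with a global scalar fallback,
because baselines drift seasonally and a yearly constant conflates baseline
movement with diet change. δ¹³C is carried through all summaries (it traces
carbon sources and feeds the mixing TEF, ~2 ‰ per step) but TL itself is
nitrogen-based only; no Suess or lipid-normalization corrections are
applied. Group summaries report mean ± SE; single-sample groups report
SE = 0 with an explicit `se_defined = False` flag rather than NaN.

## Mixing model

The likelihood is the fully specified source-uncertainty mixing structure:
for consumer i and isotope j,

    x_ij ~ Normal( Σₖ pₖ(μⱼₖ + cⱼₖ),  Σₖ pₖ²(ωⱼₖ² + τⱼₖ²) + σⱼ² )

with source means/SDs (μ, ω), TEF means/SDs (c, τ) and a per-isotope
residual scale σⱼ capturing individual variation beyond source and TEF
uncertainty. Defaults: TEF 2 ± 0.3 ‰ for δ¹³C, 3.2 ± 0.1 ‰ for δ¹⁵N.
Priors: Dirichlet(1,…,1) on **p** (uniform over the simplex) and
half-normal on σⱼ with scale equal to the observed consumer SD of isotope j
— weakly informative, scale-matched to the data. The named R package this
mirrors documents its fractionation inputs but not all prior details, so the
priors here are the package's own fully stated choice.

**Sampler.** Random-walk Metropolis on unconstrained coordinates:
additive-log-ratio/softmax for **p** (K−1 free logits, last fixed at 0,
log-Jacobian Σₖ log pₖ) and log σ (Jacobian Σⱼ log σⱼ). Each iteration
updates two blocks separately — the simplex logits and the log scales — each
with its own step size adapted toward 20–40% acceptance during burn-in only,
then frozen (keeping the post-burn-in kernel valid). The blocking matters:
σ is weakly identified whenever source variance explains most of the
consumer spread, and a single shared step lets the well-identified simplex
block starve the σ block, inflating its R-hat. Defaults: 4 chains, 20,000
iterations, 50% burn-in, thin 5. Convergence is monitored by Gelman–Rubin
R-hat per parameter across chains (threshold 1.1); non-convergence flags the
result, it never discards it. Everything is deterministic given a seed
(chains get independent streams spawned from it).

**Identifiability.** With two isotopes, three sources are identified only if
their (δ¹³C, δ¹⁵N) means form a genuine triangle. Sources lying on a line —
even if widely spaced on each axis — leave the middle source's contribution
a non-identifiable ridge; the sampler then reports honest, wide, slowly
mixing posteriors. The generator ships `WELL_SEPARATED_SOURCES`
(−24/2, −16/4, −21/11 ‰, sd 0.5 ‰) as an identifiable reference geometry for
recovery experiments; the realistic `paper-like` sources are deliberately
closer together and may legitimately return a flagged, weakly identified
fit.

Summaries are posterior mean, median and equal-tailed credibility intervals
(numpy's linear-interpolation quantiles) at a configurable level (default
95%). K = 1 degenerates to p ≡ 1 with only σ sampled. With zero consumers
the posterior reproduces the Dirichlet prior (a test asserts this).

## Fatty acids

Classification is a pure function of the shorthand `C<carbons>:<bonds>`
with optional `n-<x>`: SFA/MUFA/PUFA at 0/1/≥2 double bonds. Omega-3/6
membership comes from the suffix only; FAs without one (e.g. `C16:1n-7`'s
n-7, or suffix-free names) count toward saturation classes but toward
neither omega family. Aliases EPA = C20:5n-3, DHA = C22:6n-3, AA = C20:4n-6
and palmitic = C16:0 resolve by default; a strict mode refuses them.
Inconsistent literature spellings of EPA/AA (n-6/n-3 swaps) are treated as
typos and normalized to the canonical forms. Ratios with zero denominators
are NaN and listed in the summary's `undefined` set — never infinity.
Ratio denominators use all parseable FA columns present in the file, not a
fixed panel. Totals are homogeneous of degree 1 in concentrations and every
ratio of degree 0 (property-tested).

## PERMANOVA and SIMPER

Distances: Euclidean or Bray–Curtis `Σ|x−y|/Σ(x+y)`, after an optional
elementwise log(1+x) (natural log, configurable). A Bray–Curtis pair of
all-zero rows is defined as distance 0 with a warning. With A = −D²/2 and
G = JAJ the Gower-centered matrix, each model term's sum of squares is
tr(H_term G), where H_term is the sequential (Type I) projection increment
of that term's dummy columns over what is already in the model — mains in
the user's factor order, then two-way interactions, then the three-way.
Degrees of freedom come from rank increments (SVD), so confounded designs
are detected rather than silently absorbed. Pseudo-F = MS_term/MS_residual.
On Euclidean distances with one factor this is *exactly* classical ANOVA
(tested to 1e−10 against the closed form).

Significance uses unrestricted permutation of sample labels for all terms,
with the observed statistic included in the null set:
p = (#{F* ≥ F} + 1)/(n_perm + 1). This is exact for one-way designs and the
standard approximation for balanced crossed designs; it may differ from
residual-permutation schemes used by commercial packages. Multiway designs
must be balanced (the generator only produces balanced layouts); unbalanced
data get an error directing to one-way analyses. For small samples an
exhaustive mode enumerates all n! orderings (p without the +1 rule, n ≤ 9).
A zero total-SS input (all samples identical) yields a flagged degenerate
table, not an exception. Seeds are recorded in the output.

SIMPER decomposes the average between-group Bray–Curtis dissimilarity
additively: variable v's contribution between groups A and B is the
cross-pair average of |x_iv − x_kv| / Σ_w(x_iw + x_kw). Contributions sum to
the average dissimilarity *exactly* (it is the Bray–Curtis numerator split
by variable), percentages to 100; variables are reported sorted with
cumulative percentages. Empty-vs-empty pairs contribute zero dissimilarity.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
every parameter recorded in a `SyntheticTruth` JSON next to the CSVs:

- **Environment:** per-taxon seasonal mean-density profiles (copepod spring
  peak, pteropod winter peak, …) with log-normal noise at a configurable CV
  (default 0.15), mean-preserving.
- **Stomachs:** per-predator totals Poisson around the month's mean
  (negative-binomial via a gamma-mixing overdispersion knob), taxa
  multinomial with probabilities ∝ weight × availability. Expected diet
  share under a single reweighted taxon follows w·p/(1 − p + w·p), the
  algebra the recovery tests check.
- **Isotopes:** consumers drawn from the mixing model's own likelihood at a
  stated true **p**, plus raw per-source observation samples. The
  `paper-like` sources are back-derived from published consumer–source
  enrichment differences (consumer ≈ −19.3 ‰ δ¹³C / 4.4 ‰ δ¹⁵N; micro
  2.4/3.6 ‰ lower, meso 1.8/2.8 ‰ lower, macro sharing the consumer δ¹⁵N
  level), with sd 0.5 ‰ and residual sd 0.3 ‰ — typical within-class spreads
  for plankton isotope data. True p = (0.45, 0.40, 0.15) sits at the
  midpoints of the credibility intervals reported for this system.
- **Fatty acids:** balanced month × sex × tissue layout; per-FA log-normal
  (log-scale sd 0.25, mean-preserving) around a plausible 14-FA medusa panel
  scaled by a month effect, a gonad:soma storage multiplier (default 10, the
  magnitude reported for this system), and sex-specific spawning-season peak
  months (females: Apr–Jun, Sep, Dec; males: May, Dec).
- **Stomach/diet scale:** 20 predators per month, monthly mean totals
  shaped like the observed cycle (spring maximum ≈ 39, winter minimum ≈ 2
  prey per medusa).

What it does **not** emulate: digestion bias (soft prey vanishing from
stomachs), diel-migration sampling bias, baseline isotope drift within a
month, FA covariance structure between compounds (concentrations are
independent log-normals given the group means), unbalanced field layouts,
and any hydrodynamics or population dynamics. Passing recovery tests
therefore show the estimators invert the generator's statistical structure
at realistic effect sizes and sample sizes — not that they overcome the
field biases above.

## Problem sizes in tests and the acceptance script

The suites use the sizes the analyses are designed for: 1000-table identity
checks, 100-dataset ANOVA-oracle comparisons, 1000-replicate type-I
simulations (199 permutations each), mixing recovery over 20 seeded
replicates of 50 consumers with the full 4 × 20,000-iteration sampler, and
single deterministic end-to-end runs (with a lighter 2 × 4000 sampler, since
the end-to-end checks target wiring and detection, not posterior accuracy).
The full suite runs in a few minutes on one CPU.

## Known limitations

- The chi-square electivity test assumes both margins are counts from
  comparable sampling processes; the pseudo-count policies paper over the
  density-vs-count mismatch but cannot remove it.
- Sequential (Type I) SS makes multiway PERMANOVA term order matter; the
  default order is month, sex, tissue.
- The mixing model has no concentration dependence, isotope routing, or
  covariates; sources enter as summary means/SDs, not raw observations.
- Monthly TL estimates are only as good as the supplied baseline series;
  the package deliberately refuses to invent one.
- Unrestricted label permutation for interaction terms is approximate;
  exact tests for interactions in distance-based ANOVA remain an open
  methodological problem.
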