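# Methods

`burnoutnet` implements an analysis chain for studying occupational burnout
from workplace survey data when no observed social network exists: score
burnout from the MBI-GS instrument, screen survey variables for association
with burnout, infer a colleague network from attribute similarity, and test
for burnout homophily with an exponential random graph model (ERGM).  This
note records the models, the defaults and why, and what the synthetic
cohort does and does not establish.

## The reference cohort and the synthetic generator

The package's default "stated world" is a published cross-sectional survey
of a large airport company's workforce: 6,689 questionnaires returned,
5,794 valid (86.6%), of which 728 respondents (12.6%) screened as high
burnout risk.  The raw data are not public; `burnoutnet._cohort` embeds the
cohort's baseline-characteristics table (per-level counts by burnout group
for 32 categorical variables across four categories — demographic,
work-related, health, lifestyle — plus median/IQR summaries for age and
weekly walking time), and the synthetic generator emulates it.

Generation is two-stage: a Bernoulli burnout label at the configured
prevalence (default 728/5,794), then each variable drawn from its marginal
distribution with a burnout-dependent shift.

* **Categorical variables** are drawn from the schema's level
  probabilities; the high-burnout group's probabilities are tilted by a
  per-level log-odds vector and renormalized.  Zero effects therefore give
  an *exact* null (both groups share one distribution) — the property the
  null-calibration tests rely on.  `cohort_effect_sizes()` returns the
  log odds ratios `log(p_high_l / p_low_l)` computed from the embedded
  group counts, so the simulated contrast reproduces the published one.
* **Numeric variables** use a truncated normal inside the variable's
  range.  The source reports only medians and IQRs, so the family is our
  choice: bounded, unimodal, and with scale set by IQR/1.349 (the normal
  quartile spread).  The high-group effect is a location shift expressed
  in units of the range.
* **MBI-GS items** (16 items, 7-point 0–6 scale; 5 emotional-exhaustion,
  5 cynicism, 6 professional-efficacy items — the standard MBI-GS layout,
  which the source does not spell out) are generated from latent subscale
  means placed `separation` above/below the critical boundaries, with
  unit-normal item noise, rounding and clipping.  High-risk respondents
  get high exhaustion/cynicism means and a *low* efficacy mean, so the
  reversed efficacy score also exceeds its boundary.

**Provenance note.** Two rows of the published table are internally
inconsistent (the "6–8" professional-grade overall count and the
"relatively healthy" overall count disagree with their group sums).  The
group-level counts are consistent and are treated as authoritative
throughout; overall marginals are derived as their sums.

What a green test on synthetic data establishes: that the pipeline's
statistics, estimators and selection behave correctly on data with the
stated marginals, prevalence and group contrasts.  What it does not: the
real cohort's joint dependence among variables (the generator draws
variables independently given the label), response styles, or invalid
questionnaires — the source never defines how its 895 exclusions were
identified, and the simulator does not model them.

## MBI-GS scoring

Subscale means are compared with critical boundaries; a respondent is
labelled high burnout iff **two or more** subscale scores strictly exceed
their boundaries.  Ties are not exceedances ("higher than" is read
strictly).  The professional-efficacy subscale is reversed (`6 − mean`)
before comparison by default, since low efficacy indicates burnout; the
unreversed convention is available (`efficacy_reversed=False`) because the
source does not state which was used.  The boundary values for the study
group were never published: the defaults (3, 3, 3) are simply the
simulator's generating boundaries, making label round-trips
self-consistent.  Users with real MBI-GS data must supply their
instrument's boundaries.

## Association screening

* **Categorical:** Pearson chi-squared on the level-by-group table,
  expected counts from margins, **no Yates continuity correction**.  The
  uncorrected convention is deliberate: it reproduces all of the cohort's
  recomputable printed p-values (0.09, 0.07, 0.11, 0.08, 0.01), whereas
  the corrected 2×2 statistic gives e.g. 0.11 for high blood pressure.
  Expected counts below 5 log a warning but do not abort (the published
  table evidently tested levels with expected counts near 2).
* **Continuous:** Wilcoxon rank-sum with midranks, tie-corrected null
  variance, continuity correction, two-sided normal p-value.  Exact
  enumeration is used only as a test oracle at tiny n.
* **Screen:** each schema variable is tested by kind; variables with
  p < α (default 0.05) are returned grouped by category in schema order.
  No multiple-testing correction is applied, matching the per-variable
  convention of baseline-characteristics tables.

## Network inference (Survey2Vector)

Respondents are encoded as vectors with every entry in [0, 1]:
min-max scaling for numeric variables (z-scores would violate the unit
interval the similarity construction assumes), equally spaced codes
{0, 1/(L−1), …, 1} for ordinals (preserving order), and one-hot columns
for nominal/binary variables — on one-hot blocks, cosine similarity
reduces to shared-level counting, the natural homophily notion.
Constant columns are dropped with a warning.

The cosine similarity S_ij = ⟨X_i, X_j⟩ / (‖X_i‖‖X_j‖) is computed for
all pairs (nonnegative vectors ⇒ S_ij ∈ [0, 1]; the diagonal is set to
exactly 1 and the matrix symmetrized against rounding).  The graph links
i and j iff S_ij ≥ t, ties at t included.  The full N×N matrix is
materialized — at the reference scale (N≈5,800) that is ~34M doubles,
fine on a desktop; no sparse/ANN path is provided.

The published threshold t = 0.7799 (the package default) was chosen in
the source to match an average degree estimated by the company's HR
director; neither that degree nor the procedure was published, so the
inferred network there is not recoverable.  `calibrate_threshold`
implements the intent deterministically: given a target average degree d,
it returns the ⌈Nd/2⌉-th largest dyad similarity, i.e. the empirical
quantile at rank 1 − d/(N−1), which attains the target within one edge
quantum (2/N) up to ties.

Which variables feed the encoder is configurable (`all` vs
`significant`, default `significant`) because the source describes both:
its methods text says all four categories' variables enter, its summary
says the significant ones do.

## ERGM

P(Y=y|X) ∝ exp(Σ_a θ_a g_a(y, X)) over simple undirected graphs, with
terms: `edges` (edge count), `nodefactor(attr, base)` (edge endpoints off
the base level — base `low`, so the coefficient is the degree effect of
high burnout), `nodematch(attr)` (same-status edges, uniform homophily).
The network is undirected with D = N(N−1)/2 unordered dyads.

All three terms are dyad-independent: the change statistic of a dyad is
(1, 𝟙[i high]+𝟙[j high], 𝟙[status_i = status_j]).  The likelihood is
then a product of Bernoulli dyads and:

* **Exact fit** (`fit_exact`, the default): Newton–Raphson with step
  halving on the dyad-pattern-collapsed logistic likelihood (for a binary
  attribute, three patterns: low–low, low–high, high–high).  This equals
  a brute-force logistic fit over all D dyads (tested against statsmodels
  GLM) and, for the saturated three-pattern model, the closed form
  obtained from the three within/between-group densities.  Standard
  errors are from the inverse observed Fisher information; p-values are
  two-sided normal (Wald).  Separation — a pattern with all or none of
  its dyads tied — is reported as `converged=False` with a diagnostic
  naming the pattern, never silently.
* **Sampler** (`mh_sampler`): tie-flip Metropolis — propose toggling a
  uniformly random dyad, accept with min(1, exp(θ·δ)).  Two exchangeable
  implementations: a literal sequential loop, and a blocked variant that
  draws each dyad's proposal count for a block of T toggles from the
  exact Multinomial(T, 1/D) law and advances each dyad's independent
  two-state chain in closed form (end-state probability
  π + (start − π)λ^k with λ = 1 − p01 − p10, π = p01/(p01+p10)).  For
  dyad-independent specs the two are identical in distribution; the
  blocked path is O(D) vectorized and is the default.  Agreement is
  tested against analytic stationary expectations and between samplers.
* **MCMC-MLE** (`fit_mcmcmle`): Geyer–Thompson iteration initialized at
  the exact fit (where maximum pseudolikelihood coincides with the MLE).
  Each step samples statistic vectors at θ_k and maximizes the
  importance-sampled log-likelihood-ratio surrogate; steps larger than 1
  in sup-norm are damped; iteration stops when the update falls below
  `tol` (1e-4) or at `max_iter` (20).  Defaults: burn-in 10·D toggles,
  interval D, 1,000 samples — the source names MCMC-MLE but gives no
  controls, so these follow common ERGM practice.  Standard errors use
  the sampled-statistic covariance at the final θ (the Fisher identity
  I(θ) = Cov_θ(g)).  Degeneracy — sampled statistics failing to bracket
  the observation, or importance weights collapsing below an effective
  sample size of 30 — raises an error rather than returning a fit.
  For this package's term set MCMC-MLE is a consistency check and a hook
  for future dyad-dependent terms; `fit_exact` is the production path.
* **Model comparison**: the edges-only "zero" model against the
  node-attribute model, by AIC = 2k − 2ℓ and BIC = k·ln(D) − 2ℓ with the
  dyad count as BIC's sample size.  That convention gives the structural
  identity BIC − AIC = k(ln D − 2), which at the reference scale
  (N = 5,794, k = 3) equals 43.9 — consistent with the published
  AIC/BIC gap of 44, which is how the dyad-count convention was pinned
  down.  Selection reports both criteria, selects by BIC, and flags
  disagreement and exact ties.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → table-one report + screen →
encode + similarity + threshold → zero and node-attribute ERGM fits →
comparison, writing every artifact plus a provenance JSON (config, config
hash, per-stage seeds, key counts) sufficient to re-execute the run.  All
randomness flows from one root seed split per stage by a CRC-keyed hash,
so stages are independently reproducible; a rerun with the same config is
byte-identical for the exact method.  A stage failure aborts with the
stage named; earlier artifacts are retained.

## Numerical choices and degenerate inputs

* Logistic and log(1+e^x) evaluations are overflow-guarded.
* Cosine values are clipped to [0, 1] and the diagonal forced to 1 before
  thresholding; a zero-norm feature vector is an error naming the
  respondent (it has no direction), as is an all-constant feature table.
* Thresholding uses ≥, so ties at t are all included; calibration under
  heavy ties can overshoot the target degree (the ≥-rule consequence).
* Unobserved levels in a sparse draw are dropped from a contingency table
  before testing rather than raising on a zero margin; a variable
  constant in the table is an error.
* Scoring uses strict exceedance; items must be integers in 0…6.

## Known limitations

* The inferred network is an attribute-similarity construct, not an
  observed social network; homophily estimated on it partially reflects
  the construction itself.  The package reproduces the method, and the
  end-to-end tests show the chain transports a generated group contrast
  into a positive nodematch coefficient — they cannot validate the
  sociological claim.
* Only dyad-independent ERGM terms are implemented; no triangles/GWESP,
  no directed networks, no missing data, no imputation.
* The generator draws variables independently given the burnout label;
  real surveys have richer dependence (e.g. age × grade).
* `nodefactor` counts endpoints off a single base level, which is the
  binary-attribute form; multi-level attributes would need one term per
  non-base level.
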