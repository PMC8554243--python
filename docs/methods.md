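# Methods

## Model

The belief state tracked during incremental comprehension is the Bernoulli
probability of object-initial (OS) versus subject-initial (SO) order in a
transitive clause, which under the transitivity assumption is equivalent to
the argument-role assignment (which NP is the actor).  Four logistic
mixed-effects models estimate this probability at four prefixes of the
clause: onset (no cues; intercept plus genre effects only), NP1, NP1+verb,
and NP1+verb+NP2.  Each model contains the cue main effects available at
its prefix plus a fixed interaction set; NP1 length appears in the NP1 and
NP1+verb models, NP2 length only in the final model.  Genre enters as a
random intercept; no genre slopes are used.

The processing signal at constituent *i* is the Bayesian surprise

D_KL(posterior ‖ prior) = p·log2(p/q) + (1−p)·log2((1−p)/(1−q)),

with p the belief after the constituent and q before it, in bits.
Probabilities are clipped at ε = 1e−6 (configurable) before the KL so that
fully disambiguating cues (case-marked pronouns) give large finite rather
than infinite surprise.  The headline surprise value is the KL of the
posterior-mean probabilities, which matches how single predicted values are
conventionally quoted; the per-draw mean and an 89% HPDI over index-paired
draws of the stage models are reported alongside.  Index pairing is the
default uncertainty propagation because the four models are fit
independently, so no joint posterior couples their draws; a bootstrap over
draws gives indistinguishable intervals and the pairing keeps results
seed-reproducible.

### Priors and coding

Corpus models: intercept Normal(−2.994, 2.5) — the log-odds of the baseline
OS rate of 0.05 — fixed effects Student-t(30, 0, 5), random-intercept sd
half-Cauchy(0, 2).  Binary cues are sum-coded ±0.5 (so the intercept stays
interpretable as the baseline log-odds at an average cue profile), case is
entered as two dummies against "unmarked", lengths are z-scored on the
training corpus (the standardization constants are stored with the fit and
re-used at prediction time).  In the final model, interactions carried over
from the NP1+verb model use the NP1 cue and newly introduced ones the NP2
cue; this assignment is configurable because the term list alone does not
fix it.

Reading-time models: fixed effects Student-t(3, 0, 2.5), random-effect sds
half-Cauchy(0, 2), random-effect correlations LKJ(1) (uniform).  The
residual-sd prior is not part of the inherited specification; we use a
half-Student-t(3, 0, 2.5·sd(y)), the convention of mainstream Bayesian
regression front ends.

### Sampling

All models are sampled with the package's No-U-Turn sampler (dual-averaging
step-size adaptation targeting 0.8 acceptance, diagonal mass matrix
estimated during warmup, max tree depth 10).  Gradients are analytic,
including the backward pass through the Cholesky-of-correlation transform:
random effects are non-centered (b_g = diag(τ)·L·z_g), the correlation
Cholesky factor is parameterized by tanh of canonical partial correlations,
and the LKJ density plus all transform Jacobians reduce to independent
per-coordinate terms with coefficient 1 + (K−1−k)/2 on log(1−z²) for
column k.  The sampler is validated against exact conjugate posteriors,
empirical log-odds, and statsmodels MixedLM fits.  Chain seeds spawn from a
single `SeedSequence`, so every fit is reproducible from one integer seed.

Default chain settings are 4 × (1000 warmup + 1000 draws) for corpus models
and 4 × (500 + 500) for reading-time models; tests and the acceptance
script use 1–2 chains with 150–400 draws, which is sufficient for the
posterior means, HPDIs and coverage rates they assert.  A penalized-MAP /
Laplace path exists for quick checks and is labelled as an approximation.

Convergence is flagged per parameter at split-chain R-hat > 1.01 (warning,
not error, matching exploratory practice); divergent transitions after
warmup are counted and logged.

## Reading-time pipeline

Fixed exclusion order: (1) word RTs < 100 ms or > 4000 ms (strict
inequalities; boundary values retained); (2) all words of trials with an
incorrect comprehension answer; (3) length correction: raw RT regressed on
word length with by-participant random intercepts and slopes (statsmodels
MixedLM; participants under a configurable minimum of observations fall
back to the population line); (4) corrected RTs beyond 3 SD of the
participant's mean are dropped.  The SD rule pools across regions within
participant by default (the alternative, per-region grouping, is a config
switch — the inherited procedure does not specify it).  Analysis regions:
NP1 and verb are single words; NP2 averages the post-verbal NP word with
the first adverbial word (spill-over); if one member was excluded the other
stands alone, and if the first adverbial word itself was excluded the next
surviving one substitutes (both keep-power decisions, logged).

A known property of the symmetric 3-SD trim is that it clips residuals
around the participant's overall mean rather than the condition mean, which
attenuates genuine condition effects by a factor of about 1 − 6·φ(3) ≈
0.973; recovery checks therefore target a slightly smaller estimand than
the planted slope, which their tolerances absorb.

The surprise model uses standardized D_KL as its only fixed effect with
by-participant intercepts.  Standardization is within-region by default
(each region is analyzed by its own model); a global scope across the three
regions is available as a config switch, and matters for interpreting
slopes because per-region surprise scales differ by orders of magnitude.
The linguistic model sum-codes order (SVO = +0.5), object animacy
(animate = +0.5) and verb class (experiencer = +0.5), with the full
factorial in the verb/NP2 regions and the maximal by-participant random
structure; simple effects come from a nested-contrast re-parameterization
of the same model (identical random effects and column space), not from
subset fits.  Coefficients are summarized by the kernel-density mode (MAP),
posterior SD (SE), 89% HPDI, and the posterior mass on the MAP's side of
zero.

Model comparison refits both models with the union of their random-effect
structures, computes PSIS-LOO elpd (arviz), LOOIC = −2·elpd, and the LOOIC
difference with SE from the pointwise elpd differences
(2·sqrt(n·var(d_i))); models are called distinguishable only when the
difference exceeds 2.5 SE.  Pareto-shape values above 0.7 are flagged and
reported, not silently refit.

## Synthetic-data generators

The corpus generator samples cue profiles from configurable marginals
(defaults follow the typological asymmetry: first arguments mostly
animate/definite/given/pronominal, second arguments the reverse), enforces
the structural rule that only pronouns carry case, samples lengths as
1 + Poisson for lexical NPs, and assigns OS/SO from a logistic model with
known coefficients on the same design coding the fitter uses, plus by-genre
intercept deviations (default SD 0.3 over five genres).  The intercept is
calibrated by root-finding so the *marginal* OS rate equals the configured
baseline (default 0.05) — plain centering would undershoot because of the
spread of cue effects.  The default coefficient set encodes the qualitative
structure the models assume (case dummies dominant, prominence cues
moderate, deixis strongly OS-favoring); it is configuration, not an
estimate of any treebank.

The SPR generator lays out one-word NPs, a verb, a 3–6-word adverbial and a
final word; word RT = 350 ms + 12 ms/char + participant intercept
(SD 40 ms) + (2.0 + participant slope, SD 0.5) ms per within-region SD of
design surprise on the words of the three analysis regions + Gaussian noise
(SD 15 ms; a log-normal option exists since real RTs are right-skewed).
Five percent of trials are answered incorrectly and 0.3% of word RTs are
replaced by out-of-range values, matching the exclusion rates the pipeline
is specified to report.  The noise defaults were fixed by a design power
analysis before any testing: recovering a 2.0 ms/SD linking slope to within
±0.5 at 45 participants × 64 trials requires a slope-estimator SD ≲ 0.39,
i.e. residual SD ≲ 19 ms given the participant-slope variance — which is
also the order of magnitude of effective residual implied by the precision
real region-averaged, length-corrected RT analyses of this design achieve.
What passing recovery tests therefore show is that the pipeline is
unbiased and calibrated *under its own linking assumptions at a realistic
precision*; they do not show that real button-press data are this clean,
that RT noise is Gaussian, or that real items are exchangeable within
condition (the generator gives all items in a condition the same cue
profile).

Condition rotation assigns each participant two of the eight conditions per
item, offset by participant, approximating the Latin-square balance of the
real design without modeling lists or blocks (out of scope).

## Numerical choices and limitations

- KL clipping ε = 1e−6; values are clamped at 0 to absorb rounding residue.
- HPDIs use the shortest sorted-window estimator; the MAP is the argmax of
  a Gaussian KDE on a 512-point grid, so MAP can fall marginally outside a
  short HPDI at small draw counts (tests allow that tolerance).
- Grid enumeration is capped at 1e6 rows in memory; larger grids (up to the
  full 2^36 cue space) stream to disk in chunks with identical row content.
  Combinations violating clause invariants are skipped and logged.
- Degenerate designs (constant cue columns) are rejected with a
  rank-deficiency error naming the aliased columns before sampling.
- The stage models assume every clause is transitive with exactly two overt
  NP arguments; nothing here applies to intransitives, discourse-dependent
  baselines, or languages where the order prior varies by context.
- p_posterior is reported as max(P(β>0), P(β<0)) and so is bounded below by
  0.5 by construction.
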