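# bayesurp

Expectation-based modeling of incremental argument interpretation in
transitive clauses — who did what to whom — with Bayesian surprise as the
linking quantity to reading times.

## The problem

While reading a Swedish transitive clause, a comprehender must decide which
noun phrase is the subject (actor) and which the object (undergoer).
Object-initial (OS) order is rare (about 5% of written clauses) but licit,
and many cues bear on the decision: morphosyntax (case on pronouns),
prominence properties of the NPs (animacy, givenness, definiteness, person,
pronominality, number, text deixis), verb semantics (volitional,
experiencer, causative, possessive, auxiliary), and clause structure.  On an
expectation-based account, these cues act only through the conditional
probability of the competing analyses.  This package implements that
account end to end:

1. **Staged word-order models** (`stage_models`): four Bayesian logistic
   mixed models estimate `p(OS | cues seen so far)` at the clause onset
   (intercept only), after NP1, after NP1 + verb, and after NP1 + verb +
   NP2, from a cue-annotated corpus with by-genre random intercepts and
   regularizing priors — intercept `Normal(-2.994, 2.5)` (the log-odds of
   the baseline OS rate), fixed effects `Student-t(30, 0, 5)`, random-effect
   sd `HalfCauchy(2)`.
2. **Bayesian surprise** (`surprise_engine`): the processing signal at
   constituent `C_i` is the belief shift

   `D_KL( p(OS | C_1..C_i) || p(OS | C_1..C_{i-1}) )`

   in bits, for the Bernoulli belief over OS/SO.  Posterior uncertainty is
   propagated by computing the KL per posterior draw (89% HPDIs).
3. **Prediction grids** (`prediction_grid`): predictions for arbitrary —
   including unattested — cue combinations without refitting, and for the
   2 × 2 × 2 experimental design (constituent order × object animacy ×
   verb class).
4. **Reading-time analysis** (`spr_pipeline`): self-paced-reading
   preprocessing (strict 100–4000 ms range exclusions, incorrect-trial
   removal, mixed-model word-length correction, per-participant 3-SD rule,
   region averaging) and Bayesian linear mixed models: a *surprise* model
   (standardized `D_KL` as the only fixed effect) and a *linguistic* model
   (sum-coded design factors, maximal by-participant random structure,
   LKJ(1) prior on random-effect correlations).
5. **Model comparison** (`model_comparison`): PSIS-LOO `elpd`,
   `LOOIC = -2 elpd`, and the `ΔLOOIC ± 2.5 SE` decision rule, with both
   models refit under the union of their random-effect structures.
6. **Synthetic data** (`synthetic_data`): generators for cue-annotated
   corpora (logistic order assignment with known coefficients, calibrated
   baseline rate, genre structure) and SPR logs (linear surprise→RT link,
   word-length effect, participant random effects, error trials, RT
   outliers), so the whole pipeline is testable without any external data.

All hierarchical models are sampled with a built-in No-U-Turn sampler with
analytic gradients (`_mcmc`), validated against closed-form posteriors and
statsmodels mixed-model fits; HPDI/R-hat/ESS and PSIS-LOO use `arviz`.

## Worked example

```python
import bayesurp as bs

corpus = bs.generate_corpus(bs.CorpusGenConfig(n_clauses=4000, seed=0))
print(round(bs.summarize_corpus(corpus)["os_proportion"], 3))

fits = bs.fit_all_stages(
    corpus, sampler=bs.SamplerConfig(n_chains=2, n_warmup=300, n_samples=300))
design = bs.design_predictions(fits)
row = design.query(
    "order=='OVS' and object_animacy=='animate' "
    "and verb_class=='volitional' and region=='np2'").iloc[0]
print(round(row["dkl"], 2), round(row["p_os"], 2))
```

prints

```
0.053
2.93 0.78
```

— the corpus shows the ~5% baseline OS rate, and in an object-initial
sentence the disambiguating post-verbal subject pronoun raises the belief
in OS order to 0.78, a belief shift of 2.93 bits: exactly the kind of
late, order-driven surprise spike that predicts slow reading at NP2.
(Numbers vary slightly with seed and corpus size.)

The same trajectory for a single clause — here a subject-initial sentence
with a case-marked pronoun up front, so almost all belief movement happens
at NP1 and nothing later surprises:

```python
record = list(bs.fixture_item().records.values())[0]   # SVO condition
traj = bs.trajectory(record, fits)
print({r: round(traj.d_kl[r].mean, 3) for r in traj.regions})
```

```
{'np1': 0.066, 'verb': 0.0, 'np2': 0.001}
```

A command-line interface mirrors the pipeline stages
(`bayesurp simulate-corpus | fit | surprise | predict-grid | simulate-spr |
rt-preprocess | rt-analyze | compare | run`); `bayesurp run` executes the
full synthetic pipeline and writes a manifest with the configuration hash.

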