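"""Staged word-order models: term sets, coding, prediction, and the
regularization limit."""

import numpy as np
import pytest
from scipy.special import expit

import bayesurp as bs
from bayesurp.cue_schema import table_from_records
from bayesurp.stage_models import (RankDeficiencyError, SamplerConfig, StageSpec,
                                   build_stage_spec, encode_design, hdi_rows)


# ---------------------------------------------------------------------------
# term inventory

def test_clause_onset_is_intercept_only():
    spec = build_stage_spec("clause_onset")
    assert spec.fixed_terms == () and spec.interaction_terms == ()
    assert spec.group_term == "genre"


def test_np1_verb_stage_includes_animacy_by_volitional():
    spec = build_stage_spec("np1_verb")
    assert "np1_animacy:verb_volitional" in spec.interaction_terms
    assert "np1_length" in spec.fixed_terms


def test_full_stage_drops_animacy_volitional_keeps_pronominality_possessive():
    spec = build_stage_spec("np1_verb_np2")
    assert all("volitional" not in t for t in spec.interaction_terms)
    assert "np2_pronominality:verb_possessive" in spec.interaction_terms
    assert "np1_length" not in spec.fixed_terms
    assert "np2_length" in spec.fixed_terms


def test_stage_term_sets_are_nested_as_printed():
    np1 = set(build_stage_spec("np1").all_terms)
    np1v = set(build_stage_spec("np1_verb").all_terms)
    full = set(build_stage_spec("np1_verb_np2").all_terms)
    assert np1 <= np1v | {"np1_length"}
    assert np1v <= full | {"np1_length", "np1_animacy:verb_volitional"}


def test_clause_cues_present_at_every_non_onset_stage():
    for stage in ("np1", "np1_verb", "np1_verb_np2"):
        terms = build_stage_spec(stage).fixed_terms
        assert "clause_embedded" in terms and "clause_verb_initial" in terms


def test_interaction_np_assignment_is_configurable():
    spec = build_stage_spec("np1_verb_np2",
                            interaction_np={"givenness:possessive": "np1"})
    assert "np1_givenness:verb_possessive" in spec.interaction_terms


def test_unknown_stage_rejected():
    with pytest.raises(ValueError, match="unknown stage"):
        build_stage_spec("np3")


# ---------------------------------------------------------------------------
# coding

def test_encode_design_sum_codes_and_case_dummies(small_corpus):
    spec = build_stage_spec("np1")
    X, cols, stats = encode_design(small_corpus.frame, spec)
    assert cols[0] == "intercept" and np.all(X[:, 0] == 1.0)
    anim = X[:, cols.index("np1_animacy")]
    assert set(np.unique(anim)) <= {0.5, -0.5}
    subj = X[:, cols.index("np1_case=subject")]
    assert set(np.unique(subj)) <= {0.0, 1.0}
    length = X[:, cols.index("np1_length_z")]
    assert abs(length.mean()) < 1e-9 and abs(length.std() - 1.0) < 1e-9


def test_constant_cue_column_raises_rank_error(small_corpus):
    frame = small_corpus.frame.copy()
    frame["np1_deixis"] = "other"  # constant +-0.5 aliases the intercept
    corpus = bs.CorpusTable(frame=frame, inventory=small_corpus.inventory)
    with pytest.raises(RankDeficiencyError):
        bs.fit_stage(corpus, build_stage_spec("np1"),
                     sampler=SamplerConfig(n_chains=1, n_warmup=10, n_samples=10))


# ---------------------------------------------------------------------------
# prediction

def _constant_fit(value: float, stage="clause_onset") -> bs.PosteriorFit:
    spec = build_stage_spec(stage)
    draws = np.full((2, 50, 3), 0.0)
    draws[:, :, 0] = value
    draws[:, :, 2] = np.log(0.3)
    return bs.PosteriorFit(
        spec=spec, priors=bs.PriorConfig(), draws=draws,
        param_names=["intercept", "genre_z[g0]", "log_tau[0]"],
        design_info={"columns": ["intercept"], "length_stats": {},
                     "genre_levels": ["g0"]},
        diagnostics={})


def test_intercept_only_prediction_is_inverse_logit():
    record = list(bs.fixture_item().records.values())[0]
    fit = _constant_fit(-2.994)
    res = fit.predict_p_os(record)
    assert res.mean == pytest.approx(1.0 / (1.0 + np.exp(2.994)), abs=1e-6)
    assert res.mean == pytest.approx(0.0477, abs=5e-4)
    assert _constant_fit(0.0).predict_p_os(record).mean == pytest.approx(0.5)


def test_prediction_monotone_in_coefficient_draws(stage_fits):
    fit = stage_fits["np1"]
    record = list(bs.fixture_item().records.values())[0]
    base = fit.predict_p_os(record).mean
    bumped = bs.PosteriorFit(
        spec=fit.spec, priors=fit.priors, draws=fit.draws.copy(),
        param_names=fit.param_names, design_info=fit.design_info,
        diagnostics=fit.diagnostics, inventory=fit.inventory)
    j = fit.columns.index("np1_animacy")
    # record has an animate NP1 (+0.5 code): raising the coefficient raises p
    bumped.draws[:, :, j] += 1.0
    assert bumped.predict_p_os(record).mean > base


def test_missing_cue_raises_named_error(stage_fits):
    record = list(bs.fixture_item().records.values())[0]
    partial = bs.ClauseRecord(clause_id="x", np1=record.np1, verb=record.verb,
                              np2=None, clause=record.clause)
    with pytest.raises(ValueError, match="np2_"):
        stage_fits["np1_verb_np2"].predict_p_os(partial)


def test_prior_dominance_collapses_to_intercept_model(small_corpus, fast_sampler):
    priors = bs.PriorConfig(fixed_scale=1e-3)
    fit = bs.fit_stage(small_corpus, build_stage_spec("np1"), priors, fast_sampler)
    coefs = fit.coefficient_draws().mean()
    assert np.abs(coefs.drop("intercept")).max() < 0.01
    onset = bs.fit_stage(small_corpus, build_stage_spec("clause_onset"),
                         bs.PriorConfig(), fast_sampler)
    record = list(bs.fixture_item().records.values())[0]
    assert fit.predict_p_os(record).mean == pytest.approx(
        onset.predict_p_os(record).mean, abs=0.02)


def test_fit_determinism(small_corpus):
    sampler = SamplerConfig(n_chains=1, n_warmup=60, n_samples=60, seed=13)
    spec = build_stage_spec("clause_onset")
    f1 = bs.fit_stage(small_corpus, spec, sampler=sampler)
    f2 = bs.fit_stage(small_corpus, spec, sampler=sampler)
    assert np.array_equal(f1.draws, f2.draws)


def test_fit_serialization_round_trip(tmp_path, stage_fits):
    fit = stage_fits["np1"]
    fit.save(tmp_path)
    back = bs.PosteriorFit.load(tmp_path, "np1")
    assert np.allclose(back.draws, fit.draws)
    assert back.columns == fit.columns
    record = list(bs.fixture_item().records.values())[0]
    assert back.predict_p_os(record).mean == pytest.approx(
        fit.predict_p_os(record).mean, abs=1e-9)


def test_calibration_of_predicted_probabilities(stage_fits, small_corpus):
    """Records binned by predicted p(OS) should have matching empirical
    OS rates (model-family data, so the fit should be calibrated)."""
    fit = stage_fits["np1_verb_np2"]
    res = fit.predict_p_os_frame(small_corpus.frame)
    y = (small_corpus.frame["order"] == "OS").to_numpy()
    pred = np.asarray(res.mean)
    for lo, hi in [(0.0, 0.05), (0.05, 0.5), (0.5, 1.0)]:
        mask = (pred >= lo) & (pred < hi)
        if mask.sum() < 20:
            continue
        se = np.sqrt(pred[mask].mean() * (1 - pred[mask].mean()) / mask.sum())
        assert abs(y[mask].mean() - pred[mask].mean()) < max(4 * se, 0.04)


def test_hdi_rows_matches_definition():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, (3, 4000))
    h = hdi_rows(x, 0.89)
    # for a normal sample the 89% HDI is close to +-1.6 sd
    assert np.all(h[:, 0] < -1.3) and np.all(h[:, 1] > 1.3)
    covered = ((x >= h[:, :1]) & (x <= h[:, 1:])).mean(axis=1)
    assert np.all(np.abs(covered - 0.89) < 0.01)
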