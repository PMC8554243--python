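"""Reading-time pipeline: exclusions, length correction, regions, models."""

import numpy as np
import pandas as pd
import pytest

import bayesurp as bs
from bayesurp.spr_pipeline import (EffectSummary, RTSamplerConfig,
                                   linguistic_design, region_average,
                                   summarize_effect)


def _word_frame(rows):
    return pd.DataFrame(rows, columns=["participant", "item", "order",
                                       "object_animacy", "verb_class", "region",
                                       "word_index", "raw_rt", "word_length",
                                       "question_correct"])


def _make_trials(n_trials=125, words_per_trial=8, rt=300.0, correct=True,
                 participant=0, start_item=0):
    rows = []
    regions = ["np1", "verb", "np2"] + ["adverbial"] * (words_per_trial - 4) + ["final"]
    for t in range(n_trials):
        for w, region in enumerate(regions, start=1):
            rows.append((participant, start_item + t, "SVO", "animate",
                         "volitional", region, w, rt, 5, correct))
    return rows


def test_exclusion_fixture_counts_planted_words_exactly():
    rows = _make_trials(120)                      # 960 in-range correct words
    rows += _make_trials(5, correct=False, start_item=200)  # 40 incorrect words
    frame = _word_frame(rows)
    out_of_range = [30, 99, 150, 260, 333, 401, 470, 555, 610, 700, 808, 901]
    for i, idx in enumerate(out_of_range):
        frame.loc[idx, "raw_rt"] = 50.0 if i % 2 else 4500.0
    assert len(frame) == 1000
    kept, report = bs.exclude_trials(frame)
    assert report["n_range_excluded"] == 12
    assert report["n_incorrect_excluded"] == 40
    assert report["n_retained"] == 1000 - 12 - 40 == len(kept)


def test_range_boundaries_are_strict():
    frame = _word_frame(_make_trials(2))
    frame.loc[0, "raw_rt"] = 100.0    # retained
    frame.loc[1, "raw_rt"] = 4000.0   # retained
    frame.loc[2, "raw_rt"] = 99.999   # excluded
    frame.loc[3, "raw_rt"] = 4000.01  # excluded
    _, report = bs.exclude_trials(frame)
    assert report["n_range_excluded"] == 2


def test_fully_clean_trial_retained():
    frame = _word_frame(_make_trials(3))
    kept, report = bs.exclude_trials(frame)
    assert len(kept) == len(frame)
    assert report["n_range_excluded"] == report["n_incorrect_excluded"] == 0


def test_length_correction_perfect_linear_fit_gives_zero_residuals():
    rows = []
    rng = np.random.default_rng(0)
    for t in range(30):
        for w, region in enumerate(["np1", "verb", "np2", "adverbial", "final"], 1):
            length = int(rng.integers(2, 9))
            rows.append((0, t, "SVO", "animate", "volitional", region, w,
                         300.0 + 20.0 * length, length, True))
    corrected, _ = bs.length_correct(_word_frame(rows))
    assert np.abs(corrected["corrected_rt"]).max() < 1e-8


def test_three_sd_rule_catches_planted_outlier():
    rng = np.random.default_rng(1)
    rows = []
    for p in range(4):
        for t in range(40):
            for w, region in enumerate(["np1", "verb", "np2", "adverbial", "final"], 1):
                length = int(rng.integers(2, 9))
                rt = 250 + 15 * length + rng.normal(0, 20)
                rows.append((p, t, "SVO", "animate", "volitional", region, w,
                             rt, length, True))
    frame = _word_frame(rows)
    clean, _ = bs.length_correct(frame)
    spread = clean["corrected_rt"].std()
    planted = frame.loc[57, "raw_rt"] + 10 * spread  # 10-SD outlier
    frame.loc[57, "raw_rt"] = planted
    corrected, report = bs.length_correct(frame)
    assert report["n_sd_excluded"] >= 1
    assert planted not in corrected["raw_rt"].to_numpy()


def test_residuals_uncorrelated_with_word_length(small_spr):
    kept, _ = bs.exclude_trials(small_spr)
    corrected, _ = bs.length_correct(kept)
    slope = np.polyfit(corrected["word_length"], corrected["corrected_rt"], 1)[0]
    assert abs(slope) < 1.0  # ms/char residual slope ~ 0 (true slope is 12)


def test_region_average_rules():
    rows = _make_trials(1)
    frame = _word_frame(rows)
    frame["corrected_rt"] = [10.0, 20.0, 50.0, 30.0, 7.0, 9.0, 11.0, 4.0]
    regions = region_average(frame)
    r = regions.set_index("region")["rt"]
    assert r["np1"] == 10.0 and r["verb"] == 20.0
    assert r["np2"] == pytest.approx(40.0)    # mean of NP2 word and 1st adverbial
    assert r["adverbial"] == pytest.approx(8.0)  # next two adverbial words
    assert r["final"] == 4.0
    # NP2 word excluded -> remaining member stands alone
    dropped = frame.drop(index=2)
    r2 = region_average(dropped).set_index("region")["rt"]
    assert r2["np2"] == pytest.approx(30.0)


def test_region_average_commutes_with_participant_subsetting(small_spr):
    corrected, _ = bs.preprocess(small_spr)
    full = region_average(corrected)
    part0 = region_average(corrected[corrected["participant"] == 0])
    merged = part0.merge(full[full["participant"] == 0],
                         on=["participant", "item", "order", "object_animacy",
                             "verb_class", "region"], suffixes=("_a", "_b"))
    assert len(merged) == len(part0)
    assert np.allclose(merged["rt_a"], merged["rt_b"])


def test_linguistic_design_coding_and_simple_effect_span(small_region_table):
    frame = small_region_table[small_region_table["region"] == "verb"]
    X, cols = linguistic_design(frame, "verb")
    assert cols == ["intercept", "animacy", "order", "verb", "animacy:order",
                    "animacy:verb", "order:verb", "animacy:order:verb"]
    svo = frame["order"].to_numpy() == "SVO"
    assert np.all(X[svo, cols.index("order")] == 0.5)          # SVO coded +0.5
    exp = frame["verb_class"].to_numpy() == "experiencer"
    assert np.all(X[exp, cols.index("verb")] == 0.5)
    Xn, cols_n = linguistic_design(frame, "verb", nest_within="order")
    assert Xn.shape == X.shape
    # same column space: projecting the main design onto the nested one
    # reproduces it exactly
    proj = Xn @ np.linalg.lstsq(Xn, X, rcond=None)[0]
    assert np.allclose(proj, X, atol=1e-8)
    # NP1 design has no verb-class terms
    X1, cols1 = linguistic_design(frame, "np1")
    assert cols1 == ["intercept", "animacy", "order", "animacy:order"]


def test_effect_summary_invariants():
    rng = np.random.default_rng(2)
    draws = rng.normal(1.3, 0.4, 4000)
    s = summarize_effect("x", draws)
    assert s.hpdi89[0] - 0.05 <= s.beta_map <= s.hpdi89[1] + 0.05
    assert 0.5 <= s.p_posterior <= 1.0
    assert s.se == pytest.approx(0.4, abs=0.05)


def test_surprise_lmm_prior_dominance(small_region_table, design_surprise):
    priors = bs.RTPriorConfig(fixed_scale=1e-4)
    fit = bs.fit_surprise_lmm(small_region_table, design_surprise, "verb",
                              priors=priors,
                              sampler=RTSamplerConfig(n_chains=1, n_warmup=120,
                                                      n_samples=120, seed=3))
    slope = next(s for s in fit.summaries() if s.term == "surprise")
    assert abs(slope.beta_map) < 0.01


def test_linguistic_lmm_detects_planted_order_effect():
    """A pure order main effect should surface in the order term only."""
    rng = np.random.default_rng(4)
    rows = []
    for p in range(12):
        for i in range(16):
            order = "SVO" if (i + p) % 2 else "OVS"
            animacy = "animate" if i % 2 else "inanimate"
            verb = "volitional" if (i // 2) % 2 else "experiencer"
            rt = (6.0 if order == "SVO" else -6.0) + rng.normal(0, 4)
            rows.append((p, i, order, animacy, verb, "np1", rt))
    table = pd.DataFrame(rows, columns=["participant", "item", "order",
                                        "object_animacy", "verb_class",
                                        "region", "rt"])
    fit = bs.fit_linguistic_lmm(table, "np1",
                                sampler=RTSamplerConfig(n_chains=2, n_warmup=200,
                                                        n_samples=200, seed=5))
    summaries = {s.term: s for s in fit.summaries()}
    assert summaries["order"].beta_map > 0          # slower SVO -> positive
    assert summaries["order"].p_posterior > 0.95
    assert summaries["animacy"].p_posterior < 0.95
    assert summaries["animacy:order"].p_posterior < 0.95
    # simple-effects re-parameterization spans the same model
    nested = bs.fit_linguistic_lmm(table, "np1", nest_within="order",
                                   sampler=RTSamplerConfig(n_chains=1,
                                                           n_warmup=150,
                                                           n_samples=150, seed=6))
    terms = {s.term for s in nested.summaries()}
    assert {"order", "animacy@order=SVO", "animacy@order=OVS"} <= terms
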