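"""Generators: calibration, dependency rules, determinism, SPR structure."""

import numpy as np
import pandas as pd
import pytest

import bayesurp as bs
from bayesurp.cue_schema import validate_table
from bayesurp.spr_pipeline import validate_spr_table
from bayesurp.synthetic_data import SPR_COLUMNS, standardize_design_surprise


def test_null_model_marginal_os_rate_matches_binomial_oracle():
    cfg = bs.CorpusGenConfig(n_clauses=100_000, seed=1, true_coefficients={},
                             genre_sd=0.0)
    table = bs.generate_corpus(cfg)
    frac = (table.frame["order"] == "OS").mean()
    se = np.sqrt(0.05 * 0.95 / 100_000)
    assert abs(frac - 0.05) < 4 * se


def test_calibrated_marginal_with_nonzero_coefficients():
    table = bs.generate_corpus(bs.CorpusGenConfig(n_clauses=30_000, seed=2))
    frac = (table.frame["order"] == "OS").mean()
    assert abs(frac - 0.05) < 0.01


def test_negative_animacy_coefficient_lowers_os_among_animate():
    cfg = bs.CorpusGenConfig(n_clauses=20_000, seed=3,
                             true_coefficients={"np1_animacy": -2.0})
    frame = bs.generate_corpus(cfg).frame
    os_rate = frame.groupby("np1_animacy")["order"].apply(lambda s: (s == "OS").mean())
    assert os_rate["animate"] < os_rate["inanimate"]


def test_generation_is_seed_deterministic(tmp_path):
    cfg = bs.CorpusGenConfig(n_clauses=500, seed=9)
    a = bs.generate_corpus(cfg)
    b = bs.generate_corpus(bs.CorpusGenConfig(n_clauses=500, seed=9))
    pd.testing.assert_frame_equal(a.frame, b.frame)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    bs.write_corpus(a, pa)
    bs.write_corpus(b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_generated_corpus_passes_validation():
    table = bs.generate_corpus(bs.CorpusGenConfig(n_clauses=300, seed=4))
    assert validate_table(table) == []
    # dependency rule: case only on pronouns
    lexical = table.frame["np1_pronominality"] == "lexical"
    assert (table.frame.loc[lexical, "np1_case"] == "unmarked").all()


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="marginal"):
        bs.generate_corpus(bs.CorpusGenConfig(
            cue_marginals={"np1_animacy": {"animate": 0.7, "inanimate": 0.7}}))
    with pytest.raises(ValueError, match="unknown design columns"):
        bs.generate_corpus(bs.CorpusGenConfig(
            n_clauses=50, true_coefficients={"np9_animacy": 1.0}))


def test_fixture_item_profiles():
    item = bs.fixture_item()
    assert len(item.records) == 8
    ovs = item.records[("OVS", "animate", "volitional")]
    assert ovs.np1["pronominality"] == "lexical" and ovs.np1["case"] == "unmarked"
    assert ovs.np2["pronominality"] == "pronominal" and ovs.np2["case"] == "subject"
    svo = item.records[("SVO", "inanimate", "experiencer")]
    assert svo.np1["pronominality"] == "pronominal" and svo.np1["case"] == "subject"
    assert svo.verb["experiencer"] == "yes" and svo.verb["volitional"] == "no"
    from bayesurp.cue_schema import table_from_records
    table = table_from_records(list(item.records.values()))  # validates
    assert len(table) == 8


def test_spr_table_structure_and_validation(design_surprise):
    trials = bs.generate_spr(bs.SPRGenConfig(n_participants=4, n_items=6, seed=5),
                             design_surprise)
    validate_spr_table(trials)
    assert list(trials.columns) == list(SPR_COLUMNS)
    per_part = trials.groupby("participant")[["item"]].nunique()
    assert (per_part["item"] == 6).all()
    # two instances of each participant x item (two conditions per list)
    counts = trials.groupby(["participant", "item"])["word_index"].apply(
        lambda s: (s == 1).sum())
    assert (counts == 2).all()


def test_clean_config_yields_no_exclusions_before_sd_step(design_surprise):
    trials = bs.generate_spr(
        bs.SPRGenConfig(n_participants=4, n_items=6, seed=6,
                        error_rate=0.0, outlier_rate=0.0), design_surprise)
    _, report = bs.exclude_trials(trials)
    assert report["n_range_excluded"] == 0
    assert report["n_incorrect_excluded"] == 0


def test_spr_determinism(design_surprise):
    cfg = bs.SPRGenConfig(n_participants=3, n_items=4, seed=7)
    a = bs.generate_spr(cfg, design_surprise)
    b = bs.generate_spr(bs.SPRGenConfig(n_participants=3, n_items=4, seed=7),
                        design_surprise)
    pd.testing.assert_frame_equal(a, b)


def test_standardize_design_surprise_unit_scale(design_surprise):
    std = standardize_design_surprise(design_surprise)
    for _, sub in std.groupby("region"):
        assert sub["z_dkl"].mean() == pytest.approx(0.0, abs=1e-9)
        assert sub["z_dkl"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
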