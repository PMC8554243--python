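"""Bernoulli KL divergence and belief trajectories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import rel_entr

import bayesurp as bs
from bayesurp.cue_schema import table_from_records
from bayesurp.surprise_engine import OUTPUT_COLUMNS, batch_trajectories, trajectory


def _oracle_kl(p, q):
    """Generic discrete KL over the explicit two-outcome vector, in bits."""
    return float(np.sum(rel_entr([p, 1 - p], [q, 1 - q]))) / np.log(2.0)


@pytest.mark.parametrize("p,q,expected,tol", [
    (0.5, 0.5, 0.0, 1e-12),
    (0.75, 0.25, 0.7925, 5e-4),
    (0.99, 0.02, 5.507, 5e-3),
])
def test_kl_reference_values(p, q, expected, tol):
    assert bs.bernoulli_kl(p, q) == pytest.approx(expected, abs=tol)


def test_kl_agrees_with_generic_discrete_oracle():
    grid = np.linspace(0.001, 0.999, 40)
    for p in grid:
        for q in grid:
            assert abs(bs.bernoulli_kl(p, q) - _oracle_kl(p, q)) <= 1e-12


@settings(derandomize=True, max_examples=200)
@given(p=st.floats(1e-5, 1 - 1e-5), q=st.floats(1e-5, 1 - 1e-5))
def test_kl_nonnegative_and_zero_iff_equal(p, q):
    kl = bs.bernoulli_kl(p, q)
    assert kl >= 0.0
    if abs(p - q) > 1e-9:
        assert kl > 0.0
    assert bs.bernoulli_kl(p, p) == 0.0


@settings(derandomize=True, max_examples=100)
@given(q=st.floats(0.1, 0.9), d=st.floats(0.001, 0.04))
def test_kl_strictly_monotone_away_from_prior(q, d):
    below = bs.bernoulli_kl(q - d, q)
    further_below = bs.bernoulli_kl(q - 2 * d, q)
    above = bs.bernoulli_kl(q + d, q)
    further_above = bs.bernoulli_kl(q + 2 * d, q)
    assert further_below > below > 0
    assert further_above > above > 0


@pytest.mark.parametrize("bad", [-0.1, 1.1, np.nan])
def test_kl_rejects_non_probabilities(bad):
    with pytest.raises(ValueError):
        bs.bernoulli_kl(bad, 0.5)
    with pytest.raises(ValueError):
        bs.bernoulli_kl(0.5, bad)


def test_kl_vectorized_matches_scalar():
    p = np.array([0.1, 0.6, 0.99])
    q = np.array([0.3, 0.6, 0.02])
    vec = bs.bernoulli_kl(p, q)
    assert np.allclose(vec, [bs.bernoulli_kl(a, b) for a, b in zip(p, q)])


# ---------------------------------------------------------------------------
# trajectories

def test_constant_beliefs_give_zero_surprise():
    from tests_helpers_constant import constant_fits
    fits = constant_fits(-2.0)
    record = list(bs.fixture_item().records.values())[0]
    traj = trajectory(record, fits)
    assert all(traj.d_kl[r].mean == 0.0 for r in traj.regions)


def test_partial_record_yields_truncated_trajectory(stage_fits):
    record = list(bs.fixture_item().records.values())[0]
    partial = bs.ClauseRecord(clause_id="p", np1=record.np1, verb=record.verb,
                              np2=None, clause=record.clause)
    traj = trajectory(partial, stage_fits)
    assert traj.regions == ["np1", "verb"]


def test_batch_empty_table(stage_fits):
    empty = table_from_records([])
    out = batch_trajectories(empty, stage_fits)
    assert list(out.columns) == OUTPUT_COLUMNS and len(out) == 0


def test_batch_properties_and_order_invariance(stage_fits, small_corpus):
    sub = bs.CorpusTable(frame=small_corpus.frame.head(40).copy(),
                         inventory=small_corpus.inventory)
    out = batch_trajectories(sub, stage_fits)
    assert len(out) == 40 * 3
    assert (out["dkl_mean"] >= 0).all() and (out["dkl_draw_mean"] >= 0).all()
    assert out["p_os_mean"].between(0, 1).all()
    # HPDI brackets the point value of p
    assert (out["p_os_lo"] <= out["p_os_mean"] + 1e-12).all()
    shuffled = bs.CorpusTable(
        frame=sub.frame.sample(frac=1.0, random_state=1).reset_index(drop=True),
        inventory=sub.inventory)
    out2 = batch_trajectories(shuffled, stage_fits)
    merged = out.merge(out2, on=["clause_id", "region"], suffixes=("", "_2"))
    assert len(merged) == len(out)
    assert np.allclose(merged["dkl_mean"], merged["dkl_mean_2"])


def test_per_draw_mean_kl_at_least_kl_of_means(stage_fits, small_corpus):
    """Jensen direction: KL is jointly convex, so averaging over draws can
    only increase the divergence relative to the KL of mean beliefs."""
    sub = bs.CorpusTable(frame=small_corpus.frame.head(30).copy(),
                         inventory=small_corpus.inventory)
    out = batch_trajectories(sub, stage_fits)
    assert (out["dkl_draw_mean"] >= out["dkl_mean"] - 1e-9).all()


def test_batch_collects_per_record_errors(stage_fits, small_corpus):
    frame = small_corpus.frame.head(10).copy().reset_index(drop=True)
    frame.loc[3, "np1_animacy"] = "unknown_level"
    table = bs.CorpusTable(frame=frame, inventory=small_corpus.inventory)
    out = batch_trajectories(table, stage_fits)
    assert set(out["clause_id"]) == set(frame["clause_id"]) - {frame.loc[3, "clause_id"]}
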