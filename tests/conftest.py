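"""Shared fixtures: a small synthetic corpus, fast sampler settings, and
session-scoped stage fits so expensive MCMC runs once."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import bayesurp as bs

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_corpus() -> bs.CorpusTable:
    return bs.generate_corpus(bs.CorpusGenConfig(n_clauses=500, seed=11))


@pytest.fixture()
def fast_sampler() -> bs.SamplerConfig:
    return bs.SamplerConfig(n_chains=2, n_warmup=150, n_samples=150, seed=2)


@pytest.fixture(scope="session")
def stage_fits(small_corpus) -> dict[str, bs.PosteriorFit]:
    sampler = bs.SamplerConfig(n_chains=2, n_warmup=150, n_samples=150, seed=5)
    return bs.fit_all_stages(small_corpus, sampler=sampler)


@pytest.fixture(scope="session")
def design_surprise(stage_fits) -> pd.DataFrame:
    return bs.design_predictions(stage_fits)


@pytest.fixture(scope="session")
def small_spr(design_surprise) -> pd.DataFrame:
    cfg = bs.SPRGenConfig(n_participants=10, n_items=8, seed=21)
    return bs.generate_spr(cfg, design_surprise)


@pytest.fixture(scope="session")
def small_region_table(small_spr) -> pd.DataFrame:
    corrected, _ = bs.preprocess(small_spr)
    return bs.region_average(corrected)
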