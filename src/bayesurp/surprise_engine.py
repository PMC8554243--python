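"""Bayesian surprise over argument-role beliefs, per sentence constituent.

The belief state is the probability of object-initial (OS) order.  When a
constituent is processed the belief moves from p(OS | previous constituents)
to p(OS | previous + current), and the processing cost signal is the
Kullback-Leibler divergence of the posterior Bernoulli distribution from the
prior one, in bits.  Trajectories evaluate the four staged models on one
clause and report p(OS) at each point and the KL at NP1, the verb and NP2.

The headline surprise value is the KL of the posterior-mean probabilities
(matching how single predicted values are usually reported); uncertainty
comes from per-draw KL across index-paired posterior draws of the stage
models, summarized as an 89% HPDI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cue_schema import ClauseRecord, CorpusTable, table_from_records
from .stage_models import STAGES, PosteriorFit, hdi_rows

logger = logging.getLogger("bayesurp.surprise")

REGIONS = ("np1", "verb", "np2")
#: stage providing the belief *after* each region is processed
_REGION_POSTERIOR_STAGE = {"np1": "np1", "verb": "np1_verb", "np2": "np1_verb_np2"}
_REGION_PRIOR_STAGE = {"np1": "clause_onset", "verb": "np1", "np2": "np1_verb"}

DEFAULT_CLIP = 1e-6

OUTPUT_COLUMNS = ["clause_id", "region", "p_os_mean", "p_os_lo", "p_os_hi",
                  "dkl_mean", "dkl_lo", "dkl_hi", "dkl_draw_mean"]


def bernoulli_kl(posterior_p, prior_p, clip: float = DEFAULT_CLIP):
    """KL divergence D(posterior || prior) between Bernoulli beliefs, in bits.

    Probabilities are clipped to [clip, 1-clip] so that fully disambiguating
    cues (near-certain beliefs) stay finite.  Scalar or array inputs.
    """
    p = np.asarray(posterior_p, dtype=float)
    q = np.asarray(prior_p, dtype=float)
    if np.any((p < 0) | (p > 1) | (q < 0) | (q > 1)) or not (
            np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("inputs to bernoulli_kl must be probabilities in [0, 1]")
    p = np.clip(p, clip, 1.0 - clip)
    q = np.clip(q, clip, 1.0 - clip)
    kl = p * np.log2(p / q) + (1.0 - p) * np.log2((1.0 - p) / (1.0 - q))
    # clamp tiny negative rounding residue when p == q
    kl = np.maximum(kl, 0.0)
    return float(kl) if kl.ndim == 0 else kl


@dataclass
class SummaryStat:
    mean: float
    lo: float
    hi: float


@dataclass
class BeliefTrajectory:
    """p(OS) at the four incremental points and per-region surprise.

    ``p_os`` maps stage name -> SummaryStat; ``d_kl`` maps region -> the
    headline KL (of mean probabilities) with an 89% HPDI from per-draw KL;
    ``d_kl_draw_mean`` carries the draw-wise mean KL alongside.  Partial
    records yield truncated trajectories (e.g., only the NP1 region).
    """

    clause_id: str
    p_os: dict[str, SummaryStat]
    d_kl: dict[str, SummaryStat]
    d_kl_draw_mean: dict[str, float]

    @property
    def regions(self) -> list[str]:
        return [r for r in REGIONS if r in self.d_kl]


def _stages_for(has_np2: bool) -> list[str]:
    stages = ["clause_onset", "np1", "np1_verb"]
    if has_np2:
        stages.append("np1_verb_np2")
    return stages


def _frame_trajectories(frame: pd.DataFrame, fits: Mapping[str, PosteriorFit],
                        stages: list[str], clip: float) -> pd.DataFrame:
    """Vectorized trajectories for a frame whose rows all cover ``stages``."""
    p_draws: dict[str, np.ndarray] = {}
    p_stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for stage in stages:
        res = fits[stage].predict_p_os_frame(frame)
        p_draws[stage] = res.draws
        p_stats[stage] = (np.atleast_1d(res.mean), np.atleast_2d(res.hpdi89))
    n_draws = min(a.shape[1] for a in p_draws.values())

    out: list[pd.DataFrame] = []
    clause_ids = frame["clause_id"].astype(str).to_numpy()
    for prev, curr, region in zip(stages[:-1], stages[1:], REGIONS):
        mean_c, hpdi_c = p_stats[curr]
        mean_p, _ = p_stats[prev]
        per_draw = bernoulli_kl(p_draws[curr][:, :n_draws],
                                p_draws[prev][:, :n_draws], clip)
        kl_hpdi = hdi_rows(per_draw, 0.89)
        out.append(pd.DataFrame({
            "clause_id": clause_ids,
            "region": region,
            "p_os_mean": mean_c,
            "p_os_lo": hpdi_c[:, 0],
            "p_os_hi": hpdi_c[:, 1],
            "dkl_mean": bernoulli_kl(mean_c, mean_p, clip),
            "dkl_lo": kl_hpdi[:, 0],
            "dkl_hi": kl_hpdi[:, 1],
            "dkl_draw_mean": per_draw.mean(axis=1),
        }))
    return pd.concat(out, ignore_index=True)


def trajectory(record: ClauseRecord, fits: Mapping[str, PosteriorFit],
               clip: float = DEFAULT_CLIP) -> BeliefTrajectory:
    """Belief trajectory and per-region Bayesian surprise for one clause.

    Stage draws are index-paired across the (independently fitted) stage
    models to propagate posterior uncertainty into the KL.
    """
    missing = [s for s in STAGES if s not in fits]
    if missing:
        raise ValueError(f"missing stage fits: {missing}")
    stages = _stages_for(record.np2 is not None)
    table = table_from_records([record], fits["np1"].inventory, validate=False)

    p_os: dict[str, SummaryStat] = {}
    p_draws: dict[str, np.ndarray] = {}
    for stage in stages:
        res = fits[stage].predict_p_os_frame(table.frame)
        p_draws[stage] = res.draws[0]
        p_os[stage] = SummaryStat(float(res.mean[0]), float(res.hpdi89[0][0]),
                                  float(res.hpdi89[0][1]))
    n_draws = min(len(v) for v in p_draws.values())

    d_kl: dict[str, SummaryStat] = {}
    d_kl_draw_mean: dict[str, float] = {}
    for prev, curr, region in zip(stages[:-1], stages[1:], REGIONS):
        point = bernoulli_kl(p_os[curr].mean, p_os[prev].mean, clip)
        per_draw = bernoulli_kl(p_draws[curr][:n_draws], p_draws[prev][:n_draws], clip)
        lo, hi = hdi_rows(per_draw[None, :], 0.89)[0]
        d_kl[region] = SummaryStat(point, float(lo), float(hi))
        d_kl_draw_mean[region] = float(np.mean(per_draw))
    return BeliefTrajectory(clause_id=record.clause_id, p_os=p_os, d_kl=d_kl,
                            d_kl_draw_mean=d_kl_draw_mean)


def batch_trajectories(table: CorpusTable, fits: Mapping[str, PosteriorFit],
                       clip: float = DEFAULT_CLIP,
                       chunk_size: int = 512) -> pd.DataFrame:
    """Trajectories for every clause in a corpus; tidy output with one row
    per clause x region (columns per :data:`OUTPUT_COLUMNS`).

    Evaluation is vectorized in chunks; if a chunk fails to encode, its
    records are retried one by one and individual failures are logged and
    skipped rather than raised.
    """
    missing = [s for s in STAGES if s not in fits]
    if missing:
        raise ValueError(f"missing stage fits: {missing}")
    frame = table.frame
    if not len(frame):
        return pd.DataFrame(columns=OUTPUT_COLUMNS)

    np2_cols = [c for c in frame.columns if c.startswith("np2_")]
    has_np2 = frame[np2_cols].notna().all(axis=1).to_numpy()
    pieces: list[pd.DataFrame] = []
    errors: list[tuple[str, str]] = []
    for full in (True, False):
        sub = frame[has_np2 == full]
        stages = _stages_for(full)
        for start in range(0, len(sub), chunk_size):
            chunk = sub.iloc[start:start + chunk_size]
            try:
                pieces.append(_frame_trajectories(chunk, fits, stages, clip))
            except Exception:  # noqa: BLE001 - retry per record
                sub_table = CorpusTable(frame=chunk, inventory=table.inventory)
                for record in sub_table.records():
                    try:
                        traj = trajectory(record, fits, clip)
                    except Exception as exc:  # noqa: BLE001
                        errors.append((record.clause_id, str(exc)))
                        continue
                    rows = []
                    for region in traj.regions:
                        stage = _REGION_POSTERIOR_STAGE[region]
                        rows.append({
                            "clause_id": traj.clause_id, "region": region,
                            "p_os_mean": traj.p_os[stage].mean,
                            "p_os_lo": traj.p_os[stage].lo,
                            "p_os_hi": traj.p_os[stage].hi,
                            "dkl_mean": traj.d_kl[region].mean,
                            "dkl_lo": traj.d_kl[region].lo,
                            "dkl_hi": traj.d_kl[region].hi,
                            "dkl_draw_mean": traj.d_kl_draw_mean[region],
                        })
                    pieces.append(pd.DataFrame(rows, columns=OUTPUT_COLUMNS))
    for cid, msg in errors[:10]:
        logger.warning("trajectory failed for clause %s: %s", cid, msg)
    if len(errors) > 10:
        logger.warning("... %d further trajectory failures", len(errors) - 10)
    result = pd.concat([p for p in pieces if len(p)], ignore_index=True) \
        if pieces else pd.DataFrame(columns=OUTPUT_COLUMNS)
    # stable clause-major ordering regardless of chunking
    order = {str(c): i for i, c in enumerate(frame["clause_id"].astype(str))}
    region_rank = {r: i for i, r in enumerate(REGIONS)}
    if len(result):
        result = result.sort_values(
            by=["clause_id", "region"],
            key=lambda s: s.map(order) if s.name == "clause_id" else s.map(region_rank),
            kind="stable").reset_index(drop=True)
    return result
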