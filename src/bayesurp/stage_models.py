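"""Staged Bayesian logistic mixed models of OS vs. SO constituent order.

Four models estimate p(OS | cues seen so far) at four incremental points of
a transitive clause: the clause onset (intercept only), after NP1, after
NP1 + verb, and after NP1 + verb + NP2.  Each model contains all cues
available up to its point, a fixed interaction set, and by-genre random
intercepts.  Coefficients get regularizing priors: the intercept is centered
at the baseline log-odds of OS order, other fixed effects get a wide
Student-t, and the genre-intercept sd a half-Cauchy.

Predictor coding: binary cues are sum-coded +-0.5 (first inventory level
positive), case is entered as two dummies against "unmarked", and NP length
is standardized on the training corpus.  Centering keeps the intercept
interpretable as the baseline log-odds of OS order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from ._mcmc import HierarchicalGLM, NutsConfig, fit_map, sample_nuts
from .cue_schema import (ClauseRecord, CorpusTable, CueInventory,
                         DEFAULT_INVENTORY, GENRE_COLUMN, ORDER_COLUMN,
                         table_from_records)

logger = logging.getLogger("bayesurp.stage_models")

STAGES = ("clause_onset", "np1", "np1_verb", "np1_verb_np2")


def hdi_rows(draws: np.ndarray, prob: float = 0.89) -> np.ndarray:
    """Row-wise highest-density interval of a (rows, n_draws) array.

    Shortest interval containing ``prob`` of the draws (same estimator as the
    usual sorted-window HDI); returns an array of shape (rows, 2).
    """
    x = np.sort(np.atleast_2d(draws), axis=1)
    n = x.shape[1]
    include = max(int(np.ceil(prob * n)), 2)
    widths = x[:, include - 1:] - x[:, :n - include + 1]
    best = np.argmin(widths, axis=1)
    rows = np.arange(x.shape[0])
    return np.column_stack([x[rows, best], x[rows, best + include - 1]])

#: interaction inventory: (np cue, verb cue) pairs per stage.  For the final
#: stage the dict below assigns each pair to NP1 or NP2; interactions carried
#: over from the NP1+verb model keep the NP1 cue, newly introduced ones use
#: the NP2 cue.  The assignment is configurable through ``interaction_np``.
_NP1_VERB_INTERACTIONS = (
    ("animacy", "volitional"),
    ("animacy", "causative"),
    ("person", "experiencer"),
    ("definiteness", "possessive"),
)
_FULL_INTERACTIONS = (
    ("animacy", "causative"),
    ("person", "experiencer"),
    ("givenness", "possessive"),
    ("definiteness", "possessive"),
    ("pronominality", "possessive"),
)
DEFAULT_INTERACTION_NP = {
    "animacy:causative": "np1",
    "person:experiencer": "np1",
    "definiteness:possessive": "np1",
    "givenness:possessive": "np2",
    "pronominality:possessive": "np2",
}


@dataclass(frozen=True)
class StageSpec:
    """Term set of one incremental model."""

    stage: str
    fixed_terms: tuple[str, ...]
    interaction_terms: tuple[str, ...]
    group_term: str = GENRE_COLUMN

    @property
    def all_terms(self) -> tuple[str, ...]:
        return self.fixed_terms + self.interaction_terms


def build_stage_spec(stage_name: str,
                     inventory: CueInventory = DEFAULT_INVENTORY,
                     interaction_np: Mapping[str, str] | None = None) -> StageSpec:
    """Return the term set for one of the four incremental models.

    ``interaction_np`` optionally remaps which NP's cue enters each
    interaction of the final model (keys like ``"animacy:causative"``,
    values ``"np1"`` or ``"np2"``).
    """
    if stage_name not in STAGES:
        raise ValueError(f"unknown stage {stage_name!r}; expected one of {STAGES}")
    np_cat = [c.name for c in inventory.np_cues if c.kind != "continuous"]
    verb = [f"verb_{c.name}" for c in inventory.verb_cues]
    clause = [f"clause_{c.name}" for c in inventory.clause_cues]

    if stage_name == "clause_onset":
        return StageSpec(stage_name, (), ())
    if stage_name == "np1":
        fixed = [f"np1_{c}" for c in np_cat] + ["np1_length"] + clause
        return StageSpec(stage_name, tuple(fixed), ())
    if stage_name == "np1_verb":
        fixed = [f"np1_{c}" for c in np_cat] + ["np1_length"] + verb + clause
        inter = tuple(f"np1_{a}:verb_{b}" for a, b in _NP1_VERB_INTERACTIONS)
        return StageSpec(stage_name, tuple(fixed), inter)
    # np1_verb_np2: NP1 length is dropped, NP2 cues (incl. length) enter
    assignment = dict(DEFAULT_INTERACTION_NP)
    if interaction_np:
        assignment.update(interaction_np)
    fixed = ([f"np1_{c}" for c in np_cat] + verb
             + [f"np2_{c}" for c in np_cat] + ["np2_length"] + clause)
    inter = tuple(f"{assignment[f'{a}:{b}']}_{a}:verb_{b}" for a, b in _FULL_INTERACTIONS)
    return StageSpec(stage_name, tuple(fixed), inter)


@dataclass
class PriorConfig:
    """Regularizing priors for a stage model (values on the logit scale)."""

    intercept_mean: float = -2.994
    intercept_scale: float = 2.5
    fixed_df: float = 30.0
    fixed_loc: float = 0.0
    fixed_scale: float = 5.0
    re_scale: float = 2.0

    def __post_init__(self) -> None:
        if min(self.intercept_scale, self.fixed_scale, self.re_scale) <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class SamplerConfig:
    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    target_accept: float = 0.8
    seed: int = 0
    rhat_threshold: float = 1.01
    method: str = "nuts"  # "nuts" | "laplace" (fast approximation)


# ---------------------------------------------------------------------------
# design encoding

class RankDeficiencyError(ValueError):
    pass


def _coded_column(frame: pd.DataFrame, term: str, inventory: CueInventory,
                  length_stats: dict, stage: str) -> tuple[list[str], np.ndarray]:
    """Return (column names, n x m coded values) for one main-effect term."""
    if term.endswith("_length"):
        vals = pd.to_numeric(frame[term], errors="coerce").to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"stage {stage!r}: missing cue {term!r}")
        mean, sd = length_stats.setdefault(term, (float(np.mean(vals)),
                                                  float(np.std(vals)) or 1.0))
        return [f"{term}_z"], ((vals - mean) / sd)[:, None]
    cue = inventory.descriptor(term)
    col = frame[term]
    if col.isna().any():
        raise ValueError(f"stage {stage!r}: missing cue {term!r}")
    unknown = set(col.unique()) - set(cue.levels)
    if unknown:
        raise ValueError(f"stage {stage!r}: unknown level(s) {sorted(unknown)} "
                         f"for cue {term!r}")
    if cue.kind == "binary":
        coded = np.where(col.to_numpy() == cue.levels[0], 0.5, -0.5)
        return [term], coded[:, None]
    # three-level case: dummies against "unmarked"
    arr = col.to_numpy()
    out = np.column_stack([(arr == lvl).astype(float) for lvl in cue.levels[1:]])
    return [f"{term}={lvl}" for lvl in cue.levels[1:]], out


def encode_design(frame: pd.DataFrame, spec: StageSpec,
                  inventory: CueInventory = DEFAULT_INVENTORY,
                  length_stats: dict | None = None) -> tuple[np.ndarray, list[str], dict]:
    """Build the fixed-effects design matrix (with leading intercept column).

    ``length_stats`` carries training-corpus standardization constants; pass
    the dict stored in a fit's design_info to encode new records consistently.
    """
    length_stats = {} if length_stats is None else dict(length_stats)
    cols: list[str] = ["intercept"]
    mats: list[np.ndarray] = [np.ones((len(frame), 1))]
    for term in spec.fixed_terms:
        names, mat = _coded_column(frame, term, inventory, length_stats, spec.stage)
        cols += names
        mats.append(mat)
    for term in spec.interaction_terms:
        left, right = term.split(":")
        _, ml = _coded_column(frame, left, inventory, length_stats, spec.stage)
        _, mr = _coded_column(frame, right, inventory, length_stats, spec.stage)
        if ml.shape[1] != 1 or mr.shape[1] != 1:
            raise ValueError(f"interaction {term!r} must involve binary cues")
        cols.append(term)
        mats.append(ml * mr)
    X = np.hstack(mats)
    return X, cols, length_stats


def _check_rank(X: np.ndarray, cols: Sequence[str]) -> None:
    if len(X) == 0:
        raise ValueError("empty design matrix")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify aliased columns via QR pivoting
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [cols[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
            f"aliased columns: {bad or 'undetermined'}")


# ---------------------------------------------------------------------------
# fitted model

@dataclass
class PosteriorProbability:
    """Per-draw posterior predictive probabilities with a point summary."""

    draws: np.ndarray  # (n_draws,) or (n_records, n_draws)
    mean: np.ndarray | float
    hpdi89: np.ndarray  # (..., 2)


@dataclass
class PosteriorFit:
    """Posterior draws and metadata for one stage model."""

    spec: StageSpec
    priors: PriorConfig
    draws: np.ndarray               # (chains, draws, dim) full parameter draws
    param_names: list[str]
    design_info: dict               # columns, length_stats, genre_levels
    diagnostics: dict               # rhat / ess / divergences per parameter
    inventory: CueInventory = field(default_factory=CueInventory)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def columns(self) -> list[str]:
        return list(self.design_info["columns"])

    def coefficient_draws(self) -> pd.DataFrame:
        """Flattened fixed-effect draws, one column per design column."""
        p = len(self.columns)
        flat = self.draws.reshape(-1, self.draws.shape[-1])[:, :p]
        return pd.DataFrame(flat, columns=self.columns)

    def genre_sd_draws(self) -> np.ndarray:
        idx = self.param_names.index("log_tau[0]")
        return np.exp(self.draws.reshape(-1, self.draws.shape[-1])[:, idx])

    def to_arviz(self) -> az.InferenceData:
        named = {name: self.draws[:, :, i] for i, name in enumerate(self.param_names)}
        return az.from_dict(posterior=named)

    # -- prediction ---------------------------------------------------------
    def design_rows(self, frame: pd.DataFrame) -> np.ndarray:
        X, cols, _ = encode_design(frame, self.spec, self.inventory,
                                   self.design_info["length_stats"])
        if cols != self.columns:
            raise ValueError("encoded columns do not match the fitted design")
        return X

    def predict_p_os_frame(self, frame: pd.DataFrame,
                           marginalize_genre: bool = False,
                           seed: int = 0) -> PosteriorProbability:
        """p(OS) for each row of a corpus-format frame; population level
        (genre deviation zero) unless ``marginalize_genre``, which instead
        integrates over the fitted genre-intercept distribution."""
        X = self.design_rows(frame)
        p = len(self.columns)
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        eta = X @ flat[:, :p].T  # (n_records, n_draws)
        if marginalize_genre:
            idx = self.param_names.index("log_tau[0]")
            tau = np.exp(flat[:, idx])
            rng = np.random.default_rng(seed)
            eta = eta + tau[None, :] * rng.standard_normal(eta.shape[1])[None, :]
        prob = expit(eta)
        mean = prob.mean(axis=1)
        hpdi = hdi_rows(prob, 0.89)
        return PosteriorProbability(draws=prob, mean=mean, hpdi89=hpdi)

    def predict_p_os(self, record: ClauseRecord,
                     marginalize_genre: bool = False) -> PosteriorProbability:
        table = table_from_records([record], self.inventory, validate=False)
        res = self.predict_p_os_frame(table.frame, marginalize_genre=marginalize_genre)
        return PosteriorProbability(draws=res.draws[0], mean=float(res.mean[0]),
                                    hpdi89=res.hpdi89[0])

    # -- serialization ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        chains, ndraw, dim = self.draws.shape
        long = pd.DataFrame({
            "chain": np.repeat(np.arange(chains), ndraw * dim),
            "draw": np.tile(np.repeat(np.arange(ndraw), dim), chains),
            "parameter": np.tile(self.param_names, chains * ndraw),
            "value": self.draws.ravel(),
        })
        long.to_csv(directory / f"{self.spec.stage}_draws.csv", index=False)
        sidecar = {
            "spec": asdict(self.spec),
            "priors": asdict(self.priors),
            "design_info": self.design_info,
            "diagnostics": self.diagnostics,
            "param_names": self.param_names,
            "shape": [chains, ndraw, dim],
        }
        with open(directory / f"{self.spec.stage}_design.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, directory: str | Path, stage: str,
             inventory: CueInventory = DEFAULT_INVENTORY) -> "PosteriorFit":
        directory = Path(directory)
        with open(directory / f"{stage}_design.json") as fh:
            sidecar = json.load(fh)
        long = pd.read_csv(directory / f"{stage}_draws.csv")
        chains, ndraw, dim = sidecar["shape"]
        draws = long["value"].to_numpy().reshape(chains, ndraw, dim)
        spec_d = sidecar["spec"]
        spec = StageSpec(spec_d["stage"], tuple(spec_d["fixed_terms"]),
                         tuple(spec_d["interaction_terms"]), spec_d["group_term"])
        info = sidecar["design_info"]
        info["length_stats"] = {k: tuple(v) for k, v in info["length_stats"].items()}
        return cls(spec=spec, priors=PriorConfig(**sidecar["priors"]), draws=draws,
                   param_names=list(sidecar["param_names"]), design_info=info,
                   diagnostics=sidecar["diagnostics"], inventory=inventory)


# ---------------------------------------------------------------------------
# fitting

def _convergence_diagnostics(draws: np.ndarray, param_names: list[str],
                             n_fixed: int, threshold: float) -> dict:
    rhat, ess = {}, {}
    # fixed effects, random-effect sd and the genre deviations
    for i, name in enumerate(param_names):
        arr = draws[:, :, i]
        if draws.shape[0] > 1:
            r = float(az.rhat(arr))
        else:
            r = float("nan")
        rhat[name] = r
        ess[name] = float(az.ess(arr))
    flagged = [n for n, r in rhat.items() if np.isfinite(r) and r > threshold]
    return {"rhat": rhat, "ess": ess, "flagged": flagged}


def fit_stage(corpus: CorpusTable, spec: StageSpec,
              priors: PriorConfig | None = None,
              sampler: SamplerConfig | None = None) -> PosteriorFit:
    """Fit one stage model on a fully labeled corpus.

    OS order is the modeled success.  Raises :class:`RankDeficiencyError` for
    aliased designs and logs a warning (with the per-parameter report) if any
    split-chain R-hat exceeds the configured threshold.
    """
    priors = priors or PriorConfig()
    sampler = sampler or SamplerConfig()
    frame = corpus.frame
    if frame[ORDER_COLUMN].isna().any():
        raise ValueError("fit_stage requires order labels on all records")

    X, cols, length_stats = encode_design(frame, spec, corpus.inventory)
    _check_rank(X, cols)
    y = (frame[ORDER_COLUMN] == "OS").to_numpy(dtype=float)
    genre_levels = sorted(frame[GENRE_COLUMN].astype(str).unique())
    genre_idx = frame[GENRE_COLUMN].astype(str).map(
        {g: i for i, g in enumerate(genre_levels)}).to_numpy()

    p = X.shape[1]
    prior_loc = np.full(p, priors.fixed_loc)
    prior_scale = np.full(p, priors.fixed_scale)
    prior_df = np.full(p, priors.fixed_df)
    prior_loc[0], prior_scale[0], prior_df[0] = (
        priors.intercept_mean, priors.intercept_scale, np.inf)

    model = HierarchicalGLM(X=X, y=y, group=genre_idx, family="bernoulli",
                            prior_loc=prior_loc, prior_scale=prior_scale,
                            prior_df=prior_df, re_scale=priors.re_scale)
    if sampler.method == "laplace":
        mode, lap = fit_map(model, laplace_draws=sampler.n_samples,
                            seed=sampler.seed)
        draws = lap[None, :, :]
        stats_divergences = 0
    else:
        cfg = NutsConfig(n_warmup=sampler.n_warmup, n_samples=sampler.n_samples,
                         n_chains=sampler.n_chains, seed=sampler.seed,
                         target_accept=sampler.target_accept)
        draws, stats = sample_nuts(model, cfg)
        stats_divergences = stats.divergences

    names = model.param_names()
    # rename for readability
    names = cols + [f"genre_z[{g}]" for g in genre_levels] + ["log_tau[0]"]
    diagnostics = _convergence_diagnostics(draws, names, p, sampler.rhat_threshold)
    diagnostics["divergences"] = stats_divergences
    diagnostics["approximation"] = sampler.method
    if diagnostics["flagged"]:
        logger.warning("stage %s: R-hat above %.3f for %s", spec.stage,
                       sampler.rhat_threshold, diagnostics["flagged"])

    design_info = {"columns": cols, "length_stats": length_stats,
                   "genre_levels": genre_levels}
    return PosteriorFit(spec=spec, priors=priors, draws=draws, param_names=names,
                        design_info=design_info, diagnostics=diagnostics,
                        inventory=corpus.inventory)


def fit_all_stages(corpus: CorpusTable,
                   priors: PriorConfig | None = None,
                   sampler: SamplerConfig | None = None,
                   interaction_np: Mapping[str, str] | None = None,
                   inventory: CueInventory | None = None) -> dict[str, PosteriorFit]:
    """Fit the four incremental models; per-stage seeds are offset so chains
    are independent across stages but reproducible overall."""
    inventory = inventory or corpus.inventory
    sampler = sampler or SamplerConfig()
    fits = {}
    for i, stage in enumerate(STAGES):
        spec = build_stage_spec(stage, inventory, interaction_np)
        stage_sampler = SamplerConfig(**{**asdict(sampler), "seed": sampler.seed + i})
        fits[stage] = fit_stage(corpus, spec, priors, stage_sampler)
    return fits


def predict_p_os(fit: PosteriorFit, record: ClauseRecord,
                 marginalize_genre: bool = False) -> PosteriorProbability:
    """Population-level posterior p(OS) for one clause under one stage fit."""
    return fit.predict_p_os(record, marginalize_genre=marginalize_genre)
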