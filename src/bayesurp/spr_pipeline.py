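"""Self-paced-reading analysis: exclusions, length correction, region
averaging, and the Bayesian mixed-effects reading-time models.

The pipeline order is fixed: (1) remove word RTs outside (100, 4000) ms
(strict inequalities, boundary values retained), (2) remove all words from
trials whose comprehension question was answered incorrectly, (3) regress
raw RT on word length with by-participant random intercepts and length
slopes and keep the residuals as length-corrected RTs, (4) exclude corrected
RTs more than three standard deviations from the participant's mean.
Analysis regions are then: NP1 and verb = the single word's corrected RT;
NP2 = the mean of the post-verbal NP word and the first adverbial word (if
one of the two was excluded, the remaining word stands alone); the adverbial
region (next two adverbial words) and the sentence-final word are averaged
for reporting only.

Two model families run per region: a *surprise* LMM with standardized
Bayesian surprise as the only fixed effect (by-participant intercepts), and
a *linguistic* LMM with sum-coded design factors (order: SVO = +0.5,
object animacy: animate = +0.5, verb class: experiencer = +0.5) and the
maximal by-participant random structure.  Coefficients are summarized by the
MAP estimate (kernel-density mode of the marginal), posterior SE, 89% HPDI,
and the posterior mass on the MAP's side of zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._mcmc import HierarchicalGLM, NutsConfig, sample_nuts
from .stage_models import hdi_rows
from .synthetic_data import CONDITION_COLUMNS, SPR_COLUMNS

logger = logging.getLogger("bayesurp.spr")

ANALYSIS_REGIONS = ("np1", "verb", "np2")
RT_LOW, RT_HIGH = 100.0, 4000.0

_SUM_CODES = {"order": ("SVO", "OVS"), "object_animacy": ("animate", "inanimate"),
              "verb_class": ("experiencer", "volitional")}


def validate_spr_table(frame: pd.DataFrame) -> None:
    missing = set(SPR_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"SPR table missing columns: {sorted(missing)}")
    if (frame["raw_rt"] <= 0).any():
        raise ValueError("raw_rt must be positive")
    bad_regions = set(frame["region"]) - {"np1", "verb", "np2", "adverbial", "final"}
    if bad_regions:
        raise ValueError(f"unknown regions: {sorted(bad_regions)}")
    for col, levels in _SUM_CODES.items():
        bad = set(frame[col]) - set(levels)
        if bad:
            raise ValueError(f"unknown levels in {col}: {sorted(bad)}")


# ---------------------------------------------------------------------------
# exclusions and length correction

def exclude_trials(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Range exclusions then accuracy exclusions, with a count report."""
    validate_spr_table(frame)
    n_total = len(frame)
    in_range = (frame["raw_rt"] >= RT_LOW) & (frame["raw_rt"] <= RT_HIGH)
    n_range = int((~in_range).sum())
    kept = frame[in_range]
    correct = kept["question_correct"].astype(bool)
    n_incorrect = int((~correct).sum())
    kept = kept[correct].reset_index(drop=True)
    report = {
        "n_words_total": n_total,
        "n_range_excluded": n_range,
        "frac_range_excluded": n_range / n_total if n_total else 0.0,
        "n_incorrect_excluded": n_incorrect,
        "frac_incorrect_excluded": n_incorrect / n_total if n_total else 0.0,
        "n_retained": len(kept),
    }
    return kept, report


def length_correct(frame: pd.DataFrame, sd_limit: float = 3.0,
                   min_obs: int = 10, per_region: bool = False
                   ) -> tuple[pd.DataFrame, dict]:
    """Length-correct RTs and apply the per-participant 3-SD rule.

    Fits raw_rt ~ word_length with by-participant random intercepts and
    length slopes (statsmodels MixedLM); the residual is the corrected RT.
    Participants with fewer than ``min_obs`` words get the population line
    only (with a warning).  The SD rule is applied per participant across
    all their words by default, or within region with ``per_region``.
    """
    import statsmodels.formula.api as smf

    frame = frame.copy().reset_index(drop=True)
    counts = frame.groupby("participant").size()
    sparse = counts[counts < min_obs].index.tolist()
    if sparse:
        logger.warning("participants with < %d observations use the "
                       "population length slope: %s", min_obs, sparse)

    n_participants = frame["participant"].nunique()
    fitted = None
    if n_participants >= 3:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm("raw_rt ~ word_length", data=frame,
                                    groups=frame["participant"],
                                    re_formula="~word_length")
                res = model.fit(reml=True, method="lbfgs")
            fe = res.fe_params
            fitted = (fe["Intercept"] + fe["word_length"] * frame["word_length"]).to_numpy()
            for part, re_vals in res.random_effects.items():
                mask = (frame["participant"] == part).to_numpy()
                if part in sparse:
                    continue
                fitted[mask] += (re_vals.get("Group", 0.0)
                                 + re_vals.get("word_length", 0.0)
                                 * frame.loc[mask, "word_length"].to_numpy())
        except Exception as exc:  # noqa: BLE001 - fall back to OLS below
            logger.warning("mixed length-correction failed (%s); falling back "
                           "to per-participant least squares", exc)
            fitted = None
    if fitted is None:
        fitted = np.empty(len(frame))
        pooled = np.polyfit(frame["word_length"], frame["raw_rt"], 1)
        for part, sub in frame.groupby("participant"):
            idx = sub.index.to_numpy()
            if len(sub) >= max(min_obs, 3) and sub["word_length"].nunique() > 1:
                coef = np.polyfit(sub["word_length"], sub["raw_rt"], 1)
            else:
                coef = pooled
            fitted[idx] = np.polyval(coef, sub["word_length"])

    out = frame.copy()
    out["corrected_rt"] = out["raw_rt"] - fitted

    group_cols = ["participant", "region"] if per_region else ["participant"]
    grp = out.groupby(group_cols)["corrected_rt"]
    mean = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    keep = (out["corrected_rt"] - mean).abs() <= sd_limit * sd.replace(0.0, np.inf)
    n_sd = int((~keep).sum())
    report = {"n_before_sd_rule": len(out), "n_sd_excluded": n_sd,
              "frac_sd_excluded": n_sd / len(out) if len(out) else 0.0,
              "n_retained": int(keep.sum())}
    return out[keep].reset_index(drop=True), report


def preprocess(frame: pd.DataFrame, sd_limit: float = 3.0,
               min_obs: int = 10, per_region: bool = False
               ) -> tuple[pd.DataFrame, dict]:
    """Full fixed-order preprocessing: range -> accuracy -> length
    correction -> SD rule.  Returns the word-level corrected table and a
    merged exclusion report."""
    kept, rep1 = exclude_trials(frame)
    corrected, rep2 = length_correct(kept, sd_limit=sd_limit, min_obs=min_obs,
                                     per_region=per_region)
    report = {**rep1, **{f"post_correction_{k}": v for k, v in rep2.items()}}
    report["n_final"] = rep2["n_retained"]
    report["frac_excluded_total"] = (
        1.0 - rep2["n_retained"] / rep1["n_words_total"]
        if rep1["n_words_total"] else 0.0)
    return corrected, report


# ---------------------------------------------------------------------------
# region averaging

def region_average(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse word-level corrected RTs to analysis regions.

    NP1/verb: the single word.  NP2: mean of the NP2 word and the first
    adverbial word (or whichever of the two survived exclusion).  Adverbial:
    mean of the next two adverbial words; final: the last word (reporting
    regions).  Trials whose words were all excluded in a region yield no row
    for that region (logged)."""
    if "corrected_rt" not in frame.columns:
        raise ValueError("region_average needs length-corrected RTs")
    trial_cols = ["participant", "item", *CONDITION_COLUMNS]
    work = frame.sort_values(trial_cols + ["word_index"], kind="stable").copy()
    adv = work["region"] == "adverbial"
    adv_rank = work[adv].groupby(trial_cols, sort=False).cumcount()
    analysis = work["region"].astype(object).copy()
    # first surviving adverbial word joins the NP2 region; the next two form
    # the reported adverbial region; later adverbial words are dropped
    analysis.loc[adv] = np.select(
        [adv_rank == 0, adv_rank <= 2], ["np2", "adverbial"], default="drop")
    work["analysis_region"] = analysis
    work = work[work["analysis_region"] != "drop"]
    out = (work.groupby(trial_cols + ["analysis_region"], sort=False,
                        observed=True)["corrected_rt"]
           .mean().reset_index()
           .rename(columns={"analysis_region": "region", "corrected_rt": "rt"}))
    n_expected = out.groupby(trial_cols, observed=True).ngroups * 5
    if len(out) < n_expected:
        logger.info("region_average: %d trial x region cells had no "
                    "surviving words", n_expected - len(out))
    return out


# ---------------------------------------------------------------------------
# posterior summaries

@dataclass
class EffectSummary:
    term: str
    beta_map: float
    se: float
    hpdi89: tuple[float, float]
    p_posterior: float


def _map_estimate(draws: np.ndarray) -> float:
    """Kernel-density mode of a marginal posterior (the usual MAP summary
    for MCMC output)."""
    draws = np.asarray(draws, dtype=float)
    if np.allclose(draws, draws[0]):
        return float(draws[0])
    kde = sps.gaussian_kde(draws)
    grid = np.linspace(draws.min(), draws.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def summarize_effect(term: str, draws: np.ndarray) -> EffectSummary:
    lo, hi = hdi_rows(np.asarray(draws)[None, :], 0.89)[0]
    beta_map = _map_estimate(draws)
    p_pos = float(np.mean(draws > 0))
    return EffectSummary(term=term, beta_map=beta_map, se=float(np.std(draws)),
                         hpdi89=(float(lo), float(hi)),
                         p_posterior=max(p_pos, 1.0 - p_pos))


# ---------------------------------------------------------------------------
# reading-time LMMs

@dataclass
class RTPriorConfig:
    """Weakly regularizing priors for the reading-time models."""

    fixed_df: float = 3.0
    fixed_scale: float = 2.5
    re_scale: float = 2.0
    lkj_eta: float = 1.0
    sigma_df: float = 3.0
    sigma_scale_mult: float = 2.5  # x sd(y) for the residual-sd prior


@dataclass
class RTSamplerConfig:
    n_chains: int = 4
    n_warmup: int = 500
    n_samples: int = 500
    target_accept: float = 0.8
    seed: int = 0


@dataclass
class LMMFit:
    """A fitted reading-time model: draws plus the design needed for
    prediction and pointwise log-likelihood."""

    model: HierarchicalGLM
    draws: np.ndarray                 # (chains, draws, dim)
    fixed_columns: list[str]
    re_columns: list[str]
    obs_index: pd.DataFrame           # participant/item/condition per row
    diagnostics: dict

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def coefficient_draws(self) -> pd.DataFrame:
        return pd.DataFrame(self.flat[:, :len(self.fixed_columns)],
                            columns=self.fixed_columns)

    def summaries(self) -> list[EffectSummary]:
        coefs = self.coefficient_draws()
        return [summarize_effect(c, coefs[c].to_numpy()) for c in coefs.columns]

    def pointwise_loglik(self) -> np.ndarray:
        """Log-likelihood per draw and observation, conditional on the
        sampled random effects; shape (chains, draws, n)."""
        chains, ndraw, _ = self.draws.shape
        n = len(self.model.y)
        out = np.empty((chains * ndraw, n))
        flat = self.flat
        m = self.model
        for s in range(flat.shape[0]):
            eta = m.linear_predictor(flat[s])
            sigma = float(np.exp(flat[s][-1]))
            out[s] = (-0.5 * np.log(2.0 * np.pi) - np.log(sigma)
                      - 0.5 * ((m.y - eta) / sigma) ** 2)
        return out.reshape(chains, ndraw, n)


#: short factor names used in model terms -> SPR table columns
_FACTORS = {"animacy": "object_animacy", "order": "order", "verb": "verb_class"}


def _sum_code(frame: pd.DataFrame, short: str) -> np.ndarray:
    column = _FACTORS[short]
    plus = _SUM_CODES[column][0]
    return np.where(frame[column].to_numpy() == plus, 0.5, -0.5)


def linguistic_design(frame: pd.DataFrame, region: str,
                      nest_within: str | None = None
                      ) -> tuple[np.ndarray, list[str]]:
    """Sum-coded fixed design for the linguistic model.

    NP1 region: animacy, order, and their interaction; verb and NP2 regions:
    the full 2x2x2 factorial.  ``nest_within`` (a factor short name, e.g.
    ``"order"``) re-parameterizes to simple effects: each term not involving
    the nesting factor is split into within-level versions, spanning exactly
    the same column space as the main coding."""
    if region == "np1":
        term_names = ["animacy", "order", "animacy:order"]
    else:
        term_names = ["animacy", "order", "verb", "animacy:order",
                      "animacy:verb", "order:verb", "animacy:order:verb"]

    def term_column(term: str) -> np.ndarray:
        col = np.ones(len(frame))
        for part in term.split(":"):
            col = col * _sum_code(frame, part)
        return col

    if nest_within is None:
        cols = ["intercept"] + term_names
        X = np.column_stack([np.ones(len(frame))]
                            + [term_column(t) for t in term_names])
        return X, cols

    if nest_within not in _FACTORS:
        raise ValueError(f"unknown nesting factor {nest_within!r}")
    levels = _SUM_CODES[_FACTORS[nest_within]]
    nest_code = _sum_code(frame, nest_within)
    cols = ["intercept", nest_within]
    mats = [np.ones(len(frame)), nest_code]
    for term in term_names:
        if nest_within in term.split(":"):
            continue  # spanned by the within-level splits
        base = term_column(term)
        for level, mask in ((levels[0], nest_code > 0), (levels[1], nest_code < 0)):
            cols.append(f"{term}@{nest_within}={level}")
            mats.append(base * mask)
    return np.column_stack(mats), cols


def _fit_lmm(y: np.ndarray, X: np.ndarray, cols: list[str],
             participant: np.ndarray, Z: np.ndarray, re_cols: list[str],
             obs_index: pd.DataFrame, priors: RTPriorConfig,
             sampler: RTSamplerConfig) -> LMMFit:
    parts = pd.unique(participant)
    part_idx = pd.Series(participant).map(
        {p: i for i, p in enumerate(parts)}).to_numpy()
    sd_y = float(np.std(y)) or 1.0
    p = X.shape[1]
    model = HierarchicalGLM(
        X=X, y=y, group=part_idx, family="gaussian", Z=Z,
        prior_loc=np.zeros(p), prior_scale=np.full(p, priors.fixed_scale),
        prior_df=np.full(p, priors.fixed_df), re_scale=priors.re_scale,
        lkj_eta=priors.lkj_eta, sigma_df=priors.sigma_df,
        sigma_scale=priors.sigma_scale_mult * sd_y)
    cfg = NutsConfig(n_warmup=sampler.n_warmup, n_samples=sampler.n_samples,
                     n_chains=sampler.n_chains, seed=sampler.seed,
                     target_accept=sampler.target_accept)
    draws, stats = sample_nuts(model, cfg)
    diagnostics = {"divergences": stats.divergences,
                   "mean_accept": stats.mean_accept}
    if stats.divergences:
        logger.warning("reading-time LMM: %d divergent transitions", stats.divergences)
    return LMMFit(model=model, draws=draws, fixed_columns=cols,
                  re_columns=re_cols, obs_index=obs_index, diagnostics=diagnostics)


def standardize_surprise(region_table: pd.DataFrame,
                         design_surprise: pd.DataFrame, region: str,
                         scope: str = "region") -> pd.DataFrame:
    """Join per-condition surprise onto region rows and z-score it.

    ``scope="region"`` (default) standardizes within the analyzed region;
    ``scope="global"`` uses the mean/sd of surprise across all three
    analysis regions of the analyzed rows."""
    d = design_surprise[design_surprise["region"].isin(ANALYSIS_REGIONS)]
    merged_all = region_table[region_table["region"].isin(ANALYSIS_REGIONS)].merge(
        d[[*CONDITION_COLUMNS, "region", "dkl"]],
        on=[*CONDITION_COLUMNS, "region"], how="left")
    if merged_all["dkl"].isna().any():
        raise ValueError("design surprise does not cover all conditions")
    if scope == "global":
        mu, sd = merged_all["dkl"].mean(), merged_all["dkl"].std(ddof=0) or 1.0
    elif scope == "region":
        sub = merged_all[merged_all["region"] == region]
        mu, sd = sub["dkl"].mean(), sub["dkl"].std(ddof=0) or 1.0
    else:
        raise ValueError(f"unknown standardization scope {scope!r}")
    out = merged_all[merged_all["region"] == region].copy()
    out["z_surprise"] = (out["dkl"] - mu) / sd
    return out


def fit_surprise_lmm(region_table: pd.DataFrame, design_surprise: pd.DataFrame,
                     region: str, priors: RTPriorConfig | None = None,
                     sampler: RTSamplerConfig | None = None,
                     scope: str = "region",
                     re_structure: str = "intercept") -> LMMFit:
    """Corrected region RT ~ standardized surprise, by-participant
    intercepts (``re_structure="maximal_linguistic"`` adds the linguistic
    random slopes, used for like-for-like model comparison)."""
    priors = priors or RTPriorConfig()
    sampler = sampler or RTSamplerConfig()
    data = standardize_surprise(region_table, design_surprise, region, scope)
    data = data.dropna(subset=["rt"]).reset_index(drop=True)
    X = np.column_stack([np.ones(len(data)), data["z_surprise"].to_numpy()])
    cols = ["intercept", "surprise"]
    if re_structure == "intercept":
        Z, re_cols = np.ones((len(data), 1)), ["intercept"]
    elif re_structure == "maximal_linguistic":
        Z, re_cols = linguistic_design(data, region)
    else:
        raise ValueError(f"unknown re_structure {re_structure!r}")
    obs_index = data[["participant", "item", *CONDITION_COLUMNS]]
    return _fit_lmm(data["rt"].to_numpy(), X, cols, data["participant"].to_numpy(),
                    Z, re_cols, obs_index, priors, sampler)


def fit_linguistic_lmm(region_table: pd.DataFrame, region: str,
                       priors: RTPriorConfig | None = None,
                       sampler: RTSamplerConfig | None = None,
                       nest_within: str | None = None,
                       extra_surprise: pd.DataFrame | None = None) -> LMMFit:
    """Corrected region RT ~ sum-coded design factors with the maximal
    by-participant random structure.  ``nest_within`` produces the
    simple-effects re-parameterization of the same model (identical random
    effects and column space)."""
    priors = priors or RTPriorConfig()
    sampler = sampler or RTSamplerConfig()
    data = region_table[region_table["region"] == region].dropna(
        subset=["rt"]).reset_index(drop=True)
    X, cols = linguistic_design(data, region, nest_within=nest_within)
    Z, re_cols = linguistic_design(data, region)  # maximal REs, main coding
    obs_index = data[["participant", "item", *CONDITION_COLUMNS]]
    return _fit_lmm(data["rt"].to_numpy(), X, cols, data["participant"].to_numpy(),
                    Z, re_cols, obs_index, priors, sampler)
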