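"""Synthetic corpora and self-paced-reading logs.

Two generators mirror the statistical structure the analysis pipeline
assumes, so every stage of the pipeline can be exercised end to end:

* :func:`generate_corpus` samples clause cue profiles from configurable
  marginals (with the structural dependency that only pronouns carry case)
  and then samples the OS/SO order label from a logistic model with known
  coefficients, a baseline log-odds and by-genre intercept deviations.  The
  default baseline is the logit of 0.05, the rate at which object-initial
  clauses occur in written Swedish.  Cue marginals default to typological
  plausibility (first arguments mostly animate/definite/given, second
  arguments mostly inanimate/indefinite/new) and are pure configuration: no
  claim is made that they match any particular treebank.

* :func:`generate_spr` builds moving-window reading logs for the 2x2x2
  sentence design (constituent order x object animacy x verb class): word
  reading times follow a linear model with a word-length effect, a linear
  effect of region-standardized Bayesian surprise on the words of the three
  critical analysis regions, by-participant random intercepts and surprise
  slopes, and Gaussian (optionally log-normal) trial noise; a configurable
  fraction of trials is answered incorrectly and a configurable fraction of
  word RTs is replaced by out-of-range values.

:func:`fixture_item` returns the cue annotations of the eight design
conditions (case-marked pronominal subject, caseless lexical object).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cue_schema import (ClauseRecord, CorpusTable, CueInventory,
                         DEFAULT_INVENTORY)
from .stage_models import build_stage_spec, encode_design

CONDITION_COLUMNS = ("order", "object_animacy", "verb_class")
SPR_COLUMNS = ("participant", "item", "order", "object_animacy", "verb_class",
               "region", "word_index", "raw_rt", "word_length", "question_correct")
WORD_REGIONS = ("np1", "verb", "np2", "adverbial", "final")


# ---------------------------------------------------------------------------
# corpus generation

def _default_marginals() -> dict[str, dict[str, float]]:
    """P(level) per categorical cue column; lengths and case are handled by
    dedicated rules."""
    np1 = {"animacy": 0.62, "givenness": 0.65, "definiteness": 0.72,
           "number": 0.78, "person": 0.22, "pronominality": 0.45, "deixis": 0.015}
    np2 = {"animacy": 0.20, "givenness": 0.30, "definiteness": 0.45,
           "number": 0.70, "person": 0.05, "pronominality": 0.18, "deixis": 0.05}
    verb = {"volitional": 0.35, "experiencer": 0.22, "causative": 0.20,
            "possessive": 0.08, "auxiliary": 0.25}
    clause = {"embedded": 0.25, "verb_initial": 0.06}
    out: dict[str, dict[str, float]] = {}
    inv = DEFAULT_INVENTORY
    for prefix, probs, cues in (("np1", np1, inv.np_cues), ("np2", np2, inv.np_cues),
                                ("verb", verb, inv.verb_cues),
                                ("clause", clause, inv.clause_cues)):
        for cue in cues:
            if cue.kind != "binary":
                continue
            out[f"{prefix}_{cue.name}"] = {cue.levels[0]: probs[cue.name],
                                           cue.levels[1]: 1.0 - probs[cue.name]}
    return out


def _default_coefficients() -> dict[str, float]:
    """True log-odds effects on OS order used by default (design-column
    scale, i.e., +-0.5 sum coding / case dummies / standardized length)."""
    return {
        "np1_animacy": -1.2,        # animate first arguments favor SO
        "np1_definiteness": -0.5,
        "np1_pronominality": -0.8,
        "np1_person": -0.6,
        "np1_deixis": 2.8,          # text-deictic first NP strongly favors OS
        "np1_case=subject": -2.5,
        "np1_case=object": 3.0,
        "np2_animacy": 0.8,
        "np2_pronominality": 0.9,
        "np2_person": 0.7,
        "np2_case=subject": 3.5,    # subject-marked NP2 disambiguates to OS
        "np2_case=object": -2.0,
        "verb_experiencer": 0.4,
        "np1_animacy:verb_causative": -0.6,
        "np1_person:verb_experiencer": -0.5,
    }


@dataclass
class CorpusGenConfig:
    """Generating process for a synthetic cue-annotated corpus."""

    n_clauses: int = 16552
    baseline_os_logodds: float = float(logit(0.05))
    true_coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    cue_marginals: dict[str, dict[str, float]] = field(default_factory=_default_marginals)
    #: P(case level | pronominal), per NP slot; lexical NPs are always unmarked
    pronoun_case: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "np1": {"unmarked": 0.10, "subject": 0.82, "object": 0.08},
        "np2": {"unmarked": 0.10, "subject": 0.12, "object": 0.78},
    })
    lexical_length_mean: float = 2.2   # mean extra words beyond 1 (Poisson)
    genres: tuple[str, ...] = ("news", "fiction", "popular_science", "blog", "official")
    genre_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for col, probs in self.cue_marginals.items():
            total = sum(probs.values())
            if not np.isclose(total, 1.0) or min(probs.values()) < 0:
                raise ValueError(f"invalid marginal for {col!r} (sums to {total})")
        for slot, probs in self.pronoun_case.items():
            if not np.isclose(sum(probs.values()), 1.0):
                raise ValueError(f"invalid case distribution for {slot!r}")
        if self.genre_sd < 0:
            raise ValueError("genre_sd must be non-negative")


def generate_corpus(config: CorpusGenConfig | None = None,
                    inventory: CueInventory = DEFAULT_INVENTORY) -> CorpusTable:
    """Sample a corpus of transitive clauses with known order-assignment
    process.  Deterministic given the seed."""
    config = config or CorpusGenConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_clauses

    data: dict[str, object] = {"clause_id": [f"c{i:06d}" for i in range(n)]}
    for col, probs in config.cue_marginals.items():
        levels = list(probs)
        data[col] = rng.choice(levels, size=n, p=[probs[l] for l in levels])
    # structural dependency: case only on pronouns
    for slot in ("np1", "np2"):
        pron = np.asarray(data[f"{slot}_pronominality"]) == "pronominal"
        case = np.full(n, "unmarked", dtype=object)
        dist = config.pronoun_case[slot]
        levels = list(dist)
        case[pron] = rng.choice(levels, size=int(pron.sum()),
                                p=[dist[l] for l in levels])
        data[f"{slot}_case"] = case
        length = np.ones(n, dtype=int)
        length[~pron] = 1 + rng.poisson(config.lexical_length_mean, int((~pron).sum()))
        data[f"{slot}_length"] = length
    data["genre"] = rng.choice(list(config.genres), size=n)
    data["order"] = "SO"  # placeholder, replaced below

    frame = pd.DataFrame(data)
    spec = build_stage_spec("np1_verb_np2", inventory)
    X, cols, _ = encode_design(frame, spec, inventory)
    unknown = set(config.true_coefficients) - set(cols)
    if unknown:
        raise ValueError(f"true_coefficients refer to unknown design columns: "
                         f"{sorted(unknown)}")
    beta = np.zeros(len(cols))
    for term, value in config.true_coefficients.items():
        beta[cols.index(term)] = value
    # calibrate the intercept on the sampled cue profiles so that the
    # *marginal* OS probability equals expit(baseline_os_logodds); plain
    # centering would undershoot because of the spread of the cue effects
    contrib = X @ beta
    contrib -= contrib.mean()
    genre_dev = rng.normal(0.0, config.genre_sd, len(config.genres))
    genre_idx = frame["genre"].map({g: i for i, g in enumerate(config.genres)})
    spread = contrib + genre_dev[genre_idx.to_numpy()]
    target = float(expit(config.baseline_os_logodds))
    if np.allclose(spread, 0.0):
        intercept = config.baseline_os_logodds
    else:
        from scipy.optimize import brentq
        intercept = brentq(lambda c: float(np.mean(expit(c + spread))) - target,
                           -25.0, 10.0)
    eta = intercept + spread
    frame["order"] = np.where(rng.random(n) < expit(eta), "OS", "SO")

    table = CorpusTable(frame=frame[inventory.columns()], inventory=inventory,
                        provenance=f"<synthetic seed={config.seed}>")
    return table


# ---------------------------------------------------------------------------
# the 2x2x2 item design

def _pronoun_np(case: str) -> dict[str, object]:
    return {"animacy": "animate", "givenness": "given", "definiteness": "definite",
            "number": "singular", "person": "local", "pronominality": "pronominal",
            "case": case, "deixis": "other", "length": 1}


def _lexical_np(animacy: str) -> dict[str, object]:
    return {"animacy": animacy, "givenness": "new", "definiteness": "definite",
            "number": "singular", "person": "third", "pronominality": "lexical",
            "case": "unmarked", "deixis": "other", "length": 1}


def _verb(verb_class: str) -> dict[str, object]:
    return {"volitional": "yes" if verb_class == "volitional" else "no",
            "experiencer": "yes" if verb_class == "experiencer" else "no",
            "causative": "no", "possessive": "no", "auxiliary": "no"}


@dataclass
class FixtureItem:
    """Cue annotations for the eight design conditions plus the word/region
    layout of a critical sentence (one-word NPs, single verb, adverbial
    phrase, sentence-final word)."""

    records: dict[tuple[str, str, str], ClauseRecord]
    word_regions: tuple[str, ...] = ("np1", "verb", "np2", "adverbial",
                                     "adverbial", "adverbial", "final")

    def conditions(self) -> list[tuple[str, str, str]]:
        return list(self.records)


def fixture_item() -> FixtureItem:
    """The 2x2x2 design: SVO/OVS x volitional/experiencer x animate/inanimate
    object.  Subjects are case-marked pronouns; objects are caseless lexical
    NPs, so OVS sentences stay ambiguous until the post-verbal subject."""
    clause = {"embedded": "main", "verb_initial": "verb_medial"}
    records: dict[tuple[str, str, str], ClauseRecord] = {}
    for order in ("SVO", "OVS"):
        for verb_class in ("volitional", "experiencer"):
            for animacy in ("animate", "inanimate"):
                if order == "SVO":
                    np1, np2 = _pronoun_np("subject"), _lexical_np(animacy)
                else:
                    np1, np2 = _lexical_np(animacy), _pronoun_np("subject")
                cid = f"{order.lower()}_{verb_class}_{animacy}"
                records[(order, animacy, verb_class)] = ClauseRecord(
                    clause_id=cid, np1=np1, verb=_verb(verb_class), np2=np2,
                    clause=dict(clause))
    return FixtureItem(records=records)


# ---------------------------------------------------------------------------
# SPR generation

@dataclass
class SPRGenConfig:
    """Generating process for self-paced-reading logs of the 2x2x2 design."""

    n_participants: int = 45
    n_items: int = 32
    base_rt: float = 350.0            # ms
    length_slope: float = 12.0        # ms per character
    surprise_slope: float = 2.0       # ms per within-region SD of surprise
    participant_intercept_sd: float = 40.0
    participant_slope_sd: float = 0.5
    residual_sd: float = 15.0
    error_rate: float = 0.05
    outlier_rate: float = 0.003
    noise: str = "gaussian"           # or "lognormal"
    adverbial_words: tuple[int, int] = (3, 6)
    #: character-length ranges by word type
    length_ranges: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "pronoun": (3, 4), "noun": (5, 8), "verb": (6, 8),
        "adverbial": (2, 4), "final": (5, 9)})
    seed: int = 0

    def validate(self) -> None:
        if min(self.participant_intercept_sd, self.participant_slope_sd,
               self.residual_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (0 <= self.error_rate <= 1 and 0 <= self.outlier_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


def _condition_list() -> list[tuple[str, str, str]]:
    return [(o, a, v) for o in ("SVO", "OVS")
            for a in ("animate", "inanimate")
            for v in ("volitional", "experiencer")]


def standardize_design_surprise(design_surprise: pd.DataFrame) -> pd.DataFrame:
    """z-score the dkl column within each region across the 8 conditions."""
    out = design_surprise.copy()
    out["z_dkl"] = out.groupby("region")["dkl"].transform(
        lambda s: (s - s.mean()) / (s.std(ddof=0) or 1.0))
    return out


def generate_spr(config: SPRGenConfig | None = None,
                 design_surprise: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate a long-format SPR trial log.

    ``design_surprise`` must cover all 8 conditions x 3 critical regions with
    columns (order, object_animacy, verb_class, region, dkl) — typically the
    output of :func:`bayesurp.prediction_grid.design_predictions`.  The
    surprise effect is planted on the words entering each analysis region:
    the NP1 word, the verb word, and both the NP2 word and the first
    adverbial word (whose average forms the NP2 analysis region).
    """
    config = config or SPRGenConfig()
    config.validate()
    if design_surprise is None:
        raise ValueError("generate_spr requires per-condition design surprise")
    needed = {(o, a, v, r) for (o, a, v) in _condition_list()
              for r in ("np1", "verb", "np2")}
    have = set(map(tuple, design_surprise[
        ["order", "object_animacy", "verb_class", "region"]].to_numpy()))
    if not needed <= have:
        raise ValueError("design_surprise must cover all 8 conditions x "
                         "{np1, verb, np2}")
    std = standardize_design_surprise(
        design_surprise[design_surprise["region"].isin(("np1", "verb", "np2"))])
    z_map = {(r.order, r.object_animacy, r.verb_class, r.region): r.z_dkl
             for r in std.itertuples()}

    rng = np.random.default_rng(config.seed)
    conditions = _condition_list()
    b0 = rng.normal(0.0, config.participant_intercept_sd, config.n_participants)
    b1 = rng.normal(0.0, config.participant_slope_sd, config.n_participants)

    rows: list[tuple] = []
    for p in range(config.n_participants):
        for item in range(config.n_items):
            # two conditions per item per participant, rotated across
            # participants so the design stays balanced in expectation
            first = (item + p) % 8
            for cond_i in (first, (first + 4) % 8):
                order, animacy, verb_class = conditions[cond_i]
                incorrect = rng.random() < config.error_rate
                n_adv = int(rng.integers(config.adverbial_words[0],
                                         config.adverbial_words[1] + 1))
                words = (["np1", "verb", "np2"] + ["adverbial"] * n_adv + ["final"])
                for w_idx, region in enumerate(words, start=1):
                    kind = {"np1": "pronoun" if order == "SVO" else "noun",
                            "np2": "noun" if order == "SVO" else "pronoun",
                            "verb": "verb", "adverbial": "adverbial",
                            "final": "final"}[region]
                    lo, hi = config.length_ranges[kind]
                    wlen = int(rng.integers(lo, hi + 1))
                    rt = config.base_rt + b0[p] + config.length_slope * wlen
                    surprise_region = None
                    if region in ("np1", "verb"):
                        surprise_region = region
                    elif region == "np2" or (region == "adverbial"
                                             and words[w_idx - 2] == "np2"):
                        surprise_region = "np2"
                    if surprise_region is not None:
                        z = z_map[(order, animacy, verb_class, surprise_region)]
                        rt += (config.surprise_slope + b1[p]) * z
                    if config.noise == "lognormal":
                        sd_log = config.residual_sd / max(rt, 1.0)
                        rt = float(np.exp(np.log(max(rt, 1.0))
                                          + rng.normal(0.0, sd_log)))
                    else:
                        rt += rng.normal(0.0, config.residual_sd)
                    if rng.random() < config.outlier_rate:
                        rt = float(rng.choice([50.0, 4500.0]))
                    rows.append((p, item, order, animacy, verb_class, region,
                                 w_idx, max(rt, 1.0), wlen, not incorrect))
    return pd.DataFrame(rows, columns=list(SPR_COLUMNS))
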