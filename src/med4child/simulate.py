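"""Synthetic preschool cohorts with the structure a screener validation assumes.

A one-dimensional latent adherence trait drives all 18 item indicators
through a logistic link (item probability = expit(base + loading * trait)).
Each child's *true* item states generate two imperfect observations:

* the administered questionnaire, where quantities are drawn from the
  satisfying or violating region of each item's criterion after optional
  item-specific misreporting flips (social-desirability bias is modelled
  as one-directional flips toward scoring the point);
* the FFQ, where food-group gram intakes and weekly frequencies are drawn
  so that the shipped FFQ mapping reproduces the (possibly independently
  flipped) item states.

Cardiometabolic outcomes are linear in the true total score with age and
sex effects and Gaussian noise.  Base rates can be calibrated so simulated
item prevalences match target marginals (e.g. the published per-item
percentages).  Within-child food-group intakes are conditionally
independent given the trait; real dietary data are more strongly
cross-correlated, which this generator does not attempt to emulate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigurationError
from .analysis import homa_ir
from . import ffq as ffq_mod
from . import scoring as scoring_mod

#: Default target marginal prevalences per item: the published per-item
#: fraction of children scoring the point on the administered screener.
#: Item 11 (sofrito) has no published marginal; 0.5 is used.
DEFAULT_ITEM_MARGINALS: dict[int, float] = {
    1: 0.963, 2: 0.677, 3: 0.449, 4: 0.399, 5: 0.400, 6: 0.599,
    7: 0.795, 8: 0.600, 9: 0.261, 10: 0.826, 11: 0.500, 12: 0.572,
    13: 0.857, 14: 0.721, 15: 0.448, 16: 0.418, 17: 0.458, 18: 0.717,
}

#: Items whose criterion caps consumption of a less healthy food; the
#: published agreement pattern shows markedly lower kappas for these.
UNHEALTHY_ITEMS = (12, 13, 14, 15, 16, 17, 18)


@dataclass(frozen=True)
class Misreport:
    """Per-item misreporting: flip probabilities per instrument and the
    desirability direction (+1 flips only toward scoring the point, -1
    only away from it, 0 symmetric)."""

    p_flip_questionnaire: float = 0.0
    p_flip_ffq: float = 0.0
    desirability_direction: int = 1

    def __post_init__(self):
        for p in (self.p_flip_questionnaire, self.p_flip_ffq):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"flip probability {p} outside [0, 1]")
        if self.desirability_direction not in (-1, 0, 1):
            raise ConfigurationError("desirability_direction must be -1, 0 or 1")


@dataclass(frozen=True)
class OutcomeEffect:
    """Linear generative model for one outcome:
    intercept + beta_score * true_total + beta_age * (age - 4.5)
    + beta_girl * 1[girl] + Normal(0, sd), optionally floored."""

    intercept: float
    beta_score: float
    sd: float
    beta_age: float = 0.0
    beta_girl: float = 0.0
    floor: float | None = None

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigurationError("residual sd must be positive")


def default_outcome_effects() -> dict[str, OutcomeEffect]:
    """Small score effects with the qualitative sign pattern of published
    diet-quality associations (negative for waist circumference,
    triglycerides and insulin, positive for HDL); magnitudes are package
    defaults, not published values."""
    return {
        "bmi": OutcomeEffect(16.4, 0.0, 1.9, beta_age=0.2),
        "bmi_z": OutcomeEffect(0.4, 0.0, 1.3),
        "wc": OutcomeEffect(53.0, -0.15, 6.0, beta_age=1.5),
        "sbp": OutcomeEffect(104.0, 0.0, 13.0),
        "dbp": OutcomeEffect(64.0, 0.0, 12.0),
        "total_chol": OutcomeEffect(164.0, 0.0, 25.0),
        "hdl": OutcomeEffect(53.0, 0.30, 9.0),
        "ldl": OutcomeEffect(95.0, 0.0, 20.0),
        "tg": OutcomeEffect(60.0, -0.80, 18.0, floor=15.0),
        "glucose": OutcomeEffect(76.0, 0.0, 10.0, floor=50.0),
        "insulin": OutcomeEffect(4.8, -0.05, 2.0, beta_girl=0.8, floor=0.5),
    }


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Parameters governing one simulated cohort."""

    n: int = 858
    seed: int = 0
    trait_sd: float = 1.0
    item_loadings: Mapping[int, float] = field(
        default_factory=lambda: {i: 1.0 for i in range(1, 19)}
    )
    item_marginals: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_MARGINALS)
    )
    misreport: Mapping[int, Misreport] = field(
        default_factory=lambda: {i: Misreport() for i in range(1, 19)}
    )
    outcome_effects: Mapping[str, OutcomeEffect] = field(
        default_factory=default_outcome_effects
    )
    age_range: tuple[float, float] = (3.0, 6.0)
    girl_fraction: float = 0.5

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if self.trait_sd <= 0:
            raise ConfigurationError("trait_sd must be positive")
        if not 0.0 <= self.girl_fraction <= 1.0:
            raise ConfigurationError("girl_fraction outside [0, 1]")
        for i, p in self.item_marginals.items():
            if not 0.0 < p < 1.0:
                raise ConfigurationError(
                    f"item {i} marginal {p} must be strictly inside (0, 1)"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["misreport"] = {str(k): asdict(v) for k, v in self.misreport.items()}
        d["outcome_effects"] = {
            k: asdict(v) for k, v in self.outcome_effects.items()
        }
        d["item_loadings"] = {str(k): v for k, v in self.item_loadings.items()}
        d["item_marginals"] = {str(k): v for k, v in self.item_marginals.items()}
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class SyntheticCohort:
    """Truth, questionnaire, FFQ and outcome tables sharing child_ids."""

    truth: pd.DataFrame
    questionnaire: pd.DataFrame
    ffq: pd.DataFrame
    outcomes: pd.DataFrame
    config: SyntheticCohortConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.truth.to_csv(out / "truth.csv", index=False)
        self.questionnaire.to_csv(out / "questionnaire.csv", index=False)
        self.ffq.to_csv(out / "ffq.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        (out / "config.json").write_text(
            json.dumps(self.config.to_dict(), indent=2, sort_keys=True)
        )


def calibrate_to_marginals(
    target_marginals: Mapping[int, float],
    item_loadings: Mapping[int, float] | None = None,
    trait_sd: float = 1.0,
    n_quad: int = 61,
) -> dict[int, float]:
    """Base logits such that E_T[expit(base + loading*T)] hits each target.

    The expectation over the Gaussian trait is taken by Gauss-Hermite
    quadrature and inverted per item with Brent's method.  Targets of
    exactly 0 or 1 are unreachable under the logistic link and raise.
    """
    if item_loadings is None:
        item_loadings = {i: 1.0 for i in target_marginals}
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    scaled = np.sqrt(2.0) * trait_sd * nodes
    weights = weights / np.sqrt(np.pi)

    out = {}
    for item_id, target in target_marginals.items():
        if not 0.0 < target < 1.0:
            raise ConfigurationError(
                f"target marginal for item {item_id} must be in (0, 1)"
            )
        loading = float(item_loadings.get(item_id, 1.0))

        def prevalence(base: float) -> float:
            return float(weights @ expit(base + loading * scaled)) - target

        out[item_id] = float(brentq(prevalence, -40.0, 40.0, xtol=1e-12))
    return out


def _calibrate_union_base(
    target: float,
    other_base: float,
    loading: float,
    other_loading: float,
    trait_sd: float,
    n_quad: int = 61,
) -> float:
    """Base logit for an item whose final state is the union with another
    item (conditionally independent given the trait), such that the union
    prevalence hits ``target``."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    scaled = np.sqrt(2.0) * trait_sd * nodes
    weights = weights / np.sqrt(np.pi)
    p_other = expit(other_base + other_loading * scaled)
    floor = float(weights @ p_other)
    if target <= floor:
        raise ConfigurationError(
            f"union target {target} unreachable: entailed item already has "
            f"prevalence {floor:.3f}"
        )

    def union_prev(base: float) -> float:
        p_self = expit(base + loading * scaled)
        return float(weights @ (1.0 - (1.0 - p_self) * (1.0 - p_other))) - target

    return float(brentq(union_prev, -40.0, 40.0, xtol=1e-12))


def _flip(states: np.ndarray, p: float, direction: int, rng) -> np.ndarray:
    """Apply misreporting flips to a binary state vector."""
    if p == 0.0:
        return states.copy()
    u = rng.random(states.shape)
    flipped = states.copy()
    if direction >= 0:
        mask = (states == 0) & (u < p)
        flipped[mask] = 1
    if direction <= 0:
        mask = (states == 1) & (u < p)
        flipped[mask] = 0
    return flipped


def _draw_quantity(
    state: np.ndarray, direction: str, threshold: float, rng
) -> np.ndarray:
    """Draw a reported quantity in the satisfying (state=1) or violating
    (state=0) region of a criterion.

    at_least t: satisfied ~ U[t, 2t+1), violated ~ U[0, t);
    less_than t: satisfied ~ U[0, t), violated ~ U[t, 2t).
    The bounded violating region for less_than items keeps intakes within
    plausible child-sized ranges (and keeps fat intakes mutually coherent).
    """
    u = rng.random(state.shape)
    if direction == "at_least":
        sat = threshold + u * (threshold + 1.0)
        vio = u * threshold
    else:
        sat = u * threshold
        vio = threshold + u * threshold
    return np.where(state == 1, sat, vio)


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Simulate one cohort (truth, questionnaire, FFQ and outcome tables).

    Deterministic given the config (including its seed); the same config
    regenerates bit-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    registry = scoring_mod.registry_index(scoring_mod.load_registry())
    mapping = ffq_mod.load_mapping()
    child_ids = np.array([f"C{i:06d}" for i in range(1, n + 1)])

    trait = rng.normal(0.0, config.trait_sd, n)
    bases = calibrate_to_marginals(
        config.item_marginals, config.item_loadings, config.trait_sd
    )
    # item 1's final truth state is the union with item 2 (the coherence
    # step below); re-solve its base so the post-union marginal still hits
    # the calibration target
    bases[1] = _calibrate_union_base(
        config.item_marginals[1],
        bases[2],
        config.item_loadings.get(1, 1.0),
        config.item_loadings.get(2, 1.0),
        config.trait_sd,
    )

    items = list(range(1, 19))
    true = {}
    for i in items:
        p = expit(bases[i] + config.item_loadings.get(i, 1.0) * trait)
        true[i] = (rng.random(n) < p).astype(int)
    # coherence: >= 3 tbsp olive oil per day implies olive oil is a
    # culinary fat, so item 2 entails item 1
    true[1] = np.maximum(true[1], true[2])

    q_states, f_states = {}, {}
    for i in items:
        m = config.misreport.get(i, Misreport())
        q_states[i] = _flip(true[i], m.p_flip_questionnaire, m.desirability_direction, rng)
        f_states[i] = _flip(true[i], m.p_flip_ffq, m.desirability_direction, rng)
    q_states[1] = np.maximum(q_states[1], q_states[2])
    f_states[1] = np.maximum(f_states[1], f_states[2])

    # ---- administered questionnaire ----------------------------------
    q_cols: dict[str, np.ndarray] = {"child_id": child_ids}
    for i in items:
        crit = registry[i]
        if crit.direction == "yes":
            q_cols[f"q{i:02d}"] = q_states[i].astype(float)
        else:
            q_cols[f"q{i:02d}"] = _draw_quantity(
                q_states[i], crit.direction, crit.threshold, rng
            )
    # item 3 sub-condition: raw/salad servings per week, satisfied
    # whenever the item state is satisfied
    q_cols["q03_raw"] = np.where(
        q_states[3] == 1, 1.0 + rng.random(n) * 6.0, rng.random(n) * 7.0
    )

    # ---- FFQ ----------------------------------------------------------
    grams: dict[str, np.ndarray] = {}
    freqs: dict[str, np.ndarray] = {}

    def serving_g(group: str) -> float:
        return mapping.serving(group).grams_per_serving

    for i in items:
        rule = mapping.item_rules[i]
        kind, groups = rule["rule"], rule["groups"]
        if kind == "not_derivable":
            continue
        crit = registry[i]
        if kind == "servings":
            (group,) = groups
            servings = _draw_quantity(f_states[i], crit.direction, crit.threshold, rng)
            per_day = servings if crit.unit.endswith("_day") else servings / 7.0
            grams[group] = per_day * serving_g(group)
        elif kind == "frequency":
            (group,) = groups
            freq = _draw_quantity(f_states[i], crit.direction, crit.threshold, rng)
            freqs[group] = freq
            grams[group] = freq * serving_g(group) / 7.0

    # item 10: white- vs red-meat weekly frequency (red fixed by item 12)
    red = freqs["red_processed_meat"]
    white = np.where(
        f_states[10] == 1,
        red + 0.5 + rng.random(n) * 2.0,
        red * rng.random(n) * 0.9,
    )
    freqs["white_meat"] = white
    grams["white_meat"] = white * serving_g("white_meat") / 7.0

    # item 1: olive oil as main fat; adjust olive grams against butter
    # without crossing item 2's threshold (butter's violating region is
    # bounded below 2 servings/day = 24 g, the item-2 threshold is 27.6 g)
    olive, butter = grams["olive_oil"], grams["butter_cream"]
    olive = np.where(
        f_states[1] == 1, np.maximum.reduce([olive, butter + 0.5, np.full(n, 1.0)]), 0.0
    )
    grams["olive_oil"] = olive

    # ambient quantities not tied to any item
    grams["refined_cereals"] = 70.0 * np.exp(
        -0.15 * trait + rng.normal(0.0, 0.3, n)
    )
    energy = np.clip(rng.normal(1820.0, 560.0, n), 800.0, None)

    true_total = np.sum([true[i] for i in items], axis=0)
    ffq_cols: dict[str, np.ndarray] = {"child_id": child_ids}
    for group in ffq_mod.CANONICAL_GROUPS:
        if group in grams:
            ffq_cols[group] = grams[group]
    for group, freq in freqs.items():
        ffq_cols[f"freq_{group}"] = freq
    ffq_cols["energy_kcal_day"] = energy
    # two trait-linked nutrient summaries for quartile-gradient analyses
    ffq_cols["fibre_g"] = np.clip(
        13.0 + 1.2 * (true_total - 11.0) / 3.0 + rng.normal(0.0, 3.0, n), 2.0, None
    )
    ffq_cols["vitamin_c_mg"] = np.clip(
        95.0 + 16.0 * (true_total - 11.0) / 3.0 + rng.normal(0.0, 35.0, n), 5.0, None
    )

    # ---- outcomes -----------------------------------------------------
    lo, hi = config.age_range
    age = lo + rng.random(n) * (hi - lo)
    girl = (rng.random(n) < config.girl_fraction).astype(int)
    out_cols: dict[str, np.ndarray] = {
        "child_id": child_ids,
        "age": age,
        "sex": np.where(girl == 1, "girl", "boy"),
    }
    for name, eff in config.outcome_effects.items():
        value = (
            eff.intercept
            + eff.beta_score * true_total
            + eff.beta_age * (age - 4.5)
            + eff.beta_girl * girl
            + rng.normal(0.0, eff.sd, n)
        )
        if eff.floor is not None:
            value = np.clip(value, eff.floor, None)
        out_cols[name] = value
    if "glucose" in out_cols and "insulin" in out_cols:
        out_cols["homa"] = homa_ir(out_cols["glucose"], out_cols["insulin"])

    truth_cols: dict[str, np.ndarray] = {"child_id": child_ids, "trait": trait}
    for i in items:
        truth_cols[f"t{i:02d}"] = true[i]
    truth_cols["true_total"] = true_total

    return SyntheticCohort(
        truth=pd.DataFrame(truth_cols),
        questionnaire=pd.DataFrame(q_cols),
        ffq=pd.DataFrame(ffq_cols),
        outcomes=pd.DataFrame(out_cols),
        config=config,
    )


# ---- presets ----------------------------------------------------------


def preset_null(n: int = 858, seed: int = 0) -> SyntheticCohortConfig:
    """No misreporting and no outcome effects: both instruments observe
    the truth exactly and every outcome is independent of the score."""
    effects = {
        name: OutcomeEffect(
            eff.intercept, 0.0, eff.sd, beta_age=eff.beta_age,
            beta_girl=eff.beta_girl, floor=eff.floor,
        )
        for name, eff in default_outcome_effects().items()
    }
    return SyntheticCohortConfig(n=n, seed=seed, outcome_effects=effects)


def preset_calibrated(n: int = 858, seed: int = 0) -> SyntheticCohortConfig:
    """Item marginals calibrated to the published per-item percentages,
    no misreporting, default outcome effects."""
    return SyntheticCohortConfig(n=n, seed=seed)


def preset_biased(
    n: int = 858,
    seed: int = 0,
    p_flip_unhealthy: float = 0.30,
    p_flip_healthy: float = 0.10,
    p_flip_ffq: float = 0.05,
) -> SyntheticCohortConfig:
    """Social-desirability misreporting: caregivers over-claim points on
    the questionnaire, most strongly for items capping less healthy foods."""
    misreport = {}
    for i in range(1, 19):
        p_q = p_flip_unhealthy if i in UNHEALTHY_ITEMS else p_flip_healthy
        misreport[i] = Misreport(
            p_flip_questionnaire=p_q,
            p_flip_ffq=p_flip_ffq,
            desirability_direction=1,
        )
    return SyntheticCohortConfig(n=n, seed=seed, misreport=misreport)


PRESETS = {
    "null": preset_null,
    "calibrated": preset_calibrated,
    "biased": preset_biased,
}
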