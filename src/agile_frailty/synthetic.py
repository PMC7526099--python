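"""Seeded synthetic geriatric-cohort generator.

The generator emulates the statistical structure an instrument-validation
study assumes: a single latent frailty trait ``z`` that loads on age and
drives every deficit item, demographic marginals (age 77 ± 7 truncated at
65, 55.5% women), per-item overall prevalences, independent 16.8%
attrition over 24 months, and outcomes (death, incident disability,
hospitalization) that rise steeply across frailty strata.

Item model: item *j* of subject *i* is Bernoulli with probability
``logistic(alpha_j + beta_j * z_i)`` where
``z_i = lambda * standardized(age_i) + eps_i``, ``eps_i ~ N(0, 1)``.
The intercept ``alpha_j`` is calibrated by deterministic root-finding on
the *population* expectation (quadrature over the age and noise
distributions), so the configured prevalence is matched exactly up to
Monte-Carlo sampling error — seeds only affect sampling noise.

Outcome models:

``stratum_conditional``
    each outcome is Bernoulli with a per-stratum probability; the default
    light/severe endpoints are the study gradients (mortality 6.5→41.8%,
    disability 16.1→64.2%, hospitalization 17.2→58.7%) and the unprinted
    moderate value is the log-odds midpoint.

``per_unit_logistic``
    logit P(outcome) = gamma_0 + log(OR) * score, with the per-unit odds
    ratio configurable (defaults 1.56 / 1.44 / 1.24 per AGILE point) and
    gamma_0 calibrated so the marginal prevalence matches the
    stratum-implied one.  The true log-odds slope equals log(OR) exactly,
    which is what makes parameter-recovery experiments meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .domain import AGILE_ITEMS, REVERSE_CODED, SubjectRecord
from .cohort_io import frame_to_records
from .scoring import (
    AGILE_SCHEMES,
    GRIP_THRESHOLD_KG,
    IFI_ITEM_COLUMNS,
    METHODS_TERTILES,
    StratificationScheme,
    score_frame,
)

OUTCOMES = ("mortality", "disability", "hospitalization")

#: Overall item prevalences of the ten screener deficits ("All" column of
#: the study's item-prevalence table), as proportions.
DEFAULT_ITEM_PREVALENCES = {
    "effort": 0.838,
    "help_stairs": 0.518,
    "grip_deficit": 0.808,
    "temporal_orientation_deficit": 0.550,
    "delayed_recall_deficit": 0.808,
    "feels_depressed": 0.758,
    "weight_loss_gt_4_5kg": 0.293,
    "help_eating": 0.235,
    "financial_help_from_family": 0.528,
    "physical_help_from_family": 0.220,
}

#: Stratum-endpoint outcome probabilities; moderate (None) is filled with
#: the log-odds midpoint at resolution time.
DEFAULT_STRATUM_OUTCOME_PROBS = {
    "mortality": {"light": 0.065, "moderate": None, "severe": 0.418},
    "disability": {"light": 0.161, "moderate": None, "severe": 0.642},
    "hospitalization": {"light": 0.172, "moderate": None, "severe": 0.587},
}

#: Per-unit odds ratios per one-point increase of the driving score.
DEFAULT_PER_UNIT_OR = {"mortality": 1.56, "disability": 1.44, "hospitalization": 1.24}

#: Baseline BADL-lost distribution by stratum (mean, sd), clipped to [0, 5].
BADL_BASELINE_PARAMS = {
    "not_frail": (0.3, 0.7),
    "light": (0.5, 0.9),
    "moderate": (2.2, 1.7),
    "severe": (3.8, 1.3),
}


class ConfigurationError(ValueError):
    """Raised for an invalid or infeasible cohort configuration."""


@dataclass
class CohortConfig:
    """All generative-model parameters for one simulated cohort."""

    n_subjects: int = 400
    seed: int = 0
    age_mean: float = 77.0
    age_sd: float = 7.0
    age_min: float = 65.0
    female_fraction: float = 0.555
    item_prevalences: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_PREVALENCES)
    )
    #: common slope of every deficit item on the latent trait
    item_discriminations: Union[float, Dict[str, float]] = 1.5
    latent_age_loading: float = 0.6
    attrition_rate: float = 0.168
    #: extra log-odds of dropout per latent-trait unit (0 = independent attrition)
    attrition_frailty_loading: float = 0.0
    outcome_mode: str = "stratum_conditional"
    stratum_outcome_probs: Dict[str, Dict[str, Optional[float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STRATUM_OUTCOME_PROBS.items()}
    )
    per_unit_or: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PER_UNIT_OR))
    #: which score drives outcomes in per_unit_logistic mode: "agile" or "ifi"
    per_unit_score: str = "agile"
    rater_disagreement: float = 0.07
    scheme: str = "methods"
    #: expected score of each generic IFi item (on its 0/0.5/1 scale)
    ifi_generic_mean: float = 0.5
    ifi_discrimination: float = 1.0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        for name, p in [("female_fraction", self.female_fraction), ("attrition_rate", self.attrition_rate)]:
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        missing = set(AGILE_ITEMS) - set(self.item_prevalences)
        if missing:
            raise ConfigurationError(f"item_prevalences missing items: {sorted(missing)}")
        for item, p in self.item_prevalences.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"prevalence of '{item}' must be in [0, 1], got {p}")
        if self.outcome_mode not in ("stratum_conditional", "per_unit_logistic"):
            raise ConfigurationError(f"unknown outcome_mode '{self.outcome_mode}'")
        if self.per_unit_score not in ("agile", "ifi"):
            raise ConfigurationError(f"unknown per_unit_score '{self.per_unit_score}'")
        for outcome, orr in self.per_unit_or.items():
            if not orr > 0:
                raise ConfigurationError(f"per-unit OR for '{outcome}' must be > 0")
        if not 0 <= self.rater_disagreement <= 0.5:
            raise ConfigurationError("rater_disagreement must be in [0, 0.5]")
        if self.scheme not in AGILE_SCHEMES:
            raise ConfigurationError(f"unknown scheme '{self.scheme}'")
        for outcome, probs in self.resolved_stratum_probs().items():
            seq = [probs[s] for s in ("light", "moderate", "severe")]
            if any(not 0 <= p <= 1 for p in seq):
                raise ConfigurationError(f"stratum probabilities for '{outcome}' outside [0, 1]")
            if not (seq[0] <= seq[1] <= seq[2]):
                raise ConfigurationError(
                    f"stratum probabilities for '{outcome}' must be non-decreasing light→severe"
                )

    def discrimination_of(self, item: str) -> float:
        if isinstance(self.item_discriminations, dict):
            return self.item_discriminations[item]
        return float(self.item_discriminations)

    def resolved_stratum_probs(self) -> Dict[str, Dict[str, float]]:
        """Fill unprinted moderate probabilities with the log-odds midpoint."""
        out = {}
        for outcome, probs in self.stratum_outcome_probs.items():
            lo, hi = probs["light"], probs["severe"]
            mid = probs.get("moderate")
            if mid is None:
                mid = _logodds_midpoint(lo, hi)
            out[outcome] = {"light": lo, "moderate": mid, "severe": hi, "not_frail": lo}
        return out


def _logodds_midpoint(p_lo: float, p_hi: float) -> float:
    if p_lo in (0.0, 1.0) or p_hi in (0.0, 1.0):
        return (p_lo + p_hi) / 2  # degenerate endpoints: fall back to arithmetic mean
    return float(expit((logit(p_lo) + logit(p_hi)) / 2))


# ---------------------------------------------------------------------------
# Latent-trait quadrature and intercept calibration

_N_AGE_NODES = 201
_N_GH_NODES = 41

_grid_cache: dict = {}


def _age_dist(age_mean, age_sd, age_min):
    a = (age_min - age_mean) / age_sd
    return truncnorm(a, np.inf, loc=age_mean, scale=age_sd)


def latent_quadrature(age_mean, age_sd, age_min, latent_age_loading):
    """Equal-weight quadrature nodes for the latent trait z = λ·s(age) + ε."""
    key = (age_mean, age_sd, age_min, latent_age_loading)
    if key in _grid_cache:
        return _grid_cache[key]
    dist = _age_dist(age_mean, age_sd, age_min)
    mu, var = dist.stats(moments="mv")
    q = (np.arange(_N_AGE_NODES) + 0.5) / _N_AGE_NODES
    s_grid = (dist.ppf(q) - float(mu)) / math.sqrt(float(var))
    gh_x, gh_w = np.polynomial.hermite.hermgauss(_N_GH_NODES)
    eps = math.sqrt(2.0) * gh_x
    w_eps = gh_w / math.sqrt(math.pi)
    z = (latent_age_loading * s_grid)[:, None] + eps[None, :]
    w = np.broadcast_to(w_eps[None, :] / _N_AGE_NODES, z.shape)
    out = (z.ravel(), w.ravel().copy())
    _grid_cache[key] = out
    return out


def calibrate_intercept(target: float, slope: float, z_nodes, z_weights) -> float:
    """Intercept alpha with population mean logistic(alpha + slope·z) = target.

    Targets of exactly 0 or 1 yield ∓inf (a deterministic constant item).
    """
    if target <= 0.0:
        if target < 0:
            raise ConfigurationError(f"target prevalence {target} < 0")
        return -np.inf
    if target >= 1.0:
        if target > 1:
            raise ConfigurationError(f"target prevalence {target} > 1")
        return np.inf

    def f(alpha):
        return float(z_weights @ expit(alpha + slope * z_nodes)) - target

    return brentq(f, -60.0, 60.0, xtol=1e-12)


_alpha_cache: dict = {}


def resolve_item_intercepts(config: CohortConfig) -> Dict[str, float]:
    """Calibrated per-item intercepts (cached across identical generative setups)."""
    key = (
        config.age_mean,
        config.age_sd,
        config.age_min,
        config.latent_age_loading,
        tuple(sorted(config.item_prevalences.items())),
        tuple(sorted((i, config.discrimination_of(i)) for i in AGILE_ITEMS)),
    )
    if key in _alpha_cache:
        return _alpha_cache[key]
    z, w = latent_quadrature(config.age_mean, config.age_sd, config.age_min, config.latent_age_loading)
    alphas = {
        item: calibrate_intercept(config.item_prevalences[item], config.discrimination_of(item), z, w)
        for item in AGILE_ITEMS
    }
    _alpha_cache[key] = alphas
    return alphas


def _bernoulli_from_latent(rng, alpha, beta, z):
    if np.isneginf(alpha):
        return np.zeros(z.shape[0], dtype=bool)
    if np.isposinf(alpha):
        return np.ones(z.shape[0], dtype=bool)
    return rng.random(z.shape[0]) < expit(alpha + beta * z)


# ---------------------------------------------------------------------------
# Cohort generation

def generate_cohort_frame(config: CohortConfig) -> pd.DataFrame:
    """Generate a scored cohort as a DataFrame (deterministic given seed).

    The frame carries the cohort-CSV columns plus the appended score,
    domain and stratum columns from :func:`~agile_frailty.scoring.score_frame`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    scheme = AGILE_SCHEMES[config.scheme]

    dist = _age_dist(config.age_mean, config.age_sd, config.age_min)
    age = dist.rvs(n, random_state=rng)
    mu, var = dist.stats(moments="mv")
    s = (age - float(mu)) / math.sqrt(float(var))
    z = config.latent_age_loading * s + rng.standard_normal(n)
    female = rng.random(n) < config.female_fraction

    alphas = resolve_item_intercepts(config)
    deficits = {}
    for item in AGILE_ITEMS:
        deficits[item] = _bernoulli_from_latent(
            rng, alphas[item], config.discrimination_of(item), z
        )

    data = {
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "age": np.round(age, 1),
        "sex": np.where(female, "female", "male"),
    }
    # answers: deficit == "yes" except for the reverse-coded help items
    for item in AGILE_ITEMS:
        ans = ~deficits[item] if item in REVERSE_CODED else deficits[item]
        data[item] = ans.astype(int)

    data.update(_grip_measurements(rng, deficits["grip_deficit"], female))

    # IFi inputs: 38 generic graded deficits plus SSS / MNA totals
    z_ifi, w_ifi = latent_quadrature(
        config.age_mean, config.age_sd, config.age_min, config.latent_age_loading
    )
    alpha_g = calibrate_intercept(config.ifi_generic_mean, config.ifi_discrimination, z_ifi, w_ifi)
    for col in IFI_ITEM_COLUMNS:
        halves = sum(
            _bernoulli_from_latent(rng, alpha_g, config.ifi_discrimination, z).astype(float)
            for _ in range(2)
        )
        data[col] = halves / 2.0
    data["sss_score"] = np.clip(
        np.round(8.5 + 1.3 * z + rng.normal(0.0, 1.8, n)), 1, 19
    ).astype(int)
    data["mna_score"] = np.clip(
        np.round((21.8 - 2.8 * z + rng.normal(0.0, 2.0, n)) * 2) / 2, 0.0, 30.0
    )

    df = pd.DataFrame(data)
    df = score_frame(df, scheme=scheme)
    strata = df["agile_stratum"].to_numpy()

    # baseline disability graded by stratum
    badl0 = np.zeros(n)
    for stratum, (m, sd) in BADL_BASELINE_PARAMS.items():
        mask = strata == stratum
        if mask.any():
            badl0[mask] = m + sd * rng.standard_normal(mask.sum())
    badl0 = np.clip(np.round(badl0), 0, 5).astype(int)
    df["badl_lost_baseline"] = badl0

    # outcomes
    probs = _outcome_probabilities(config, df)
    died = rng.random(n) < probs["mortality"]
    disabled = rng.random(n) < probs["disability"]
    hospitalized = rng.random(n) < probs["hospitalization"]

    room = 6 - badl0  # baseline is clipped to 5, so room >= 1
    increment = 1 + (rng.random(n) * room).astype(int)
    badl1 = np.where(disabled, np.minimum(badl0 + increment, 6), badl0)

    drop_logit = logit(np.clip(config.attrition_rate, 1e-12, 1 - 1e-12))
    p_drop = expit(drop_logit + config.attrition_frailty_loading * z)
    completed = rng.random(n) >= p_drop

    df["completed_followup"] = completed.astype(int)
    df["died"] = died.astype(int)
    df["badl_lost_followup"] = badl1
    df["hospitalized"] = hospitalized.astype(int)
    df["incident_disability"] = disabled.astype(int)
    return df


def _grip_measurements(rng, grip_def, female):
    """Three per-subject dynamometer readings consistent with the deficit item."""
    n = grip_def.shape[0]
    thr = np.where(female, GRIP_THRESHOLD_KG["female"], GRIP_THRESHOLD_KG["male"])
    lo_def, hi_def = 0.35 * thr, thr  # deficit: mean in (0.35·thr, thr]
    lo_ok, hi_ok = thr + 1.0, thr + 20.0
    u = rng.random(n)
    mean = np.where(grip_def, lo_def + u * (hi_def - lo_def), lo_ok + u * (hi_ok - lo_ok))
    noise = rng.normal(0.0, 0.8, (n, 3))
    noise -= noise.mean(axis=1, keepdims=True)  # keeps the mean (and the deficit) exact
    readings = np.maximum(np.round(mean[:, None] + noise, 1), 0.0)
    # rounding can push a borderline mean across the threshold: fall back to
    # flat readings pinned inside the correct side
    safe = np.where(grip_def, np.minimum(np.round(mean, 1), thr), np.maximum(np.round(mean, 1), thr + 0.5))
    crossed = (readings.mean(axis=1) <= thr) != grip_def
    readings = np.where(crossed[:, None], safe[:, None], readings)
    return {f"grip_{k + 1}": np.round(readings[:, k], 1) for k in range(3)}


def _outcome_probabilities(config: CohortConfig, df: pd.DataFrame) -> Dict[str, np.ndarray]:
    probs = {}
    resolved = config.resolved_stratum_probs()
    if config.outcome_mode == "stratum_conditional":
        strata = df["agile_stratum"].to_numpy()
        for outcome in OUTCOMES:
            table = resolved[outcome]
            probs[outcome] = np.array([table[s] for s in strata])
    else:
        score_col = "agile_score" if config.per_unit_score == "agile" else "ifi_score"
        score = df[score_col].to_numpy(dtype=float)
        strata = df["agile_stratum"].to_numpy()
        for outcome in OUTCOMES:
            b = math.log(config.per_unit_or[outcome])
            target = float(np.mean([resolved[outcome][s] for s in strata]))
            g0 = brentq(
                lambda g: float(np.mean(expit(g + b * score))) - target, -40.0, 40.0
            )
            probs[outcome] = expit(g0 + b * score)
    return probs


def generate_cohort(config: CohortConfig) -> List[SubjectRecord]:
    """Generate the cohort as domain records (all pass ``validate_record``)."""
    return frame_to_records(generate_cohort_frame(config))


# ---------------------------------------------------------------------------
# Paired-rater simulation

def generate_rater_pair(
    cohort: pd.DataFrame, rater_disagreement: float, seed: int
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Two raters' per-item AGILE deficit codes for every subject.

    Rater A's codes are taken from the cohort; rater B independently
    flips each of A's item codes with probability ``rater_disagreement``.
    """
    if not 0 <= rater_disagreement <= 0.5:
        raise ConfigurationError("rater_disagreement must be in [0, 0.5]")
    from .scoring import item_code_frame

    a = item_code_frame(cohort)
    rng = np.random.default_rng(seed)
    flips = rng.random(a.shape) < rater_disagreement
    b = pd.DataFrame(a.to_numpy() ^ flips, columns=a.columns, index=a.index).astype(int)
    return a, b


def population_item_kappa(prevalences, disagreement: float) -> float:
    """Cohen's kappa implied by the flip model on pooled item codes.

    Observed agreement is exactly 1 − f; chance agreement comes from the
    pooled marginals of the two raters (rater B's positive rate is
    p(1−f) + (1−p)f for pooled deficit prevalence p).
    """
    p = float(np.mean(list(prevalences)))
    f = disagreement
    po = 1.0 - f
    pb = p * (1 - f) + (1 - p) * f
    pe = p * pb + (1 - p) * (1 - pb)
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def tune_rater_disagreement(target_kappa: float, prevalences=None) -> float:
    """Bisection-solve the flip probability yielding a target population kappa."""
    if prevalences is None:
        prevalences = DEFAULT_ITEM_PREVALENCES.values()
    prevalences = list(prevalences)
    k0 = population_item_kappa(prevalences, 0.0)
    k1 = population_item_kappa(prevalences, 0.5)
    if not (k1 <= target_kappa <= k0):
        raise ConfigurationError(
            f"target kappa {target_kappa} outside the attainable range [{k1:.3f}, {k0:.3f}]"
        )
    return brentq(
        lambda f: population_item_kappa(prevalences, f) - target_kappa, 0.0, 0.5, xtol=1e-12
    )
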