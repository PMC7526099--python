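"""Deterministic scoring: AGILE, IFi, grip deficit, strata, item selection.

AGILE is the unweighted sum of ten 0/1 deficit codes (range 0-10).  The
IFi is a 40-item deficit-accumulation index: 38 generic items scored in
{0, 0.5, 1} plus two banded instrument totals — the Social Support Score
(SSS, higher = worse support) and the Mini Nutritional Assessment (MNA,
lower = worse nutrition) — giving a range of 0-40 in half-point steps.

Strata are closed-above interval bands on the score.  Two AGILE schemes
exist: the tertile scheme used for all stratified results (light 0-3,
moderate 4-7, severe 8-10) and a four-level variant that splits score 0
out as "not frail".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .domain import (
    AGILE_ITEMS,
    DOMAINS,
    FEMALE,
    IFI_ITEM_VALUES,
    ITEM_DOMAINS,
    MALE,
    N_IFI_GENERIC_ITEMS,
    REVERSE_CODED,
    AgileResponse,
    FrailtyAssessment,
)

#: Dynamometer deficit thresholds (inclusive): mean grip ≤ threshold is a deficit.
GRIP_THRESHOLD_KG = {MALE: 30.0, FEMALE: 20.0}


class ScoringError(ValueError):
    """Raised when an input cannot be scored (missing item, bad value)."""


def grip_deficit(measurements: Sequence[float], sex: str) -> bool:
    """Grip-strength deficit from three dynamometer readings.

    The deficit criterion is the mean of the three measurements at or
    below 30 kg for men, 20 kg for women (thresholds inclusive).
    """
    grips = list(measurements)
    if len(grips) != 3:
        raise ScoringError(f"expected exactly three grip readings, got {len(grips)}")
    for g in grips:
        if g < 0:
            raise ScoringError(f"negative grip reading: {g}")
    if sex not in GRIP_THRESHOLD_KG:
        raise ScoringError(f"unknown sex '{sex}'")
    return float(np.mean(grips)) <= GRIP_THRESHOLD_KG[sex]


def sss_band(sss_score: float) -> float:
    """Banded IFi contribution of the Social Support Score: >13→1, 6-13→0.5, ≤5→0."""
    if sss_score > 13:
        return 1.0
    if sss_score >= 6:
        return 0.5
    return 0.0


def mna_band(mna_score: float) -> float:
    """Banded IFi contribution of the MNA total: <17→1, 17-23→0.5, ≥24→0."""
    if mna_score < 17:
        return 1.0
    if mna_score < 24:
        return 0.5
    return 0.0


@dataclass(frozen=True)
class StratificationScheme:
    """Ordered closed-above score bands mapping a score to a stratum label.

    ``boundaries`` is a tuple of (inclusive upper bound, label) pairs; the
    first band starts at 0.  Bands are contiguous: band *i* covers
    (upper_{i-1}, upper_i], with the first band also including 0.
    """

    name: str
    boundaries: tuple

    def __post_init__(self):
        uppers = [u for u, _ in self.boundaries]
        if not self.boundaries:
            raise ValueError("a scheme needs at least one band")
        if any(b >= a for b, a in zip(uppers, uppers[1:])):
            raise ValueError("band upper bounds must be strictly increasing")

    @property
    def max_score(self) -> float:
        return self.boundaries[-1][0]

    def stratum_of(self, score: float) -> str:
        if score < 0 or score > self.max_score:
            raise ScoringError(
                f"score {score} outside [0, {self.max_score:g}] for scheme '{self.name}'"
            )
        for upper, label in self.boundaries:
            if score <= upper:
                return label
        raise AssertionError("unreachable: bands cover the range")


METHODS_TERTILES = StratificationScheme(
    "methods_tertiles", ((3, "light"), (7, "moderate"), (10, "severe"))
)
DISCUSSION_FOUR_LEVEL = StratificationScheme(
    "discussion_four_level",
    ((0, "not_frail"), (3, "light"), (7, "moderate"), (10, "severe")),
)
#: IFi bands; the shared boundary 27.0 belongs to the moderate band.
IFI_TERTILES = StratificationScheme(
    "ifi_tertiles", ((16.0, "light"), (27.0, "moderate"), (40.0, "severe"))
)

AGILE_SCHEMES = {"methods": METHODS_TERTILES, "discussion": DISCUSSION_FOUR_LEVEL}


def stratify(score: float, scheme: StratificationScheme) -> str:
    """Map a score to its stratum label under ``scheme`` (total on the range)."""
    return scheme.stratum_of(score)


def score_agile(
    response: AgileResponse, scheme: StratificationScheme = METHODS_TERTILES
) -> FrailtyAssessment:
    """Score a complete AGILE response: sum of deficit codes, 0-10."""
    codes = response.deficit_codes()  # raises MissingItemError naming the item
    domain_scores = {d: 0 for d in DOMAINS}
    for item, code in codes.items():
        domain_scores[ITEM_DOMAINS[item]] += code
    score = sum(domain_scores.values())
    return FrailtyAssessment("AGILE", float(score), stratify(score, scheme), domain_scores)


def score_ifi(
    generic_items: Sequence[float],
    sss_score: float,
    mna_score: float,
    scheme: StratificationScheme = IFI_TERTILES,
) -> FrailtyAssessment:
    """Score the 40-item IFi: 38 generic deficits plus banded SSS and MNA.

    The generic items are anonymous coded deficits (their identities are a
    property of the administering study, not of the index arithmetic), so
    the domain breakdown reports them as a single "generic" pool, with the
    SSS band under socio_economic and the MNA band under nutritional.
    """
    items = [float(v) for v in generic_items]
    if len(items) != N_IFI_GENERIC_ITEMS:
        raise ScoringError(
            f"expected {N_IFI_GENERIC_ITEMS} generic IFi items, got {len(items)}"
        )
    for i, v in enumerate(items):
        if v not in IFI_ITEM_VALUES:
            raise ScoringError(f"generic IFi item {i} has score {v}, not in {{0, 0.5, 1}}")
    domain_scores = {
        "generic": float(sum(items)),
        "socio_economic": sss_band(sss_score),
        "nutritional": mna_band(mna_score),
    }
    score = sum(domain_scores.values())
    return FrailtyAssessment("IFi", score, stratify(score, scheme), domain_scores)


@dataclass(frozen=True)
class ItemEffect:
    """A candidate item with its frailty domain and per-item mortality risk ratio."""

    item_id: str
    domain: str
    mortality_rr: float

    def __post_init__(self):
        if not (self.mortality_rr > 0 and math.isfinite(self.mortality_rr)):
            raise ValueError(f"mortality_rr must be positive and finite, got {self.mortality_rr}")


#: Per-domain item counts that produce the 10-item screener.
AGILE_QUOTAS = {"physical": 3, "mental": 3, "nutritional": 2, "socio_economic": 2}


def select_items(
    effects: Iterable[ItemEffect], quotas: Mapping[str, int] = None
) -> list:
    """Domain-balanced selection of the most mortality-predictive items.

    Within each domain with a positive quota, pick the quota-many items
    with the largest mortality risk ratio; ties break on the smaller
    item_id.  With the screener quotas (3/3/2/2) this yields 10 items.
    """
    if quotas is None:
        quotas = AGILE_QUOTAS
    by_domain = {}
    for e in effects:
        by_domain.setdefault(e.domain, []).append(e)
    selected = []
    for domain in sorted(quotas, key=lambda d: DOMAINS.index(d) if d in DOMAINS else len(DOMAINS)):
        quota = quotas[domain]
        if quota <= 0:
            continue
        pool = by_domain.get(domain, [])
        if quota > len(pool):
            raise ValueError(
                f"quota {quota} exceeds the {len(pool)} available items in domain '{domain}'"
            )
        pool = sorted(pool, key=lambda e: (-e.mortality_rr, e.item_id))
        selected.extend(e.item_id for e in pool[:quota])
    return selected


def incident_disability(badl_lost_baseline: int, badl_lost_followup: int) -> bool:
    """Incident disability: an increase in BADL lost of ≥1 from baseline."""
    for name, v in (("baseline", badl_lost_baseline), ("followup", badl_lost_followup)):
        if not (0 <= v <= 6):
            raise ScoringError(f"badl_lost_{name} {v} outside [0, 6]")
    return (badl_lost_followup - badl_lost_baseline) >= 1


# ---------------------------------------------------------------------------
# Vectorised cohort-frame scoring (the CSV pipeline path)

DOMAIN_COLUMNS = {d: f"agile_domain_{d}" for d in DOMAINS}
IFI_ITEM_COLUMNS = tuple(f"ifi_item_{i:02d}" for i in range(1, N_IFI_GENERIC_ITEMS + 1))


def item_code_frame(df: pd.DataFrame) -> pd.DataFrame:
    """0/1 deficit codes for the ten AGILE answer columns of a cohort frame."""
    codes = {}
    for item in AGILE_ITEMS:
        col = df[item].astype(int)
        codes[item] = (1 - col) if item in REVERSE_CODED else col
    return pd.DataFrame(codes, index=df.index)


def score_frame(
    df: pd.DataFrame, scheme: StratificationScheme = METHODS_TERTILES
) -> pd.DataFrame:
    """Append AGILE (and, when present, IFi) scores and strata to a cohort frame.

    Adds ``agile_score``, ``agile_stratum``, the four per-domain sub-score
    columns, and ``ifi_score`` / ``ifi_stratum`` when the 38 generic item
    columns plus ``sss_score`` and ``mna_score`` are all present.
    """
    out = df.copy()
    codes = item_code_frame(df)
    for d in DOMAINS:
        cols = [i for i in AGILE_ITEMS if ITEM_DOMAINS[i] == d]
        out[DOMAIN_COLUMNS[d]] = codes[cols].sum(axis=1)
    out["agile_score"] = codes.sum(axis=1)
    out["agile_stratum"] = [scheme.stratum_of(s) for s in out["agile_score"]]

    has_ifi = all(c in df.columns for c in IFI_ITEM_COLUMNS) and {
        "sss_score",
        "mna_score",
    } <= set(df.columns)
    if has_ifi and not df[list(IFI_ITEM_COLUMNS)].isna().any().any():
        generic = df[list(IFI_ITEM_COLUMNS)].sum(axis=1)
        sss = df["sss_score"].to_numpy(dtype=float)
        mna = df["mna_score"].to_numpy(dtype=float)
        sss_b = np.select([sss > 13, sss >= 6], [1.0, 0.5], default=0.0)
        mna_b = np.select([mna < 17, mna < 24], [1.0, 0.5], default=0.0)
        out["ifi_score"] = generic + sss_b + mna_b
        out["ifi_stratum"] = [IFI_TERTILES.stratum_of(s) for s in out["ifi_score"]]
    return out
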