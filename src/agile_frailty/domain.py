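"""Core record types shared by scoring, simulation and validation.

The package models a geriatric screening cohort: each subject has
demographics (age, sex), responses to the ten AGILE screener items,
optionally the 40-item Italian Frailty index (IFi) inputs (38 generic
deficit scores plus the Social Support Score and Mini Nutritional
Assessment totals that enter as banded items), and a 24-month outcome
record (death, incident disability, hospitalization, completion flag).

AGILE spans four frailty domains — physical (items 1-3), mental (4-6),
nutritional (7-8) and socio-economic (9-10).  Items are yes/no answers;
most code yes→1 (deficit present), but the two family-help items are
reverse-coded because *absence* of help is the deficit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

MIN_AGE = 65.0
BADL_MAX = 6  # six basic activities of daily living
N_IFI_GENERIC_ITEMS = 38
IFI_ITEM_VALUES = (0.0, 0.5, 1.0)
SSS_RANGE = (1, 19)
MNA_RANGE = (0.0, 30.0)

PHYSICAL = "physical"
MENTAL = "mental"
NUTRITIONAL = "nutritional"
SOCIO_ECONOMIC = "socio_economic"
DOMAINS = (PHYSICAL, MENTAL, NUTRITIONAL, SOCIO_ECONOMIC)

#: The ten AGILE items, in instrument order.
AGILE_ITEMS = (
    "effort",
    "help_stairs",
    "grip_deficit",
    "temporal_orientation_deficit",
    "delayed_recall_deficit",
    "feels_depressed",
    "weight_loss_gt_4_5kg",
    "help_eating",
    "financial_help_from_family",
    "physical_help_from_family",
)

ITEM_DOMAINS = {
    "effort": PHYSICAL,
    "help_stairs": PHYSICAL,
    "grip_deficit": PHYSICAL,
    "temporal_orientation_deficit": MENTAL,
    "delayed_recall_deficit": MENTAL,
    "feels_depressed": MENTAL,
    "weight_loss_gt_4_5kg": NUTRITIONAL,
    "help_eating": NUTRITIONAL,
    "financial_help_from_family": SOCIO_ECONOMIC,
    "physical_help_from_family": SOCIO_ECONOMIC,
}

#: Items where a "yes" answer means help is present, i.e. *no* deficit.
REVERSE_CODED = frozenset(
    {"financial_help_from_family", "physical_help_from_family"}
)


class MissingItemError(ValueError):
    """An AGILE item answer is absent where a complete response is required."""


@dataclass(frozen=True)
class AgileResponse:
    """Yes/no answers to the ten AGILE items (True = "yes")."""

    effort: Optional[bool]
    help_stairs: Optional[bool]
    grip_deficit: Optional[bool]
    temporal_orientation_deficit: Optional[bool]
    delayed_recall_deficit: Optional[bool]
    feels_depressed: Optional[bool]
    weight_loss_gt_4_5kg: Optional[bool]
    help_eating: Optional[bool]
    financial_help_from_family: Optional[bool]
    physical_help_from_family: Optional[bool]

    def answers(self) -> dict:
        return {name: getattr(self, name) for name in AGILE_ITEMS}

    def missing_items(self) -> list:
        return [name for name, v in self.answers().items() if v is None]

    def deficit_codes(self) -> dict:
        """Per-item 0/1 deficit codes under the instrument's coding rules.

        yes→1 / no→0 for items 1-8; reverse-coded (yes→0 / no→1) for the
        two family-help items.  Raises :class:`MissingItemError` naming the
        first absent item.
        """
        codes = {}
        for name, answer in self.answers().items():
            if answer is None:
                raise MissingItemError(f"AGILE item '{name}' has no answer")
            code = int(bool(answer))
            if name in REVERSE_CODED:
                code = 1 - code
            codes[name] = code
        return codes


@dataclass(frozen=True)
class OutcomeRecord:
    """24-month follow-up status for one subject.

    ``badl_lost_followup`` is only meaningful for subjects who completed
    follow-up alive; ``incident_disability`` is the derived flag
    (an increase in BADL lost of at least one activity from baseline).
    """

    completed_followup: bool
    died: bool
    badl_lost_followup: int
    hospitalized: bool
    incident_disability: bool


@dataclass(frozen=True)
class FrailtyAssessment:
    """An instrument score with its stratum label and per-domain breakdown."""

    instrument: str  # "AGILE" or "IFi"
    score: float
    stratum: str
    domain_scores: dict

    def __post_init__(self):
        total = sum(self.domain_scores.values())
        if abs(total - self.score) > 1e-9:
            raise ValueError(
                f"domain scores sum to {total}, not the total score {self.score}"
            )


@dataclass
class SubjectRecord:
    """One person's demographics, item responses and instrument inputs."""

    subject_id: str
    age: float
    sex: str
    agile_items: AgileResponse
    badl_lost_baseline: int = 0
    ifi_items: Optional[Sequence[float]] = None
    sss_score: Optional[int] = None
    mna_score: Optional[float] = None
    grip_measurements: Optional[Sequence[float]] = None
    outcome: Optional[OutcomeRecord] = None


def validate_record(record: SubjectRecord) -> list:
    """Check every domain invariant; return a list of violation messages.

    Returns an empty list iff the record satisfies all invariants.  The
    function is pure: it never mutates the record and never raises for a
    rule violation (malformed violations are *returned*, not thrown).
    """
    violations = []

    if record.sex not in SEXES:
        violations.append(f"sex: '{record.sex}' is not one of {SEXES}")
    if record.age < MIN_AGE:
        violations.append(
            f"age: {record.age} violates the study inclusion criterion age >= {MIN_AGE:g}"
        )

    missing = record.agile_items.missing_items()
    for name in missing:
        violations.append(f"agile_items.{name}: answer is missing (complete response required)")

    if record.ifi_items is not None:
        items = list(record.ifi_items)
        if len(items) != N_IFI_GENERIC_ITEMS:
            violations.append(
                f"ifi_items: expected {N_IFI_GENERIC_ITEMS} generic item scores, got {len(items)}"
            )
        for i, v in enumerate(items):
            if v not in IFI_ITEM_VALUES:
                violations.append(
                    f"ifi_items[{i}]: score {v} is not in {{0, 0.5, 1}}"
                )

    if record.sss_score is not None:
        lo, hi = SSS_RANGE
        if not (lo <= record.sss_score <= hi):
            violations.append(f"sss_score: {record.sss_score} outside [{lo}, {hi}]")
    if record.mna_score is not None:
        lo, hi = MNA_RANGE
        if not (lo <= record.mna_score <= hi):
            violations.append(f"mna_score: {record.mna_score} outside [{lo:g}, {hi:g}]")

    if record.grip_measurements is not None:
        grips = list(record.grip_measurements)
        if len(grips) != 3:
            violations.append(
                f"grip_measurements: expected exactly three readings, got {len(grips)}"
            )
        for i, g in enumerate(grips):
            if g < 0:
                violations.append(f"grip_measurements[{i}]: negative reading {g}")

    if not (0 <= record.badl_lost_baseline <= BADL_MAX):
        violations.append(
            f"badl_lost_baseline: {record.badl_lost_baseline} outside [0, {BADL_MAX}]"
        )

    out = record.outcome
    if out is not None:
        if not (0 <= out.badl_lost_followup <= BADL_MAX):
            violations.append(
                f"outcome.badl_lost_followup: {out.badl_lost_followup} outside [0, {BADL_MAX}]"
            )
        elif out.completed_followup:
            derived = (out.badl_lost_followup - record.badl_lost_baseline) >= 1
            if out.incident_disability != derived:
                violations.append(
                    "outcome.incident_disability: inconsistent with the definition "
                    "(increase in BADL lost >= 1 from baseline)"
                )

    return violations
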