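"""Individual- and couple-level IPV severity, category, direction and
repetition classification.

Couple-level scoring follows the two-informant *union rule*: an act counts
as having occurred if either partner reports it, regardless of intradyadic
consistency, and an act reported by both partners counts once.  Physical
severity is impact-based, not act-based: an act crosses the clinically
significant (CS) threshold only through a reported injury, an inherently
dangerous act, or victim-reported fear.  Psychological CS status is scored
from the victim's report alone (the instrument collects psychological
victimization only).

Each couple with at least one report falls into exactly one of six
mutually exclusive categories::

    NO_IPV               no physical acts, no psychological CS
    LI_PHY_ONLY          physical acts, no impact of any kind
    CS_PHY_ONLY          physical acts with impact, no psychological CS
    CS_PSY_ONLY          psychological CS, no physical acts
    CS_PSY_AND_LI_PHY    psychological CS plus impact-free physical acts
    CS_PSY_AND_CS_PHY    both types above the CS threshold
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .fm_core import (
    DEFAULT_DANGEROUS_ACTS,
    CoupleRecord,
    Frequency,
    Impact,
    IndividualReport,
    ReportDirection,
    Role,
    min_count,
)


class ContractError(ValueError):
    """An operation was called outside its stated precondition."""


class Direction(str, enum.Enum):
    """Couple-level direction of aggression, named by the perpetrator."""

    WOMAN_TO_PARTNER = "woman_to_partner"
    PARTNER_TO_WOMAN = "partner_to_woman"


DIRECTIONS = (Direction.WOMAN_TO_PARTNER, Direction.PARTNER_TO_WOMAN)

PERPETRATOR: dict[Direction, Role] = {
    Direction.WOMAN_TO_PARTNER: Role.PREGNANT_WOMAN,
    Direction.PARTNER_TO_WOMAN: Role.PARTNER,
}
VICTIM: dict[Direction, Role] = {
    Direction.WOMAN_TO_PARTNER: Role.PARTNER,
    Direction.PARTNER_TO_WOMAN: Role.PREGNANT_WOMAN,
}
#: Direction in which the given role is the victim.
DIRECTION_OF_VICTIM: dict[Role, Direction] = {v: d for d, v in VICTIM.items()}


class DirectionLabel(str, enum.Enum):
    WOMAN_TO_PARTNER = "woman_to_partner"
    PARTNER_TO_WOMAN = "partner_to_woman"
    BIDIRECTIONAL = "bidirectional"


class Severity(enum.IntEnum):
    """Physical severity of one direction: none < low-impact < CS."""

    NONE = 0
    LI = 1
    CS = 2


class Category(str, enum.Enum):
    NO_IPV = "no_ipv"
    LI_PHY_ONLY = "li_phy_only"
    CS_PHY_ONLY = "cs_phy_only"
    CS_PSY_ONLY = "cs_psy_only"
    CS_PSY_AND_LI_PHY = "cs_psy_and_li_phy"
    CS_PSY_AND_CS_PHY = "cs_psy_and_cs_phy"


CATEGORIES = tuple(Category)

#: Category membership of the three overlap rollups.
ANY_PHY_CATEGORIES = frozenset({Category.LI_PHY_ONLY, Category.CS_PHY_ONLY,
                                Category.CS_PSY_AND_LI_PHY,
                                Category.CS_PSY_AND_CS_PHY})
CS_PHY_CATEGORIES = frozenset({Category.CS_PHY_ONLY, Category.CS_PSY_AND_CS_PHY})
CS_PSY_CATEGORIES = frozenset({Category.CS_PSY_ONLY, Category.CS_PSY_AND_LI_PHY,
                               Category.CS_PSY_AND_CS_PHY})
#: Categories whose couples enter the low-impact physical direction table.
LI_PHY_CATEGORIES = frozenset({Category.LI_PHY_ONLY, Category.CS_PSY_AND_LI_PHY})


@dataclass(frozen=True)
class CoupleClassification:
    couple_id: str
    category: Category
    phy_severity: Mapping[Direction, Severity]
    psy_cs: Mapping[Role, bool]  # keyed by victim role
    direction_phy_li: Optional[DirectionLabel]
    direction_phy_cs: Optional[DirectionLabel]
    direction_psy: Optional[DirectionLabel]
    repeated_phy: Optional[bool]
    repeated_psy: Optional[bool]
    n_reports: int


# ---------------------------------------------------------------------------
# Couple-level occurrence (two-informant union)
# ---------------------------------------------------------------------------

def _require_reports(couple: CoupleRecord) -> None:
    if couple.n_reports < 1:
        raise ContractError(f"couple {couple.couple_id}: both reports missing")


def couple_act_occurrence(couple: CoupleRecord,
                          direction: Direction) -> dict[str, Frequency]:
    """Acts occurring in ``direction`` at the couple level.

    An act occurs if the perpetrator self-reports it or the victim reports
    it; the couple-level frequency is the maximum of the two reported
    categories (the same event reported by both informants counts once).
    """
    _require_reports(couple)
    occ: dict[str, Frequency] = {}
    sources = (
        (couple.reports[PERPETRATOR[direction]], ReportDirection.PERPETRATED_BY_SELF),
        (couple.reports[VICTIM[direction]], ReportDirection.PERPETRATED_BY_PARTNER),
    )
    for report, rd in sources:
        if report.missing:
            continue
        for par in report.physical_acts:
            if par.direction is rd and par.frequency > Frequency.NEVER:
                prev = occ.get(par.act_id, Frequency.NEVER)
                occ[par.act_id] = max(prev, par.frequency)
    return occ


def couple_direction_impacts(couple: CoupleRecord, direction: Direction,
                             victim_only: bool = False) -> frozenset:
    """Union of injury impacts reported for ``direction``.

    With ``victim_only`` the perpetrator's self-reported inflictions are
    ignored and only the victim's own injury follow-ups count.
    """
    _require_reports(couple)
    impacts: set = set()
    sources = [
        (couple.reports[VICTIM[direction]], ReportDirection.PERPETRATED_BY_PARTNER),
    ]
    if not victim_only:
        sources.append((couple.reports[PERPETRATOR[direction]],
                        ReportDirection.PERPETRATED_BY_SELF))
    for report, rd in sources:
        if report.missing:
            continue
        for inj in report.injuries:
            if inj.direction is rd:
                impacts |= inj.impacts
    return frozenset(impacts)


# ---------------------------------------------------------------------------
# Severity classification
# ---------------------------------------------------------------------------

def classify_physical(couple: CoupleRecord, direction: Direction,
                      dangerous_acts: frozenset = DEFAULT_DANGEROUS_ACTS) -> Severity:
    """Physical severity of one direction of a couple.

    CS requires an occurring act plus impact: any injury reported by either
    informant, an inherently dangerous act, or the victim's own report of
    having feared for their safety.  Fear reported by the perpetrator about
    the victim does not qualify (fear is the victim's experience).
    """
    occ = couple_act_occurrence(couple, direction)
    if not occ:
        return Severity.NONE
    either = couple_direction_impacts(couple, direction)
    victim = couple_direction_impacts(couple, direction, victim_only=True)
    injury = bool(either - {Impact.FEARED_FOR_OWN_SAFETY})
    fear = Impact.FEARED_FOR_OWN_SAFETY in victim
    dangerous = any(a in dangerous_acts for a in occ)
    return Severity.CS if (injury or fear or dangerous) else Severity.LI


def classify_psych(victim_report: IndividualReport) -> bool:
    """Clinically significant psychological victimization, victim report only.

    True iff at least one psychological act is endorsed and an impact
    clause holds: the acts are attributed to screened depression/stress/
    fear, or safety fears are endorsed, or fear interfered with a major
    life activity.
    """
    if victim_report.missing:
        raise ContractError("psych classification requires a non-missing report")
    p = victim_report.psych
    if not p.endorsed_acts():
        return False
    attributed = p.attribution and bool(p.screener)
    return attributed or bool(p.safety_fears) or bool(p.interference)


# ---------------------------------------------------------------------------
# Repetition
# ---------------------------------------------------------------------------

def _phy_totals(couple: CoupleRecord) -> dict[Direction, int]:
    return {
        d: sum(min_count(f) for f in couple_act_occurrence(couple, d).values())
        for d in DIRECTIONS
    }


def is_repeated(couple: CoupleRecord, ipv_type: str) -> bool:
    """More than one act per partner in the past year.

    Uses the conservative minimum-count mapping of frequency categories, so
    a single act at frequency "twice" already counts as repeated, as do two
    distinct acts by the same perpetrator.  Physical repetition is computed
    on the couple-level union; psychological repetition on each CS victim's
    endorsed acts.
    """
    _require_reports(couple)
    if ipv_type == "physical":
        totals = _phy_totals(couple)
        if not any(totals.values()):
            raise ContractError(f"couple {couple.couple_id} has no physical IPV")
        return any(t >= 2 for t in totals.values())
    if ipv_type == "psychological":
        totals = []
        for role, report in couple.reports.items():
            if not report.missing and classify_psych(report):
                totals.append(sum(min_count(f)
                                  for _, f in report.psych.endorsed_acts()))
        if not totals:
            raise ContractError(
                f"couple {couple.couple_id} has no psychological CS-IPV")
        return any(t >= 2 for t in totals)
    raise ValueError(f"unknown ipv_type: {ipv_type!r}")


# ---------------------------------------------------------------------------
# Six-category couple classification
# ---------------------------------------------------------------------------

def _direction_label(positive: Mapping[Direction, bool]) -> Optional[DirectionLabel]:
    w = positive[Direction.WOMAN_TO_PARTNER]
    p = positive[Direction.PARTNER_TO_WOMAN]
    if w and p:
        return DirectionLabel.BIDIRECTIONAL
    if w:
        return DirectionLabel.WOMAN_TO_PARTNER
    if p:
        return DirectionLabel.PARTNER_TO_WOMAN
    return None


def classify_couple(couple: CoupleRecord,
                    dangerous_acts: frozenset = DEFAULT_DANGEROUS_ACTS,
                    ) -> CoupleClassification:
    """Assign the six-category label plus direction and repetition summaries.

    The six definitions are mutually exclusive and exhaustive over couples
    with at least one report; the most severe applicable category applies
    by construction.
    """
    _require_reports(couple)
    sev = {d: classify_physical(couple, d, dangerous_acts) for d in DIRECTIONS}
    psy = {
        role: (not rep.missing) and classify_psych(rep)
        for role, rep in couple.reports.items()
    }

    any_phy = any(s > Severity.NONE for s in sev.values())
    cs_phy = any(s is Severity.CS for s in sev.values())
    cs_psy = any(psy.values())

    if cs_psy and cs_phy:
        category = Category.CS_PSY_AND_CS_PHY
    elif cs_psy and any_phy:
        category = Category.CS_PSY_AND_LI_PHY
    elif cs_psy:
        category = Category.CS_PSY_ONLY
    elif cs_phy:
        category = Category.CS_PHY_ONLY
    elif any_phy:
        category = Category.LI_PHY_ONLY
    else:
        category = Category.NO_IPV

    direction_phy_li = direction_phy_cs = direction_psy = None
    if category in LI_PHY_CATEGORIES:
        direction_phy_li = _direction_label(
            {d: sev[d] > Severity.NONE for d in DIRECTIONS})
    if category in CS_PHY_CATEGORIES:
        direction_phy_cs = _direction_label(
            {d: sev[d] is Severity.CS for d in DIRECTIONS})
    if category in CS_PSY_CATEGORIES:
        direction_psy = _direction_label(
            {DIRECTION_OF_VICTIM[role]: flag for role, flag in psy.items()})

    repeated_phy = is_repeated(couple, "physical") if any_phy else None
    repeated_psy = is_repeated(couple, "psychological") if cs_psy else None

    return CoupleClassification(
        couple_id=couple.couple_id,
        category=category,
        phy_severity=sev,
        psy_cs=psy,
        direction_phy_li=direction_phy_li,
        direction_phy_cs=direction_phy_cs,
        direction_psy=direction_psy,
        repeated_phy=repeated_phy,
        repeated_psy=repeated_psy,
        n_reports=couple.n_reports,
    )


def classify_records(records: Iterable[CoupleRecord],
                     dangerous_acts: frozenset = DEFAULT_DANGEROUS_ACTS,
                     ) -> list[CoupleClassification]:
    """Classify every couple with at least one report; skip the rest."""
    return [classify_couple(c, dangerous_acts) for c in records if c.n_reports >= 1]


def classifications_to_frame(classifications: Iterable[CoupleClassification],
                             ) -> pd.DataFrame:
    def cell(label):
        return label.value if label is not None else ""

    rows = [{
        "couple_id": c.couple_id,
        "category": c.category.value,
        "phy_li_direction": cell(c.direction_phy_li),
        "phy_cs_direction": cell(c.direction_phy_cs),
        "psy_direction": cell(c.direction_psy),
        "repeated_phy": "" if c.repeated_phy is None else int(c.repeated_phy),
        "repeated_psy": "" if c.repeated_psy is None else int(c.repeated_psy),
        "n_reports": c.n_reports,
    } for c in classifications]
    return pd.DataFrame(rows, columns=[
        "couple_id", "category", "phy_li_direction", "phy_cs_direction",
        "psy_direction", "repeated_phy", "repeated_psy", "n_reports"])
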