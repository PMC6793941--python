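"""Domain types, instrument registries, validation and CSV I/O for
two-informant Family Maltreatment survey records.

The instrument collects, from each member of a couple *separately*:

* physical-aggression acts, each asked in a pair of items (perpetrated by
  self / perpetrated by partner) on a five-point past-year frequency scale
  ("never", "once", "twice", "3-5 times", "6 times or more");
* injury follow-ups for each reported act (six impact kinds, from fear for
  one's own safety up to fainting);
* a psychological-victimization section: a screener for significant
  depression, stress or fear caused by the partner, a list of specific
  controlling/demeaning acts with frequencies, an attribution item linking
  the endorsed acts to the screened distress, and checklists of safety
  fears and of interference with major life activities.

One :class:`CoupleRecord` holds both partners' reports (either may be a
missing marker).  Roles are positional labels -- ``pregnant_woman`` and
``partner`` -- chosen to match the recruitment setting; same-sex couples
are supported transparently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd


class SchemaError(ValueError):
    """A records CSV does not follow the documented wide schema."""


# ---------------------------------------------------------------------------
# Frequency scale
# ---------------------------------------------------------------------------

class Frequency(enum.IntEnum):
    """Ordinal past-year frequency category of an act.

    The integer values encode only the total order
    ``never < once < twice < three_to_five < six_plus``; use
    :func:`min_count` for the conservative count floor of each category.
    """

    NEVER = 0
    ONCE = 1
    TWICE = 2
    THREE_TO_FIVE = 3
    SIX_PLUS = 4

    @property
    def label(self) -> str:
        return _FREQ_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Frequency":
        try:
            return _FREQ_BY_LABEL[label]
        except KeyError:
            raise SchemaError(f"unknown frequency label: {label!r}") from None


_FREQ_LABELS: dict[Frequency, str] = {
    Frequency.NEVER: "never",
    Frequency.ONCE: "once",
    Frequency.TWICE: "twice",
    Frequency.THREE_TO_FIVE: "three_to_five",
    Frequency.SIX_PLUS: "six_plus",
}
_FREQ_BY_LABEL = {v: k for k, v in _FREQ_LABELS.items()}

#: Conservative minimum count per category: the lower bound of the printed
#: range ("3-5 times" -> 3, "6 times or more" -> 6).  Used by the
#: repeated-IPV rule so that "repeated" is a lower bound, not an estimate.
MIN_COUNTS: dict[Frequency, int] = {
    Frequency.NEVER: 0,
    Frequency.ONCE: 1,
    Frequency.TWICE: 2,
    Frequency.THREE_TO_FIVE: 3,
    Frequency.SIX_PLUS: 6,
}


def min_count(frequency: Frequency | str) -> int:
    """Minimum number of occurrences implied by a frequency category."""
    if isinstance(frequency, str):
        frequency = Frequency.from_label(frequency)
    if not isinstance(frequency, Frequency):
        raise SchemaError(f"unknown frequency category: {frequency!r}")
    return MIN_COUNTS[frequency]


# ---------------------------------------------------------------------------
# Roles and per-item enumerations
# ---------------------------------------------------------------------------

class Role(str, enum.Enum):
    """Positional label of a respondent within the couple."""

    PREGNANT_WOMAN = "pregnant_woman"
    PARTNER = "partner"


ROLES: tuple[Role, Role] = (Role.PREGNANT_WOMAN, Role.PARTNER)


def other_role(role: Role) -> Role:
    return Role.PARTNER if role is Role.PREGNANT_WOMAN else Role.PREGNANT_WOMAN


class ReportDirection(str, enum.Enum):
    """Direction of an act as seen from the *respondent's* point of view."""

    PERPETRATED_BY_SELF = "perp"
    PERPETRATED_BY_PARTNER = "vict"


class Impact(str, enum.Enum):
    """Injury follow-up impact kinds for physical acts."""

    FEARED_FOR_OWN_SAFETY = "feared_for_own_safety"
    PAIN_AT_LEAST_4H = "pain_at_least_4h"
    GRAZE_OR_WOUND = "graze_or_wound"
    BRUISE_OR_WELT = "bruise_or_welt"
    SPRAIN_OR_FRACTURE = "sprain_or_fracture"
    FAINTED = "fainted"


class Screener(str, enum.Enum):
    """Screened psychological impacts caused by the partner's behaviour."""

    DEPRESSION = "depression"
    STRESS = "stress"
    FEAR = "fear"


class SafetyFear(str, enum.Enum):
    FEAR_OWN_SAFETY = "fear_own_safety"
    FEAR_HARM_CLOSE_OTHERS = "fear_harm_close_others"


class Interference(str, enum.Enum):
    """Major life activities the victim limited out of fear."""

    WORK = "work"
    EDUCATION = "education"
    RELIGION = "religion"
    HEALTH_SERVICES = "health_services"
    FAMILY_FRIENDS = "family_friends"


# ---------------------------------------------------------------------------
# Act registries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysicalAct:
    act_id: str
    display_name: str
    inherently_dangerous: bool = False


@dataclass(frozen=True)
class PsychAct:
    act_id: str
    display_name: str


class Registry(Mapping):
    """Ordered, extensible act registry keyed by ``act_id``.

    The default registries carry the standard act sets; the instrument has
    slots for a couple of additional acts, which callers may append with
    :meth:`add`.
    """

    def __init__(self, acts: Iterable):
        items = list(acts)
        ids = [a.act_id for a in items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate act_id in registry")
        self._acts = {a.act_id: a for a in items}

    def __getitem__(self, act_id: str):
        return self._acts[act_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._acts)

    def __len__(self) -> int:
        return len(self._acts)

    def add(self, act) -> "Registry":
        """Return a new registry with ``act`` appended."""
        return Registry([*self._acts.values(), act])


#: The 13 physical acts of the default instrument.  ``other`` is a write-in
#: slot; write-ins are human-coded upstream and enter the pipeline as the
#: pre-coded ``other_is_ipv`` flag (non-IPV write-ins are dropped at load).
PHYSICAL_ACTS = Registry([
    PhysicalAct("pushed_or_shoved", "Pushed or shoved"),
    PhysicalAct("grabbed", "Grabbed"),
    PhysicalAct("scratched", "Scratched"),
    PhysicalAct("slapped", "Slapped"),
    PhysicalAct("thrown_hard_object", "Thrown hard object"),
    PhysicalAct("bitten", "Bitten"),
    PhysicalAct("hit_or_punched", "Hit or punched"),
    PhysicalAct("slammed_against_wall", "Slammed against a wall"),
    PhysicalAct("held_down", "Held down (e.g. twisted arm, hair)"),
    PhysicalAct("kicked", "Kicked"),
    PhysicalAct("choked", "Choked", inherently_dangerous=True),
    PhysicalAct("hit_with_object_that_could_hurt",
                "Hit with an object that could hurt",
                inherently_dangerous=True),
    PhysicalAct("other", "Other"),
])

#: Acts of high inherent dangerousness: endorsing one is sufficient for the
#: clinically-significant physical threshold even without a reported injury.
#: Configurable wherever severity is classified.
DEFAULT_DANGEROUS_ACTS = frozenset(
    a for a in PHYSICAL_ACTS if PHYSICAL_ACTS[a].inherently_dangerous
)

#: The 9 psychological acts of the default instrument.
PSYCH_ACTS = Registry([
    PsychAct("id_withheld", "Not allowed to have ID, driver's license or passport"),
    PsychAct("put_down_or_humiliated", "Put down or humiliated"),
    PsychAct("kept_from_service_providers", "Kept from seeing service providers"),
    PsychAct("stalked", "Stalked"),
    PsychAct("kept_from_family_friends",
             "Not allowed to see/talk to a family member or friend"),
    PsychAct("made_me_think_crazy", "Tried to make me think that I was crazy"),
    PsychAct("insulted_or_sworn_at", "Insulted or sworn at"),
    PsychAct("money_withheld", "Not allowed access to money"),
    PsychAct("grilled_or_interrogated", "Grilled or interrogated"),
])


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysicalActReport:
    act_id: str
    direction: ReportDirection
    frequency: Frequency


@dataclass(frozen=True)
class InjuryReport:
    act_id: str
    direction: ReportDirection
    impacts: frozenset = frozenset()


@dataclass(frozen=True)
class PsychSection:
    """Psychological-victimization section of one respondent's report.

    ``acts`` holds ``(act_id, Frequency)`` pairs.  ``attribution`` records
    whether the respondent linked the endorsed acts to the screened
    distress; it is meaningful only when ``acts`` is non-empty.
    """

    screener: frozenset = frozenset()
    acts: tuple = ()
    attribution: bool = False
    safety_fears: frozenset = frozenset()
    interference: frozenset = frozenset()

    def endorsed_acts(self) -> tuple:
        return tuple((a, f) for a, f in self.acts if f > Frequency.NEVER)


EMPTY_PSYCH = PsychSection()


@dataclass(frozen=True)
class IndividualReport:
    """One respondent's full instrument response, or a missing marker."""

    role: Role
    physical_acts: tuple = ()
    injuries: tuple = ()
    psych: PsychSection = EMPTY_PSYCH
    missing: bool = False


def missing_report(role: Role) -> IndividualReport:
    return IndividualReport(role=role, missing=True)


@dataclass(frozen=True)
class CoupleRecord:
    """Couple id plus a role-keyed pair of reports (either may be missing)."""

    couple_id: str
    reports: Mapping[Role, IndividualReport]

    @property
    def n_reports(self) -> int:
        return sum(1 for r in self.reports.values() if not r.missing)

    def report(self, role: Role) -> IndividualReport:
        return self.reports[role]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    couple_id: str
    field: str
    rule: str


def validate_record(couple: CoupleRecord,
                    physical_registry: Registry = PHYSICAL_ACTS,
                    psych_registry: Registry = PSYCH_ACTS) -> list[Violation]:
    """Check a couple record against the type invariants.

    Returns a (possibly empty) list of violations; never raises on content.
    """
    out: list[Violation] = []
    cid = couple.couple_id

    for role in ROLES:
        if role not in couple.reports:
            out.append(Violation(cid, f"reports[{role.value}]", "role_missing"))
    for role, rep in couple.reports.items():
        prefix = f"reports[{role.value}]"
        if rep.role is not role:
            out.append(Violation(cid, prefix, "role_mismatch"))
        if rep.missing:
            if rep.physical_acts or rep.injuries or rep.psych != EMPTY_PSYCH:
                out.append(Violation(cid, prefix, "missing_report_nonempty"))
            continue

        seen: set = set()
        reported: set = set()
        for par in rep.physical_acts:
            if par.act_id not in physical_registry:
                out.append(Violation(cid, f"{prefix}.physical_acts",
                                     "unknown_physical_act"))
            key = (par.act_id, par.direction)
            if key in seen:
                out.append(Violation(cid, f"{prefix}.physical_acts",
                                     "duplicate_act_report"))
            seen.add(key)
            if par.frequency > Frequency.NEVER:
                reported.add(key)
        for inj in rep.injuries:
            if inj.act_id not in physical_registry:
                out.append(Violation(cid, f"{prefix}.injuries",
                                     "unknown_physical_act"))
            elif (inj.act_id, inj.direction) not in reported:
                out.append(Violation(cid, f"{prefix}.injuries",
                                     "injury_without_act"))
        psych = rep.psych
        for act_id, _freq in psych.acts:
            if act_id not in psych_registry:
                out.append(Violation(cid, f"{prefix}.psych.acts",
                                     "unknown_psych_act"))
        if psych.attribution and not psych.endorsed_acts():
            out.append(Violation(cid, f"{prefix}.psych.attribution",
                                 "attribution_without_acts"))
    return out


# ---------------------------------------------------------------------------
# Wide CSV schema (one row per respondent)
# ---------------------------------------------------------------------------

_DIR_SUFFIX = {ReportDirection.PERPETRATED_BY_SELF: "perp",
               ReportDirection.PERPETRATED_BY_PARTNER: "vict"}
_DIRECTIONS = tuple(_DIR_SUFFIX)
_SEP = ";"


def csv_columns(physical_registry: Registry = PHYSICAL_ACTS,
                psych_registry: Registry = PSYCH_ACTS) -> list[str]:
    cols = ["couple_id", "role", "missing"]
    for act_id in physical_registry:
        for d in _DIRECTIONS:
            cols.append(f"phy_{act_id}_{_DIR_SUFFIX[d]}")
    for act_id in physical_registry:
        for d in _DIRECTIONS:
            cols.append(f"inj_{act_id}_{_DIR_SUFFIX[d]}")
    cols.append("psy_screen")
    cols.extend(f"psy_act_{act_id}" for act_id in psych_registry)
    cols.extend(["psy_attrib", "psy_safety", "psy_interfere", "other_is_ipv"])
    return cols


def _report_to_row(couple_id: str, rep: IndividualReport,
                   other_is_ipv: bool = True) -> dict:
    row = {c: "" for c in csv_columns()}
    row["couple_id"] = couple_id
    row["role"] = rep.role.value
    row["missing"] = "1" if rep.missing else "0"
    if rep.missing:
        return row
    for par in rep.physical_acts:
        if par.frequency > Frequency.NEVER:
            row[f"phy_{par.act_id}_{_DIR_SUFFIX[par.direction]}"] = par.frequency.label
    for inj in rep.injuries:
        col = f"inj_{inj.act_id}_{_DIR_SUFFIX[inj.direction]}"
        row[col] = _SEP.join(sorted(i.value for i in inj.impacts))
    p = rep.psych
    row["psy_screen"] = _SEP.join(sorted(s.value for s in p.screener))
    for act_id, freq in p.acts:
        if freq > Frequency.NEVER:
            row[f"psy_act_{act_id}"] = freq.label
    row["psy_attrib"] = "1" if p.attribution else "0"
    row["psy_safety"] = _SEP.join(sorted(s.value for s in p.safety_fears))
    row["psy_interfere"] = _SEP.join(sorted(s.value for s in p.interference))
    row["other_is_ipv"] = "1" if other_is_ipv else "0"
    return row


def records_to_frame(records: Iterable[CoupleRecord]) -> pd.DataFrame:
    rows = []
    for couple in records:
        for role in ROLES:
            rows.append(_report_to_row(couple.couple_id, couple.reports[role]))
    return pd.DataFrame(rows, columns=csv_columns())


def _parse_set(cell: str, enum_cls) -> frozenset:
    if not cell:
        return frozenset()
    try:
        return frozenset(enum_cls(tok) for tok in cell.split(_SEP) if tok)
    except ValueError as exc:
        raise SchemaError(str(exc)) from None


def _row_to_report(row: Mapping[str, str], rownum: int,
                   physical_registry: Registry,
                   psych_registry: Registry) -> IndividualReport:
    try:
        role = Role(row["role"])
    except ValueError:
        raise SchemaError(f"row {rownum}: unknown role {row.get('role')!r}") from None
    if str(row.get("missing", "0")).strip() in ("1", "true", "True"):
        return missing_report(role)

    other_ok = str(row.get("other_is_ipv", "0")).strip() in ("1", "true", "True")
    acts, injuries = [], []
    for act_id in physical_registry:
        if act_id == "other" and not other_ok:
            continue  # write-in coded as not IPV
        for d in _DIRECTIONS:
            cell = row.get(f"phy_{act_id}_{_DIR_SUFFIX[d]}", "")
            if cell:
                acts.append(PhysicalActReport(act_id, d, Frequency.from_label(cell)))
            icell = row.get(f"inj_{act_id}_{_DIR_SUFFIX[d]}", "")
            if icell:
                injuries.append(InjuryReport(act_id, d, _parse_set(icell, Impact)))
    psy_acts = []
    for act_id in psych_registry:
        cell = row.get(f"psy_act_{act_id}", "")
        if cell:
            psy_acts.append((act_id, Frequency.from_label(cell)))
    psych = PsychSection(
        screener=_parse_set(row.get("psy_screen", ""), Screener),
        acts=tuple(psy_acts),
        attribution=str(row.get("psy_attrib", "0")).strip() in ("1", "true", "True"),
        safety_fears=_parse_set(row.get("psy_safety", ""), SafetyFear),
        interference=_parse_set(row.get("psy_interfere", ""), Interference),
    )
    return IndividualReport(role=role, physical_acts=tuple(acts),
                            injuries=tuple(injuries), psych=psych)


def frame_to_records(frame: pd.DataFrame,
                     physical_registry: Registry = PHYSICAL_ACTS,
                     psych_registry: Registry = PSYCH_ACTS) -> list[CoupleRecord]:
    if "couple_id" not in frame.columns or "role" not in frame.columns:
        raise SchemaError("records CSV must have couple_id and role columns")
    by_couple: dict[str, dict[Role, IndividualReport]] = {}
    for i, row in enumerate(frame.fillna("").astype(str).to_dict("records")):
        rownum = i + 2  # 1-based, after header
        cid = row["couple_id"]
        if not cid:
            raise SchemaError(f"row {rownum}: empty couple_id")
        rep = _row_to_report(row, rownum, physical_registry, psych_registry)
        reports = by_couple.setdefault(cid, {})
        if rep.role in reports:
            raise SchemaError(f"row {rownum}: duplicate report for couple "
                              f"{cid!r} role {rep.role.value!r}")
        reports[rep.role] = rep
    records = []
    for cid, reports in by_couple.items():
        for role in ROLES:
            reports.setdefault(role, missing_report(role))
        records.append(CoupleRecord(cid, reports))
    return records


def write_records_csv(records: Iterable[CoupleRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path,
                     physical_registry: Registry = PHYSICAL_ACTS,
                     psych_registry: Registry = PSYCH_ACTS) -> list[CoupleRecord]:
    """Read respondent rows and assemble couple records.

    A couple present with a single row gets a missing marker for the absent
    role; duplicate (couple, role) rows raise :class:`SchemaError`.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty records file") from None
    if frame.empty:
        raise SchemaError(f"{path}: no respondent rows")
    return frame_to_records(frame, physical_registry, psych_registry)
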