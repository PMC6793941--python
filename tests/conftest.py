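"""Shared fixtures and an independent brute-force classification oracle.

The oracle re-evaluates the six couple-category definitions directly from
the raw reports, written as a literal transcription of the definitions and
sharing no code with ``ipvpipe.classify``.  It is used to cross-check the
classifier over an exhaustively enumerated small universe of couples.
"""

from __future__ import annotations

import itertools

import pytest

from ipvpipe.fm_core import (
    CoupleRecord,
    Frequency,
    Impact,
    IndividualReport,
    InjuryReport,
    PhysicalActReport,
    PsychSection,
    ReportDirection,
    Role,
    Screener,
    missing_report,
)

DANGEROUS = {"choked", "hit_with_object_that_could_hurt"}


# ---------------------------------------------------------------------------
# Record builders
# ---------------------------------------------------------------------------

def make_couple(couple_id="C1", woman=None, partner=None):
    """Couple from two reports; None means a missing marker."""
    return CoupleRecord(couple_id, {
        Role.PREGNANT_WOMAN: woman or missing_report(Role.PREGNANT_WOMAN),
        Role.PARTNER: partner or missing_report(Role.PARTNER),
    })


# Physical scenario codes for one direction of aggression:
#   key -> (list of (act_id, Frequency), victim impact or None)
PHY_SCENARIOS = {
    "none": ([], None),
    "once": ([("pushed_or_shoved", Frequency.ONCE)], None),
    "twice": ([("pushed_or_shoved", Frequency.TWICE)], None),
    "dangerous": ([("choked", Frequency.ONCE)], None),
    "injury": ([("pushed_or_shoved", Frequency.ONCE)], Impact.BRUISE_OR_WELT),
    "fear": ([("pushed_or_shoved", Frequency.ONCE)],
             Impact.FEARED_FOR_OWN_SAFETY),
}

# Psychological scenario codes for one victim:
PSY_SCENARIOS = {
    "none": PsychSection(),
    "cs": PsychSection(screener=frozenset({Screener.STRESS}),
                       acts=(("insulted_or_sworn_at", Frequency.ONCE),),
                       attribution=True),
    "acts_only": PsychSection(acts=(("insulted_or_sworn_at", Frequency.ONCE),)),
}


def scenario_couple(phy_w2p, phy_p2w, psy_woman, psy_partner, couple_id="C1"):
    """Couple whose both informants faithfully report the given scenarios.

    ``phy_w2p``/``phy_p2w`` are PHY_SCENARIOS keys for the
    woman-perpetrated and partner-perpetrated directions; ``psy_woman``/
    ``psy_partner`` are PSY_SCENARIOS keys for each member as *victim*.
    """
    acts_w2p, imp_w2p = PHY_SCENARIOS[phy_w2p]
    acts_p2w, imp_p2w = PHY_SCENARIOS[phy_p2w]

    def report(role):
        # perpetration of this role, victimization of this role
        mine = acts_w2p if role is Role.PREGNANT_WOMAN else acts_p2w
        theirs = acts_p2w if role is Role.PREGNANT_WOMAN else acts_w2p
        my_injury = imp_p2w if role is Role.PREGNANT_WOMAN else imp_w2p
        pacts = [PhysicalActReport(a, ReportDirection.PERPETRATED_BY_SELF, f)
                 for a, f in mine]
        pacts += [PhysicalActReport(a, ReportDirection.PERPETRATED_BY_PARTNER, f)
                  for a, f in theirs]
        injuries = ()
        if my_injury is not None and theirs:
            injuries = (InjuryReport(theirs[0][0],
                                     ReportDirection.PERPETRATED_BY_PARTNER,
                                     frozenset({my_injury})),)
        psy = PSY_SCENARIOS[psy_woman if role is Role.PREGNANT_WOMAN
                            else psy_partner]
        return IndividualReport(role=role, physical_acts=tuple(pacts),
                                injuries=injuries, psych=psy)

    return make_couple(couple_id, report(Role.PREGNANT_WOMAN),
                       report(Role.PARTNER))


def small_universe():
    """Exhaustive enumeration over the closed scenario universe."""
    combos = itertools.product(PHY_SCENARIOS, PHY_SCENARIOS,
                               PSY_SCENARIOS, PSY_SCENARIOS)
    for i, (pw, pp, qw, qp) in enumerate(combos):
        yield (pw, pp, qw, qp), scenario_couple(pw, pp, qw, qp, f"U{i:04d}")


# ---------------------------------------------------------------------------
# Independent oracle: literal transcription of the six definitions
# ---------------------------------------------------------------------------

def _oracle_acts(couple, perp_role):
    """Acts perpetrated by perp_role per the union of both informants."""
    victim_role = (Role.PARTNER if perp_role is Role.PREGNANT_WOMAN
                   else Role.PREGNANT_WOMAN)
    acts = {}
    perp = couple.reports[perp_role]
    if not perp.missing:
        for p in perp.physical_acts:
            if (p.direction is ReportDirection.PERPETRATED_BY_SELF
                    and p.frequency != Frequency.NEVER):
                acts[p.act_id] = max(acts.get(p.act_id, Frequency.NEVER),
                                     p.frequency)
    vict = couple.reports[victim_role]
    if not vict.missing:
        for p in vict.physical_acts:
            if (p.direction is ReportDirection.PERPETRATED_BY_PARTNER
                    and p.frequency != Frequency.NEVER):
                acts[p.act_id] = max(acts.get(p.act_id, Frequency.NEVER),
                                     p.frequency)
    return acts


def _oracle_phy_impact(couple, perp_role):
    """Any impact making perp_role's aggression clinically significant."""
    victim_role = (Role.PARTNER if perp_role is Role.PREGNANT_WOMAN
                   else Role.PREGNANT_WOMAN)
    acts = _oracle_acts(couple, perp_role)
    if not acts:
        return False
    if any(a in DANGEROUS for a in acts):
        return True
    perp, vict = couple.reports[perp_role], couple.reports[victim_role]
    for inj in () if vict.missing else vict.injuries:
        if inj.direction is ReportDirection.PERPETRATED_BY_PARTNER and inj.impacts:
            return True  # victim-reported injury, incl. fear for own safety
    for inj in () if perp.missing else perp.injuries:
        if (inj.direction is ReportDirection.PERPETRATED_BY_SELF
                and inj.impacts - {Impact.FEARED_FOR_OWN_SAFETY}):
            return True  # perpetrator-confirmed infliction, fear excluded
    return False


def _oracle_psy_cs(couple, victim_role):
    rep = couple.reports[victim_role]
    if rep.missing:
        return False
    p = rep.psych
    endorsed = [a for a, f in p.acts if f != Frequency.NEVER]
    if not endorsed:
        return False
    return ((p.attribution and len(p.screener) > 0)
            or len(p.safety_fears) > 0 or len(p.interference) > 0)


def oracle_category(couple):
    """Six-category label per the definitions, evaluated from scratch."""
    phy_acts = any(_oracle_acts(couple, r) for r in Role)
    phy_impact = any(_oracle_phy_impact(couple, r) for r in Role)
    psy_cs = any(_oracle_psy_cs(couple, r) for r in Role)
    if not phy_acts and not psy_cs:
        return "no_ipv"                          # (1)
    if phy_acts and not phy_impact and not psy_cs:
        return "li_phy_only"                     # (2)
    if phy_impact and not psy_cs:
        return "cs_phy_only"                     # (3)
    if psy_cs and not phy_acts:
        return "cs_psy_only"                     # (4)
    if psy_cs and phy_acts and not phy_impact:
        return "cs_psy_and_li_phy"               # (5)
    return "cs_psy_and_cs_phy"                   # (6)


# ---------------------------------------------------------------------------
# Session fixtures: the exact-count study fixture, classified once
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def study_fixture():
    from ipvpipe.synthdata import exact_study_fixture
    return exact_study_fixture()


@pytest.fixture(scope="session")
def study_analyzed(study_fixture):
    records, _ = study_fixture
    return [c for c in records if c.n_reports >= 1]


@pytest.fixture(scope="session")
def study_classifications(study_analyzed):
    from ipvpipe.classify import classify_records
    return classify_records(study_analyzed)
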