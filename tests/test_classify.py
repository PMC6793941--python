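"""Severity, category, direction and repetition classification."""

import pytest
from hypothesis import given, settings, strategies as st

from ipvpipe.classify import (
    Category,
    ContractError,
    Direction,
    DirectionLabel,
    Severity,
    classify_couple,
    classify_physical,
    classify_psych,
    couple_act_occurrence,
    is_repeated,
)
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
)

from conftest import (
    PHY_SCENARIOS,
    PSY_SCENARIOS,
    make_couple,
    oracle_category,
    scenario_couple,
    small_universe,
)


class TestCoupleActOccurrence:
    def test_same_event_reported_by_both_counts_once(self):
        couple = scenario_couple("none", "once", "none", "none")
        # both informants report the partner-to-woman push
        occ = couple_act_occurrence(couple, Direction.PARTNER_TO_WOMAN)
        assert occ == {"pushed_or_shoved": Frequency.ONCE}
        assert couple_act_occurrence(couple, Direction.WOMAN_TO_PARTNER) == {}

    def test_union_with_missing_victim(self):
        perp = IndividualReport(
            role=Role.PREGNANT_WOMAN,
            physical_acts=(PhysicalActReport(
                "slapped", ReportDirection.PERPETRATED_BY_SELF,
                Frequency.ONCE),))
        couple = make_couple(woman=perp)
        occ = couple_act_occurrence(couple, Direction.WOMAN_TO_PARTNER)
        assert occ == {"slapped": Frequency.ONCE}

    def test_discordant_frequencies_resolve_to_maximum(self):
        woman = IndividualReport(
            role=Role.PREGNANT_WOMAN,
            physical_acts=(PhysicalActReport(
                "grabbed", ReportDirection.PERPETRATED_BY_PARTNER,
                Frequency.TWICE),))
        partner = IndividualReport(
            role=Role.PARTNER,
            physical_acts=(PhysicalActReport(
                "grabbed", ReportDirection.PERPETRATED_BY_SELF,
                Frequency.SIX_PLUS),))
        couple = make_couple(woman=woman, partner=partner)
        occ = couple_act_occurrence(couple, Direction.PARTNER_TO_WOMAN)
        assert occ == {"grabbed": Frequency.SIX_PLUS}

    def test_requires_at_least_one_report(self):
        with pytest.raises(ContractError):
            couple_act_occurrence(make_couple(), Direction.WOMAN_TO_PARTNER)


class TestClassifyPhysical:
    @pytest.mark.parametrize("scenario, expected", [
        ("none", Severity.NONE),
        ("once", Severity.LI),
        ("twice", Severity.LI),
        ("injury", Severity.CS),      # bruise or welt
        ("dangerous", Severity.CS),   # choking, no injury follow-up
        ("fear", Severity.CS),        # victim feared for own safety
    ])
    def test_severity_clauses(self, scenario, expected):
        couple = scenario_couple("none", scenario, "none", "none")
        assert classify_physical(couple, Direction.PARTNER_TO_WOMAN) is expected

    def test_perpetrator_reported_injury_satisfies_impact(self):
        # the victim's report is missing entirely; the perpetrator admits
        # inflicting a bruise (union rule)
        perp = IndividualReport(
            role=Role.PARTNER,
            physical_acts=(PhysicalActReport(
                "slapped", ReportDirection.PERPETRATED_BY_SELF,
                Frequency.ONCE),),
            injuries=(InjuryReport("slapped",
                                   ReportDirection.PERPETRATED_BY_SELF,
                                   frozenset({Impact.BRUISE_OR_WELT})),))
        couple = make_couple(partner=perp)
        assert classify_physical(couple, Direction.PARTNER_TO_WOMAN) \
            is Severity.CS

    def test_perpetrator_reported_fear_does_not_qualify(self):
        # fear is the victim's experience; a perpetrator-side fear report
        # alone leaves the direction low impact
        perp = IndividualReport(
            role=Role.PARTNER,
            physical_acts=(PhysicalActReport(
                "slapped", ReportDirection.PERPETRATED_BY_SELF,
                Frequency.ONCE),),
            injuries=(InjuryReport(
                "slapped", ReportDirection.PERPETRATED_BY_SELF,
                frozenset({Impact.FEARED_FOR_OWN_SAFETY})),))
        couple = make_couple(partner=perp)
        assert classify_physical(couple, Direction.PARTNER_TO_WOMAN) \
            is Severity.LI

    def test_dangerous_act_set_is_configurable(self):
        couple = scenario_couple("none", "dangerous", "none", "none")
        assert classify_physical(couple, Direction.PARTNER_TO_WOMAN,
                                 dangerous_acts=frozenset()) is Severity.LI


class TestClassifyPsych:
    def test_attributed_acts_with_screener_are_cs(self):
        rep = IndividualReport(
            role=Role.PREGNANT_WOMAN,
            psych=PsychSection(screener=frozenset({Screener.STRESS}),
                               acts=(("insulted_or_sworn_at", Frequency.TWICE),),
                               attribution=True))
        assert classify_psych(rep)

    def test_acts_without_any_impact_clause_are_not_cs(self):
        rep = IndividualReport(
            role=Role.PREGNANT_WOMAN,
            psych=PsychSection(acts=(("insulted_or_sworn_at", Frequency.TWICE),)))
        assert not classify_psych(rep)

    def test_screener_without_acts_is_not_cs(self):
        rep = IndividualReport(
            role=Role.PREGNANT_WOMAN,
            psych=PsychSection(screener=frozenset({Screener.DEPRESSION})))
        assert not classify_psych(rep)

    def test_safety_fear_and_interference_routes(self):
        from ipvpipe.fm_core import Interference, SafetyFear
        acts = (("stalked", Frequency.ONCE),)
        safety = IndividualReport(
            role=Role.PARTNER,
            psych=PsychSection(acts=acts, safety_fears=frozenset(
                {SafetyFear.FEAR_OWN_SAFETY})))
        interfere = IndividualReport(
            role=Role.PARTNER,
            psych=PsychSection(acts=acts, interference=frozenset(
                {Interference.WORK})))
        assert classify_psych(safety) and classify_psych(interfere)

    def test_attribution_without_screener_is_not_cs(self):
        # the attribution item refers back to the screened distress; with
        # no screener endorsed there is nothing to attribute to
        rep = IndividualReport(
            role=Role.PARTNER,
            psych=PsychSection(acts=(("stalked", Frequency.ONCE),),
                               attribution=True))
        assert not classify_psych(rep)


class TestClassifyCouple:
    @pytest.mark.parametrize("scenarios, expected", [
        (("none", "none", "none", "none"), Category.NO_IPV),
        (("once", "none", "none", "none"), Category.LI_PHY_ONLY),
        (("none", "injury", "none", "none"), Category.CS_PHY_ONLY),
        (("none", "none", "cs", "none"), Category.CS_PSY_ONLY),
        (("once", "none", "cs", "none"), Category.CS_PSY_AND_LI_PHY),
        (("injury", "none", "none", "cs"), Category.CS_PSY_AND_CS_PHY),
        # psych acts without impact never cross the threshold on their own
        (("none", "none", "acts_only", "acts_only"), Category.NO_IPV),
    ])
    def test_category_assignment(self, scenarios, expected):
        assert classify_couple(scenario_couple(*scenarios)).category is expected

    def test_direction_labels_follow_the_perpetrator(self):
        one_way = classify_couple(scenario_couple("once", "none", "none", "none"))
        assert one_way.direction_phy_li is DirectionLabel.WOMAN_TO_PARTNER
        both = classify_couple(scenario_couple("once", "once", "none", "none"))
        assert both.direction_phy_li is DirectionLabel.BIDIRECTIONAL

    def test_cs_direction_counts_only_cs_sides(self):
        # woman-to-partner direction is CS, partner-to-woman merely LI:
        # the couple is CS overall with a one-way CS direction label
        cls = classify_couple(scenario_couple("injury", "once", "none", "none"))
        assert cls.category is Category.CS_PHY_ONLY
        assert cls.direction_phy_cs is DirectionLabel.WOMAN_TO_PARTNER
        assert cls.direction_phy_li is None

    def test_psych_direction_named_by_perpetrator_of_victim(self):
        # the pregnant woman is the psychological victim
        cls = classify_couple(scenario_couple("none", "none", "cs", "none"))
        assert cls.direction_psy is DirectionLabel.PARTNER_TO_WOMAN
        cls = classify_couple(scenario_couple("none", "none", "cs", "cs"))
        assert cls.direction_psy is DirectionLabel.BIDIRECTIONAL

    def test_both_missing_rejected(self):
        with pytest.raises(ContractError):
            classify_couple(make_couple())


class TestIsRepeated:
    def test_one_act_once_per_partner_is_not_repeated(self):
        couple = scenario_couple("once", "once", "none", "none")
        assert not is_repeated(couple, "physical")

    def test_single_act_twice_is_repeated(self):
        couple = scenario_couple("twice", "none", "none", "none")
        assert is_repeated(couple, "physical")

    def test_two_distinct_acts_once_each_same_perpetrator(self):
        rep = IndividualReport(
            role=Role.PREGNANT_WOMAN,
            physical_acts=(
                PhysicalActReport("slapped",
                                  ReportDirection.PERPETRATED_BY_SELF,
                                  Frequency.ONCE),
                PhysicalActReport("grabbed",
                                  ReportDirection.PERPETRATED_BY_SELF,
                                  Frequency.ONCE),
            ))
        assert is_repeated(make_couple(woman=rep), "physical")

    def test_exhaustive_single_act_frequencies(self):
        # oracle: a single act is repeated iff its minimum count is >= 2
        from ipvpipe.fm_core import MIN_COUNTS
        for freq, floor in MIN_COUNTS.items():
            if freq is Frequency.NEVER:
                continue
            rep = IndividualReport(
                role=Role.PARTNER,
                physical_acts=(PhysicalActReport(
                    "kicked", ReportDirection.PERPETRATED_BY_SELF, freq),))
            assert is_repeated(make_couple(partner=rep), "physical") \
                == (floor >= 2)

    def test_contract_on_nonpositive_couple(self):
        couple = scenario_couple("none", "none", "none", "none")
        with pytest.raises(ContractError):
            is_repeated(couple, "physical")
        with pytest.raises(ContractError):
            is_repeated(couple, "psychological")


def _swap_roles(couple):
    """Mirror a couple: each report reassigned to the opposite role."""
    swapped = {}
    for role, rep in couple.reports.items():
        new_role = (Role.PARTNER if role is Role.PREGNANT_WOMAN
                    else Role.PREGNANT_WOMAN)
        swapped[new_role] = IndividualReport(
            role=new_role, physical_acts=rep.physical_acts,
            injuries=rep.injuries, psych=rep.psych, missing=rep.missing)
    return CoupleRecord(couple.couple_id, swapped)


_MIRROR = {DirectionLabel.WOMAN_TO_PARTNER: DirectionLabel.PARTNER_TO_WOMAN,
           DirectionLabel.PARTNER_TO_WOMAN: DirectionLabel.WOMAN_TO_PARTNER,
           DirectionLabel.BIDIRECTIONAL: DirectionLabel.BIDIRECTIONAL,
           None: None}

_SEVERITY_RANK = {Category.NO_IPV: 0, Category.LI_PHY_ONLY: 1,
                  Category.CS_PHY_ONLY: 2, Category.CS_PSY_ONLY: 2,
                  Category.CS_PSY_AND_LI_PHY: 3, Category.CS_PSY_AND_CS_PHY: 4}


class TestUniverseProperties:
    def test_matches_brute_force_oracle_on_closed_universe(self):
        """Classifier equals a from-scratch transcription of the six
        definitions over every couple in the enumerated universe."""
        for scenarios, couple in small_universe():
            got = classify_couple(couple).category.value
            want = oracle_category(couple)
            assert got == want, (scenarios, got, want)

    def test_role_symmetry(self):
        """Swapping roles mirrors direction labels and changes nothing else."""
        for _, couple in small_universe():
            a = classify_couple(couple)
            b = classify_couple(_swap_roles(couple))
            assert a.category is b.category
            assert b.direction_phy_li is _MIRROR[a.direction_phy_li]
            assert b.direction_phy_cs is _MIRROR[a.direction_phy_cs]
            assert b.direction_psy is _MIRROR[a.direction_psy]
            assert a.repeated_phy == b.repeated_phy
            assert a.repeated_psy == b.repeated_psy

    def test_adding_injury_impact_never_lowers_severity(self):
        """Monotonicity: attaching a victim-reported bruise to an occurring
        act can only move the category toward more severe."""
        for _, couple in small_universe():
            cls = classify_couple(couple)
            for direction in Direction:
                occ = couple_act_occurrence(couple, direction)
                if not occ:
                    continue
                victim_role = (Role.PREGNANT_WOMAN
                               if direction is Direction.PARTNER_TO_WOMAN
                               else Role.PARTNER)
                vic = couple.reports[victim_role]
                act_id = next(iter(occ))
                augmented = IndividualReport(
                    role=vic.role, physical_acts=vic.physical_acts,
                    injuries=vic.injuries + (InjuryReport(
                        act_id, ReportDirection.PERPETRATED_BY_PARTNER,
                        frozenset({Impact.BRUISE_OR_WELT})),),
                    psych=vic.psych)
                reports = dict(couple.reports)
                reports[victim_role] = augmented
                worse = classify_couple(CoupleRecord(couple.couple_id, reports))
                assert _SEVERITY_RANK[worse.category] \
                    >= _SEVERITY_RANK[cls.category]

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_determinism_and_partition(self, data):
        keys_phy = sorted(PHY_SCENARIOS)
        keys_psy = sorted(PSY_SCENARIOS)
        scen = (data.draw(st.sampled_from(keys_phy)),
                data.draw(st.sampled_from(keys_phy)),
                data.draw(st.sampled_from(keys_psy)),
                data.draw(st.sampled_from(keys_psy)))
        couple = scenario_couple(*scen)
        first = classify_couple(couple)
        second = classify_couple(couple)
        assert first == second
        assert first.category in Category
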