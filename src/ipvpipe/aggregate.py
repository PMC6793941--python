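"""Prevalence, direction, concordance and sensitivity summaries.

Builds the couple-level output tables: per-category prevalence with overlap
rollups, direction/act/impact breakdowns per IPV type, intradyadic
concordance on dual-report couples, two-proportion chi-squared comparisons,
worst-case missingness bounds, and a deterministic plain-text rendering
with small-cell disclosure masking.

Percentages are rounded half away from zero to one decimal and computed
exactly from integer counts (no float division before rounding).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .classify import (
    ANY_PHY_CATEGORIES,
    CATEGORIES,
    CS_PHY_CATEGORIES,
    CS_PSY_CATEGORIES,
    LI_PHY_CATEGORIES,
    Category,
    CoupleClassification,
    Direction,
    DirectionLabel,
    DIRECTIONS,
    PERPETRATOR,
    Severity,
    VICTIM,
    couple_act_occurrence,
    couple_direction_impacts,
)
from .fm_core import (
    CoupleRecord,
    Frequency,
    Impact,
    PHYSICAL_ACTS,
    PSYCH_ACTS,
    ReportDirection,
    Role,
)


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (decimal ROUND_HALF_UP semantics)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denominator: int, decimals: int = 1) -> float:
    """Exact integer-ratio percentage, rounded half away from zero."""
    if denominator == 0:
        raise ValueError("percentage with zero denominator")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100 * count) / Decimal(denominator))
                 .quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Prevalence (six categories + overlap rollups)
# ---------------------------------------------------------------------------

ROLLUPS = ("any_ipv", "any_phy", "cs_phy", "cs_psy", "cs_phy_and_cs_psy")


@dataclass(frozen=True)
class PrevalenceReport:
    denominator: int
    counts: Mapping[Category, int]
    rollup_counts: Mapping[str, int]
    percents: Mapping[Category, float]
    rollup_percents: Mapping[str, float]


def prevalence(classifications: Sequence[CoupleClassification],
               denominator: Optional[int] = None) -> PrevalenceReport:
    """Category counts, overlap rollups and rounded percentages.

    The denominator defaults to the number of classified couples (couples
    with at least one report); a supplied denominator that disagrees is
    used anyway after a warning, so callers can quote prevalence against an
    externally fixed sample size.
    """
    n = len(classifications)
    if denominator is None:
        denominator = n
    elif denominator != n:
        warnings.warn(f"denominator {denominator} != {n} classifications; "
                      "proceeding with supplied denominator", stacklevel=2)
    if denominator < 1:
        raise ValueError("denominator must be >= 1")

    counts = Counter(c.category for c in classifications)
    counts = {cat: counts.get(cat, 0) for cat in CATEGORIES}
    rollups = {
        "any_ipv": sum(v for cat, v in counts.items() if cat is not Category.NO_IPV),
        "any_phy": sum(v for cat, v in counts.items() if cat in ANY_PHY_CATEGORIES),
        "cs_phy": sum(v for cat, v in counts.items() if cat in CS_PHY_CATEGORIES),
        "cs_psy": sum(v for cat, v in counts.items() if cat in CS_PSY_CATEGORIES),
        "cs_phy_and_cs_psy": counts[Category.CS_PSY_AND_CS_PHY],
    }
    return PrevalenceReport(
        denominator=denominator,
        counts=counts,
        rollup_counts=rollups,
        percents={cat: percent(v, denominator) for cat, v in counts.items()},
        rollup_percents={k: percent(v, denominator) for k, v in rollups.items()},
    )


def prevalence_frame(report: PrevalenceReport) -> pd.DataFrame:
    rows = [{"row": cat.value, "couples": report.counts[cat],
             "percent": report.percents[cat]} for cat in CATEGORIES]
    rows += [{"row": k, "couples": report.rollup_counts[k],
              "percent": report.rollup_percents[k]} for k in ROLLUPS]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Direction tables (per IPV type), with act / impact tallies
# ---------------------------------------------------------------------------

IPV_TYPES = ("phy_li", "phy_cs", "psy_cs")

_TYPE_CATEGORIES = {
    "phy_li": LI_PHY_CATEGORIES,
    "phy_cs": CS_PHY_CATEGORIES,
    "psy_cs": CS_PSY_CATEGORIES,
}
_TYPE_DIRECTION_ATTR = {
    "phy_li": "direction_phy_li",
    "phy_cs": "direction_phy_cs",
    "psy_cs": "direction_psy",
}

#: Table columns: one-way couples contribute a single victim column,
#: bidirectional couples one column per victim.
ColumnKey = tuple[str, Role]  # ("one_way" | "bidirectional", victim role)
COLUMN_KEYS: tuple[ColumnKey, ...] = (
    ("one_way", Role.PREGNANT_WOMAN),
    ("one_way", Role.PARTNER),
    ("bidirectional", Role.PREGNANT_WOMAN),
    ("bidirectional", Role.PARTNER),
)


@dataclass(frozen=True)
class DirectionTable:
    ipv_type: str
    denominator: int
    direction_counts: Mapping[DirectionLabel, int]
    direction_percents: Mapping[DirectionLabel, float]
    act_counts: Mapping[ColumnKey, Counter]
    impact_counts: Mapping[ColumnKey, Counter]


def _phy_active_directions(c: CoupleClassification, ipv_type: str) -> list[Direction]:
    if ipv_type == "phy_cs":
        return [d for d in DIRECTIONS if c.phy_severity[d] is Severity.CS]
    return [d for d in DIRECTIONS if c.phy_severity[d] >= Severity.LI]


def direction_table(classifications: Sequence[CoupleClassification],
                    couples: Iterable[CoupleRecord],
                    ipv_type: str) -> DirectionTable:
    """Direction split plus per-act and per-impact couple tallies.

    One count per couple per act (or impact) per direction: within a couple
    the two informants' reports of the same act merge before tallying.
    """
    if ipv_type not in IPV_TYPES:
        raise ValueError(f"unknown ipv_type: {ipv_type!r}")
    by_id = {c.couple_id: c for c in couples}
    members = [c for c in classifications
               if c.category in _TYPE_CATEGORIES[ipv_type]]
    attr = _TYPE_DIRECTION_ATTR[ipv_type]

    dcounts = Counter(getattr(c, attr) for c in members)
    dcounts = {lbl: dcounts.get(lbl, 0) for lbl in DirectionLabel}
    denom = len(members)
    dpercents = {lbl: (percent(v, denom) if denom else 0.0)
                 for lbl, v in dcounts.items()}

    acts: dict[ColumnKey, Counter] = {k: Counter() for k in COLUMN_KEYS}
    impacts: dict[ColumnKey, Counter] = {k: Counter() for k in COLUMN_KEYS}
    for cls in members:
        couple = by_id.get(cls.couple_id)
        if couple is None:
            continue
        label = getattr(cls, attr)
        group = ("bidirectional" if label is DirectionLabel.BIDIRECTIONAL
                 else "one_way")
        if ipv_type in ("phy_li", "phy_cs"):
            for d in _phy_active_directions(cls, ipv_type):
                key = (group, VICTIM[d])
                for act_id in couple_act_occurrence(couple, d):
                    acts[key][act_id] += 1
                if ipv_type == "phy_cs":
                    victim_fear = couple_direction_impacts(
                        couple, d, victim_only=True)
                    for imp in couple_direction_impacts(couple, d):
                        if (imp is Impact.FEARED_FOR_OWN_SAFETY
                                and imp not in victim_fear):
                            continue  # fear counts from the victim only
                        impacts[key][imp.value] += 1
        else:
            for role, flag in cls.psy_cs.items():
                if not flag:
                    continue
                key = (group, role)
                report = couple.reports[role]
                for act_id, _f in report.psych.endorsed_acts():
                    acts[key][act_id] += 1
                for s in report.psych.screener:
                    impacts[key][f"screener_{s.value}"] += 1
                for s in report.psych.safety_fears:
                    impacts[key][f"safety_{s.value}"] += 1
                for s in report.psych.interference:
                    impacts[key][f"interference_{s.value}"] += 1
    return DirectionTable(ipv_type=ipv_type, denominator=denom,
                          direction_counts=dcounts,
                          direction_percents=dpercents,
                          act_counts=acts, impact_counts=impacts)


# ---------------------------------------------------------------------------
# Small-cell disclosure masking
# ---------------------------------------------------------------------------

def mask(count: int, threshold: int = 3) -> str:
    """Masked rendering of a small cell: 0 -> "-", 1..threshold-1 -> "<t".

    Masking is a pure rendering layer -- the unmasked counts are kept
    internally and in the unmasked CSV outputs.
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    if threshold < 1:
        raise ValueError("mask threshold must be >= 1")
    if count == 0:
        return "-"
    if count < threshold:
        return f"<{threshold}"
    return str(count)


# ---------------------------------------------------------------------------
# Two-proportion chi-squared
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def compare_rates(count_a: int, count_b: int, n_a: int, n_b: int,
                  alpha: float = 0.05, yates: bool = False) -> ComparisonResult:
    """Pearson chi-squared on the 2x2 table of two independent proportions.

    No continuity correction by default; set ``yates`` for the corrected
    statistic.  Degenerate tables (all successes or all failures) carry no
    evidence of a difference and return statistic 0, p 1.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("denominators must be positive")
    if not (0 <= count_a <= n_a and 0 <= count_b <= n_b):
        raise ValueError("counts must lie within their denominators")
    total = count_a + count_b
    if total == 0 or total == n_a + n_b:
        return ComparisonResult(0.0, 1.0, False, alpha)
    table = [[count_a, n_a - count_a], [count_b, n_b - count_b]]
    res = stats.chi2_contingency(table, correction=yates)
    return ComparisonResult(float(res.statistic), float(res.pvalue),
                            bool(res.pvalue < alpha), alpha)


# ---------------------------------------------------------------------------
# Intradyadic concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceTable:
    direction: Direction
    both_yes: int
    both_no: int
    woman_yes_only: int
    partner_yes_only: int

    @property
    def n(self) -> int:
        return (self.both_yes + self.both_no
                + self.woman_yes_only + self.partner_yes_only)

    @property
    def agreement(self) -> float:
        """Percent of dual-report couples whose informants agree."""
        if self.n == 0:
            return float("nan")
        return percent(self.both_yes + self.both_no, self.n)


def _informant_indicator(report, direction: Direction) -> bool:
    """Any physical act in ``direction`` according to one report alone."""
    rd = (ReportDirection.PERPETRATED_BY_SELF
          if report.role is PERPETRATOR[direction]
          else ReportDirection.PERPETRATED_BY_PARTNER)
    return any(p.direction is rd and p.frequency > Frequency.NEVER
               for p in report.physical_acts)


def concordance(couples: Iterable[CoupleRecord],
                direction: Direction) -> ConcordanceTable:
    """2x2 occurrence agreement between the two informants.

    Restricted to couples with two non-missing reports; agreement is the
    share of couples where both reports indicate, or both deny, any
    physical act in the given direction.
    """
    yy = nn = wy = py = 0
    for couple in couples:
        if couple.n_reports < 2:
            continue
        w = _informant_indicator(couple.reports[Role.PREGNANT_WOMAN], direction)
        p = _informant_indicator(couple.reports[Role.PARTNER], direction)
        if w and p:
            yy += 1
        elif not w and not p:
            nn += 1
        elif w:
            wy += 1
        else:
            py += 1
    return ConcordanceTable(direction, yy, nn, wy, py)


# ---------------------------------------------------------------------------
# Missingness sensitivity bound
# ---------------------------------------------------------------------------

def missingness_bound(n_detected: int, n_assumed_positive: int,
                      denominator: int) -> float:
    """Prevalence under the assumption that unobserved couples are positive.

    ``100 * (detected + assumed) / denominator`` rounded to one decimal.
    With ``n_assumed_positive = 0`` this is the unadjusted prevalence of a
    subsample.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if min(n_detected, n_assumed_positive) < 0:
        raise ValueError("counts must be nonnegative")
    if n_detected + n_assumed_positive > denominator:
        raise ValueError("assumed positives exceed the denominator")
    return percent(n_detected + n_assumed_positive, denominator)


# ---------------------------------------------------------------------------
# Plain-text report rendering
# ---------------------------------------------------------------------------

_CATEGORY_TITLES = {
    Category.NO_IPV: "No IPV",
    Category.LI_PHY_ONLY: "Low impact physical IPV-only",
    Category.CS_PHY_ONLY: "Clinically significant physical IPV-only",
    Category.CS_PSY_ONLY: "Clinically significant psychological IPV-only",
    Category.CS_PSY_AND_LI_PHY: "CS psychological & low impact physical IPV",
    Category.CS_PSY_AND_CS_PHY: "CS psychological & CS physical IPV",
}
_ROLLUP_TITLES = {
    "any_ipv": "Any IPV", "any_phy": "Any physical IPV",
    "cs_phy": "CS physical IPV", "cs_psy": "CS psychological IPV",
    "cs_phy_and_cs_psy": "CS physical & CS psychological IPV",
}
_DIRECTION_TITLES = {
    DirectionLabel.PARTNER_TO_WOMAN: "Partner-to-pregnant-woman",
    DirectionLabel.WOMAN_TO_PARTNER: "Pregnant-woman-to-partner",
    DirectionLabel.BIDIRECTIONAL: "Bidirectional",
}
_TYPE_TITLES = {
    "phy_li": "Low impact physical IPV",
    "phy_cs": "Clinically significant physical IPV",
    "psy_cs": "Clinically significant psychological IPV",
}
_COLUMN_TITLES = {
    ("one_way", Role.PREGNANT_WOMAN): "One way / pregnant vic.",
    ("one_way", Role.PARTNER): "One way / partner vic.",
    ("bidirectional", Role.PREGNANT_WOMAN): "Bidirectional / pregnant vic.",
    ("bidirectional", Role.PARTNER): "Bidirectional / partner vic.",
}


def _row(label: str, cells: Sequence[str], width: int = 44,
         cell_width: int = 14) -> str:
    return label.ljust(width) + "".join(c.rjust(cell_width) for c in cells)


def direction_frame(table: DirectionTable,
                    mask_threshold: Optional[int] = None) -> pd.DataFrame:
    """Act/impact tallies as a tidy frame; masked when a threshold is given."""
    rows = []
    registry = PSYCH_ACTS if table.ipv_type == "psy_cs" else PHYSICAL_ACTS
    for kind, counters in (("act", table.act_counts),
                           ("impact", table.impact_counts)):
        keys: list[str]
        if kind == "act":
            keys = list(registry)
        else:
            seen = sorted({k for c in counters.values() for k in c})
            keys = seen
        for item in keys:
            row = {"kind": kind, "item": item}
            for col in COLUMN_KEYS:
                v = counters[col].get(item, 0)
                row[_COLUMN_TITLES[col]] = (mask(v, mask_threshold)
                                            if mask_threshold else v)
            rows.append(row)
    return pd.DataFrame(rows)


def render_report(prevalence_report: Optional[PrevalenceReport] = None,
                  direction_tables: Sequence[DirectionTable] = (),
                  concordance_tables: Sequence[ConcordanceTable] = (),
                  mask_threshold: int = 3,
                  alpha: float = 0.05,
                  yates: bool = False) -> str:
    """Deterministic text rendering of the analysis tables.

    Small act/impact cells are masked; one-way direction splits carry a
    significance column from the two-proportion chi-squared in place of
    typographic emphasis.
    """
    lines: list[str] = []
    if prevalence_report is not None:
        pr = prevalence_report
        lines.append(f"Prevalence of past-year IPV by subtype "
                     f"(N = {pr.denominator} couples)")
        lines.append(_row("", ["couples", "percent"]))
        for cat in CATEGORIES:
            lines.append(_row(_CATEGORY_TITLES[cat],
                              [str(pr.counts[cat]), f"{pr.percents[cat]:.1f}"]))
        for k in ROLLUPS:
            lines.append(_row(_ROLLUP_TITLES[k],
                              [str(pr.rollup_counts[k]),
                               f"{pr.rollup_percents[k]:.1f}"]))
        lines.append("")

    for table in direction_tables:
        lines.append(f"{_TYPE_TITLES[table.ipv_type]} "
                     f"(n = {table.denominator} couples)")
        cmp_cell = ""
        if table.denominator:
            one_way = compare_rates(
                table.direction_counts[DirectionLabel.WOMAN_TO_PARTNER],
                table.direction_counts[DirectionLabel.PARTNER_TO_WOMAN],
                table.denominator, table.denominator, alpha=alpha, yates=yates)
            cmp_cell = ("significant" if one_way.significant
                        else "not significant")
        for lbl in (DirectionLabel.PARTNER_TO_WOMAN,
                    DirectionLabel.WOMAN_TO_PARTNER,
                    DirectionLabel.BIDIRECTIONAL):
            lines.append(_row(
                _DIRECTION_TITLES[lbl],
                [str(table.direction_counts[lbl]),
                 f"{table.direction_percents[lbl]:.1f}"]))
        if cmp_cell:
            lines.append(_row("One-way split (chi-squared)", [cmp_cell]))
        frame = direction_frame(table, mask_threshold=mask_threshold)
        if not frame.empty:
            lines.append(_row("", [_COLUMN_TITLES[c].split(" / ")[1]
                                   for c in COLUMN_KEYS]))
            for _, r in frame.iterrows():
                lines.append(_row(f"  [{r['kind']}] {r['item']}",
                                  [str(r[_COLUMN_TITLES[c]])
                                   for c in COLUMN_KEYS]))
        lines.append("")

    for table in concordance_tables:
        lines.append(f"Concordance of informant reports, "
                     f"{table.direction.value} physical IPV "
                     f"(n = {table.n} dual-report couples)")
        lines.append(_row("Both report", [str(table.both_yes)]))
        lines.append(_row("Neither reports", [str(table.both_no)]))
        lines.append(_row("Pregnant woman only", [str(table.woman_yes_only)]))
        lines.append(_row("Partner only", [str(table.partner_yes_only)]))
        if table.n:
            lines.append(_row("Percent agreement", [f"{table.agreement:.1f}"]))
        lines.append("")

    return "\n".join(lines).rstrip() + "\n"
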