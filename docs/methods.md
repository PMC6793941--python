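# Methods

## Instrument model

`ipvpipe` operates on records from a two-informant act-frequency survey of
partner aggression. Each respondent answers, for each physical act in a
13-act registry (push/shove, grab, scratch, slap, thrown hard object,
bite, hit/punch, slam against a wall, hold down, kick, choke, hit with an
object that could hurt, plus a write-in "other"), a *pair* of items — how
often they perpetrated it and how often their partner did — on the ordinal
scale `never < once < twice < 3–5 times < 6+ times`. Reported acts carry
injury follow-ups over six impact kinds (feared for own safety, pain ≥ 4 h,
graze/wound, bruise/welt, sprain/fracture, fainted). A separate
psychological-victimization section has a screener (significant
depression, stress or fear caused by the partner), a 9-act registry
(ID/passport withheld, put down or humiliated, kept from service
providers, stalked, kept from family/friends, "tried to make me think I
was crazy", insulted or sworn at, money withheld, grilled or
interrogated), an attribution item linking endorsed acts to the screened
distress, and checklists of safety fears and of fear-driven interference
with five major life areas (work, education, religion, health services,
family/friends).

Both registries are extensible (the instrument has slots for additional
acts, bringing the item pairs to 15 and the psychological acts to 10); the
registry contents are configuration, not code. Write-in "other" acts are
human-coded upstream; the pipeline consumes the resulting `other_is_ipv`
flag and drops non-IPV write-ins at load time.

Roles are positional labels, `pregnant_woman` and `partner`, reflecting
the prenatal recruitment setting the default parameters describe; nothing
in the scoring depends on gender, and same-sex couples pass through
transparently.

## Scoring rules

**Union rule.** A couple is positive for an act in a direction if the
perpetrator self-reports it *or* the victim reports it; the couple-level
frequency is the maximum of the two categories. This deliberately trades
specificity for sensitivity, because individual-level under-reporting is
the dominant error in community samples. The classifier never requires
intradyadic agreement.

**Physical severity** per direction: `NONE` if no act occurs; `CS` if any
injury impact is reported for that direction by either informant, or any
occurring act is in the inherently-dangerous set, or the victim endorses
having feared for their own safety; otherwise `LI`. Three deliberate
choices sit here:

* The dangerous-act set defaults to {choked, hit with an object that
  could hurt} and is configurable, since "high inherent dangerousness" is
  a clinical judgment, not an enumeration.
* A perpetrator's self-reported injury infliction satisfies the impact
  clause (union rule applied to impacts), which matters when the victim's
  report is missing.
* The fear impact counts only from the victim's own report: fear is the
  victim's experience, and letting a perpetrator's guess about it trigger
  CS would conflate informants.

**Psychological CS** is true iff the victim endorses at least one act
*and* one impact clause holds: attribution to a non-empty screener, any
safety fear, or any interference item. Frequency plays no role in
severity (it is collected gated on the screener and used only for
repetition). Perpetrator self-reports of psychological aggression are not
scored at all.

**Six categories.** With `any_phy`, `cs_phy`, `cs_psy` as above, the
partition is: no-IPV; LI-physical-only; CS-physical-only (no psych CS);
CS-psych-only (no physical acts); CS-psych + LI-physical; CS-psych +
CS-physical. The definitions are mutually exclusive and exhaustive, so
"most severe applicable category" needs no tie-break.

**Direction labels** are named by the perpetrator; bidirectional means
both directions positive *at the relevant severity*. Low-impact direction
is tabulated over couples in the two LI-involving categories, CS-physical
direction over the two CS-physical categories, psychological direction
over the three CS-psych categories — this is what makes the published
type denominators (204 = 181 + 23, 61 = 47 + 14, 91 = 54 + 23 + 14)
reproduce.

**Repetition** ("more than one act per partner") sums the *minimum count*
of each occurring act per perpetrator — `never:0, once:1, twice:2,
3–5:3, 6+:6` — and flags the couple if any perpetrator's total reaches 2.
Using category minima makes "repeated" a lower bound; no midpoint rule is
assumed.

**Concordance** is computed only on dual-report couples as the 2×2 table
of each informant's own any-occurrence indicator per direction; percent
agreement is (both-yes + both-no)/n.

**Missingness bounds.** Couples with both reports missing are excluded
from the analysis denominator but counted; `missingness_bound(detected,
assumed, denominator)` returns the prevalence if all `assumed` couples
were positive. The function deliberately blesses no particular
denominator: callers choose whether the bound is over reporting couples
or the full enrolled sample.

## Statistics and numerics

* Percentages are computed from integer counts with `decimal` arithmetic
  and rounded **half away from zero to one decimal**; no float division
  happens before rounding, so printed percentages are exact functions of
  the counts.
* Rate comparisons use the Pearson chi-squared on the 2×2 table of two
  independent proportions (scipy, no continuity correction by default; a
  Yates flag is exposed). α = 0.05 two-sided. Degenerate tables (all
  successes or all failures) return statistic 0, p = 1 rather than
  raising.
* Small-cell disclosure masking renders 0 as `-` and counts below the
  threshold (default 3) as `<3`; it is purely a rendering layer — all
  unmasked counts remain available and re-derivable.
* The pipeline is deterministic end to end: identical input CSV and
  configuration give byte-identical outputs.

## Synthetic data generator

The generator is couple-first: it draws a latent category, then a
direction profile from per-type direction mixtures, then a repetition
flag, and only then realizes acts, frequencies and impacts as two faithful
reports. Realization guarantees classifier-consistency — with faithful
reporters and no missingness, classification recovers the latent category,
direction and repetition of every couple exactly (a tested invariant).

Default parameters are the study conditions of the motivating cohort of
expectant couples: 1,781 enrolled couples; category mixture
1407/181/47/54/23/14 over the 1,726 reporting couples; direction mixtures
24/102/78 (low-impact, over 204), 18/22/21 (CS physical, over 61) and
36/50/5 (CS psychological, over 91); repetition probabilities 185/265
(physical) and 70/91 (psychological CS); one-report probability 110/1781
and both-missing probability 55/1781; faithful reporters
(sensitivity = specificity = 1). Act mixtures default to
pushing/grabbing/slapping-dominated distributions loosely following the
published act tables, with inherently dangerous acts rare and confined to
the CS mixture; act-frequency distributions are not published, so the
default is uniform over the non-`never` categories. All of these are
`GeneratorConfig` fields.

Misreporting (`degrade`) flips each informant's item indicators
independently: true items are dropped with probability 1 − sensitivity,
false act items switched on at frequency `once` with probability
1 − specificity. Impacts are only ever degraded *off* — inventing
injuries would create severity the latent truth does not contain — and an
injury follow-up cannot survive the loss of its act report. Under
per-informant sensitivity *s*, couple-level union detection of a true act
is 1 − (1 − s)², the closed form the tests check by simulation.

`exact_study_fixture()` is the deterministic quota counterpart: it emits
a roster whose classified marginals equal the published couple counts
*exactly* — category counts, all three direction splits, repetition
counts, 110 one-report couples of which 27 are IPV-positive, and 55
both-missing couples. Within the quotas, assignments are fixed rather
than sampled (e.g. repetition goes to a prefix of the physical-couple
roster; one-report status to low-impact woman-to-partner couples whose
single report still determines the classification), so the fixture is
reproducible byte for byte and is the workhorse for verifying that the
pipeline regenerates printed percentages.

### What the generator does and does not emulate

It emulates the couple-level category/direction/repetition structure,
two-informant redundancy, under-reporting and unit missingness. It does
**not** model demographic covariates, within-couple correlation of
reporting behaviour (informant errors are independent given the truth),
seasonal or longitudinal dynamics, item-level nonresponse within a
returned questionnaire, or act co-occurrence patterns beyond 1–2 acts per
direction. Passing tests therefore demonstrate correctness of the
*scoring and aggregation machinery* under known truth — not that the
default parameters describe any new population.

## Problem sizes in the tests

The default suite classifies the 1,781-couple fixture once (shared across
tests), enumerates a closed 324-couple scenario universe exhaustively for
the brute-force oracle and symmetry/monotonicity checks, and runs the
stochastic properties at n = 10,000 (partition), n = 100,000 (noiseless
parameter recovery, 3-SE bands) and n = 4,000 (union-detection closed
form, 3-SE Monte-Carlo band). The full suite runs in well under a minute
on one CPU.

## Known limitations

* CS thresholds implement one operationalization of the ICD-11
  partner-maltreatment criteria; other instruments draw the
  injury/dangerousness line differently.
* The union rule makes prevalence robust to under-reporting but
  susceptible to over-reporting; no correction for false positives is
  attempted (specificity is a generator dial for sensitivity analyses,
  not an estimator input).
* Percent agreement is reported without a chance-corrected coefficient;
  with prevalence this low, kappa would be unstable and is deliberately
  out of scope.
* Repetition based on category minima under-counts true act totals; it
  is a lower bound by design.
* One-decimal rounding follows a single fixed rule; published tables
  rounded by other software may disagree by 0.1 on boundary values.
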