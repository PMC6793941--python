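# ipvpipe

Couple-level classification and prevalence analysis of two-informant
intimate partner violence (IPV) survey records.

## What problem this solves

Prevalence studies of partner violence usually interview one member of a
couple and grade severity by the *type* of act (a slap is "minor", a weapon
"severe"). Both choices are known to bias results: individuals under-report
their own and their partner's aggression, and the same act can range from
trivial to injurious. `ipvpipe` implements the alternative design used in
dyadic Family-Maltreatment-style surveys:

* **two informants per couple** — each partner separately reports both
  perpetration and victimization on an act-frequency checklist, and a
  couple counts as positive if *either* partner reports an act (the union
  rule), with the same event reported twice counted once;
* **impact-based severity** — a physical act is *clinically significant*
  (CS-IPV, in the sense of the ICD-11 partner-maltreatment criteria) only
  if it produced a reported injury, was inherently dangerous (e.g.
  choking), or left the victim fearing for their safety; otherwise it is
  *low-impact* (LI-IPV). Psychological CS-IPV requires an endorsed act
  *plus* an impact clause — acts attributed to screened depression/stress/
  fear, safety fears, or fear-driven interference with major life
  activities — and is scored from the victim's report only.

Each couple with at least one report is assigned exactly one of six
mutually exclusive categories (no IPV; LI physical only; CS physical only;
CS psychological only; CS psychological + LI physical; CS psychological +
CS physical), from which the pipeline derives prevalence rollups,
direction splits (woman-to-partner / partner-to-woman / bidirectional,
named by the perpetrator), repetition rates (more than one act per partner,
via a conservative minimum-count mapping of the ordinal frequency scale),
intradyadic concordance on dual-report couples, chi-squared comparisons of
victimization rates, small-cell disclosure masking, and worst-case
missingness bounds.

Because such records are too sensitive to deposit, the package ships a
synthetic dyad generator with known latent truth (`ipvpipe.synthdata`):
couples are drawn category-first and realized as faithful instrument
responses, optionally degraded by per-informant sensitivity/specificity
and missingness. A deterministic *exact-count* fixture reproduces the
marginals of a published cohort of 1,781 expectant couples, so every
pipeline stage can be verified against printed tables.

## Worked example

```python
from ipvpipe import (classify_records, direction_table, exact_study_fixture,
                     missingness_bound, prevalence)

records, truth = exact_study_fixture()          # 1,781 couples
analyzed = [c for c in records if c.n_reports >= 1]
cls = classify_records(analyzed)

prev = prevalence(cls)
print(prev.denominator)                          # 1726
print(prev.rollup_counts["any_ipv"],
      prev.rollup_percents["any_ipv"])           # 319 18.5
print(prev.rollup_percents["any_phy"])           # 15.4
print(prev.rollup_percents["cs_psy"])            # 5.3

li = direction_table(cls, analyzed, "phy_li")
print(li.denominator,
      {k.value: v for k, v in li.direction_percents.items()})
# 204 {'woman_to_partner': 50.0, 'partner_to_woman': 11.8, 'bidirectional': 38.2}

print(missingness_bound(319, 55, 1781))          # 21.0
```

Reading: 18.5 % of the 1,726 couples with at least one report had some IPV
in the past year; 15.4 % had physical acts; 5.3 % met the psychological CS
threshold. Among the 204 couples with low-impact physical IPV, half was
perpetrated by the pregnant woman, 11.8 % by the partner, and 38.2 % was
bidirectional. If all 55 couples whose reports were entirely missing were
assumed positive, any-IPV prevalence would rise to at most 21.0 %.

The same analysis from a shell:

```sh
ipvpipe generate --exact-counts --out records.csv
ipvpipe report -i records.csv --out-dir out/
cat out/report.txt
```

which writes the classification CSV, per-table CSVs and a masked
plain-text report (`ipvpipe generate` without `--exact-counts` samples a
random cohort from a YAML `GeneratorConfig`).

## Layout

| module | contents |
| --- | --- |
| `ipvpipe.fm_core` | domain types, act registries, frequency scale, validation, CSV schema |
| `ipvpipe.classify` | union-rule occurrence, severity, six-category, direction and repetition classification |
| `ipvpipe.aggregate` | prevalence/direction/concordance tables, chi-squared, masking, missingness bounds, rendering |
| `ipvpipe.synthdata` | generator config, random cohorts, item-level misreporting, exact-count fixture |
| `ipvpipe.cli` | `run_pipeline` plus the `ipvpipe generate|classify|report` console script |

See `docs/methods.md` for the scoring rules in detail, the generator's
assumptions, and known limitations.
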