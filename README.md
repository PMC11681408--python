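# twostage

Two-stage recruitment calculator for clinical trials that screen on an
expensive imaging measure — specifically, trials of white-matter-
hyperintensity (WMH) progression, where eligibility (significant WMH burden,
CHS grade > 2 or volume ≥ 9.3 cm³) is only observable on an MRI scan
(~$650/person) but only ~10% of a late-midlife population qualifies. The
package quantifies how much a cheap first-stage prescreen — a retinal fundus
photograph (~$32.50) scored for microvascular signs, or clinical chart
features at $0 — reduces recruitment cost by enriching the group sent to
MRI.

For trial designers, epidemiologists, and biostatisticians sizing screening
cascades; the same arithmetic applies to any setting where a low-cost marker
prescreens for an expensive eligibility measure.

## The model

With trial target `T`, prescreen-positive fraction `p_pre` (score in a
chosen severity range), significant-WMH fraction among positives `p_wmh|+`,
attrition `a`, and per-person costs `c_pre`, `c_mri`:

```
n_prescreen = ⌈ T / (p_pre · p_wmh|+ · (1 − a)) ⌉
n_mri       = ⌈ p_pre · n_prescreen ⌉
cost        = n_prescreen·c_pre + n_mri·c_mri
```

MRI-only screening is the degenerate case `p_pre = 1, c_pre = 0`. Prescreen
positivity comes from 0–3 point scores (retinal: retinopathy 3, each other
retinal sign 1, truncated at 3; clinical: age ≥ 60, hypertension, diabetes 1
each; combined: sum truncated at 3), graded none/mild/moderate/severe.
Severity ranges: severe = score 3, moderate–severe ≥ 2, mild–severe ≥ 1. A
weighted variant derives feature weights from ridge-logistic regression.
See `docs/methods.md` for the full model, rounding/precision policy, and
design choices.

## Worked example

Designs from the published late-midlife summary counts (N = 1311, 9.9%
significant WMH), printed-precision mode, trial target 646:

```python
from twostage.reference import MIDLIFE_CROSSTABS
from twostage.recruitment import design_from_crosstab, mri_only_design

for kind in ("clinical", "retinal", "combined"):
    cost_pre = 0.0 if kind == "clinical" else 32.50
    e = design_from_crosstab(MIDLIFE_CROSSTABS[kind], "severe",
                             cost_prescreen_usd=cost_pre, precision="paper")
    print(f"{kind:9s} severe: prescreen {e.n_prescreen:>6,} "
          f"(${e.cost_prescreen_usd:,.0f})  MRI {e.n_mri:,} "
          f"(${e.cost_mri_usd:,.0f})  total ${e.cost_total_usd:,.0f}")
e = mri_only_design(646, 0.099, 650)
print(f"MRI-only: {e.n_mri:,} scans, total ${e.cost_total_usd:,.0f}")
```

prints

```
clinical  severe: prescreen 52,778 ($0)  MRI 3,801 ($2,470,650)  total $2,470,650
retinal   severe: prescreen 37,450 ($1,217,125)  MRI 2,809 ($1,825,850)  total $3,042,975
combined  severe: prescreen 13,572 ($441,090)  MRI 3,801 ($2,470,650)  total $2,911,740
MRI-only: 6,526 scans, total $4,241,900
```

Reading the clinical-severe row: screening 52,778 people on free clinical
features finds the 7.2% (3,801) with the top score, of whom 17% (646) show
significant WMH on MRI — $2.47M all-in versus $4.24M for scanning everyone.
The combined score needs only 13,572 people screened for a similar cost.

The same calculations are available from the shell:

```
twostage design --target-n 646 --p-prescreen 0.075 --p-wmh 0.23 \
    --cost-prescreen 32.50 --cost-mri 650 --precision paper
twostage simulate --n 1311 --seed 1 --output cohort.csv
twostage report --cohort cohort.csv --output designs.csv
```

Other subcommands: `score`, `tabulate`, `metrics`, `wmh-map fit|convert`,
`progression`. Every file-writing command leaves a
`*.provenance.json` (version, seed, resolved parameters) beside its output.

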