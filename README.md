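# apmonitor

Census-date monitoring of antipsychotic prescribing in dementia caseloads,
reimplemented end to end on synthetic electronic health records.

The pipeline mirrors a quality-improvement surveillance workflow: on the
28th of each month it ascertains the patients under active older-adult
mental-health care who have a dementia diagnosis (from structured ICD-10
fields or free-text mentions) and evidence of recent antipsychotic use, links
them to antipsychotic monitoring forms, and feeds back per-team completion
percentages. Two versions of the recency rule are provided: `v1` (any
medication reference in the lookback window) and the refined `v2` (a minimum
pooled reference count, and per-drug disqualification on "stop" references),
plus a sensitivity output that excludes psychosis comorbidity and superseded
dementia diagnoses.

Because the source records cannot be distributed, the package ships a seeded
synthetic EHR generator with full ground truth, so every stage is testable
offline. The text extractor is an explicit, simpler stand-in for a clinical
NLP stack: case-insensitive whole-word lexicon matching with sentence-local
start/stop/negation cue attribution (nearest cue within 5 tokens wins; stop
outranks start outranks mention).

## Modules

| module | what it does |
| --- | --- |
| `apmonitor.synthetic_ehr` | seeded bundle generation, note rendering from templates, CSV/JSONL round-trip |
| `apmonitor.text_extraction` | lexicon extraction of diagnoses and medication references; unified event stream |
| `apmonitor.cohort` | active caseload, dementia index, recent-use v1/v2, sensitivity exclusions |
| `apmonitor.forms` | form-completion linkage, completion percentages, reverse check |
| `apmonitor.reporting` + `apmonitor.cli` | monthly orchestration, trend series, variant cascade, team reports |

## CLI

```sh
# generate a synthetic bundle (CSV + JSONL + ground_truth.json)
apmonitor generate --seed 1 --n-patients 660 --out scratch/bundle

# unified event stream export
apmonitor extract --bundle scratch/bundle --out scratch/events.csv

# cohort at one census
apmonitor cohort --bundle scratch/bundle --census 2018-06-28 \
    --algorithm v2 --window-days 183 --out scratch/cohort.csv

# per-team feedback report
apmonitor report --bundle scratch/bundle --census 2018-06-28

# every monthly census: cohort.csv, completion.csv, reverse_check.csv, trend.csv
apmonitor run --bundle scratch/bundle --census-start 2017-10 \
    --census-end 2019-01 --out scratch/monthly

# three-stage algorithm cascade at one census
apmonitor compare --bundle scratch/bundle --census 2018-07-28
```

Generator parameters can also be given as a flat YAML file
(`apmonitor generate --config my.yaml`); keys mirror
`apmonitor.config.GeneratorConfig`. Lexicons are plain YAML package data
(`src/apmonitor/data/lexicons.yaml`) and can be overridden with
`--lexicons`.

## Conventions and defaults

- All intervals are closed on both ends; dates are ISO-8601.
- Lookback window: 183 days (~6 months); form validity defaults to the same
  window (both configurable, and surfaced in report headers).
- The v2 minimum-reference rule pools references across drugs by default;
  `rule1_per_drug=True` switches to per-drug counting.
- Percentages are rounded half-away-from-zero to one decimal.
- Ground truth (`ground_truth.json`) is written by the generator and read
  only by tests, never by the pipeline.
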