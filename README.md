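# vahier

Hierarchical expert-algorithm cause-of-death assignment for verbal autopsy
(VA) data, with a full resampling validation framework.

Expert algorithms are boolean combinations of close-ended questionnaire
responses judged predictive of particular causes of neonatal (0–27 days) and
child (1–59 months) death. When several algorithms fire for one death, an
ordered *hierarchy* picks the single primary cause; when none fires the death
is "unspecified". The method is fully deterministic and needs no training
data.

The package provides:

- **`vahier.rules_engine`** — rule-set parsing (YAML/JSON expression trees
  over symptom atoms), record evaluation, and hierarchical primary-cause
  selection. Six neonatal hierarchies (arifeen, baqui, kalter, lawn, liu,
  compromise) and three child hierarchies (arifeen, kalter, liu) ship as
  bundled configs.
- **`vahier.reference_harmonizer`** — ICD-10-style reduction of co-morbid
  reference-standard cause sets to single underlying causes (preterm/birth
  asphyxia → birth asphyxia; preterm/sepsis → sepsis; three-way sets split
  proportionally over sepsis and birth asphyxia; child pneumonia/diarrhea
  split proportionally), plus collapsing of "possible" VA causes into their
  definite scoring counterparts.
- **`vahier.scenario_resampler`** — target cause-distribution draws for four
  mortality scenarios (high U5MR with/without endemic malaria, moderate
  U5MR, and a general scenario with every fraction uniform on 5–40%), and
  largest-remainder resampling of a labelled death pool to match a target.
- **`vahier.metrics`** — CSMF accuracy, per-cause absolute CSMF difference,
  Cohen's kappa, and chance-corrected concordance (CCC).
- **`vahier.synthetic_data`** — reference-labelled deaths and paired VA
  records with controlled sensitivity/specificity, derived from the same
  rule set the classifier uses, so the whole pipeline is testable offline.
- **`vahier.validation_pipeline`** — the orchestrated experiment: draw a
  target, resample, classify under every hierarchy (paired within a
  replicate), score all metrics, and summarize as median and range over
  replicates.

The bundled rule sets are *illustrative placeholders*: transcribe published,
validated algorithm definitions into the same YAML schema for substantive
analyses. The bundled country CSMF table is synthetic; supply a real
WHO-style table via `--country-table` for real scenarios.

## CLI

```sh
# paired synthetic cohort: records.csv, labels.csv, truth_manifest.json
vahier simulate --age-group neonate --n 1000 --seed 20160601 --out sim/

# assign one primary cause per death
vahier classify --records sim/records.csv --age-group neonate \
    --hierarchy kalter --out assigned.csv

# the resampling validation experiment (1000 replicates by default)
vahier validate --records sim/records.csv --labels sim/labels.csv \
    --age-group neonate --scenario general --replicates 1000 --seed 1 \
    --out validation/
```

`validate` writes `replicates.csv` (tidy per-replicate metrics),
`summary.csv` / `summary.json` (median and min–max range per scenario ×
hierarchy × metric; use `--range-mode percentile` for 2.5–97.5 percentiles)
and optionally a box plot (`--plot`).

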