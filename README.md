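# emocready

Scoring and aggregation of **health-facility readiness for obstetric
emergencies**, comparing two measurement models on the same resource
inventory:

* **WHO signal functions / Service Readiness Index (SRI)** — a facility is
  "ready" for a clinical action (give parenteral antibiotics, uterotonics,
  anticonvulsants; remove a retained placenta; remove retained products of
  conception) when its *tracer items* are present. The SRI averages tracer
  presence into a single index.
* **Clinical cascades** — each emergency (maternal sepsis, haemorrhage,
  hypertensive emergency, retained placenta, incomplete abortion) has three
  ordered stages of care — *identify*, *treat*, *monitor-modify* — each a
  conjunction of alternative-groups of resources. Readiness is **cumulative**:
  a facility is ready through stage *k* only if it holds all resources of
  stages 1..*k*.

The package is aimed at health-systems researchers and programme analysts who
score facility surveys: it reads resource inventories from CSV, evaluates
both models from a config-driven definition set (resource lists are data, not
code), and produces the standard indicator family — readiness proportions,
stage **drop-offs**, pooled means with sample SDs, tracer-vs-cascade
**overestimation**, and stratified variants by level of care (caesarean-section
capability), ownership and country.

## The indicators

For a cohort of *n* facilities and emergency *e* with cumulative stage
readiness *R₁ ≥ R₂ ≥ R₃* (percent of facilities):

* stage drop-offs: *D₁ = 100 − R₁*, *D₂ = R₁ − R₂*, *D₃ = R₂ − R₃*
  (non-negative by cumulativity; *D₁+D₂+D₃+R₃ = 100* exactly);
* overestimation for the paired signal function *f*: *S_f − R₂* in
  percentage points;
* pooled means are unweighted across emergencies; SDs use the sample
  (*n−1*) denominator.

All arithmetic is carried on exact fractions (counts over *n*); rounding is
half-away-from-zero to one decimal, applied once at display. That is what
makes pooled rows reproducible from integer facility counts.

## Worked example

The package ships a deterministic 23-facility **replica cohort** whose
facility counts are recovered from published 1-decimal readiness marginals
(for n = 23 consecutive counts differ by ≈4.35 points, so each printed
percentage pins down a unique count):

```python
from emocready import build_paper_replica, build_tables, replica_definitions

defs = replica_definitions()
cohort = build_paper_replica(defs)
tables = build_tables(cohort, defs, strata=["country"])
cols = ["n", "signal_pct", "cascade_stage2_pct", "overestimation_pp"]
print(tables["comparison"].set_index("label")[cols].round(1))
```

```
                      n  signal_pct  cascade_stage2_pct  overestimation_pp
label
sepsis               23        69.6                47.8               21.7
haemorrhage          23        60.9                60.9                0.0
hypertension         23        78.3                26.1               52.2
retained_placenta    23        69.6                43.5               26.1
incomplete_abortion  23        69.6                56.5               13.0
medical_pooled       23        69.6                44.9               24.6
manual_pooled        23        69.6                50.0               19.6
overall_pooled       23        69.6                47.0               22.6
```

Reading the overall row: tracer items suggest 69.6% of facilities are ready,
but only 47.0% hold everything needed to *identify and treat* the average
emergency — the signal functions overestimate practical readiness by 22.6
percentage points. The drop-off table (`tables["dropoff"]`) shows where
readiness is lost: a 28.4% pooled mean drop per stage (SD 3.0 across
emergencies), largest in the treatment stage (33.9%).

The same pipeline runs from the shell:

```bash
emocready simulate --replica --out runs/replica
emocready report --inventory runs/replica/inventory.csv \
    --attributes runs/replica/attributes.csv \
    --definitions src/emocready/data/replica_definitions.yaml \
    --by country --by csec --out runs/report
```

`report` writes `table1_readiness.csv`, `table3_dropoff.csv` and one
stratified pair per `--by` flag, plus a run manifest (tool and definition-set
versions, input digests, command line). For real surveys, point
`--inventory/--attributes` at your own CSVs (long form
`facility_id,resource_id,present` or wide form) and `--definitions` at a
definition config — the packaged `default_definitions.yaml` encodes the WHO
first-line operational definitions (three-drug antibiotic escalation,
oxytocin, magnesium sulfate) with the standard proxy substitutions.

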