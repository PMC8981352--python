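# Methods

## The two readiness models

Both models score a facility from the same physical inventory: a set of
resources (obstetric drugs, consumable supplies, durable goods, and written
guidelines/protocols) observed present at the facility level, regardless of
the unit or ward in which an item sits.

**Signal functions.** Each of the five measurable WHO clinical actions —
three medical treatments (parenteral antibiotics, uterotonics,
anticonvulsants) and two manual procedures (removal of a retained placenta,
removal of retained products of conception) — has a *tracer requirement*: a
conjunction of alternative-groups of resources. A facility is ready for the
function when every group is satisfied by at least one of its alternatives.
The sixth classical function, assisted vaginal delivery, carries no default
definition here (its tracer data are typically unmeasurable in inventory
surveys); the engine accepts one if a user supplies it. The Service
Readiness Index (SRI) variant averages tracer-group presence: the fraction
of *distinct* tracer groups satisfied, in [0, 1].

**Clinical cascades.** Each emergency has exactly three ordered stage
requirements — *identify*, *treat*, *monitor-modify* — of the same
conjunction-of-disjunctions form. Readiness is cumulative: ready-through-
stage-k requires satisfying stages 1..k. This encodes the clinical claim
that a facility able to stock treatment drugs but unable to recognise the
emergency is not practically ready to treat it.

Model assumptions, shared with the source methodology:

* **Skill is assumed.** These are commodity-based metrics; clinician skill
  is taken as universally present. A stage with no resource groups
  (identification of haemorrhage or of a retained placenta rests on
  clinical observation alone) is satisfied by every facility.
* **Binary presence.** An item is present or absent; no stock depth,
  functionality, expiry or accessibility semantics.
* **Proxies as alternatives.** A proxy substitution (electrical power for
  refrigeration; power or a working flashlight for a light source) is an
  extra alternative inside the group, so evaluation needs only one
  semantics. Satisfaction is therefore monotone in the inventory — adding a
  resource can never un-satisfy anything — which is property-tested.
* **No partial credit** within a stage or a tracer requirement.

## Indicator arithmetic

For emergency *e*, cumulative readiness percentages R1 ≥ R2 ≥ R3 over a
cohort of n facilities give stage drop-offs D1 = 100 − R1, D2 = R1 − R2,
D3 = R2 − R3; the three drops plus final readiness telescope to exactly 100,
and cumulativity guarantees every drop is non-negative. Overestimation for a
(signal function, cascade) pair is the tracer proportion minus cascade
stage-2 readiness, in percentage points.

Pooled means are **unweighted across emergencies** (each emergency counts
equally, not each facility×emergency pair); SDs are sample SDs (n−1). In the
drop-off table, the overall pooled mean is the mean of the five per-emergency
mean drops; the overall SD is the sample SD of those five means (the SD of
all fifteen cells is a different, larger number and is not reported); the
mean-of-SDs averages the five per-emergency stage SDs. These choices
reproduce every pooled row of the published comparison they mirror.

All percentages are carried as exact `fractions.Fraction` values
(100·count/n) through every pooled difference and mean; rounding is
half-away-from-zero to one decimal, applied once at display
(`emocready.rounding.round1`). Differences are computed from counts, never
from pre-rounded percentages: e.g. a 16/23 vs 11/23 pair yields
(16−11)/23 → 21.7, not 69.6 − 47.8 = 21.8. SDs take an exact rational
variance and apply one floating square root; a two-pass float oracle agrees
to 1e-12.

## The definition config

Definition sets load from YAML/JSON (`resources`, `cascades`,
`signal_functions`; see `src/emocready/data/default_definitions.yaml`) with
full validation: unique identifiers, exactly three stages per cascade,
referential integrity of every token, and the skill-only flag consistent
with an empty group list. A flat CSV export
(`definitions_to_csv`) provides an audit trail of every (group, alternative)
pair. `validate_antibiotic_definition` enforces the WHO three-step
antibiotic escalation (ampicillin AND gentamicin AND metronidazole, each its
own single-drug group) on any config claiming an antibiotic function.

The shipped default config is a representative reconstruction from WHO
first-line operational guidance, not a transcription of any particular
survey instrument; users scoring real surveys should review it against their
instrument before use. Two structural guarantees hold for it and are
config-level tests: every tracer group is drawn from the linked cascade's
stage-1∪2 groups (so cascade stage-2 readiness implies signal-function
readiness), and the anticonvulsant tracer is magnesium sulfate alone (WHO
first line; configs are free to add alternatives).

## The replica fixture

`ReplicaCountSpec.from_printed_tables()` inverts 1-decimal display rounding
over n = 23: consecutive counts differ by ≈4.35 points, so each published
percentage identifies a unique integer facility count (`recover_count`, an
exhaustive scan that errors on zero or multiple matches). Stage-1 counts
come from published identification-stage drops, stage-2 counts from the
published cumulative stage-2 readiness (individually rounded stage drops
need not telescope to a representable count — see the artifact cells below),
and stage-3 counts from the published monitor-stage drops.

`build_paper_replica` realises the counts as a cohort by **nested prefix
assignment**: the abstract resource bundle with target count k is present in
facilities 1..k. Because the per-emergency counts are weakly decreasing,
cumulative scoring reproduces every count exactly through the ordinary
pipeline, with no per-facility bookkeeping. The replica uses disjoint
abstract bundles per emergency (e.g. `hypertension_treat_kit`) because the
true cross-emergency sharing pattern of real commodities is not recoverable
from published marginals; shared-commodity behaviour is covered by scoring
unit tests on the default config instead. The true overlap between tracer
possession and cascade readiness is likewise unidentified; the nested
assignment is one consistent completion (it makes tracer holders and
stage-ready facilities maximally overlapping prefixes).

Attributes are fixed and documented: facilities 1–10 C-section capable,
1–4 private, 5–10 Ugandan (every Ugandan facility reports C-section
capability; the private facilities sit in Kenya). The joint
attribute×readiness distribution is **not** constrained to reproduce
published stratified cell values — that joint data is unpublished — so
stratified outputs on the replica are regression-tested against themselves,
and stratified *pooled* values are verified aggregation-only from published
stratified columns.

**Known print artifacts.** Four published cells cannot be produced by exact
count arithmetic and are accepted at ±0.1: the hypertension treat-stage drop
(printed 4.4; exact 1/23 → 4.3), the incomplete-abortion overestimation
(printed 13.1; exact 3/23 → 13.0), the incomplete-abortion stage SD (printed
26.5; exact 26.447 → 26.4), and the Kenya pooled mean drop (printed 27.8;
its own printed column averages to 27.88 → 27.9). The engine never forces
these values.

## The random generator

`generate_random` emulates an inventory survey for property testing, not for
inference. Defaults mirror the study conditions the replica encodes: 23
facilities, attribute probabilities 10/23 (C-section), 4/23 (private), 6/23
(Uganda, forced C-section capable), seed 20160101. Marginal availability
defaults to 0.7 per resource (typical of the tracer marginals above,
~60–78%) and can be set per resource. `nested_threshold` mode draws one
latent capacity u per facility and grants every resource whose marginal is
≥ u — richer facilities hold supersets of poorer ones, the pattern that
makes cascade readiness decline smoothly across a cohort; `independent` mode
flips one coin per (facility, resource). What the generator does **not**
emulate: real cross-resource correlation structure, stock-out dynamics,
seasonal procurement, unit-level location, or any attribute–readiness
association beyond the Uganda→C-section constraint. Passing tests on
generated cohorts therefore demonstrate arithmetic and structural
correctness, not calibration to any real facility population.

## Numerical and degenerate-input choices

* Empty cohorts: proportions and scoring raise; empty *strata* in batch
  table building yield NA cells instead (small-cohort robustness).
* SD of fewer than two values raises rather than returning 0 or NaN.
* `recover_count` distinguishes "no matching count" (transcription
  inconsistency) from "ambiguous" (n too large for unique inversion,
  n ≳ 1000 at one decimal).
* Table CSVs are deterministic: fixed column order, percentages formatted at
  one decimal half-away-from-zero, counts as integers, NA for missing —
  byte-identical output for identical input.
* Ties at exactly .x5 cannot arise from /23 fractions; the Decimal-based
  rounding path is exact for Fraction inputs regardless.

## Limitations

Resource presence on one survey day is a weak proxy for sustained readiness;
skill, resource quality and accessibility are unmeasured by construction.
The replica reproduces all-facility marginals exactly but its stratified
cells are one consistent completion, not estimates. The default definition
lists are a documented reconstruction and should be reviewed against the
local instrument before scoring real data.
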