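# brscore

Benefit-risk scoring for deciding whether a personalized prognostic model
should be turned into a clinical tool.

## The problem

Many survey-based outcome prediction models perform only modestly better
than the population average, yet communicating their predictions changes
patient behaviour: some patients are motivated into a recommended
treatment they would otherwise have skipped, others are talked out of a
treatment they would actually have benefited from, and the communicated
expectation itself shifts outcomes through placebo and nocebo effects.
Whether such a model should be built into a tool at all is therefore a
population-level trade-off, not a pure accuracy question.

`brscore` makes that trade-off explicit. It enumerates the 16
possibilities that follow the introduction of a prediction tool — every
combination of a patient's **a priori intent** to follow the recommended
treatment, the tool's binary **prediction** (improvement / no
improvement), the patient's actual **participation**, and their
counterfactual **would-benefit** status — allocates a cohort across them
from stated branching probabilities, and weights each possibility's
consequences *relative to the no-tool world* on one additive scale.
The comparison collapses into the Benefit-Risk Score

```
BRS = Σ_{i=1..16} n_i (B_i + PNE_i + SE_i)
```

where `n_i` is the number of patients in possibility *i*, `B_i` the
direct benefit/harm delta, `PNE_i` the placebo/nocebo delta and `SE_i`
the side-effect delta. `BRS > 0` favours implementing the tool;
otherwise refrain (or roll it out partially, gatekept by clinicians).
Intended users are researchers assessing a prognostic model's impact
before committing to tool development.

## Worked example

The packaged osteoarthritis scenario models 1000 patients facing
education-and-exercise therapy: half are a priori willing, the tool
predicts improvement for three quarters, patients follow a prediction
aligned with their intent 29 times out of 30, a positive prediction
converts half of the decliners, a third of the willing persist despite a
negative prediction, and three fifths of predictions are correct.
Counts are taken in whole patients at each branch, as in a spreadsheet.

```
$ brscore example
scenario: osteoarthritis (whole-patient counts)
cohort size: 1000
total effect-points: 832
per capita: 0.832
harmed patients: 40 (expected 40.0)
decision: implement
```

The score of 832 effect-points (0.832 per patient, > 0) favours
implementing the tool — while making explicit that 40 patients would be
harmed by forgoing a treatment they actually needed. Sensitivity and
rollout questions are one command away:

```
$ brscore sweep --config oa.yaml --parameter side_effect_scale --grid 1,3
 value  total_points  per_capita  decision
   1.0         832.0       0.832 implement
   3.0        1026.0       1.026 implement

$ brscore partial --config oa.yaml --expose decliners
exposure: decliners
scenario: osteoarthritis (whole-patient counts)
cohort size: 500
total effect-points: 646
per capita: 1.292
harmed patients: 0 (expected 0.0)
decision: implement
```

Tripling the side-effect weights (a treatment with stronger secondary
effects) raises the score to 1026; restricting the rollout to a priori
decliners keeps 646 of the 832 points while eliminating the harmed
subgroup entirely, since the harm pattern requires willing patients who
are flipped away from treatment.

The same objects are available as a library (`load_scenario`,
`allocate`, `compute_brs`, `one_way_sweep`, `threshold`,
`partial_implementation`, `export_table`, `checklist_report`, …), and a
patient-level microsimulation (`microsim_oracle`) provides an
independent stochastic cross-check of the analytic expectation. An
eleven-question checklist (`brscore checklist`) walks through the
assumptions that must be pinned down before the numbers mean anything.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the packaged worked example from scratch — full score,
side-effect sensitivity variant, harmed subgroup, microsimulation
cross-check and decliner-only rollout — printing the results and writing
the results file.

## Layout

| module | contents |
|---|---|
| `brscore.tree` | the 16-leaf outcome tree and leaf classification |
| `brscore.cohort` | branching assumptions and cohort allocation |
| `brscore.scoring` | effect weights, the BRS formula, the decision rule |
| `brscore.scenario` | scenario container, named-parameter access |
| `brscore.sensitivity` | one-way sweeps, BRS = 0 thresholds, partial rollout |
| `brscore.io` / `brscore.checklist` | YAML configs, CSV/XLSX calculation table, checklist report |
| `brscore.examples` | packaged worked example, random scenarios, microsimulation oracle |
| `brscore.cli` | the `brscore` command |

See `docs/methods.md` for the model's assumptions, parameter meanings
and numerical choices.
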