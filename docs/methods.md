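# Methods

## Model

A cohort of `N` patients faces a one-size-fits-all first-line treatment
recommendation. Introducing a personalized outcome-prediction tool
routes each patient down a four-level binary tree:

1. **a priori intent** — would the patient have followed the
   recommendation without the tool (probability `p_intent`);
2. **prediction** — does the tool predict an improvement
   (`p_positive`), assumed independent of intent (a correlation hook
   exists in the schema but is rejected until its semantics are
   validated);
3. **participation** — does the patient receive the treatment, with one
   probability per intent × prediction cell
   (`adherence.willing_positive`, `.willing_negative`,
   `.decliner_positive`, `.decliner_negative`);
4. **outcome** — the patient's counterfactual *would-benefit* status,
   conditioned on the prediction sign only:
   `P(benefit | improve) = p_correct`,
   `P(benefit | no-improve) = 1 − p_correct`.

Modelling the outcome as a counterfactual (defined also for
non-participants) is what lets the tree express the severe-harm pattern
— a patient who forgoes a treatment they *would have* benefited from —
and makes "prediction correctness" well defined for every leaf. The
binary outcome is itself a simplification: the underlying clinical
endpoints (e.g. pain on a 0–100 visual analog scale) are dichotomized
before entering the model.

The expected count in leaf *i* is the product of the probabilities along
its path. Leaves are indexed 1…16 lexicographically (intent: yes < no,
prediction: improve < no-improve, participation: yes < no, outcome:
benefit < no-benefit). Under the conventional tree drawing (B-level =
intent, D-level = intent × prediction × participation, benefit child
first) this index coincides with the E-node number, so the severe-harm
leaf is E7, the nocebo leaf E5, the top-benefit leaf E9; the mapping is
exposed by `node_path` as an annotation, not a contract.

## Scoring

Each leaf carries a triplet `(B_i, PNE_i, SE_i)` of effect deltas
*relative to the no-tool world* in which everyone follows their own
intent, all on one additive scale (scale coherence — "a benefit three
times the placebo effect gets three times the points" — is the user's
contract and cannot be machine-checked). The decision statistic is

    BRS = Σ_i n_i (B_i + PNE_i + SE_i),

reported both as total effect-points and per capita; implement iff
BRS > 0 (an exact zero refrains, with a warning). A per-leaf
`catastrophic` flag can veto implementation outright for harms that no
aggregate benefit may outweigh (off by default).

`default_weights` encodes the published palette:

| situation | B | PNE | SE (favourable profile) |
|---|---|---|---|
| decision unchanged | 0 | see below | 0 |
| flipped into treatment, would benefit | +3 | | +1 |
| flipped into treatment, no benefit (wasted effort) | −1 | | +1 |
| flipped out of treatment, would benefit (harm) | −3 | | −1 |
| flipped out of treatment, no benefit (effort avoided) | +1 | | −1 |

PNE is +1 for every treated patient under an improvement prediction
(positive expectations act even when the treatment itself will not
help), and −1 for treated patients under a no-improvement prediction
*who would benefit*: a nocebo dampens an improvement that would
otherwise occur, so by default it is not applied where there is no
improvement to lose (`nocebo_requires_benefit=False` restores the
unconditional variant). The side-effect sign follows the treatment's
profile (`SideEffectProfile.positive()` for exercise-like treatments
whose secondary effects are favourable); only patients whose
participation *changed* get a side-effect delta, since aligned patients
have the same side effects with or without the tool.

This table is exactly the pinned weight set of the packaged
osteoarthritis fixture; the per-leaf weights are fully user-overridable
in the scenario config.

## Counting modes

`allocate` returns exact fractional expected counts by default. The
`whole_patients=True` mode emulates a calculation sheet filled with
whole patients: at every binary split the first branch is rounded half
away from zero and the sibling receives the remainder, so each level —
and the cohort total — adds up exactly. The packaged worked example
uses the whole-patient mode; its totals (832 effect-points, 1026 with
side-effect weights at ±3, 40 harmed patients) arise from that table,
while the same probabilities and weights give 825.0 / 1016.7 / 40.83 in
fractional mode. The microsimulation oracle converges to the
*fractional* values, which are the true expectations under the stated
probabilities; the whole-patient table is a presentation convention,
not a different model.

The harmed subgroup counts a priori willing patients who end up
untreated although they would have benefited — both the
false-negative-driven flips (E7) and the behaviourally unlikely
positive-prediction flips (E3's pattern under D2). Its fractional
expectation is reported alongside the half-away-from-zero rounded
integer.

## Sensitivity analysis

BRS is multilinear in the branching probabilities and exactly linear in
the weights, hence continuous in every named parameter.

* `one_way_sweep` re-runs allocation + scoring along a strictly
  increasing grid and reports linearly interpolated sign changes.
* `threshold` finds BRS = 0: closed-form two-point solve for weight
  parameters (`benefit_scale`, `side_effect_scale`, …, `benefit[i]`,
  …), bisection otherwise; a root is accepted when
  `|BRS| < 1e−6 × cohort_size` (effect-points are O(cohort size)).
  Same-sign endpoints return `None`; an identically zero score returns
  the interval start with a degeneracy warning.
* `partial_implementation` models the clinician-gatekeeper rollout: one
  a priori intent stratum is exposed to the tool, the rest follow their
  own intent and — because the weights are deltas against exactly that
  behaviour — contribute zero points. Adherence inside the exposed
  stratum is kept unchanged; how gatekeeping itself shifts adherence is
  not modelled. Per-capita in the result is taken over the exposed
  patients. Exposure rules are intent-based only.

## Synthetic data and what a green test establishes

`random_scenario(seed)` draws probabilities uniformly on [0, 1], a
cohort size uniformly on [100, 10 000] (a realistic planning range for
a single-indication rollout; the worked example uses 1000), and weights
from the published discrete palette ({−3,−1,0,1,3} × {−1,0,1} ×
{−1,0,1}). These scenarios exercise the algebraic invariants —
conservation, linearity, additivity over the intent partition,
microsimulation agreement — across the whole parameter space. They do
*not* emulate real populations: probabilities are mutually independent,
weights need not be clinically coherent, and there is no correlation
between intent and prediction. A green property suite therefore
establishes the arithmetic and its implementation, not the realism of
any particular scenario; realism enters only through the user's inputs
and the checklist that interrogates them.

`microsim_oracle(scenario, m, seed)` draws `m` synthetic patients
through the four sequential decisions with one seeded
`numpy.random.default_rng` generator, scores each from the leaf they
land in, and rescales to the cohort; it shares no code with the
analytic allocation and reports the sample standard error of the
rescaled mean (exactly zero under degenerate probabilities).

## Numerical choices

* Allocation conservation is enforced at 1e−9 relative; whole-patient
  rounding uses half-away-from-zero with a 1e−9 epsilon guard against
  float representation of exact halves.
* Probabilities in YAML configs may be exact fraction strings
  (`"29/30"`), parsed via `fractions.Fraction`.
* The CSV calculation table always has exactly 16 data rows; scenario
  metadata and totals travel as `#` comment lines written with full
  `repr` precision, so export → import is bit-identical and
  re-computable.
* Report rendering: effect-point totals print as integers when within
  1e−9 of one, counts with one decimal.
* BRS = 0 is decided as refrain (with a warning): a tie carries no
  implementation signal.

## Known limitations

* One clinical outcome, binarized; additional health outcomes can only
  be folded into the side-effect term.
* Prediction ⟂ intent is hard-wired; scenarios where willing patients
  are likelier to receive positive predictions cannot yet be expressed.
* Population-level averaging: the score trades harms against benefits
  across patients. The harmed-subgroup count and the catastrophic veto
  are deliberate pressure valves, not a substitute for an ethical
  assessment of whether the worst-affected group's harm is acceptable.
* Only one treatment versus no treatment; multi-option shared-decision
  settings are out of scope.
* The whole-patient rounding scheme is one defensible spreadsheet
  convention (round first branch, remainder to sibling); other
  conventions would change totals by a few points.
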