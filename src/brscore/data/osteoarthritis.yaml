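# Worked osteoarthritis example shipped with the package.
#
# A cohort of 1000 patients facing the first-line recommendation of
# education and exercise therapy.  Half are a priori willing to follow
# it; the personalized prognostic tool predicts improvement for three
# quarters; patients follow a prediction aligned with their own intent
# 29 times out of 30; a positive prediction converts half of the
# decliners, while a third of the willing persist despite a negative
# prediction; three fifths of the predictions are correct regarding
# benefit.  Counts are taken in whole patients at every branch, as in a
# spreadsheet; with the default weight palette this yields 832
# effect-points, 1026 when side-effect weights are tripled, and 40
# patients harmed by forgoing a treatment they needed.
name: osteoarthritis
description: >-
  Education-and-exercise therapy for knee osteoarthritis with a
  survey-based personalized outcome prediction tool; favourable
  side-effect profile (physical activity benefits general health).
cohort_size: 1000
whole_patients: true
probabilities:
  intent: 1/2
  positive_prediction: 3/4
  correct_prediction: 3/5
  adherence:
    willing_positive: 29/30
    willing_negative: 1/3
    decliner_positive: 1/2
    decliner_negative: 1/30
weights:
  - {leaf: 1, benefit: 0, placebo_nocebo: 1, side_effect: 0}
  - {leaf: 2, benefit: 0, placebo_nocebo: 1, side_effect: 0}
  - {leaf: 3, benefit: -3, placebo_nocebo: 0, side_effect: -1}
  - {leaf: 4, benefit: 1, placebo_nocebo: 0, side_effect: -1}
  - {leaf: 5, benefit: 0, placebo_nocebo: -1, side_effect: 0}
  - {leaf: 6, benefit: 0, placebo_nocebo: 0, side_effect: 0}
  - {leaf: 7, benefit: -3, placebo_nocebo: 0, side_effect: -1}
  - {leaf: 8, benefit: 1, placebo_nocebo: 0, side_effect: -1}
  - {leaf: 9, benefit: 3, placebo_nocebo: 1, side_effect: 1}
  - {leaf: 10, benefit: -1, placebo_nocebo: 1, side_effect: 1}
  - {leaf: 11, benefit: 0, placebo_nocebo: 0, side_effect: 0}
  - {leaf: 12, benefit: 0, placebo_nocebo: 0, side_effect: 0}
  - {leaf: 13, benefit: 3, placebo_nocebo: -1, side_effect: 1}
  - {leaf: 14, benefit: -1, placebo_nocebo: 0, side_effect: 1}
  - {leaf: 15, benefit: 0, placebo_nocebo: 0, side_effect: 0}
  - {leaf: 16, benefit: 0, placebo_nocebo: 0, side_effect: 0}
metadata:
  expected:
    total_points: 832
    total_points_se_tripled: 1026
    harmed_rounded: 40
    provenance: >-
      Published worked example; totals arise from the whole-patient
      spreadsheet-style table with the default weight palette.
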