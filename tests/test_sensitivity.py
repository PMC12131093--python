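"""Sweeps, BRS = 0 thresholds, and partial (gatekeeper) implementation."""

import numpy as np
import pytest

from brscore import (
    REFRAIN,
    ValidationError,
    classify_leaf,
    one_way_sweep,
    partial_implementation,
    random_scenario,
    threshold,
    with_parameter,
)
from brscore.sensitivity import _bisect


class TestOneWaySweep:
    def test_side_effect_scale_reproduces_published_variant(self, oa_scenario):
        """Scaling side-effect weights from +-1 to +-3 moves the total
        from 832 to 1026."""
        result = one_way_sweep(oa_scenario, "side_effect_scale", [1, 3])
        assert result.totals.tolist() == [832.0, 1026.0]

    def test_single_point_identity(self, oa_scenario):
        current = oa_scenario.run().total_points
        result = one_way_sweep(oa_scenario, "p_intent", [0.5])
        assert result.totals.tolist() == [current]

    def test_benefit_scale_linear_decomposition(self, oa_scenario):
        """At scale 0 only PNE + SE contribute; direct recomputation of
        the two components confirms the linear split."""
        result = one_way_sweep(oa_scenario, "benefit_scale", [0, 1])
        alloc = oa_scenario.allocation()
        pne_se_only = float(
            alloc.counts
            @ (oa_scenario.weights.placebo_nocebo + oa_scenario.weights.side_effect)
        )
        assert result.totals[0] == pytest.approx(pne_se_only)
        assert result.totals[1] == pytest.approx(832.0)
        b_part = float(alloc.counts @ oa_scenario.weights.benefit)
        assert result.totals[1] - result.totals[0] == pytest.approx(b_part)

    def test_probability_sweep_recomputes_allocation(self, oa_fractional):
        result = one_way_sweep(oa_fractional, "p_correct", [0.0, 0.6, 1.0])
        assert result.totals[1] == pytest.approx(825.0)
        assert not np.allclose(result.totals[0], result.totals[2])

    def test_crossings_reported_on_sign_change(self, oa_scenario):
        result = one_way_sweep(oa_scenario, "side_effect_scale", [-10, 0, 3])
        assert len(result.crossings) == 1
        assert result.crossings[0] == pytest.approx(-735 / 97, rel=1e-6)

    @pytest.mark.parametrize(
        "parameter, grid, match",
        [
            ("no_such_knob", [0, 1], "unknown parameter"),
            ("p_intent", [0.5, 0.2], "strictly increasing"),
            ("p_intent", [0.5, 1.5], "domain"),
            ("p_intent", [], "empty"),
        ],
    )
    def test_invalid_sweeps_rejected(self, oa_scenario, parameter, grid, match):
        with pytest.raises(ValidationError, match=match):
            one_way_sweep(oa_scenario, parameter, grid)


class TestThreshold:
    def test_closed_form_equals_bisection_for_weight_parameter(self, oa_scenario):
        """BRS(s) = 735 + 97 s for the side-effect scale of the worked
        example; the closed-form root matches an independent bisection."""
        root = threshold(oa_scenario, "side_effect_scale", (-10.0, 0.0))
        assert root == pytest.approx(-735 / 97, rel=1e-9)

        f = lambda s: with_parameter(  # noqa: E731
            oa_scenario, "side_effect_scale", s
        ).run().total_points
        bis = _bisect(f, -10.0, 0.0, f(-10.0), f(0.0), tol=1e-6 * 1000)
        assert root == pytest.approx(bis, abs=1e-4)
        assert abs(f(root)) < 1e-6 * 1000

    def test_probability_threshold_by_bisection(self, oa_fractional):
        """In a benefit-only variant (expectation and side-effect weights
        zeroed) prediction correctness has a break-even point: wrong
        predictions flip patients the wrong way."""
        scenario = oa_fractional.replace(
            weights=oa_fractional.weights.scaled(
                placebo_nocebo_scale=0.0, side_effect_scale=0.0
            )
        )
        assert with_parameter(scenario, "p_correct", 0.0).run().total_points < 0
        assert with_parameter(scenario, "p_correct", 1.0).run().total_points > 0
        root = threshold(scenario, "p_correct", (0.0, 1.0))
        assert root is not None and 0.0 < root < 0.6
        at_root = with_parameter(scenario, "p_correct", root).run().total_points
        assert abs(at_root) < 1e-6 * 1000

    def test_no_sign_change_returns_none(self, oa_scenario):
        assert threshold(oa_scenario, "side_effect_scale", (0.0, 5.0)) is None

    def test_all_zero_weights_degenerate(self, oa_scenario):
        from brscore import EffectWeights

        degenerate = oa_scenario.replace(weights=EffectWeights.zeros())
        with pytest.warns(UserWarning, match="identically zero"):
            root = threshold(degenerate, "side_effect_scale", (-1.0, 1.0))
        assert root == -1.0

    def test_invalid_interval_rejected(self, oa_scenario):
        with pytest.raises(ValidationError):
            threshold(oa_scenario, "side_effect_scale", (1.0, -1.0))
        with pytest.raises(ValidationError, match="domain"):
            threshold(oa_scenario, "p_intent", (-0.5, 0.5))


class TestPartialImplementation:
    def test_decliner_exposure_has_no_harm_leaves(self, oa_scenario):
        """The severe-harm pattern needs a priori willing patients, so a
        decliner-only rollout contributes zero harm-leaf points."""
        result = partial_implementation(oa_scenario, "decliners")
        assert result.harmed_count == 0.0
        alloc = oa_scenario.allocation()
        for leaf in alloc.leaves:
            if classify_leaf(leaf).harm_leaf:
                assert leaf.intent  # harm pattern lives in the willing stratum

    def test_exposing_everyone_equals_full_scenario(self, oa_scenario):
        full = oa_scenario.run()
        partial = partial_implementation(oa_scenario, "all")
        assert partial.total_points == full.total_points
        assert partial.harmed_count == full.harmed_count

    def test_exposing_nobody_is_zero_with_warning(self, oa_scenario):
        with pytest.warns(UserWarning, match="no patients"):
            result = partial_implementation(oa_scenario, "none")
        assert result.total_points == 0.0
        assert result.decision == REFRAIN

    def test_intent_partition_decomposition(self, oa_scenario):
        """Full-population BRS splits exactly over the intent strata."""
        full = oa_scenario.run().total_points
        decliners = partial_implementation(oa_scenario, "decliners").total_points
        willing = partial_implementation(oa_scenario, "willing").total_points
        assert decliners + willing == pytest.approx(full, rel=1e-12)
        assert (decliners, willing) == (646.0, 186.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_decomposition_on_random_scenarios(self, seed):
        scenario = random_scenario(seed).scenario
        full = scenario.run().total_points
        parts = sum(
            partial_implementation(scenario, rule).total_points
            for rule in ("decliners", "willing")
        )
        assert parts == pytest.approx(full, rel=1e-9, abs=1e-9)

    def test_unknown_exposure_rule_rejected(self, oa_scenario):
        with pytest.raises(ValidationError, match="expose"):
            partial_implementation(oa_scenario, "random-half")
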