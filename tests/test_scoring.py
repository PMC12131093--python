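"""Effect weights and the Benefit-Risk Score formula."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brscore import (
    Adherence,
    BranchingAssumptions,
    EffectWeights,
    IMPLEMENT,
    LeafAllocation,
    REFRAIN,
    SideEffectProfile,
    ValidationError,
    allocate,
    build_tree,
    compute_brs,
    decide,
    default_weights,
    harmed_count,
    leaf_index,
)


@pytest.fixture(scope="module")
def tree():
    return build_tree()


class TestDefaultWeights:
    def test_reproduces_pinned_osteoarthritis_table(self, oa_scenario):
        """The rule-derived weights with the favourable side-effect
        profile equal the packaged worked-example table."""
        w = default_weights(profile=SideEffectProfile.positive())
        np.testing.assert_array_equal(w.benefit, oa_scenario.weights.benefit)
        np.testing.assert_array_equal(
            w.placebo_nocebo, oa_scenario.weights.placebo_nocebo
        )
        np.testing.assert_array_equal(w.side_effect, oa_scenario.weights.side_effect)

    def test_harm_and_top_benefit_extremes(self):
        w = default_weights()
        e7 = leaf_index(True, False, False, True)
        e9 = leaf_index(False, True, True, True)
        assert w.triplet(e7)[0] == -3.0
        assert w.triplet(e9)[0] == 3.0

    def test_minor_flip_weights_are_one_point(self):
        """Flips that only avoid or waste effort score +-1."""
        w = default_weights()
        avoided = leaf_index(True, False, False, False)
        wasted = leaf_index(False, True, True, False)
        assert w.triplet(avoided)[0] == 1.0
        assert w.triplet(wasted)[0] == -1.0

    def test_aligned_leaves_have_zero_benefit_delta(self, tree):
        w = default_weights(profile=SideEffectProfile.neutral())
        for leaf in tree:
            if leaf.participation == leaf.intent:
                b, _, s = w.triplet(leaf.index)
                assert b == 0.0 and s == 0.0

    def test_neutral_profile_zeroes_side_effects(self):
        w = default_weights(profile=SideEffectProfile.neutral())
        assert np.all(w.side_effect == 0.0)

    def test_nocebo_requires_benefit_by_default(self):
        w = default_weights()
        benefit_nocebo = leaf_index(True, False, True, True)   # E5
        futile_nocebo = leaf_index(True, False, True, False)   # E6
        assert w.triplet(benefit_nocebo)[1] == -1.0
        assert w.triplet(futile_nocebo)[1] == 0.0
        w_all = default_weights(
            profile=SideEffectProfile(sign=1, nocebo_requires_benefit=False)
        )
        assert w_all.triplet(futile_nocebo)[1] == -1.0

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValidationError):
            default_weights(profile="positive")
        with pytest.raises(ValidationError):
            SideEffectProfile(sign=2)


class TestComputeBRS:
    def test_worked_example_totals(self, oa_scenario):
        """The packaged whole-patient table scores 832 effect-points;
        tripling the side-effect weights gives 1026."""
        result = oa_scenario.run()
        assert result.total_points == 832.0
        assert result.per_capita == 0.832
        assert result.decision == IMPLEMENT
        tripled = oa_scenario.replace(
            weights=oa_scenario.weights.scaled(side_effect_scale=3)
        )
        assert tripled.run().total_points == 1026.0

    def test_fractional_counts_score(self, oa_fractional):
        """With exact expected (fractional) counts the same weights give
        825 points — the whole-patient table is what yields 832."""
        assert oa_fractional.run().total_points == pytest.approx(825.0, abs=1e-9)

    def test_zero_weights_zero_score_refrain(self, oa_scenario):
        alloc = oa_scenario.allocation()
        result = compute_brs(alloc, EffectWeights.zeros())
        assert result.total_points == 0.0
        assert result.decision == REFRAIN

    def test_harmed_subgroup(self, oa_scenario, oa_fractional):
        """Willing patients flipped out of a treatment they needed: 40
        whole patients (fractional expectation 40.83)."""
        result = oa_scenario.run()
        assert result.harmed_count == 40.0
        assert result.harmed_rounded == 40
        assert oa_fractional.run().harmed_count == pytest.approx(245 / 6)

    def test_nobody_harmed_without_flips(self):
        a = BranchingAssumptions(1000, 0.5, 0.75, Adherence(1, 1, 0, 0), 0.6)
        assert harmed_count(allocate(a)) == 0.0

    def test_perfect_predictions_protect_negative_followers(self):
        """With p_correct = 1 and full adherence to predictions, forgone
        treatment is never beneficial, so nobody is harmed (enumeration:
        would-benefit requires an improvement prediction)."""
        a = BranchingAssumptions(1000, 0.5, 0.75, Adherence(1, 0, 1, 0), 1.0)
        assert harmed_count(allocate(a)) == 0.0

    def test_leaf_set_mismatch_rejected(self, oa_scenario):
        alloc = oa_scenario.allocation()
        with pytest.raises(ValidationError):
            compute_brs(alloc, EffectWeights.zeros(), tree=build_tree()[::-1])

    @given(st.floats(-5, 5, allow_nan=False))
    def test_linearity_in_weights(self, alpha):
        """compute_brs(allocation, a*W) = a * compute_brs(allocation, W)."""
        scenario = _fixture_scenario()
        alloc = scenario.allocation()
        base = compute_brs(alloc, scenario.weights).total_points
        scaled = compute_brs(
            alloc,
            scenario.weights.scaled(
                benefit_scale=alpha, placebo_nocebo_scale=alpha, side_effect_scale=alpha
            ),
        ).total_points
        assert scaled == pytest.approx(alpha * base, rel=1e-9, abs=1e-9)

    def test_additivity_over_subpopulations(self, oa_fractional):
        """Splitting the cohort into disjoint subpopulations splits the
        score: BRS(n) = BRS(n') + BRS(n - n')."""
        alloc = oa_fractional.allocation()
        rng = np.random.default_rng(7)
        part = alloc.counts * rng.uniform(0, 1, size=16)
        rest = alloc.counts - part
        w = oa_fractional.weights
        total = compute_brs(alloc, w).total_points
        t1 = compute_brs(LeafAllocation(part, part.sum(), alloc.leaves), w).total_points
        t2 = compute_brs(LeafAllocation(rest, rest.sum(), alloc.leaves), w).total_points
        assert t1 + t2 == pytest.approx(total, rel=1e-12)

    def test_monotonicity_in_single_weight(self, oa_scenario):
        """Raising one weight on an occupied leaf strictly raises the total."""
        alloc = oa_scenario.allocation()
        base = compute_brs(alloc, oa_scenario.weights).total_points
        for index in (1, 7, 9):
            assert alloc[index] > 0
            bumped = oa_scenario.weights.with_value(
                "benefit", index, oa_scenario.weights.triplet(index)[0] + 0.5
            )
            assert compute_brs(alloc, bumped).total_points > base

    def test_catastrophic_veto_forces_refrain(self, oa_scenario):
        cat = np.zeros(16, dtype=bool)
        cat[6] = True  # severe-harm leaf E7, occupied in the example
        vetoed = EffectWeights(
            oa_scenario.weights.benefit,
            oa_scenario.weights.placebo_nocebo,
            oa_scenario.weights.side_effect,
            cat,
        )
        result = compute_brs(oa_scenario.allocation(), vetoed)
        assert result.total_points == 832.0  # the score itself is unchanged
        assert result.vetoed and result.decision == REFRAIN


class TestDecide:
    def test_positive_score_implements(self, oa_scenario):
        assert decide(oa_scenario.run()) == IMPLEMENT

    def test_zero_is_refrain_with_warning(self, oa_scenario):
        result = compute_brs(oa_scenario.allocation(), EffectWeights.zeros())
        with pytest.warns(UserWarning, match="zero"):
            assert decide(result) == REFRAIN

    def test_negative_score_refrains(self, oa_scenario):
        flipped = oa_scenario.replace(
            weights=oa_scenario.weights.scaled(
                benefit_scale=-1, placebo_nocebo_scale=-1, side_effect_scale=-1
            )
        )
        result = flipped.run()
        assert result.total_points == -832.0
        assert decide(result) == REFRAIN


def _fixture_scenario():
    from brscore import osteoarthritis_scenario

    return osteoarthritis_scenario().scenario
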