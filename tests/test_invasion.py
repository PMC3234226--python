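"""Infection-frequency recursion, equilibria, threshold and fixation time."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cidrive.invasion import (
    DegenerateModelError,
    DemographyConfig,
    InvasionParams,
    equilibria,
    fixation_prevalence,
    fractional_generations_to_fixation,
    invasion_params_from_ci,
    next_frequency,
    release_threshold,
    time_to_fixation,
)
from cidrive.model import CIParameters

#: Published posterior medians of the CI parameters (f = 1 + F).
MEDIANS = InvasionParams(f=1.1925, mu=0.1073, s_h=0.7976)

#: Bistable example: no fecundity benefit, so invasion needs a threshold.
BISTABLE = InvasionParams(f=1.0, mu=0.05, s_h=0.8)


def param_values():
    return st.builds(
        InvasionParams,
        f=st.floats(0.5, 2.0),
        mu=st.floats(0.0, 0.5),
        s_h=st.floats(0.0, 1.0),
    ).filter(lambda p: not p.degenerate)


class TestRecursion:
    def test_extinction_is_absorbing(self):
        assert next_frequency(0.0, MEDIANS) == 0.0

    def test_fixation_absorbing_under_perfect_transmission(self):
        params = InvasionParams(f=1.2, mu=0.0, s_h=0.8)
        assert next_frequency(1.0, params) == 1.0

    def test_hand_evaluated_step_at_published_medians(self):
        assert next_frequency(0.1, MEDIANS) == pytest.approx(0.1125, abs=5e-5)

    @given(param_values(), st.floats(0.0, 1.0))
    def test_maps_unit_interval_into_itself(self, params, p):
        assert 0.0 <= next_frequency(p, params) <= 1.0

    @given(param_values())
    def test_monotone_approach_to_stable_equilibrium(self, params):
        """Strictly between threshold and fixation the frequency grows;
        strictly above fixation it declines."""
        fixation = fixation_prevalence(params)
        threshold = release_threshold(params)
        if fixation == 0.0 or threshold is None:
            return
        lo, hi = threshold, fixation
        if hi - lo > 1e-6:
            p = lo + 0.5 * (hi - lo)
            assert next_frequency(p, params) > p
        if fixation < 1.0 - 1e-6:
            p = fixation + 0.5 * (1.0 - fixation)
            assert next_frequency(p, params) < p


class TestEquilibria:
    def test_perfect_transmission_with_benefit_fixes(self):
        eq = equilibria(InvasionParams(f=1.2, mu=0.0, s_h=0.8))
        by_freq = {round(e.frequency, 6): e.stable for e in eq.points}
        assert by_freq[0.0] is False
        assert by_freq[1.0] is True

    def test_published_medians_have_single_stable_interior_root(self):
        eq = equilibria(MEDIANS)
        stable = eq.stable_in_unit_interval()
        assert len(stable) == 1
        assert stable[0] == pytest.approx(0.9660, abs=5e-5)
        assert eq.points[0].stable is False  # p=0 invadable

    def test_bistable_case_roots_and_stability(self):
        eq = equilibria(BISTABLE)
        assert eq.unstable_interior()[0] == pytest.approx(0.0667, abs=5e-5)
        assert max(eq.stable_in_unit_interval()) == pytest.approx(0.98590, abs=5e-5)

    def test_degenerate_neutral_case_flagged(self):
        eq = equilibria(InvasionParams(f=1.0, mu=0.0, s_h=0.0))
        assert eq.degenerate and eq.points == ()
        with pytest.raises(DegenerateModelError):
            fixation_prevalence(InvasionParams(f=1.0, mu=0.0, s_h=0.0))

    @given(param_values())
    def test_quadratic_roots_agree_with_iteration_limit(self, params):
        """Root-finder vs brute-force iteration from a point just above the
        threshold: the long-run limit is the stable equilibrium to 1e-8."""
        fixation = fixation_prevalence(params)
        threshold = release_threshold(params)
        if fixation == 0.0 or threshold is None or threshold > 0.95:
            return
        p = min(threshold + 0.02, 1.0)
        for _ in range(20_000):
            p_next = next_frequency(p, params)
            if abs(p_next - p) < 1e-14:
                p = p_next
                break
            p = p_next
        assert p == pytest.approx(fixation, abs=1e-8)

    def test_random_sweep_roots_vs_iteration(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 100:
            params = InvasionParams(
                f=float(rng.uniform(0.8, 1.6)),
                mu=float(rng.uniform(0.0, 0.4)),
                s_h=float(rng.uniform(0.05, 1.0)),
            )
            fixation = fixation_prevalence(params)
            threshold = release_threshold(params)
            if fixation == 0.0 or threshold is None or threshold > 0.9:
                continue
            p = threshold + 0.01 * (1 - threshold)
            for _ in range(200_000):
                p_next = next_frequency(p, params)
                if abs(p_next - p) < 1e-15:
                    break
                p = p_next
            assert p == pytest.approx(fixation, abs=1e-8)
            checked += 1


class TestFixationAndThreshold:
    def test_perfect_transmission_fixes_completely(self):
        assert fixation_prevalence(InvasionParams(f=1.2, mu=0.0, s_h=0.8)) == 1.0

    @given(st.floats(1.0, 2.0), st.floats(0.01, 1.0))
    def test_perfect_transmission_fixation_exact(self, f, s_h):
        params = InvasionParams(f=f, mu=0.0, s_h=s_h)
        if params.degenerate:
            return
        assert fixation_prevalence(params) == 1.0

    def test_published_medians(self):
        assert fixation_prevalence(MEDIANS) == pytest.approx(0.9660, abs=5e-5)
        assert release_threshold(MEDIANS) == 0.0

    def test_deleterious_without_ci_cannot_persist(self):
        params = InvasionParams(f=0.9, mu=0.2, s_h=0.0)
        assert fixation_prevalence(params) == 0.0
        assert release_threshold(params) is None

    def test_bistable_threshold_is_smaller_root(self):
        assert release_threshold(BISTABLE) == pytest.approx(0.0667, abs=5e-5)

    @given(param_values())
    def test_threshold_below_fixation_when_both_positive(self, params):
        fixation = fixation_prevalence(params)
        threshold = release_threshold(params)
        if threshold is not None and threshold > 0 and fixation > 0:
            assert threshold < fixation


class TestTimeToFixation:
    def test_published_medians_reach_target_in_15_generations(self):
        """Independent oracle: iterate the recursion inline and count."""
        target = 0.95 * fixation_prevalence(MEDIANS)
        p, generations = 0.10, 0
        while p < target:
            p = next_frequency(p, MEDIANS)
            generations += 1
        summary = time_to_fixation(MEDIANS)
        assert summary.generations_to_fixation == generations == 15
        assert summary.days_to_fixation == generations * 30.0

    def test_days_scale_with_generation_interval(self):
        demography = DemographyConfig(generation_days=25.0)
        summary = time_to_fixation(MEDIANS, demography)
        assert summary.days_to_fixation == summary.generations_to_fixation * 25.0

    def test_start_above_target_is_immediate(self):
        summary = time_to_fixation(MEDIANS, p0=0.96)
        assert summary.generations_to_fixation == 0
        assert summary.days_to_fixation == 0.0

    def test_release_below_threshold_never_fixes(self):
        summary = time_to_fixation(BISTABLE, p0=0.05)
        assert summary.generations_to_fixation is None
        assert summary.days_to_fixation is None
        assert "initial_prevalence_below_threshold" in summary.flags

    def test_no_invasion_possible_flagged(self):
        summary = time_to_fixation(InvasionParams(f=0.9, mu=0.2, s_h=0.0), p0=0.5)
        assert summary.generations_to_fixation is None
        assert "no_invasion_possible" in summary.flags

    def test_fractional_generations_bracket_integer_count(self):
        fractional = fractional_generations_to_fixation(MEDIANS)
        assert 14.0 < fractional <= 15.0

    def test_ci_parameter_mapping(self):
        ci = CIParameters(H=0.5, F=0.1925, W=0.2839, mu=0.1073, s_h=0.7976)
        params = invasion_params_from_ci(ci)
        assert params == MEDIANS
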