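"""Unit and property tests for the deterministic two-site model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldfine import (
    AssociationStat,
    HaplotypeFrequencies,
    StudyDesign,
    TwoSiteModel,
    chi_square_stats,
    ld_measures,
    population_state,
    prevalence,
    theorem_ratio,
)
from ldfine.twosite import FixationError

from conftest import random_valid_system


class TestPrevalence:
    def test_constant_penetrance_gives_that_prevalence(self):
        model = TwoSiteModel(0.03, 0.03, 0.03)
        for p in (0.01, 0.3, 0.9):
            assert prevalence(model, p) == pytest.approx(0.03, abs=1e-15)

    @pytest.mark.parametrize(
        "p, expected", [(0.3, 0.022), (0.5, 0.03)], ids=["p=0.3", "p=0.5"]
    )
    def test_worked_values(self, running_model, p, expected):
        assert prevalence(running_model, p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_frequency_domain_enforced(self, running_model, p):
        with pytest.raises(ValueError):
            prevalence(running_model, p)


class TestHaplotypeFrequencies:
    def test_derived_marginals_and_d_agree_both_forms(self, running_haps):
        h = running_haps
        assert h.p == pytest.approx(0.30, abs=1e-12)
        assert h.q == pytest.approx(0.40, abs=1e-12)
        assert h.D == pytest.approx(h.P11 - h.p * h.q, abs=1e-12)

    def test_from_pq_d_round_trips(self, running_haps):
        h2 = HaplotypeFrequencies.from_pq_d(0.3, 0.4, 0.13)
        assert np.allclose(h2.as_tuple(), running_haps.as_tuple(), atol=1e-12)

    def test_infeasible_d_rejected(self):
        with pytest.raises(ValueError, match="Lewontin"):
            HaplotypeFrequencies.from_pq_d(0.3, 0.4, 0.5)

    def test_simplex_violations_rejected(self):
        with pytest.raises(ValueError):
            HaplotypeFrequencies(0.5, 0.5, 0.5, -0.5)
        with pytest.raises(ValueError):
            HaplotypeFrequencies(0.3, 0.3, 0.3, 0.3)


class TestPopulationState:
    def test_worked_example_frequencies(self, running_model, running_haps):
        st_ = population_state(running_model, running_haps)
        assert st_.K == pytest.approx(0.022, abs=1e-12)
        assert st_.pD == pytest.approx(0.490909, abs=1e-6)
        assert st_.pC == pytest.approx(0.295706, abs=1e-6)
        assert st_.qD == pytest.approx(0.518182, abs=1e-6)
        assert st_.qC == pytest.approx(0.397342, abs=1e-6)
        assert np.allclose(st_.V, (0.409091, 0.081818, 0.109091, 0.400000), atol=1e-6)
        assert np.allclose(st_.U, (0.246421, 0.049284, 0.150920, 0.553374), atol=1e-6)

    def test_null_model_collapses_to_population(self, running_haps):
        st_ = population_state(TwoSiteModel(0.03, 0.03, 0.03), running_haps)
        assert st_.pD == pytest.approx(st_.pC) == pytest.approx(running_haps.p)
        assert st_.qD == pytest.approx(st_.qC) == pytest.approx(running_haps.q)
        assert np.allclose(st_.V, running_haps.as_tuple(), atol=1e-12)
        assert np.allclose(st_.U, running_haps.as_tuple(), atol=1e-12)

    def test_linkage_equilibrium_decouples_marker_only(self, running_model):
        haps = HaplotypeFrequencies.from_pq_d(0.3, 0.4, 0.0)
        st_ = population_state(running_model, haps)
        assert st_.qD == pytest.approx(0.4, abs=1e-12)
        assert st_.qC == pytest.approx(0.4, abs=1e-12)
        assert abs(st_.pD - st_.pC) > 0.01  # causal site still associated

    def test_conservation_and_mixture_identity(self, running_model, running_haps):
        st_ = population_state(running_model, running_haps)
        assert sum(st_.V) == pytest.approx(1.0, abs=1e-12)
        assert sum(st_.U) == pytest.approx(1.0, abs=1e-12)
        for Pij, Vij, Uij in zip(running_haps.as_tuple(), st_.V, st_.U):
            assert Pij == pytest.approx(st_.K * Vij + (1 - st_.K) * Uij, abs=1e-12)


class TestChiSquareStats:
    def test_worked_example_doubled_values(self, running_model, running_haps, running_design):
        st_ = population_state(running_model, running_haps)
        chi2_d, chi2_m = chi_square_stats(st_, running_design)
        assert chi2_d.convention == "pp_doubled"
        assert chi2_d.value == pytest.approx(362.90, abs=0.01)
        assert chi2_m.value == pytest.approx(121.69, abs=0.01)

    def test_null_model_statistic_is_zero(self, running_haps, running_design):
        st_ = population_state(TwoSiteModel(0.03, 0.03, 0.03), running_haps)
        chi2_d, chi2_m = chi_square_stats(st_, running_design)
        assert chi2_d.value == pytest.approx(0.0, abs=1e-20)
        assert chi2_m.value == pytest.approx(0.0, abs=1e-20)

    def test_statistic_linear_in_sample_size(self, running_model, running_haps):
        st_ = population_state(running_model, running_haps)
        small = chi_square_stats(st_, StudyDesign(2000, 2000))
        big = chi_square_stats(st_, StudyDesign(4000, 4000))
        assert big[0].value == pytest.approx(2 * small[0].value, rel=1e-12)
        assert big[1].value == pytest.approx(2 * small[1].value, rel=1e-12)


class TestLdMeasures:
    def test_worked_example(self, running_haps):
        D, r2 = ld_measures(running_haps)
        assert D == pytest.approx(0.13, abs=1e-12)
        assert r2 == pytest.approx(0.335317, abs=1e-6)

    def test_linkage_equilibrium_is_zero(self):
        D, r2 = ld_measures(HaplotypeFrequencies.from_pq_d(0.3, 0.4, 0.0))
        assert D == pytest.approx(0.0, abs=1e-15)
        assert r2 == pytest.approx(0.0, abs=1e-15)

    def test_perfect_ld_is_one(self):
        q = 0.3
        D, r2 = ld_measures(HaplotypeFrequencies(q, 0.0, 0.0, 1 - q))
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_fixation_rejected(self):
        with pytest.raises(FixationError):
            ld_measures(HaplotypeFrequencies(0.0, 0.0, 0.4, 0.6))


class TestTheorem:
    def test_worked_example_ratio_equals_r2(self, running_model, running_haps, running_design):
        ratio = theorem_ratio(running_model, running_haps, running_design)
        assert ratio == pytest.approx(ld_measures(running_haps)[1], abs=1e-10)

    def test_equilibrium_ratio_zero(self, running_model, running_design):
        haps = HaplotypeFrequencies.from_pq_d(0.3, 0.4, 0.0)
        assert theorem_ratio(running_model, haps, running_design) == pytest.approx(0.0, abs=1e-15)

    def test_marker_identical_to_causal_ratio_one(self, running_model, running_design):
        haps = HaplotypeFrequencies(0.3, 0.0, 0.0, 0.7)
        assert theorem_ratio(running_model, haps, running_design) == pytest.approx(1.0, abs=1e-12)

    def test_null_model_ratio_undefined(self, running_haps, running_design):
        with pytest.raises(ZeroDivisionError):
            theorem_ratio(TwoSiteModel(0.03, 0.03, 0.03), running_haps, running_design)

    def test_exact_over_random_systems(self):
        """Mode-of-inheritance invariance: ratio == r2 for arbitrary penetrances."""
        rng = np.random.default_rng(20160217)
        for _ in range(300):
            model, haps, design = random_valid_system(rng)
            _, r2 = ld_measures(haps)
            try:
                ratio = theorem_ratio(model, haps, design)
            except ZeroDivisionError:
                continue  # exactly-null draw
            assert ratio == pytest.approx(r2, abs=1e-10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        p=st.floats(0.01, 0.99),
        q=st.floats(0.01, 0.99),
        frac=st.floats(0.0, 1.0),
        f11=st.floats(0.001, 0.999),
        f12=st.floats(0.001, 0.999),
        f22=st.floats(0.001, 0.999),
    )
    def test_theorem_property(self, p, q, frac, f11, f12, f22):
        lo = max(-p * q, -(1 - p) * (1 - q))
        hi = min(p * (1 - q), q * (1 - p))
        haps = HaplotypeFrequencies.from_pq_d(p, q, lo + frac * (hi - lo))
        model = TwoSiteModel(f11, f12, f22)
        design = StudyDesign(1000, 3000)
        _, r2 = ld_measures(haps)
        try:
            ratio = theorem_ratio(model, haps, design)
        except ZeroDivisionError:
            return
        assert ratio == pytest.approx(r2, abs=1e-10)


class TestAssociationStat:
    def test_convention_round_trip_preserves_pvalue(self):
        doubled = AssociationStat(20.0, "pp_doubled")
        trad = doubled.to("traditional_1df")
        assert trad.value == pytest.approx(10.0)
        assert trad.pvalue == doubled.pvalue
        assert trad.to("pp_doubled").value == pytest.approx(20.0)

    def test_round_trip_is_identity(self):
        s = AssociationStat(7.3, "traditional_1df")
        assert s.to("traditional_1df") is s
        assert s.to("pp_doubled").to("traditional_1df").value == pytest.approx(7.3)

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            AssociationStat(-1.0)


def test_extreme_penetrances_keep_prevalence_in_range():
    # K is a convex combination of the penetrances, so it stays in (0, 1)
    # for any valid model; the degenerate guard protects subclass misuse.
    model = TwoSiteModel(0.999, 0.999, 0.999)
    haps = HaplotypeFrequencies.from_pq_d(0.5, 0.5, 0.1)
    st_ = population_state(model, haps)
    assert 0.0 < st_.K < 1.0
    assert sum(st_.U) == pytest.approx(1.0, abs=1e-9)


def test_penetrance_domain_enforced():
    for bad in ((0.0, 0.5, 0.5), (0.5, 1.0, 0.5), (0.5, 0.5, -0.1)):
        with pytest.raises(ValueError):
            TwoSiteModel(*bad)
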