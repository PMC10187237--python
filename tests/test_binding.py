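"""Closed-form binding models, growth law, and their weighted fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mtelong import (
    NucleotideMix,
    competition_model,
    cpp_tubulin_concentration,
    fit_affinity_ratio,
    fit_competition,
    fit_isotherm,
    minus_growth_prediction,
    propagate_sem,
    quench_isotherm,
)
from mtelong.binding import BindingParams
from mtelong.lattice import ConfigurationError


class TestCompetitivePartition:
    def test_no_competitor_leaves_the_pool_untouched(self):
        assert cpp_tubulin_concentration(1.25, NucleotideMix(0.0), 12.5) == 1.25

    def test_direct_substitution(self):
        got = cpp_tubulin_concentration(1.25, NucleotideMix(25.0), 12.5)
        assert got == pytest.approx(1.25 * 975.0 / 1287.5)
        assert got == pytest.approx(0.9466, abs=1e-4)

    def test_infinite_preference_limit(self):
        got = cpp_tubulin_concentration(1.25, NucleotideMix(25.0), 1e12)
        assert got == pytest.approx(0.0, abs=1e-9)

    def test_no_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            cpp_tubulin_concentration(1.25, NucleotideMix(0.0, total=0.0), 12.5)

    @given(
        gdp=st.floats(0.0, 900.0),
        kd_cpp=st.floats(1e-3, 10.0),
    )
    def test_exact_form_converges_to_simplified(self, gdp, kd_cpp):
        """The simplified partition drops KD_CPP against [GMPCPP]; the
        relative error of doing so is bounded by KD_CPP/[GMPCPP], so the
        forms agree to <0.5% whenever [GMPCPP] >= 200 * KD_CPP."""
        mix = NucleotideMix(gdp)
        if mix.cpp_conc < 100 * kd_cpp:
            return
        simple = cpp_tubulin_concentration(1.25, mix, 12.5)
        exact = cpp_tubulin_concentration(1.25, mix, 12.5, kd_cpp=kd_cpp)
        assert exact == pytest.approx(simple, rel=kd_cpp / mix.cpp_conc + 1e-9)
        if mix.cpp_conc >= 200 * kd_cpp:
            assert exact == pytest.approx(simple, rel=5e-3)


class TestGrowthLaw:
    def test_all_gmpcpp_rate(self):
        assert minus_growth_prediction(1.25, 0.0, 12.5) == pytest.approx(1.075)

    def test_rate_vanishes_at_the_critical_concentration(self):
        # CPP-tubulin at the x-intercept 0.05/0.9 uM gives zero growth
        got = 0.9 * (0.05 / 0.9) - 0.05
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_pure_gdp_clamps_to_zero_for_display(self):
        raw = minus_growth_prediction(1.25, 1000.0, 12.5)
        assert raw == pytest.approx(-0.05)
        with pytest.warns(UserWarning, match="clamped"):
            assert minus_growth_prediction(1.25, 1000.0, 12.5, clamp=True) == 0.0

    @given(g=st.floats(0.0, 900.0), r=st.floats(1.0, 50.0))
    def test_monotone_decreasing_in_gdp_and_ratio(self, g, r):
        base = minus_growth_prediction(1.25, g, r)
        assert minus_growth_prediction(1.25, g + 50.0, r) <= base + 1e-12
        assert minus_growth_prediction(1.25, g, r + 5.0) <= base + 1e-12


class TestAffinityRatioFit:
    @staticmethod
    def dataset(ratio, cv=0.0, seed=0, tub=1.25):
        gdp = np.array([0.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0])
        y = np.array([minus_growth_prediction(tub, g, ratio) for g in gdp])
        sem = np.maximum(0.05 * np.abs(y), 1e-3)
        if cv > 0:
            y = y + np.random.default_rng(seed).normal(0.0, cv * np.abs(y))
        return pd.DataFrame({"x_uM": gdp, "y": y, "sem": sem})

    def test_noiseless_recovery_to_four_digits(self):
        res = fit_affinity_ratio(self.dataset(12.5), tub_total=1.25)
        assert res.params["affinity_ratio"] == pytest.approx(12.5, abs=5e-4)

    def test_indifferent_nucleotides_recover_unity(self):
        res = fit_affinity_ratio(self.dataset(1.0), tub_total=1.25)
        assert res.params["affinity_ratio"] == pytest.approx(1.0, rel=1e-4)

    def test_weight_rescaling_leaves_the_fit_invariant(self):
        df = self.dataset(12.5, cv=0.05, seed=4)
        res1 = fit_affinity_ratio(df, tub_total=1.25)
        df2 = df.assign(sem=df["sem"] * 37.0)
        res2 = fit_affinity_ratio(df2, tub_total=1.25)
        assert res1.params["affinity_ratio"] == pytest.approx(res2.params["affinity_ratio"])
        assert res1.stderr["affinity_ratio"] == pytest.approx(res2.stderr["affinity_ratio"])

    def test_noisy_recovery_within_confidence_interval(self):
        hits = 0
        for seed in range(40):
            res = fit_affinity_ratio(self.dataset(12.5, cv=0.05, seed=seed), tub_total=1.25)
            lo, hi = res.ci95["affinity_ratio"]
            hits += lo <= 12.5 <= hi
        assert hits >= 32  # ~95% coverage, generous binomial slack

    def test_too_few_points_rejected(self):
        df = self.dataset(12.5).iloc[:2]
        with pytest.raises(ValueError):
            fit_affinity_ratio(df, tub_total=1.25)


class TestIsotherm:
    def test_zero_ligand_gives_the_baseline(self):
        assert quench_isotherm(0.0, 0.6, 1.0, 2.5) == pytest.approx(1.0)

    def test_half_saturation_at_kd(self):
        assert quench_isotherm(2.5, 0.6, 1.0, 2.5) == pytest.approx(1.0 - 0.3)

    def test_noiseless_roundtrip(self):
        x = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 10.0, 20.0, 40.0])
        y = quench_isotherm(x, 0.6, 1.0, 2.5)
        res = fit_isotherm((x, y, np.full_like(x, 0.01)))
        assert res.params["amp_A"] == pytest.approx(0.6, rel=1e-5)
        assert res.params["base_B"] == pytest.approx(1.0, rel=1e-5)
        assert res.params["kd_6t"] == pytest.approx(2.5, rel=1e-4)

    def test_underdetermined_fit_rejected(self):
        with pytest.raises(ValueError):
            fit_isotherm(([0.0, 1.0], [1.0, 0.8], None))


class TestCompetition:
    def test_limits(self):
        assert competition_model(0.0, 3.0, 0.6, 0.45, 40.0, 2.5) == pytest.approx(0.45)
        assert competition_model(1e12, 3.0, 0.6, 0.45, 40.0, 2.5) == pytest.approx(1.05)

    def test_amplitude_must_be_constrained(self):
        with pytest.raises(ValueError):
            fit_competition(([1.0], [0.5], None), amp_A=None, kd_6t=2.5)

    def test_noiseless_roundtrip(self):
        x = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0])
        y = competition_model(x, 3.0, 0.6, 0.45, 40.0, 2.5)
        res = fit_competition((x, y, np.full_like(x, 0.01)), amp_A=0.6, kd_6t=2.5)
        assert res.params["kd_nuc"] == pytest.approx(40.0, rel=1e-4)
        assert res.params["floor_C"] == pytest.approx(0.45, rel=1e-4)

    def test_competitor_pair_recovers_the_affinity_ratio(self):
        """Two competitors with a true 12.5-fold KD difference fit back to
        a 12.5-fold ratio through the full competition pipeline."""
        x = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0])
        kds = {}
        for name, kd in [("cpp", 50.0), ("gdp", 4.0)]:
            y = competition_model(x, 3.0, 0.6, 0.45, kd, 2.5)
            res = fit_competition((x, y, np.full_like(x, 0.01)), amp_A=0.6, kd_6t=2.5)
            kds[name] = res.params["kd_nuc"]
        assert kds["cpp"] / kds["gdp"] == pytest.approx(12.5, rel=1e-3)


class TestSemPropagation:
    def test_zero_errors_propagate_to_zero(self):
        assert propagate_sem((100, 0.0), (50, 0.0), (10, 0.0)) == 0.0

    def test_equal_relative_errors(self):
        e = 0.02
        got = propagate_sem((100, 2.0), (50, 1.0), (10, 0.2))
        assert got == pytest.approx(np.sqrt(3) * e * 0.5)

    def test_direct_arithmetic_example(self):
        got = propagate_sem((100, 1.0), (50, 1.0), (10, 0.5))
        assert got == pytest.approx(np.sqrt(0.0001 + 0.0004 + 0.0025) * 0.5)
        assert got == pytest.approx(0.02739, abs=1e-5)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            propagate_sem((0.0, 1.0), (50, 1.0), (10, 0.5))


def test_binding_params_validation():
    with pytest.raises(ConfigurationError):
        BindingParams(amp_A=1.2, base_B=1.0, kd_6t=2.5)
    with pytest.raises(ConfigurationError):
        BindingParams(amp_A=0.6, base_B=1.0, kd_6t=-1.0)
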