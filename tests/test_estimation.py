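"""Regime classification and model fitting."""

import math

import numpy as np
import pytest

from phip_kinetics import (
    CONSTANTS,
    ArrheniusParams,
    DesignSpec,
    FirstOrderParams,
    InsufficientDataError,
    Molecularity,
    Regime,
    arrhenius_rate,
    assemble_transition_state,
    builtin_profiles,
    classify_regime,
    fit_arrhenius,
    fit_degradation,
    fit_first_order,
    generate_series,
    predict_concentration,
    summarize_system,
)
from conftest import make_series


def _series_from_curve(A, k, t0, times=(4.0, 8.0, 12.0, 16.0), reps=1):
    params = FirstOrderParams(A, k, t0)
    rows = []
    for t in times:
        c = predict_concentration(params, t)
        for r in range(reps):
            rows.append((t, f"r{r}", c if c > 0 else None))
    return make_series("synthetic", 200.0, rows)


class TestClassifyRegime:
    def test_all_non_detect(self):
        s = make_series("gly", 150.0, [(t, "r1", None) for t in (4, 8, 12, 16)])
        assert classify_regime(s) is Regime.NOT_FORMED

    def test_strictly_increasing_means(self):
        s = make_series(
            "phe", 180.0,
            [(4, "r1", 0.5), (8, "r1", 1.0), (12, "r1", 1.4), (16, "r1", 1.6)],
        )
        assert classify_regime(s) is Regime.FORMATION

    def test_peak_then_decline(self):
        # shaped like the 240C series: peak 21.41 at 8 min, 19.50 at 12 min
        s = make_series(
            "phe", 240.0,
            [(4, "r1", 19.0), (8, "r1", 21.41), (12, "r1", 19.50),
             (16, "r1", 18.2)],
        )
        assert classify_regime(s) is Regime.DEGRADATION

    def test_shallow_decline_within_threshold_is_formation(self):
        s = make_series(
            "phe", 210.0,
            [(4, "r1", 1.0), (8, "r1", 2.0), (12, "r1", 2.1), (16, "r1", 2.05)],
        )
        assert classify_regime(s, decline_threshold=0.05) is Regime.FORMATION

    def test_invariant_to_replicate_order_and_scale(self):
        rows = [(4, "a", 2.0), (8, "a", 5.0), (12, "a", 4.0), (16, "a", 3.0),
                (4, "b", 2.2), (8, "b", 5.2), (12, "b", 4.1), (16, "b", 3.1)]
        base = classify_regime(make_series("x", 240.0, rows))
        shuffled = classify_regime(make_series("x", 240.0, rows[::-1]))
        scaled = classify_regime(
            make_series("x", 240.0, [(t, r, 1000 * c) for t, r, c in rows])
        )
        assert base is shuffled is scaled is Regime.DEGRADATION


class TestFitFirstOrder:
    def test_noiseless_recovery(self):
        fit = fit_first_order(_series_from_curve(10.0, 0.05, 1.0))
        assert fit.converged
        assert fit.params.plateau_A == pytest.approx(10.0, rel=1e-4)
        assert fit.params.rate_k == pytest.approx(0.05, rel=1e-4)
        assert fit.params.lag_t0 == pytest.approx(1.0, abs=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_lag_pinned_at_zero_for_steep_rise(self):
        # proline-210-like: steep rise from the first time point
        fit = fit_first_order(_series_from_curve(0.44, 1.1757, 0.0))
        assert fit.converged
        assert fit.params.lag_t0 == pytest.approx(0.0, abs=1e-6)

    def test_leading_non_detects_inform_lag(self):
        true = FirstOrderParams(0.5, 0.1, 6.0)
        rows = []
        for t in (2.0, 4.0, 8.0, 12.0, 16.0):
            c = predict_concentration(true, t)
            rows.append((t, "r1", c if c > 0 else None))
        fit = fit_first_order(make_series("pro", 180.0, rows))
        assert fit.converged
        assert fit.params.lag_t0 == pytest.approx(6.0, abs=0.2)

    def test_insufficient_distinct_times(self):
        s = make_series("x", 200.0, [(4, "r1", 1.0), (8, "r1", 2.0)])
        with pytest.raises(InsufficientDataError):
            fit_first_order(s)

    def test_forward_inverse_r_squared_consistency(self):
        """Re-predicting the fitted points reproduces the reported R^2."""
        prof = builtin_profiles()["phenylalanine_like"]
        s = generate_series(prof, 210.0, DesignSpec(seed=3))
        fit = fit_first_order(s)
        pts = [(o.time_min, o.concentration) for o in s.observations if o.detected]
        c = np.array([p[1] for p in pts])
        pred = np.array([predict_concentration(fit.params, p[0]) for p in pts])
        r2 = 1 - np.sum((c - pred) ** 2) / np.sum((c - c.mean()) ** 2)
        assert r2 == pytest.approx(fit.r_squared, abs=1e-9)


class TestFitDegradation:
    def test_two_points_reduce_to_closed_form(self):
        s = make_series("phe", 240.0, [(8, "r1", 21.41), (12, "r1", 19.50)])
        res = fit_degradation(s)
        assert res.params.rate_kd == pytest.approx(0.02336, abs=5e-6)
        assert res.params.initial_CA0 == pytest.approx(21.41)
        assert res.params.reference_time == 8.0

    def test_pure_exponential_recovered_exactly(self):
        kd, peak, t_peak = 0.1, 5.0, 4.0
        rows = [(t, "r1", peak * math.exp(-kd * (t - t_peak)))
                for t in (4.0, 8.0, 12.0, 16.0)]
        res = fit_degradation(make_series("x", 270.0, rows))
        assert res.params.rate_kd == pytest.approx(kd, rel=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_series_zero_rate(self):
        rows = [(t, "r1", 2.0) for t in (4.0, 8.0, 12.0, 16.0)]
        res = fit_degradation(make_series("x", 240.0, rows))
        assert res.params.rate_kd == 0.0

    def test_elapsed_time_measured_from_peak(self):
        # same decay observed with and without a pre-peak point
        kd = 0.05
        tail = [(t, "r1", 3.0 * math.exp(-kd * (t - 8.0))) for t in (8., 12., 16.)]
        with_rise = [(4.0, "r1", 1.0)] + tail
        res = fit_degradation(make_series("x", 240.0, with_rise))
        assert res.params.rate_kd == pytest.approx(kd, rel=1e-10)
        assert res.params.reference_time == 8.0

    def test_insufficient_tail(self):
        s = make_series("x", 240.0, [(4, "r1", 1.0), (8, "r1", 2.0)])
        # peak at the final time: nothing to decay into
        with pytest.raises(InsufficientDataError):
            fit_degradation(s)


class TestFitArrhenius:
    def test_reference_three_point_regression(self, phe_pairs):
        res = fit_arrhenius(phe_pairs)
        assert res.params.Ea == pytest.approx(95.36, rel=0.01)
        assert res.params.Ea == pytest.approx(94.8314, abs=1e-3)

    def test_two_point_equals_closed_form(self):
        # independent closed-form oracle for n = 2
        (k1, T1), (k2, T2) = (0.0268, 453.15), (1.1757, 483.15)
        Ea_oracle = (
            CONSTANTS.R * math.log(k2 / k1) / (1 / T1 - 1 / T2) / 1000.0
        )
        res = fit_arrhenius([(k1, T1), (k2, T2)])
        assert res.params.Ea == pytest.approx(Ea_oracle, rel=1e-10)

    def test_identical_rates_zero_ea(self):
        res = fit_arrhenius([(0.05, 423.15), (0.05, 483.15)])
        assert res.params.Ea == pytest.approx(0.0, abs=1e-12)

    def test_exact_log_linear_data_recovered(self):
        true = ArrheniusParams(Ea=100.0, ln_preexp=20.0)
        pairs = [(arrhenius_rate(true, T), T) for T in (420.0, 450.0, 480.0, 510.0)]
        res = fit_arrhenius(pairs)
        assert res.params.Ea == pytest.approx(100.0, rel=1e-10)
        assert res.params.ln_preexp == pytest.approx(20.0, rel=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            fit_arrhenius([(0.05, 453.15)])


class TestAssembleTransitionState:
    def test_phenylalanine_reference_values(self, phe_pairs):
        arr = fit_arrhenius(phe_pairs)
        ts = assemble_transition_state(arr, phe_pairs)
        assert ts.dH == pytest.approx(91.6, abs=0.6)
        assert ts.dS == pytest.approx(-83.95, abs=1.5)
        assert ts.molecularity is Molecularity.BIMOLECULAR

    def test_degenerate_point_is_indeterminate(self):
        # one pair with k equal to the frequency factor and Ea = R T:
        # both activation parameters vanish
        from phip_kinetics import ArrheniusResult

        T = 453.15
        k_freq = CONSTANTS.k_B * T / CONSTANTS.h
        Ea = CONSTANTS.R * T / 1000.0
        arr = ArrheniusResult(ArrheniusParams(Ea, 0.0), 1.0, (T,))
        ts = assemble_transition_state(arr, [(k_freq, T)])
        assert ts.dH == pytest.approx(0.0, abs=1e-9)
        assert ts.dS == pytest.approx(0.0, abs=1e-9)
        assert ts.molecularity is Molecularity.INDETERMINATE

    def test_si_convention_shift(self, phe_pairs):
        arr = fit_arrhenius(phe_pairs)
        paper = assemble_transition_state(arr, phe_pairs, "paper")
        si = assemble_transition_state(arr, phe_pairs, "si")
        assert paper.dS - si.dS == pytest.approx(
            CONSTANTS.R * math.log(60), abs=1e-9
        )


class TestSummarizeSystem:
    DESIGN = DesignSpec(seed=1, noise_proportional=0.01, noise_absolute=0.001)

    def _series_for(self, name):
        prof = builtin_profiles()[name]
        return [generate_series(prof, T, self.DESIGN)
                for T in self.DESIGN.temperatures]

    def test_phenylalanine_like_full_summary(self):
        summ = summarize_system(self._series_for("phenylalanine_like"))
        assert sorted(summ.formation_fits) == [150.0, 180.0, 210.0]
        assert sorted(summ.degradation_fits) == [240.0, 270.0]
        assert summ.arrhenius is not None
        assert summ.transition_state.molecularity is Molecularity.BIMOLECULAR

    def test_glycine_like_nothing_fitted(self):
        summ = summarize_system(self._series_for("glycine_like"))
        assert all(r is Regime.NOT_FORMED for r in summ.regimes.values())
        assert not summ.formation_fits and not summ.degradation_fits
        assert summ.arrhenius is None and summ.transition_state is None
        assert summ.warnings

    def test_proline_like_two_formation_temperatures(self):
        summ = summarize_system(self._series_for("proline_like"))
        assert sorted(summ.formation_fits) == [180.0, 210.0]
        assert summ.arrhenius is not None
        assert len(summ.arrhenius.temperatures_K) == 2

    def test_deterministic(self):
        a = summarize_system(self._series_for("phenylalanine_like"))
        b = summarize_system(self._series_for("phenylalanine_like"))
        assert a.arrhenius.params == b.arrhenius.params
        assert a.formation_fits == b.formation_fits

    def test_mixed_systems_rejected(self):
        s1 = self._series_for("proline_like")[1]
        s2 = self._series_for("glycine_like")[1]
        with pytest.raises(ValueError):
            summarize_system([s1, s2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_system([])
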