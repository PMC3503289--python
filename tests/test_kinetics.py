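import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from immobead import (
    ConversionSeries,
    MMKinetics,
    conversion,
    integrated_time,
    mm_rate,
    predict_outlet,
    read_conversion_csv,
    turnover_number,
    write_conversion_csv,
)

K11 = MMKinetics(km=1.0, vmax=1.0)


class TestMMKinetics:
    def test_requires_positive_km_vmax(self):
        with pytest.raises(ValueError):
            MMKinetics(km=-1.0, vmax=1.0)
        with pytest.raises(ValueError):
            MMKinetics(km=1.0, vmax=0.0)

    def test_vmax_k2_e0_consistency_enforced(self):
        MMKinetics(km=1.0, vmax=2.0, k2=2.0, e0=1.0)  # consistent: fine
        with pytest.raises(ValueError, match="Vmax"):
            MMKinetics(km=1.0, vmax=2.0, k2=3.0, e0=1.0)

    def test_km_rate_constant_consistency_enforced(self):
        MMKinetics(km=2.0, vmax=1.0, k2=1.0, k1=1.0, k_minus1=1.0)
        with pytest.raises(ValueError, match="Km"):
            MMKinetics(km=5.0, vmax=1.0, k2=1.0, k1=1.0, k_minus1=1.0)

    def test_from_seconds_converts_rates(self):
        k = MMKinetics.from_seconds(km=3.38, vmax_per_s=0.134, k2_per_s=0.05,
                                    e0=None)
        assert k.vmax == pytest.approx(8.04)
        assert k.k2 == pytest.approx(3.0)
        assert k.km == 3.38  # concentrations are not rates: unchanged


class TestRate:
    @pytest.mark.parametrize(
        "s, expected",
        [(0.0, 0.0), (1.0, 0.5), (9.0, 0.9)],  # zero, half-saturation, 9*Km
    )
    def test_known_values(self, s, expected):
        assert mm_rate(s, K11) == pytest.approx(expected)

    def test_rejects_negative_substrate(self):
        with pytest.raises(ValueError):
            mm_rate(-0.1, K11)

    @given(st.floats(min_value=0.0, max_value=1e6))
    @settings(derandomize=True, max_examples=50)
    def test_bounded_by_vmax(self, s):
        assert 0.0 <= mm_rate(s, K11) < K11.vmax

    def test_monotone_in_substrate(self):
        s = np.linspace(0, 100, 500)
        assert np.all(np.diff(mm_rate(s, K11)) >= 0)


class TestIntegratedForm:
    def test_no_conversion_takes_no_time(self):
        assert integrated_time(5.0, 5.0, K11) == 0.0

    def test_direct_evaluation(self):
        # Km=1, Vmax=1: t = ln(2) + 1 for S0=2 -> St=1
        assert integrated_time(2.0, 1.0, K11) == pytest.approx(math.log(2) + 1)

    def test_zero_order_limit_small_km(self):
        k = MMKinetics(km=1e-9, vmax=2.0)
        assert integrated_time(10.0, 4.0, k) == pytest.approx(6.0 / 2.0, rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            integrated_time(5.0, 0.0, K11)
        with pytest.raises(ValueError):
            integrated_time(5.0, 6.0, K11)

    def test_strictly_decreasing_in_outlet(self):
        sts = np.linspace(0.1, 5.0, 50)
        ts = [integrated_time(5.0, s, K11) for s in sts]
        assert np.all(np.diff(ts) < 0)


class TestPredictOutlet:
    def test_zero_time_returns_inlet(self):
        assert predict_outlet(7.0, 0.0, K11) == 7.0

    def test_inverse_of_integrated_time(self):
        assert predict_outlet(2.0, math.log(2) + 1, K11) == pytest.approx(1.0)

    def test_first_order_closed_form_in_dilute_limit(self):
        # S0 << Km: dS/dt ~ -(Vmax/Km) S, so St = S0 exp(-Vmax t / Km)
        s0 = K11.km / 1000.0
        st = predict_outlet(s0, 2.0, K11)
        assert st == pytest.approx(s0 * math.exp(-2.0), rel=2e-3)

    def test_round_trip_over_three_decades(self):
        for km in (0.05, 0.5, 5.0, 50.0):
            for vmax in (0.02, 0.2, 2.0, 20.0):
                k = MMKinetics(km=km, vmax=vmax)
                for s0 in (0.1, 1.0, 10.0, 100.0):
                    st_true = 0.3 * s0
                    t = integrated_time(s0, st_true, k)
                    assert predict_outlet(s0, t, k) == pytest.approx(
                        st_true, rel=1e-10
                    )

    def test_agrees_with_ode_integration(self):
        # independent oracle: adaptive integration of dS/dt = -Vmax S/(Km+S)
        rng = np.random.default_rng(42)
        for _ in range(100):
            km = 10 ** rng.uniform(-1, 1)
            vmax = 10 ** rng.uniform(-1, 1)
            s0 = 10 ** rng.uniform(-0.5, 1.5)
            k = MMKinetics(km=km, vmax=vmax)
            t_end = 0.5 * integrated_time(s0, 0.05 * s0, k)
            sol = solve_ivp(
                lambda t, y: [-vmax * y[0] / (km + y[0])],
                (0.0, t_end),
                [s0],
                rtol=1e-10,
                atol=1e-12 * s0,
            )
            assert predict_outlet(s0, t_end, k) == pytest.approx(
                sol.y[0, -1], rel=1e-6
            )


class TestConversion:
    @pytest.mark.parametrize(
        "s0, st, x", [(10, 10, 0.0), (10, 0, 1.0), (10, 2.5, 0.75)]
    )
    def test_values(self, s0, st, x):
        assert conversion(s0, st) == pytest.approx(x)

    def test_outlet_above_inlet_rejected(self):
        with pytest.raises(ValueError):
            conversion(10.0, 11.0)

    def test_antitone_in_outlet(self):
        xs = [conversion(10.0, st) for st in np.linspace(0, 10, 30)]
        assert np.all(np.diff(xs) < 0)


class TestTurnoverNumber:
    def test_definition_and_round_trip(self):
        assert turnover_number(1.0, 1.0) == 1.0
        assert turnover_number(0.162, 0.081) == pytest.approx(2.0)
        assert turnover_number(3.5 * 0.081, 0.081) == pytest.approx(3.5)

    def test_zero_enzyme_rejected(self):
        with pytest.raises(ValueError):
            turnover_number(1.0, 0.0)


class TestConversionSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            ConversionSeries(s0=10.0, t=[5, 5], st=[3, 2])  # non-increasing t
        with pytest.raises(ValueError):
            ConversionSeries(s0=10.0, t=[5, 10], st=[3, 12])  # St > S0
        with pytest.raises(ValueError):
            ConversionSeries(s0=10.0, t=[-1, 10], st=[3, 2])

    def test_csv_round_trip(self, tmp_path):
        a = ConversionSeries(s0=10.0, t=[5.0, 10.0], st=[6.0, 4.0])
        b = ConversionSeries(s0=2.0, t=[5.0, 10.0, 20.0], st=[1.5, 1.0, 0.5])
        path = tmp_path / "conv.csv"
        write_conversion_csv([a, b], path)
        back = read_conversion_csv(path)
        assert len(back) == 2
        assert back[0].s0 == 10.0 and back[1].s0 == 2.0
        np.testing.assert_allclose(back[0].st, a.st)
        np.testing.assert_allclose(back[1].t, b.t)
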