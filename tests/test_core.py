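"""Grey SCGM(1,1)_c estimators, restored fit and diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import greymarkov as gm
from greymarkov.core import DEGENERATE_A, accumulated_response
from greymarkov.errors import DegenerateTrendError, SeriesValidationError
from greymarkov.synthetic import SyntheticSpec, generate_gray_series


class TestDevelopmentCoefficient:
    def test_constant_sequence_gives_zero(self):
        assert gm.estimate_development([7.0] * 10) == pytest.approx(0.0)

    def test_geometric_sequence_recovers_log_ratio_exactly(self):
        k = np.arange(2, 20)
        xm = 100.0 * 0.9**k
        assert gm.estimate_development(xm) == pytest.approx(np.log(0.9), abs=1e-14)

    def test_fixture_value(self, coal_series):
        # frozen from an independent evaluation of the two sums
        xm = gm.mean_generate(coal_series)
        assert gm.estimate_development(xm) == pytest.approx(-0.0349363252, abs=1e-9)

    def test_nonpositive_entries_rejected(self):
        with pytest.raises(SeriesValidationError):
            gm.estimate_development([1.0, -2.0, 3.0])


class TestAmplitudeAndOffset:
    def test_perfect_regressor_gives_unit_slope(self):
        a = -0.1
        k = np.arange(2, 15)
        xa = np.exp(a * (k - 1))
        assert gm.estimate_amplitude(a, xa) == pytest.approx(1.0, abs=1e-12)

    def test_slope_is_intercept_invariant(self):
        a = -0.07
        k = np.arange(2, 12)
        xa = 3.0 * np.exp(a * (k - 1)) + 5.0
        assert gm.estimate_amplitude(a, xa) == pytest.approx(3.0, abs=1e-10)

    def test_zero_development_is_degenerate(self):
        with pytest.raises(DegenerateTrendError):
            gm.estimate_amplitude(0.0, np.arange(1.0, 10.0))

    def test_exact_offset_free_accumulated_gives_zero_c(self):
        a, b = -0.05, 7.0
        k = np.arange(2, 14)
        xa = b * np.exp(a * k)
        c, u = gm.estimate_offset(a, b, xa)
        assert c == pytest.approx(0.0, abs=1e-10)
        assert u == pytest.approx(0.0, abs=1e-10)

    def test_downward_shift_appears_in_offset(self):
        a, b, delta = -0.05, 7.0, 2.5
        k = np.arange(2, 14)
        xa = b * np.exp(a * k) - delta
        c, _ = gm.estimate_offset(a, b, xa)
        assert c == pytest.approx(delta, abs=1e-10)

    def test_zero_development_limit_is_level_difference(self):
        xa = np.array([4.0, 5.0, 6.0])
        c, u = gm.estimate_offset(0.0, 10.0, xa)
        assert c == pytest.approx(10.0 - xa.mean())
        assert u == 0.0


class TestRestoredFit:
    def test_closed_form_halving(self):
        # a = ln(1/2) and M = 1 (hence b = -3 by the amplitude identity)
        p = gm.SCGMParameters(a=np.log(0.5), b=-3.0, c=0.0, U=0.0, M=1.0)
        vals = gm.restored_fit(p, [2, 3])
        assert vals[0] == pytest.approx(1.0, abs=1e-14)
        assert vals[1] == pytest.approx(0.5, abs=1e-14)

    def test_amplitude_identity_holds(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.uniform(-0.3, -0.01)
            b = rng.uniform(-1e5, -1e2)
            m_amp = (1 - np.exp(-a)) * b / (1 + np.exp(-a))
            p = gm.SCGMParameters(a=a, b=b, c=0.0, U=0.0, M=m_amp)
            k = np.arange(2, 10)
            np.testing.assert_allclose(
                gm.restored_fit(p, k),
                2 * b * (1 - np.exp(-a)) / (1 + np.exp(-a)) * np.exp(a * (k - 1)),
                rtol=1e-12,
            )

    def test_k1_is_undefined_marker(self, coal_params):
        out = gm.restored_fit(coal_params, [1, 2, 3])
        assert np.isnan(out[0]) and np.all(np.isfinite(out[1:]))

    def test_fixture_1991_close_to_published_under_table_convention(self, coal_params):
        fitted = gm.restored_fit(coal_params, [2], shift=1)[0]
        assert fitted == pytest.approx(7716, rel=0.01)

    def test_fixture_published_column_within_tolerance(self, coal_params):
        """The published fitted column 1991-2009 is the shifted-convention
        evaluation of the refit parameters (2010 is a suspected misprint)."""
        published = [7716, 7451, 7196, 6949, 6710, 6479, 6257, 6042, 5835,
                     5635, 5441, 5254, 5074, 4899, 4731, 4569, 4412, 4261, 4114]
        fitted = gm.restored_fit(coal_params, range(2, 21), shift=1)
        np.testing.assert_allclose(fitted, published, rtol=0.01)

    def test_published_development_pair_is_not_reproduced(self, coal_params):
        # the originally published a = -0.039436 is inconsistent with the
        # raw data; the refit coefficient differs by far more than noise
        assert abs(coal_params.a - (-0.039436)) > 1e-3

    def test_differenced_accumulated_response_restores_fit(self, coal_params):
        k = np.arange(2, 22)
        resp = accumulated_response(coal_params, np.concatenate([[1], k]))
        restored = 2 * np.diff(resp) / (1 + np.exp(-coal_params.a))
        np.testing.assert_allclose(restored, gm.restored_fit(coal_params, k),
                                   rtol=1e-12)


class TestFitProperties:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=-0.2, max_value=-0.005),
        M=st.floats(min_value=1.0, max_value=1e4),
        n=st.integers(min_value=6, max_value=40),
    )
    def test_exact_recovery_on_noiseless_model(self, a, M, n):
        ts = generate_gray_series(SyntheticSpec(a=a, M=M, n=n, noise="none"))
        p = gm.fit(ts)
        assert abs(p.a - a) < 1e-10

    def test_scale_equivariance(self, coal_series):
        lam = 3.7
        scaled = gm.TimeSeries(coal_series.labels,
                               tuple(lam * v for v in coal_series.values))
        p1, p2 = gm.fit(coal_series), gm.fit(scaled)
        assert p2.a == pytest.approx(p1.a, abs=1e-12)
        assert p2.b == pytest.approx(lam * p1.b, rel=1e-10)
        assert p2.c == pytest.approx(lam * p1.c, rel=1e-10)
        assert p2.M == pytest.approx(lam * p1.M, rel=1e-10)

    @pytest.mark.parametrize("a, increasing", [(-0.08, False), (0.08, True)])
    def test_fit_monotone_iff_sign_of_a(self, a, increasing):
        ts = generate_gray_series(SyntheticSpec(a=a, M=100, n=12, noise="none"))
        fitted = gm.restored_fit(gm.fit(ts), range(2, 13))
        diffs = np.diff(fitted)
        assert np.all(diffs > 0) if increasing else np.all(diffs < 0)

    def test_constant_series_yields_degenerate_flag(self):
        ts = gm.TimeSeries.from_pairs((2000 + i, 42.0) for i in range(8))
        p = gm.fit(ts)
        assert p.degenerate and abs(p.a) < DEGENERATE_A
        np.testing.assert_allclose(gm.restored_fit(p, range(2, 9)), 42.0)


class TestDiagnostics:
    def test_perfect_fit_gives_unit_ratio_zero_residual(self, coal_series):
        fitted = coal_series.array()[1:]
        d = gm.diagnostics(coal_series, fitted)
        np.testing.assert_allclose(d.ratio, 1.0)
        np.testing.assert_allclose(d.residual, 0.0)
        np.testing.assert_allclose(d.delta, 0.0)

    def test_published_1993_ratio_rounds_to_84_percent(self):
        # actual 5152 against amended prediction 6125
        assert round(100 * 5152 / 6125) == 84

    def test_published_2004_deviation_magnitude(self):
        # actual 6027 against amended prediction 5433
        assert round(abs(5433 - 6027) / 6027, 3) == 0.099

    def test_identities_ratio_and_delta(self, coal_series, coal_params):
        fitted = gm.restored_fit(coal_params, range(2, 22), shift=1)
        d = gm.diagnostics(coal_series, fitted)
        np.testing.assert_allclose(d.ratio * d.fitted, d.actual, rtol=1e-12)
        np.testing.assert_allclose(d.delta * d.actual, d.residual, rtol=1e-12)
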