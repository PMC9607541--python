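import numpy as np
import pytest

from fluorbind import (
    FitError,
    QuenchingResult,
    SyntheticConfig,
    TitrationSeries,
    ValidationError,
    classify_quenching_mechanism,
    fit_double_log,
    fit_stern_volmer,
    simulate_titration_series,
)
from tests.conftest import PUBLISHED


def _qr(ksv, temperature, tau0=1e-8):
    return QuenchingResult(
        Ksv=ksv, Ksv_se=0.0, tau0=tau0, Kq=ksv / tau0, intercept=1.0,
        r_squared=1.0, temperature=temperature,
    )


class TestSternVolmer:
    def test_noiseless_recovery_is_exact(self, noiseless_sv_series):
        r = fit_stern_volmer(noiseless_sv_series)
        assert r.Ksv == pytest.approx(1.21e5, rel=1e-10)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)
        assert r.intercept == pytest.approx(1.0, abs=1e-9)

    def test_kq_is_ksv_over_tau0(self, noiseless_sv_series):
        r = fit_stern_volmer(noiseless_sv_series, tau0=1e-8)
        assert r.Kq == pytest.approx(r.Ksv / 1e-8, rel=1e-14)
        assert r.Kq == pytest.approx(1.21e13, rel=1e-10)

    def test_constant_intensity_flagged_no_quenching(self):
        series = TitrationSeries(
            quencher_conc=[0, 2e-6, 4e-6, 6e-6], peak_intensity=[1000.0] * 4
        )
        r = fit_stern_volmer(series)
        assert r.Ksv == pytest.approx(0.0, abs=1e-9)
        # slope of exactly zero is reported, not flagged as negative
        assert all("intercept" not in f for f in r.flags)

    def test_negative_slope_flagged(self):
        series = TitrationSeries(
            quencher_conc=[0, 2e-6, 4e-6, 6e-6],
            peak_intensity=[1000.0, 1100.0, 1250.0, 1400.0],
        )
        with pytest.warns(UserWarning, match="no quenching"):
            r = fit_stern_volmer(series)
        assert "no quenching detected" in r.flags

    def test_noisy_table1_series_within_5_percent(self):
        cfg = SyntheticConfig(mode="stern_volmer", noise_cv=0.01, seed=3)
        r = fit_stern_volmer(simulate_titration_series(cfg))
        assert r.Ksv == pytest.approx(1.21e5, rel=0.05)

    def test_scaling_invariance(self, noiseless_sv_series):
        scaled = TitrationSeries(
            quencher_conc=noiseless_sv_series.quencher_conc,
            peak_intensity=noiseless_sv_series.peak_intensity * 3.7,
        )
        a, b = fit_stern_volmer(noiseless_sv_series), fit_stern_volmer(scaled)
        assert b.Ksv == pytest.approx(a.Ksv, rel=1e-12)

    def test_too_few_points_rejected(self):
        series = TitrationSeries(quencher_conc=[0, 2e-6, 4e-6], peak_intensity=[1000, 800, 650])
        with pytest.raises(FitError, match="≥3 nonzero"):
            fit_stern_volmer(series)


class TestDoubleLog:
    def test_noiseless_hill_recovery_exact(self, noiseless_hill_series):
        r = fit_double_log(noiseless_hill_series)
        assert r.Ka == pytest.approx(3.79e4, rel=1e-9)
        assert r.n == pytest.approx(1.5, abs=1e-9)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_half_quenching_at_reciprocal_ka(self):
        # n = 1: at [Q] = 1/Ka the complexed fraction is half, so F = F0/2
        ka = 5.0e4
        cfg = SyntheticConfig(mode="hill_binding", Ka_true=ka, n_true=1.0)
        s = simulate_titration_series(cfg, (0.0, 1.0 / ka))
        assert s.peak_intensity[-1] == pytest.approx(cfg.F0_true / 2.0, rel=1e-12)

    def test_noisy_series_n_within_tenth(self):
        # Ka chosen so the double-log law reproduces the observed quench
        # magnitude (F0/F ≈ 2.2 at 10 μM); at the published Ka the n = 1.5
        # law predicts ~0.1% quenching, unmeasurable under any noise
        ka = 1.21 / (1e-5) ** 1.5
        cfg = SyntheticConfig(mode="hill_binding", Ka_true=ka, noise_cv=0.01, seed=5)
        r = fit_double_log(simulate_titration_series(cfg))
        assert r.n == pytest.approx(1.50, abs=0.1)

    def test_low_saturation_sv_data_gives_unit_n(self):
        # Stern-Volmer data are an n = 1 binding isotherm; at Ksv·max[Q] ≤ 0.1
        # the double-log fit must return n ≈ 1
        grid = (0.0, 2e-7, 4e-7, 6e-7, 8e-7, 1e-6)
        cfg = SyntheticConfig(mode="stern_volmer", Ksv_true=1e5)
        r = fit_double_log(simulate_titration_series(cfg, grid))
        assert abs(r.n - 1.0) < 0.02

    def test_points_at_or_above_f0_excluded_and_error_names_them(self):
        series = TitrationSeries(
            quencher_conc=[0, 2e-6, 4e-6, 6e-6],
            peak_intensity=[1000.0, 1000.0, 1001.0, 999.0],
        )
        with pytest.raises(FitError, match="F < F0"):
            fit_double_log(series)

    def test_scaling_invariance(self, noiseless_hill_series):
        scaled = TitrationSeries(
            quencher_conc=noiseless_hill_series.quencher_conc,
            peak_intensity=noiseless_hill_series.peak_intensity * 0.42,
        )
        a, b = fit_double_log(noiseless_hill_series), fit_double_log(scaled)
        assert b.Ka == pytest.approx(a.Ka, rel=1e-9)
        assert b.n == pytest.approx(a.n, rel=1e-9)


class TestMechanismClassification:
    def test_published_inputs_give_static(self):
        results = [_qr(PUBLISHED["Ksv"][t], t) for t in (298.0, 308.0)]
        call = classify_quenching_mechanism(results)
        assert call.mechanism == "static"
        assert call.rationale["Ksv_trend"] == "decreasing"

    @pytest.mark.parametrize(
        "ksv_pair,kq_scale,expected",
        [
            ((1.21e5, 0.41e5), 1e-8, "static"),  # decreasing, Kq ~ 1e13 > ceiling
            ((1e2, 2e2), 1e-8, "dynamic"),  # increasing, Kq ~ 1e10 ≤ ceiling
            ((1e5, 2e5), 1e-8, "indeterminate"),  # increasing but Kq high
            ((2e2, 1e2), 1e-8, "indeterminate"),  # decreasing but Kq low
            ((1e5, 1e5), 1e-8, "indeterminate"),  # flat trend
        ],
    )
    def test_trend_kq_truth_table(self, ksv_pair, kq_scale, expected):
        results = [_qr(k, t, tau0=kq_scale) for k, t in zip(ksv_pair, (298.0, 308.0))]
        assert classify_quenching_mechanism(results).mechanism == expected

    def test_single_temperature_uses_kq_only(self):
        call = classify_quenching_mechanism([_qr(1.21e5, 298.0)])
        assert call.mechanism == "static"
        assert "temperature trend unavailable" in call.flags
        low = classify_quenching_mechanism([_qr(1e2, 298.0)])
        assert low.mechanism == "dynamic"

    def test_kq_identity_enforced_on_result(self):
        with pytest.raises(ValidationError, match="Kq"):
            QuenchingResult(
                Ksv=1e5, Ksv_se=0.0, tau0=1e-8, Kq=1.0, intercept=1.0,
                r_squared=1.0, temperature=298.0,
            )
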