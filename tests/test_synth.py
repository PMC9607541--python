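import numpy as np
import pytest

from fluorbind import (
    SyntheticConfig,
    ValidationError,
    simulate_glycation_panel,
    simulate_synchronous_series,
    simulate_temperature_pair,
    simulate_titration_series,
    vant_hoff_ka,
)
from tests.conftest import PUBLISHED


class TestTitrationGenerator:
    def test_stern_volmer_closed_form(self):
        # F = F0 / (1 + Ksv*[Q]) at [Q] = 1e-5 with Ksv = 1.21e5: 1000/2.21
        cfg = SyntheticConfig(mode="stern_volmer", F0_true=1000.0, Ksv_true=1.21e5)
        s = simulate_titration_series(cfg, (0.0, 1e-5))
        assert s.peak_intensity[-1] == pytest.approx(452.49, abs=0.01)

    @pytest.mark.parametrize("mode", ["stern_volmer", "hill_binding"])
    def test_zero_quencher_gives_f0_exactly(self, mode):
        cfg = SyntheticConfig(mode=mode, noise_cv=0.0)
        s = simulate_titration_series(cfg)
        assert s.peak_intensity[0] == cfg.F0_true

    def test_same_seed_reproduces_series(self):
        cfg = SyntheticConfig(mode="hill_binding", noise_cv=0.05, seed=7)
        a = simulate_titration_series(cfg)
        b = simulate_titration_series(cfg)
        np.testing.assert_array_equal(a.peak_intensity, b.peak_intensity)

    def test_different_seeds_differ(self):
        a = simulate_titration_series(SyntheticConfig(noise_cv=0.05, seed=1))
        b = simulate_titration_series(SyntheticConfig(noise_cv=0.05, seed=2))
        assert not np.array_equal(a.peak_intensity[1:], b.peak_intensity[1:])


class TestTemperaturePair:
    def test_vant_hoff_ka_matches_published_pair(self):
        # (dH, dS) = (−51.53 kJ/mol, −85.25 J/mol/K) implies the printed
        # constants 3.79e4 (298 K) and 1.93e4 (308 K) within rounding
        ka298 = vant_hoff_ka(-51.53, -85.25, 298.0)
        ka308 = vant_hoff_ka(-51.53, -85.25, 308.0)
        assert ka298 / 1e4 == pytest.approx(3.79, abs=0.01)
        assert ka308 / 1e4 == pytest.approx(1.93, abs=0.01)

    def test_zero_enthalpy_gives_constant_ka(self):
        cfg = SyntheticConfig(dH_true=0.0, dS_true=50.0)
        for t in (280.0, 298.0, 320.0):
            assert vant_hoff_ka(0.0, 50.0, t) == pytest.approx(
                vant_hoff_ka(0.0, 50.0, 298.0), rel=1e-12
            )
        pair = simulate_temperature_pair(cfg, (298.0, 308.0))
        np.testing.assert_allclose(pair[0].peak_intensity, pair[1].peak_intensity)

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(ValidationError, match="distinct"):
            simulate_temperature_pair(SyntheticConfig(), (298.0, 298.0))

    def test_single_temperature_rejected(self):
        with pytest.raises(ValidationError, match="≥2"):
            simulate_temperature_pair(SyntheticConfig(), (298.0,))


class TestSynchronousGenerator:
    def test_zero_shift_keeps_band_centres_equal(self):
        series = simulate_synchronous_series(15.0, 0.0)
        argmax = [s.wavelengths[np.argmax(s.intensities)] for s in series.spectra]
        assert len(set(argmax)) == 1

    def test_amplitude_quenched_with_concentration(self):
        series = simulate_synchronous_series(60.0, 0.0)
        maxima = [s.intensities.max() for s in series.spectra]
        assert all(a > b for a, b in zip(maxima, maxima[1:]))


class TestGlycationGenerator:
    def test_zero_noise_panel_recovers_truth_exactly(self):
        from fluorbind import inhibition_rate

        panel = simulate_glycation_panel({"Total AGEs": 0.34}, noise_cv=0.0)
        r = inhibition_rate(
            panel.values("treated", "Total AGEs"), panel.values("control", "Total AGEs")
        )
        assert r.percent == pytest.approx(34.0, abs=1e-12)

    def test_zero_truth_gives_zero_inhibition(self):
        from fluorbind import inhibition_rate

        panel = simulate_glycation_panel({"ThT": 0.0}, noise_cv=0.0)
        r = inhibition_rate(panel.values("treated", "ThT"), panel.values("control", "ThT"))
        assert r.percent == 0.0

    def test_monte_carlo_mean_close_to_truth(self):
        from fluorbind import inhibition_rate

        panel = simulate_glycation_panel(
            {"Pentosidine": 0.20}, replicates=1000, noise_cv=0.05, seed=11
        )
        r = inhibition_rate(
            panel.values("treated", "Pentosidine"), panel.values("control", "Pentosidine")
        )
        assert r.percent == pytest.approx(20.0, abs=1.0)

    def test_out_of_range_truth_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            simulate_glycation_panel({"ThT": 1.5})
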