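import numpy as np
import pytest

from fluorbind import (
    EmissionSpectrum,
    TitrationSeries,
    ValidationError,
    extract_peak_intensity,
    read_titration_table,
    write_titration_table,
)
from fluorbind.synth import simulate_emission_band


def _write(tmp_path, text, name="titration.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTitrationTable:
    def test_micromolar_grid_converted_to_molar(self, tmp_path):
        path = _write(
            tmp_path,
            "conc,intensity\n0,1000\n2,800\n4,650\n6,560\n8,480\n10,430\n",
        )
        series = read_titration_table(path, {"units": "uM", "temperature_K": 298})
        np.testing.assert_allclose(
            series.quencher_conc, [0, 2e-6, 4e-6, 6e-6, 8e-6, 1e-5]
        )
        assert series.F0 == 1000.0
        assert series.temperature == 298

    def test_molar_units_pass_through(self, tmp_path):
        path = _write(tmp_path, "conc,intensity\n0,1000\n2e-6,800\n4e-6,650\n6e-6,560\n")
        series = read_titration_table(path, {"units": "M"})
        np.testing.assert_array_equal(series.quencher_conc, [0, 2e-6, 4e-6, 6e-6])

    def test_tab_delimiter_autodetected(self, tmp_path):
        path = _write(tmp_path, "conc\tintensity\n0\t1000\n2\t800\n4\t650\n6\t560\n")
        series = read_titration_table(path, {"units": "uM"})
        assert series.n_nonzero == 3

    def test_single_zero_row_rejected(self, tmp_path):
        path = _write(tmp_path, "conc,intensity\n0,1000\n")
        with pytest.raises(ValidationError, match="≥3 nonzero"):
            read_titration_table(path, {"units": "uM"})

    def test_missing_zero_row_rejected(self, tmp_path):
        path = _write(tmp_path, "conc,intensity\n2,800\n4,650\n6,560\n8,480\n")
        with pytest.raises(ValidationError, match="zero-concentration"):
            read_titration_table(path, {"units": "uM"})

    def test_duplicate_concentrations_named(self, tmp_path):
        path = _write(tmp_path, "conc,intensity\n0,1000\n2,800\n2,790\n4,650\n6,560\n")
        with pytest.raises(ValidationError, match=r"duplicate concentrations at rows \[1, 2\]"):
            read_titration_table(path, {"units": "uM"})

    def test_round_trip_full_precision(self, tmp_path):
        series = TitrationSeries(
            quencher_conc=[0.0, 1.2345678901234e-6, 3.3e-6, 7.77e-6],
            peak_intensity=[987.6543210987654, 800.1, 650.00001, 500.5],
        )
        path = tmp_path / "rt.csv"
        write_titration_table(series, path, units="M")
        back = read_titration_table(path, {"units": "M"})
        np.testing.assert_array_equal(back.quencher_conc, series.quencher_conc)
        np.testing.assert_array_equal(back.peak_intensity, series.peak_intensity)


class TestTitrationSeriesInvariants:
    @pytest.mark.parametrize(
        "conc,intensity,msg",
        [
            ([0.0, 2e-6], [1000.0, -1.0], "finite and > 0"),
            ([2e-6, 4e-6], [1000.0, 800.0], "first concentration"),
            ([0.0, 4e-6, 2e-6], [1000.0, 800.0, 900.0], "strictly increasing"),
            ([0.0, 2e-6], [1000.0], "differ in length"),
        ],
    )
    def test_invalid_series_rejected(self, conc, intensity, msg):
        with pytest.raises(ValidationError, match=msg):
            TitrationSeries(quencher_conc=conc, peak_intensity=intensity)


def _gaussian_spectrum(center, amplitude=1000.0, width=25.0, noise_cv=0.0, rng=None):
    wl = np.arange(290.0, 501.0, 1.0)
    inten = simulate_emission_band(wl, center, amplitude, width, noise_cv, rng)
    return EmissionSpectrum(wavelengths=wl, intensities=inten)


class TestPeakExtraction:
    def test_symmetric_band_recovered_exactly(self):
        est = extract_peak_intensity(_gaussian_spectrum(340.0), 340.0, 20.0)
        assert est.reliable
        assert est.wavelength == pytest.approx(340.0, abs=1e-6)
        assert est.intensity == pytest.approx(1000.0, rel=5e-3)

    def test_offset_band_found_not_nominal(self):
        # band at 346 nm, nominal 340: extraction follows the data
        est = extract_peak_intensity(_gaussian_spectrum(346.0), 340.0, 20.0)
        assert est.wavelength == pytest.approx(346.0, abs=0.5)

    def test_noisy_band_center_unbiased(self):
        # 1% multiplicative noise, 50 replicates: mean centre within 0.5 nm
        rng = np.random.default_rng(42)
        centers = [
            extract_peak_intensity(
                _gaussian_spectrum(340.0, noise_cv=0.01, rng=rng), 340.0, 20.0
            ).wavelength
            for _ in range(50)
        ]
        assert abs(np.mean(centers) - 340.0) < 0.5

    def test_invariant_under_intensity_scaling(self):
        spec = _gaussian_spectrum(343.0)
        scaled = EmissionSpectrum(
            wavelengths=spec.wavelengths, intensities=spec.intensities * 7.5
        )
        a = extract_peak_intensity(spec, 340.0, 20.0)
        b = extract_peak_intensity(scaled, 340.0, 20.0)
        assert b.wavelength == pytest.approx(a.wavelength, abs=1e-9)
        assert b.intensity == pytest.approx(7.5 * a.intensity, rel=1e-12)

    def test_boundary_maximum_flagged(self):
        wl = np.arange(290.0, 341.0, 1.0)
        inten = np.linspace(10.0, 1000.0, wl.size)  # monotone: max at edge
        spec = EmissionSpectrum(wavelengths=wl, intensities=inten)
        with pytest.warns(UserWarning, match="boundary"):
            est = extract_peak_intensity(spec, 330.0, 20.0)
        assert not est.reliable
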