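"""Spectrum container, overlap integral, Förster distance and unmixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geofret.spectra import (
    Spectrum,
    SpectrumError,
    area_normalize,
    beer_lambert_concentration,
    forster_distance,
    overlap_integral,
    read_spectrum,
    relative_quantum_yield,
    unmix_absorbance,
)
from geofret.synth import gen_absorbance_mixture

from conftest import dense_overlap_oracle, gaussian


class TestSpectrumValidation:
    def test_rejects_duplicate_wavelengths(self):
        with pytest.raises(SpectrumError, match="duplicate"):
            Spectrum([500, 600, 600, 700], [0, 1, 1, 0], kind="emission")

    def test_rejects_negative_absorptivity(self):
        with pytest.raises(SpectrumError):
            Spectrum([500, 600], [1.0, -1.0], kind="absorptivity")

    def test_rejects_single_point_and_nonfinite(self):
        with pytest.raises(SpectrumError):
            Spectrum([500], [1.0], kind="emission")
        with pytest.raises(SpectrumError):
            Spectrum([500, 600], [1.0, np.nan], kind="emission")


class TestReadSpectrum:
    def test_parses_csv_with_and_without_header(self, tmp_path):
        p = tmp_path / "em.csv"
        p.write_text("wavelength_nm,value\n500,0.0\n600,1.0\n700,0.0\n")
        s = read_spectrum(p, "emission")
        assert s.wavelengths.size == 3
        assert s.values[1] == 1.0

    def test_sorts_descending_input(self, tmp_path):
        up = tmp_path / "up.csv"
        up.write_text("500,0.0\n600,1.0\n700,0.0\n")
        down = tmp_path / "down.csv"
        down.write_text("700,0.0\n600,1.0\n500,0.0\n")
        a, b = read_spectrum(up, "emission"), read_spectrum(down, "emission")
        assert np.array_equal(a.wavelengths, b.wavelengths)
        assert np.array_equal(a.values, b.values)

    def test_duplicate_wavelength_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("500,0.0\n600,1.0\n600,2.0\n")
        with pytest.raises(SpectrumError, match="duplicate"):
            read_spectrum(p, "emission")

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("500,0.0\n600,oops\n")
        with pytest.raises(SpectrumError, match=":2"):
            read_spectrum(p, "emission")


class TestAreaNormalize:
    def test_triangle_scaled_by_inverse_area(self):
        # triangle of peak 2.0 over a 100 nm base: area = 100
        s = Spectrum([500.0, 550.0, 600.0], [0.0, 2.0, 0.0], kind="emission")
        n = area_normalize(s)
        assert np.allclose(n.values, s.values / 100.0)
        assert abs(n.area - 1.0) < 1e-9

    def test_idempotent(self, donor_emission_band):
        once = area_normalize(donor_emission_band)
        twice = area_normalize(once)
        assert np.allclose(once.values, twice.values, rtol=1e-9, atol=0)

    def test_matches_dense_quadrature(self):
        # module-grid area of a Gaussian band vs a 1e6-point quadrature
        grid = np.arange(500.0, 700.0, 0.2)
        vals = 3.7 * gaussian(grid, 600.0, 12.0)
        module_area = Spectrum(grid, vals, kind="emission").area
        dense = np.linspace(500.0, 700.0, 1_000_000)
        oracle = np.trapezoid(3.7 * gaussian(dense, 600.0, 12.0), dense)
        assert abs(module_area - oracle) / oracle < 1e-6

    def test_all_zero_errors(self):
        s = Spectrum([500, 600], [0.0, 0.0], kind="emission")
        with pytest.raises(SpectrumError):
            area_normalize(s)


class TestOverlapIntegral:
    def test_disjoint_spectra_give_zero_with_warning(self):
        donor = Spectrum([400, 450, 500], [0, 1, 0], kind="emission")
        acc = Spectrum([600, 650, 700], [0, 1e5, 0], kind="absorptivity")
        with pytest.warns(UserWarning, match="overlap"):
            assert overlap_integral(donor, acc) == 0.0

    def test_narrow_band_approaches_delta_limit(self):
        # unit-area donor band shrinking onto 600 nm with flat epsilon=1e5:
        # J -> 1e5 * 600^4 = 1.296e16
        acc = Spectrum([400.0, 800.0], [1e5, 1e5], kind="absorptivity")
        target = 1e5 * 600.0**4
        previous_err = None
        for sigma in (10.0, 3.0, 1.0):
            grid = np.arange(500.0, 700.0, 0.05)
            donor = Spectrum(grid, gaussian(grid, 600.0, sigma), kind="emission")
            err = abs(overlap_integral(donor, acc) - target) / target
            if previous_err is not None:
                assert err < previous_err
            previous_err = err
        assert previous_err < 1e-3

    def test_matches_dense_grid_oracle(self, donor_emission_band, acceptor_absorptivity_band):
        j = overlap_integral(donor_emission_band, acceptor_absorptivity_band)
        oracle = dense_overlap_oracle(600.0, 15.0, 650.0, 20.0, 1e5, 450.0, 800.0)
        assert abs(j - oracle) / oracle < 1e-3

    def test_bilinear_in_acceptor_scale(self, donor_emission_band, acceptor_absorptivity_band):
        j1 = overlap_integral(donor_emission_band, acceptor_absorptivity_band)
        scaled = Spectrum(
            acceptor_absorptivity_band.wavelengths,
            3.5 * acceptor_absorptivity_band.values,
            kind="absorptivity",
        )
        assert overlap_integral(donor_emission_band, scaled) == pytest.approx(3.5 * j1, rel=1e-12)


class TestForsterDistance:
    def test_zero_overlap_gives_zero(self):
        assert forster_distance(0.0, 0.5) == 0.0

    def test_hand_evaluated_value(self):
        # 0.0211 * (2/3 * 0.3 * 1.35^-4 * 1e15)^(1/6) = 4.177 nm
        assert forster_distance(1e15, 0.3) == pytest.approx(4.18, abs=0.005)

    @given(st.floats(min_value=1e10, max_value=1e18))
    @settings(derandomize=True, max_examples=50)
    def test_sixth_root_scaling(self, j):
        r1 = forster_distance(j, 0.5)
        r2 = forster_distance(64.0 * j, 0.5)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)

    def test_rejects_negative_overlap(self):
        with pytest.raises(ValueError):
            forster_distance(-1.0, 0.5)


class TestBeerLambert:
    @pytest.mark.parametrize(
        "absorbance,extinction,expected_M",
        [
            (0.3, 3.0e6, 100e-9),   # QD600 at 350 nm
            (0.0, 3.0e6, 0.0),
            (0.29, 2.9e7, 10e-9),   # QD660 at 350 nm
        ],
    )
    def test_concentration(self, absorbance, extinction, expected_M):
        assert beer_lambert_concentration(absorbance, extinction) == pytest.approx(
            expected_M, rel=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            beer_lambert_concentration(0.3, 0.0)
        with pytest.raises(ValueError):
            beer_lambert_concentration(0.3, 1e6, 0.0)


class TestRelativeQuantumYield:
    def test_identity_with_standard(self):
        qy = relative_quantum_yield(100.0, 0.1, 100.0, 0.1, 0.92, 1.36, 1.36)
        assert qy == pytest.approx(0.92, rel=1e-12)

    def test_linear_in_intensity(self):
        qy = relative_quantum_yield(50.0, 0.1, 100.0, 0.1, 0.92, 1.36, 1.36)
        assert qy == pytest.approx(0.46, rel=1e-12)

    def test_above_unity_warns_but_reports(self):
        # ratio 1.3 x absorbance ratio 0.8 -> 0.92*1.3*1.25 would exceed;
        # here A_std/A_sample = 0.8 so qy = 0.92*1.3*0.8 = 0.9568 (no warn),
        # and an extreme case must warn yet still return the number
        qy = relative_quantum_yield(130.0, 0.125, 100.0, 0.1, 0.92, 1.36, 1.36)
        assert qy == pytest.approx(0.92 * 1.3 * 0.8, rel=1e-12)
        with pytest.warns(UserWarning, match="exceeds 1"):
            qy_hi = relative_quantum_yield(200.0, 0.1, 100.0, 0.1, 0.92, 1.36, 1.36)
        assert qy_hi == pytest.approx(1.84, rel=1e-12)

    def test_zero_standard_errors(self):
        with pytest.raises(ValueError):
            relative_quantum_yield(1.0, 0.1, 0.0, 0.1, 0.92, 1.36, 1.36)


def _qd_and_dye_components():
    grid = np.arange(350.0, 800.0, 1.0)
    qd = np.clip(1e6 * (450.0 / grid) ** 3 * (grid < 620), 0, None) + 1e5 * gaussian(
        grid, 600.0, 12.0
    ) * 30
    dye = 2.39e5 * np.exp(-0.5 * ((grid - 650.0) / 18.0) ** 2)
    return (
        Spectrum(grid, qd, kind="absorptivity"),
        Spectrum(grid, dye, kind="absorptivity"),
    )


class TestUnmixAbsorbance:
    def test_pure_component_gives_zero_ratio(self):
        qd, dye = _qd_and_dye_components()
        measured = Spectrum(qd.wavelengths, 50e-9 * qd.values, kind="absorbance")
        result = unmix_absorbance(measured, [qd, dye], ["qd", "dye"])
        assert result.concentrations[1] == pytest.approx(0.0, abs=1e-15)
        assert result.ratio("dye", "qd") == pytest.approx(0.0, abs=1e-9)

    def test_exact_recovery_of_noiseless_mixture(self):
        qd, dye = _qd_and_dye_components()
        mix = gen_absorbance_mixture([qd, dye], [50e-9, 150e-9], noise_sd=0.0)
        result = unmix_absorbance(mix.data, [qd, dye], ["qd", "dye"])
        assert result.concentrations == pytest.approx([50e-9, 150e-9], rel=1e-6)
        assert result.ratio("dye", "qd") == pytest.approx(3.0, rel=1e-6)

    def test_noisy_mixture_ratio_unbiased(self):
        # 1% of peak absorbance Gaussian noise, 100 seeded replicates
        qd, dye = _qd_and_dye_components()
        peak = (50e-9 * qd.values + 150e-9 * dye.values).max()
        ratios = []
        for seed in range(100):
            mix = gen_absorbance_mixture(
                [qd, dye], [50e-9, 150e-9], noise_sd=0.01 * peak, seed=seed
            )
            ratios.append(unmix_absorbance(mix.data, [qd, dye], ["qd", "dye"]).ratio("dye", "qd"))
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.02)

    def test_collinear_components_rejected(self):
        qd, _ = _qd_and_dye_components()
        double = Spectrum(qd.wavelengths, 2.0 * qd.values, kind="absorptivity")
        measured = Spectrum(qd.wavelengths, 1e-7 * qd.values, kind="absorbance")
        with pytest.raises(ValueError, match="collinear"):
            unmix_absorbance(measured, [qd, double], ["a", "b"])
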