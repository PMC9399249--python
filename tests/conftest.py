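"""Shared fixtures: analytic Gaussian test bands and their dense oracles."""

import numpy as np
import pytest

from geofret.spectra import Spectrum


def gaussian(x, center, sigma):
    return np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


@pytest.fixture
def donor_emission_band():
    """Unit-area Gaussian donor emission centered at 600 nm (sigma 15 nm)."""
    grid = np.arange(450.0, 800.0, 0.5)
    return Spectrum(grid, gaussian(grid, 600.0, 15.0), kind="emission")


@pytest.fixture
def acceptor_absorptivity_band():
    """Gaussian acceptor absorptivity peaking 1e5 M⁻¹cm⁻¹ at 650 nm."""
    grid = np.arange(450.0, 800.0, 0.5)
    sigma = 20.0
    values = 1e5 * np.exp(-0.5 * ((grid - 650.0) / sigma) ** 2)
    return Spectrum(grid, values, kind="absorptivity")


def dense_overlap_oracle(
    em_center, em_sigma, abs_center, abs_sigma, abs_peak, lo, hi, n=2_000_000
):
    """Overlap integral by brute-force dense quadrature on analytic bands.

    Independent of the package's union-grid trapezoid path: evaluates the
    closed-form Gaussian integrand on a uniform 2e6-point grid.
    """
    x = np.linspace(lo, hi, n)
    em = gaussian(x, em_center, em_sigma)
    em /= np.trapezoid(em, x)
    absorp = abs_peak * np.exp(-0.5 * ((x - abs_center) / abs_sigma) ** 2)
    return float(np.trapezoid(em * absorp * x**4, x))
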