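"""Synthetic instrument emulator with stored ground truth.

Every input the analysis pipeline consumes can be generated here with a
known generating model, so each stage is testable closed-loop without any
instrument data:

* Gaussian-band emission spectra (QD emitters at 600/630/660 nm class
  peaks) and absorptivity spectra with an optional power-law UV tail
  mimicking quantum-dot absorption;
* additive absorbance mixtures for the spectral-unmixing stoichiometry
  readout;
* TCSPC decay histograms from the multi-exponential decay model with
  periodic pulse wrap-around (default 400 ns period, i.e. a 2.5 MHz
  excitation repetition rate), uniform background and Poisson counting
  noise;
* paired donor-only / donor+acceptor intensity and lifetime observables
  with multiplicative lognormal noise;
* bond-angle ensembles around a design angle, reflected into [0°, 180°].

All generators are pure functions of their arguments plus a seed; a
single global seed fans out to fixed per-generator substreams so adding a
generator never shifts an existing stream. Each generator returns the
data together with the ground truth that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .lifetime import DecayCurve
from .spectra import Spectrum

__all__ = [
    "Generated",
    "gaussian_band",
    "gen_emission_spectrum",
    "gen_absorptivity_spectrum",
    "gen_absorbance_mixture",
    "gen_decay_histogram",
    "gen_fret_observables",
    "gen_trimer_angles",
]

#: Repetition period of the pulsed excitation (2.5 MHz → 400 ns).
DEFAULT_REPETITION_PERIOD_NS = 400.0

# fixed substream keys: appending entries never disturbs earlier streams
_STREAMS = {
    "emission": 0,
    "absorptivity": 1,
    "mixture": 2,
    "decay": 3,
    "fret": 4,
    "angles": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class Generated:
    """A generated dataset bundled with the ground truth that made it."""

    data: Any
    truth: dict


def gaussian_band(grid_nm: np.ndarray, center_nm: float, fwhm_nm: float) -> np.ndarray:
    """Unit-area Gaussian band evaluated on ``grid_nm``."""
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((grid_nm - center_nm) / sigma) ** 2) / (
        sigma * np.sqrt(2.0 * np.pi)
    )


def _default_grid(start=350.0, stop=900.0, step=1.0) -> np.ndarray:
    return np.arange(start, stop + step / 2, step)


def gen_emission_spectrum(
    bands: Sequence[tuple[float, float, float]],
    grid_nm: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Generated:
    """Emission spectrum as a sum of Gaussian bands.

    ``bands`` is a list of ``(center_nm, fwhm_nm, area)``. Optional
    additive Gaussian noise (sd in the same arbitrary units) is clipped
    at zero. Deterministic for a given seed.
    """
    grid = _default_grid() if grid_nm is None else np.asarray(grid_nm, dtype=float)
    values = np.zeros_like(grid)
    for center, fwhm, area in bands:
        if fwhm <= 0 or area <= 0:
            raise ValueError("band fwhm and area must be > 0")
        if not (grid[0] <= center <= grid[-1]):
            import warnings

            warnings.warn(f"band center {center} nm outside grid", stacklevel=2)
        values += area * gaussian_band(grid, center, fwhm)
    if noise_sd > 0:
        values = np.clip(values + _rng(seed, "emission").normal(0, noise_sd, grid.size), 0, None)
    spectrum = Spectrum(grid, values, kind="emission")
    return Generated(
        data=spectrum,
        truth={"bands": list(bands), "noise_sd": noise_sd, "seed": seed},
    )


def gen_absorptivity_spectrum(
    bands: Sequence[tuple[float, float, float]],
    grid_nm: np.ndarray | None = None,
    uv_tail_peak: float = 0.0,
    uv_tail_exponent: float = 3.0,
    uv_tail_onset_nm: float | None = None,
) -> Generated:
    """Molar absorptivity: Gaussian bands plus an optional power-law UV tail.

    ``bands`` entries are ``(center_nm, fwhm_nm, peak_M_per_cm)``. The
    tail, characteristic of quantum-dot absorption, rises toward short
    wavelength as ``(onset/λ)^exponent`` below ``uv_tail_onset_nm`` with
    amplitude ``uv_tail_peak`` at the onset.
    """
    grid = _default_grid() if grid_nm is None else np.asarray(grid_nm, dtype=float)
    values = np.zeros_like(grid)
    for center, fwhm, peak in bands:
        if fwhm <= 0 or peak <= 0:
            raise ValueError("band fwhm and peak must be > 0")
        band = gaussian_band(grid, center, fwhm)
        values += peak * band / band.max()
    if uv_tail_peak > 0:
        onset = uv_tail_onset_nm if uv_tail_onset_nm is not None else (
            bands[0][0] if bands else grid[len(grid) // 2]
        )
        tail = np.where(grid < onset, uv_tail_peak * (onset / grid) ** uv_tail_exponent, 0.0)
        # smooth ramp across the onset to avoid a step
        ramp = np.clip((onset - grid) / 20.0, 0.0, 1.0)
        values += tail * ramp
    spectrum = Spectrum(grid, values, kind="absorptivity")
    return Generated(
        data=spectrum,
        truth={
            "bands": list(bands),
            "uv_tail_peak": uv_tail_peak,
            "uv_tail_exponent": uv_tail_exponent,
        },
    )


def gen_absorbance_mixture(
    components: Sequence[Spectrum],
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    path_length_cm: float = 1.0,
    seed: int = 0,
) -> Generated:
    """Composite absorbance A(λ) = Σ cᵢ εᵢ(λ) l plus Gaussian noise."""
    conc = np.asarray(concentrations, dtype=float)
    if len(components) != conc.size:
        raise ValueError("one concentration per component required")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    grid = components[0].wavelengths
    for c in components[1:]:
        if not np.array_equal(c.wavelengths, grid):
            raise ValueError("component spectra must share one wavelength grid")
    values = np.zeros_like(grid)
    for c, spectrum in zip(conc, components):
        values = values + c * spectrum.values * path_length_cm
    if noise_sd > 0:
        values = values + _rng(seed, "mixture").normal(0, noise_sd, grid.size)
    values = np.clip(values, 0.0, None)
    spectrum = Spectrum(grid, values, kind="absorbance")
    return Generated(
        data=spectrum,
        truth={
            "concentrations_M": conc.tolist(),
            "noise_sd": noise_sd,
            "path_length_cm": path_length_cm,
            "seed": seed,
        },
    )


def gen_decay_histogram(
    gammas: Sequence[float],
    taus_ns: Sequence[float],
    total_counts: float,
    bin_width_ns: float = 0.4,
    repetition_period_ns: float = DEFAULT_REPETITION_PERIOD_NS,
    background_fraction: float = 0.0,
    seed: int = 0,
) -> Generated:
    """Poisson-noised TCSPC histogram from the multi-exponential model.

    The expected bin profile includes periodic wrap-around — photons from
    earlier pulses that arrive within the current period — which matters
    because QD lifetimes (tens of ns) are not negligible against the
    400 ns period. ``background_fraction`` of the expected counts is
    spread uniformly over the period.
    """
    g = np.asarray(gammas, dtype=float)
    tau = np.asarray(taus_ns, dtype=float)
    if g.shape != tau.shape or g.size < 1:
        raise ValueError("gammas and taus must have equal length >= 1")
    if not np.isclose(g.sum(), 1.0, atol=1e-9):
        raise ValueError(f"gammas must sum to 1, got {g.sum()}")
    if np.any(tau <= 0):
        raise ValueError("lifetimes must be > 0")
    if np.any(tau >= repetition_period_ns):
        raise ValueError(
            "lifetimes must be shorter than the repetition period "
            "(wrap-around would dominate)"
        )
    if not (0.0 <= background_fraction <= 1.0):
        raise ValueError("background_fraction must be in [0, 1]")
    if total_counts <= 0 or bin_width_ns <= 0:
        raise ValueError("total_counts and bin_width_ns must be > 0")

    n_bins = int(np.floor(repetition_period_ns / bin_width_ns))
    t = (np.arange(n_bins) + 0.5) * bin_width_ns
    # steady-state periodic decay: sum over all previous pulses
    profile = np.zeros(n_bins)
    for gi, ti in zip(g, tau):
        profile += gi * np.exp(-t / ti) / (1.0 - np.exp(-repetition_period_ns / ti))
    profile /= profile.sum()
    expected = total_counts * (
        (1.0 - background_fraction) * profile + background_fraction / n_bins
    )
    counts = _rng(seed, "decay").poisson(expected).astype(float)
    curve = DecayCurve(
        time_ns=t,
        counts=counts,
        repetition_period_ns=repetition_period_ns,
        background_per_bin=background_fraction * total_counts / n_bins,
    )
    return Generated(
        data=curve,
        truth={
            "gammas": g.tolist(),
            "taus_ns": tau.tolist(),
            "tau_mean_ns": float(np.dot(g, tau)),
            "total_counts": total_counts,
            "background_fraction": background_fraction,
            "seed": seed,
        },
    )


def gen_fret_observables(
    E_true: float,
    I_D_mean: float = 1e5,
    tau_D_ns: float = 20.0,
    n_replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> Generated:
    """Replicate intensity/lifetime pairs for a known FRET efficiency.

    The forward model is I_DA = (1−E)·I_D and τ_DA = (1−E)·τ_D, each
    replicate multiplied by lognormal noise of coefficient of variation
    ``noise_cv``.
    """
    from .fret import EfficiencyMeasurement

    if not (0.0 <= E_true < 1.0):
        raise ValueError("E_true must be in [0, 1)")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = _rng(seed, "fret")
    sigma = np.sqrt(np.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0

    def _noisy(x: float) -> float:
        if sigma == 0:
            return x
        return float(x * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))

    measurements = [
        EfficiencyMeasurement(
            I_D=_noisy(I_D_mean),
            I_DA=_noisy((1.0 - E_true) * I_D_mean),
            tau_D_ns=_noisy(tau_D_ns),
            tau_DA_ns=_noisy((1.0 - E_true) * tau_D_ns),
        )
        for _ in range(n_replicates)
    ]
    return Generated(
        data=measurements,
        truth={
            "E_true": E_true,
            "I_D_mean": I_D_mean,
            "tau_D_ns": tau_D_ns,
            "noise_cv": noise_cv,
            "seed": seed,
        },
    )


def gen_trimer_angles(
    design_angle_deg: float,
    sd_deg: float,
    n: int,
    seed: int = 0,
) -> Generated:
    """Gaussian bond-angle draws reflected into [0°, 180°]."""
    if not (0.0 < design_angle_deg <= 180.0):
        raise ValueError("design angle must be in (0, 180]")
    if sd_deg < 0 or n < 1:
        raise ValueError("sd must be >= 0 and n >= 1")
    draws = _rng(seed, "angles").normal(design_angle_deg, sd_deg, size=n)
    # reflect at both boundaries (period-360 triangle wave)
    draws = np.abs(np.mod(draws, 360.0))
    draws = np.where(draws > 180.0, 360.0 - draws, draws)
    return Generated(
        data=draws,
        truth={
            "design_angle_deg": design_angle_deg,
            "sd_deg": sd_deg,
            "n": n,
            "seed": seed,
        },
    )
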