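"""Spectra, spectral overlap, Förster distance and absorbance arithmetic.

This module holds the steady-state photophysics layer: a validated
:class:`Spectrum` container, the spectral overlap integral

.. math:: J = \\int \\bar I_D(\\lambda)\\,\\varepsilon_A(\\lambda)\\,\\lambda^4\\,d\\lambda

(with the donor emission area-normalized and ``λ`` in nm, so ``J`` carries
units of M⁻¹ cm⁻¹ nm⁴), the Förster distance

.. math:: R_0 = 0.0211\\,[\\kappa^2\\,\\Phi_D\\,n^{-4}\\,J]^{1/6}\\ \\text{(nm)},

Beer–Lambert concentration determination, the relative quantum-yield
method, and non-negative least-squares unmixing of composite absorbance
spectra into per-fluorophore concentrations (the dye/QD stoichiometry
readout).

Integrals use the trapezoidal rule on the union of the input wavelength
grids after linear interpolation; spectra contribute zero outside their
own support (no extrapolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "FluorophoreSpec",
    "OverlapResult",
    "UnmixResult",
    "SpectrumError",
    "read_spectrum",
    "area_normalize",
    "overlap_integral",
    "forster_distance",
    "beer_lambert_concentration",
    "relative_quantum_yield",
    "unmix_absorbance",
]

#: Dynamic-averaging orientation factor for freely rotating dipoles.
KAPPA_SQUARED_DYNAMIC = 2.0 / 3.0
#: Refractive index of the aqueous buffer surrounding the assemblies.
REFRACTIVE_INDEX_BUFFER = 1.35
#: Prefactor of the Förster-distance formula when J is in M⁻¹ cm⁻¹ nm⁴
#: and R0 comes out in nm.
R0_PREFACTOR_NM = 0.0211

SPECTRUM_KINDS = ("emission", "absorptivity", "absorbance")


class SpectrumError(ValueError):
    """Raised for malformed or invariant-violating spectral data."""


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed curve.

    Parameters
    ----------
    wavelengths : array of float
        Strictly ascending wavelengths in nm, length >= 2.
    values : array of float
        Emission intensity (a.u.), molar absorptivity (M⁻¹ cm⁻¹) or
        absorbance (dimensionless) depending on ``kind``.
    kind : {"emission", "absorptivity", "absorbance"}
    area_normalized : bool
        True if the trapezoidal integral of ``values`` equals 1.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str
    area_normalized: bool = False

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in SPECTRUM_KINDS:
            raise SpectrumError(
                f"unknown spectrum kind {self.kind!r}; expected one of {SPECTRUM_KINDS}"
            )
        if wl.ndim != 1 or vals.ndim != 1 or wl.shape != vals.shape:
            raise SpectrumError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(vals))):
            raise SpectrumError("wavelengths and values must be finite")
        dw = np.diff(wl)
        if np.any(dw <= 0):
            if np.any(dw == 0):
                dupes = wl[:-1][dw == 0]
                raise SpectrumError(f"duplicate wavelengths: {np.unique(dupes)}")
            raise SpectrumError("wavelengths must be strictly increasing")
        if self.kind in ("absorptivity", "absorbance") and np.any(vals < 0):
            raise SpectrumError(f"{self.kind} values must be >= 0")
        if self.area_normalized:
            area = float(np.trapezoid(vals, wl))
            if not np.isclose(area, 1.0, rtol=1e-6, atol=0.0):
                raise SpectrumError(
                    f"spectrum flagged area-normalized but integral is {area:.6g}"
                )

    @property
    def area(self) -> float:
        """Trapezoidal integral of the curve over its grid."""
        return float(np.trapezoid(self.values, self.wavelengths))

    def interpolate(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid``; zero outside own support."""
        return np.interp(grid, self.wavelengths, self.values, left=0.0, right=0.0)


@dataclass(frozen=True)
class FluorophoreSpec:
    """Named emitter/absorber with its photophysical constants.

    ``extinction_at_reference`` is the molar extinction coefficient in
    M⁻¹ cm⁻¹ at ``reference_wavelength_nm`` (350 nm for the QDs used
    here); ``natural_lifetime_ns`` sets the natural relaxation rate
    k_D = 1/τ.
    """

    name: str
    emission: Spectrum | None = None
    absorptivity: Spectrum | None = None
    quantum_yield: float | None = None
    natural_lifetime_ns: float | None = None
    extinction_at_reference: float | None = None
    reference_wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.quantum_yield is not None and not (0.0 < self.quantum_yield <= 1.0):
            raise ValueError(f"quantum_yield must be in (0, 1], got {self.quantum_yield}")
        if self.natural_lifetime_ns is not None and self.natural_lifetime_ns <= 0:
            raise ValueError("natural_lifetime_ns must be > 0")

    @property
    def natural_rate_per_ns(self) -> float:
        """k_D = 1/τ in ns⁻¹."""
        if self.natural_lifetime_ns is None:
            raise ValueError(f"{self.name}: natural lifetime not set")
        return 1.0 / self.natural_lifetime_ns


@dataclass(frozen=True)
class OverlapResult:
    """Overlap integral and the Förster distance derived from it."""

    J: float  # M⁻¹ cm⁻¹ nm⁴
    R0: float  # nm
    kappa_squared: float
    refractive_index: float
    grid_nm: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.J < 0 or self.R0 < 0:
            raise ValueError("J and R0 must be >= 0")
        if (self.J == 0) != (self.R0 == 0):
            raise ValueError("R0 must be 0 iff J is 0")


def read_spectrum(path: str | Path, kind: str) -> Spectrum:
    """Read a two-column ``wavelength_nm,value`` CSV into a Spectrum.

    Header lines and ``#`` comments are skipped; rows are sorted by
    wavelength; duplicate wavelengths raise :class:`SpectrumError`.
    """
    path = Path(path)
    wl: list[float] = []
    vals: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # tolerate a single header row
                    continue
                raise SpectrumError(f"{path}:{lineno}: non-numeric row {line!r}") from None
            wl.append(w)
            vals.append(v)
    if len(wl) < 2:
        raise SpectrumError(f"{path}: fewer than 2 data rows")
    order = np.argsort(wl)
    return Spectrum(np.asarray(wl)[order], np.asarray(vals)[order], kind=kind)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a Spectrum as a two-column CSV with header."""
    arr = np.column_stack([spectrum.wavelengths, spectrum.values])
    header = "wavelength_nm,value"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")


def area_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale an emission spectrum so its trapezoidal integral equals 1."""
    area = spectrum.area
    if area <= 0:
        raise SpectrumError("cannot area-normalize a spectrum with non-positive area")
    if spectrum.area_normalized and np.isclose(area, 1.0, rtol=1e-12):
        return spectrum
    return replace(
        spectrum, values=spectrum.values / area, area_normalized=True
    )


def _union_grid(a: Spectrum, b: Spectrum) -> np.ndarray | None:
    """Union of both grids restricted to the overlap interval, or None."""
    lo = max(a.wavelengths[0], b.wavelengths[0])
    hi = min(a.wavelengths[-1], b.wavelengths[-1])
    if lo >= hi:
        return None
    grid = np.union1d(a.wavelengths, b.wavelengths)
    return grid[(grid >= lo) & (grid <= hi)]


def overlap_integral(
    donor_emission: Spectrum,
    acceptor_absorptivity: Spectrum,
    return_grid: bool = False,
):
    """Spectral overlap integral J in M⁻¹ cm⁻¹ nm⁴.

    The donor emission is area-normalized internally if it is not
    already; the integrand Ī_D(λ)·ε_A(λ)·λ⁴ is integrated by the
    trapezoidal rule on the union grid over the shared interval.
    Disjoint spectra yield J = 0 with a warning.
    """
    if donor_emission.kind != "emission":
        raise SpectrumError("donor spectrum must have kind='emission'")
    if acceptor_absorptivity.kind != "absorptivity":
        raise SpectrumError("acceptor spectrum must have kind='absorptivity'")
    donor = area_normalize(donor_emission)
    grid = _union_grid(donor, acceptor_absorptivity)
    if grid is None or grid.size < 2:
        warnings.warn(
            "donor emission and acceptor absorptivity do not overlap; J = 0",
            stacklevel=2,
        )
        return (0.0, np.empty(0)) if return_grid else 0.0
    integrand = donor.interpolate(grid) * acceptor_absorptivity.interpolate(grid) * grid**4
    j = float(np.trapezoid(integrand, grid))
    j = max(j, 0.0)
    return (j, grid) if return_grid else j


def forster_distance(
    J: float,
    quantum_yield: float,
    kappa_squared: float = KAPPA_SQUARED_DYNAMIC,
    refractive_index: float = REFRACTIVE_INDEX_BUFFER,
) -> float:
    """Förster distance R0 in nm from the overlap integral.

    R0 = 0.0211 · (κ² Φ_D n⁻⁴ J)^(1/6) with J in M⁻¹ cm⁻¹ nm⁴.
    """
    if J < 0:
        raise ValueError(f"overlap integral must be >= 0, got {J}")
    if not (0.0 < quantum_yield <= 1.0):
        raise ValueError(f"quantum_yield must be in (0, 1], got {quantum_yield}")
    if refractive_index <= 0:
        raise ValueError("refractive_index must be > 0")
    if kappa_squared < 0:
        raise ValueError("kappa_squared must be >= 0")
    return R0_PREFACTOR_NM * (
        kappa_squared * quantum_yield * refractive_index**-4 * J
    ) ** (1.0 / 6.0)


def overlap_and_forster(
    donor: FluorophoreSpec,
    acceptor: FluorophoreSpec,
    kappa_squared: float = KAPPA_SQUARED_DYNAMIC,
    refractive_index: float = REFRACTIVE_INDEX_BUFFER,
) -> OverlapResult:
    """Compute J and R0 for a donor/acceptor pair of fluorophores."""
    if donor.emission is None:
        raise ValueError(f"donor {donor.name!r} has no emission spectrum")
    if acceptor.absorptivity is None:
        raise ValueError(f"acceptor {acceptor.name!r} has no absorptivity spectrum")
    if donor.quantum_yield is None:
        raise ValueError(f"donor {donor.name!r} has no quantum yield")
    j, grid = overlap_integral(donor.emission, acceptor.absorptivity, return_grid=True)
    r0 = forster_distance(j, donor.quantum_yield, kappa_squared, refractive_index)
    return OverlapResult(
        J=j, R0=r0, kappa_squared=kappa_squared,
        refractive_index=refractive_index, grid_nm=grid,
    )


def beer_lambert_concentration(
    absorbance: float, extinction: float, path_length_cm: float = 1.0
) -> float:
    """Molar concentration from A = ε·c·l."""
    if extinction <= 0:
        raise ValueError("extinction coefficient must be > 0")
    if path_length_cm <= 0:
        raise ValueError("path length must be > 0")
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    return absorbance / (extinction * path_length_cm)


def relative_quantum_yield(
    sample_intensity_integral: float,
    sample_absorbance: float,
    standard_intensity_integral: float,
    standard_absorbance: float,
    standard_qy: float = 0.92,
    sample_ri: float = 1.33,
    standard_ri: float = 1.36,
) -> float:
    """Quantum yield by the single-point relative method.

    Φ = Φ_s · (I/I_s) · (A_s/A) · (n²/n_s²). The default standard is
    rhodamine 101 in ethanol (Φ_s = 0.92). Absorbances above 0.2 risk
    inner-filter error and produce a warning, as does a result above 1.
    """
    if standard_intensity_integral <= 0 or standard_absorbance <= 0:
        raise ValueError("standard intensity and absorbance must be > 0")
    if sample_absorbance <= 0:
        raise ValueError("sample absorbance must be > 0")
    if not (0.0 < standard_qy <= 1.0):
        raise ValueError("standard_qy must be in (0, 1]")
    for label, a in (("sample", sample_absorbance), ("standard", standard_absorbance)):
        if a > 0.2:
            warnings.warn(
                f"{label} absorbance {a:.3g} > 0.2; inner-filter effects likely",
                stacklevel=2,
            )
    qy = (
        standard_qy
        * (sample_intensity_integral / standard_intensity_integral)
        * (standard_absorbance / sample_absorbance)
        * (sample_ri**2 / standard_ri**2)
    )
    if qy > 1.0:
        warnings.warn(f"relative quantum yield {qy:.4g} exceeds 1", stacklevel=2)
    return qy


@dataclass(frozen=True)
class UnmixResult:
    """Non-negative least-squares decomposition of a composite absorbance."""

    concentrations: np.ndarray  # M, one per component
    component_names: tuple[str, ...]
    residual_norm: float
    grid_nm: np.ndarray = field(repr=False, default=None)

    def ratio(self, numerator: str, denominator: str) -> float:
        """Molar ratio c_num/c_den, e.g. dye per QD."""
        i = self.component_names.index(numerator)
        j = self.component_names.index(denominator)
        denom = self.concentrations[j]
        if denom == 0:
            raise ZeroDivisionError(f"component {denominator!r} has zero concentration")
        return float(self.concentrations[i] / denom)


def unmix_absorbance(
    measured: Spectrum,
    components: Sequence[Spectrum],
    component_names: Sequence[str] | None = None,
    path_length_cm: float = 1.0,
    baseline: bool = False,
) -> UnmixResult:
    """Decompose a measured absorbance into component concentrations.

    Solves ``measured(λ) = Σ_i c_i ε_i(λ) l`` (optionally plus a constant
    baseline) by non-negative least squares on the union wavelength grid.

    Raises ``ValueError`` naming collinear components if the component
    matrix is rank-deficient.
    """
    from scipy.optimize import nnls

    if measured.kind != "absorbance":
        raise SpectrumError("measured spectrum must have kind='absorbance'")
    if len(components) < 2:
        raise ValueError("need at least 2 component spectra to unmix")
    for c in components:
        if c.kind != "absorptivity":
            raise SpectrumError("component spectra must have kind='absorptivity'")
    names = tuple(component_names) if component_names else tuple(
        f"component_{i}" for i in range(len(components))
    )
    if len(names) != len(components):
        raise ValueError("component_names length mismatch")

    grid = measured.wavelengths
    for c in components:
        grid = np.union1d(grid, c.wavelengths)
    lo = measured.wavelengths[0]
    hi = measured.wavelengths[-1]
    grid = grid[(grid >= lo) & (grid <= hi)]

    design = np.column_stack([c.interpolate(grid) * path_length_cm for c in components])
    if baseline:
        design = np.column_stack([design, np.ones(grid.size)])

    n_free = design.shape[1]
    rank = np.linalg.matrix_rank(design, tol=1e-10 * np.linalg.norm(design))
    if rank < n_free:
        raise ValueError(
            f"component matrix is rank-deficient (rank {rank} < {n_free}); "
            f"components {names} are collinear on the shared grid"
        )
    target = measured.interpolate(grid)
    coeffs, rnorm = nnls(design, target)
    conc = coeffs[: len(components)]
    return UnmixResult(
        concentrations=conc,
        component_names=names,
        residual_norm=float(rnorm),
        grid_nm=grid,
    )
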