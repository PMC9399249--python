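"""Single-pair and multi-acceptor FRET efficiencies and their inverses.

Efficiency routes implemented here:

* intensity: ``E = 1 − I_DA/I_D``
* lifetime: ``E = 1 − τ_DA/τ_D`` (amplitude-weighted lifetimes)
* geometry, one donor to ``n`` equidistant acceptors:
  ``E = n R0⁶ / (n R0⁶ + R⁶)``
* rate picture: ``k_D→A = k_D (R0/R)⁶``, relative rate ``γ = k_D→A/k_D``,
  ``E = γ/(1+γ)``.

The two inverse problems — acceptor count from a measured efficiency and
donor–acceptor distance from a measured efficiency — are the closed-form
inverses of the multi-acceptor relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .spectra import FluorophoreSpec

__all__ = [
    "FretPair",
    "EfficiencyMeasurement",
    "efficiency_from_intensity",
    "efficiency_from_lifetime",
    "efficiency_multi_acceptor",
    "invert_for_acceptor_count",
    "invert_for_distance",
    "fret_rate",
    "relative_rate",
    "efficiency_from_relative_rate",
]


@dataclass(frozen=True)
class FretPair:
    """A donor–acceptor pairing with its Förster distance and separation."""

    donor: FluorophoreSpec | str
    acceptor: FluorophoreSpec | str
    R0_nm: float
    R_nm: float
    kappa_squared: float = 2.0 / 3.0
    refractive_index: float = 1.35

    def __post_init__(self) -> None:
        if self.R0_nm <= 0 or self.R_nm <= 0:
            raise ValueError("R0 and R must be > 0")

    @property
    def gamma(self) -> float:
        """Relative transfer rate (R0/R)⁶ for this pair."""
        return (self.R0_nm / self.R_nm) ** 6

    def efficiency(self, n_acceptors: int = 1) -> float:
        return efficiency_multi_acceptor(n_acceptors, self.R0_nm, self.R_nm)


@dataclass(frozen=True)
class EfficiencyMeasurement:
    """Observed intensities and/or lifetimes for a FRET construct.

    Any subset may be present; ``efficiencies()`` reports whichever
    routes the data support.
    """

    I_D: float | None = None
    I_DA: float | None = None
    tau_D_ns: float | None = None
    tau_DA_ns: float | None = None

    def __post_init__(self) -> None:
        for name in ("I_D", "I_DA"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_D_ns", "tau_DA_ns"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")

    def efficiencies(self) -> dict[str, float | None]:
        """E by each available route; None where inputs are missing."""
        e_int = e_tau = None
        if self.I_D is not None and self.I_DA is not None:
            e_int = efficiency_from_intensity(self.I_D, self.I_DA)
        if self.tau_D_ns is not None and self.tau_DA_ns is not None:
            e_tau = efficiency_from_lifetime(self.tau_D_ns, self.tau_DA_ns)
        return {"intensity": e_int, "lifetime": e_tau}


def efficiency_from_intensity(I_D: float, I_DA: float) -> float:
    """E = 1 − I_DA/I_D from donor-only and donor+acceptor intensities.

    A negative result (I_DA > I_D) is returned with a warning: it flags
    emission enhancement or noise rather than transfer.
    """
    if I_D <= 0:
        raise ValueError("donor-only intensity I_D must be > 0")
    if I_DA < 0:
        raise ValueError("I_DA must be >= 0")
    e = 1.0 - I_DA / I_D
    if e < 0:
        warnings.warn(
            f"I_DA > I_D gives negative efficiency {e:.4g} (enhancement, not FRET)",
            stacklevel=2,
        )
    return e


def efficiency_from_lifetime(tau_D_ns: float, tau_DA_ns: float) -> float:
    """E = 1 − τ_DA/τ_D from amplitude-weighted lifetimes."""
    if tau_D_ns <= 0 or tau_DA_ns <= 0:
        raise ValueError("lifetimes must be > 0")
    e = 1.0 - tau_DA_ns / tau_D_ns
    if e < 0:
        warnings.warn(
            f"tau_DA > tau_D gives negative efficiency {e:.4g}", stacklevel=2
        )
    return e


def efficiency_multi_acceptor(n_acceptors: float, R0_nm: float, R_nm: float) -> float:
    """E for one donor transferring to n equidistant acceptors.

    E = n R0⁶ / (n R0⁶ + R⁶); strictly increasing in n, strictly
    decreasing in R. ``n_acceptors`` may be fractional (the inverse
    problem returns real n).
    """
    if n_acceptors < 1:
        raise ValueError("n_acceptors must be >= 1")
    if R0_nm <= 0 or R_nm <= 0:
        raise ValueError("R0 and R must be > 0")
    nr06 = n_acceptors * R0_nm**6
    return nr06 / (nr06 + R_nm**6)


def invert_for_acceptor_count(
    E: float, R0_nm: float, R_nm: float
) -> tuple[float, int]:
    """Acceptor count from a measured multi-acceptor efficiency.

    Returns ``(n_real, n_int)`` where ``n_real = E·R⁶/((1−E)·R0⁶)`` and
    ``n_int`` is its round-half-to-even integer.
    """
    if not (0.0 < E < 1.0):
        raise ValueError(f"E must be in (0, 1) to invert, got {E}")
    if R0_nm <= 0 or R_nm <= 0:
        raise ValueError("R0 and R must be > 0")
    n_real = E * R_nm**6 / ((1.0 - E) * R0_nm**6)
    return n_real, int(round(n_real))


def invert_for_distance(E: float, R0_nm: float, n_acceptors: float = 1) -> float:
    """Donor–acceptor distance from efficiency: R = R0·(n(1−E)/E)^(1/6)."""
    if not (0.0 < E < 1.0):
        raise ValueError(f"E must be in (0, 1) to invert, got {E}")
    if R0_nm <= 0:
        raise ValueError("R0 must be > 0")
    if n_acceptors < 1:
        raise ValueError("n_acceptors must be >= 1")
    return R0_nm * (n_acceptors * (1.0 - E) / E) ** (1.0 / 6.0)


def fret_rate(k_D_per_ns: float, R0_nm: float, R_nm: float) -> float:
    """Transfer rate k_D→A = k_D (R0/R)⁶ in ns⁻¹."""
    if k_D_per_ns <= 0 or R0_nm <= 0 or R_nm <= 0:
        raise ValueError("k_D, R0 and R must all be > 0")
    return k_D_per_ns * (R0_nm / R_nm) ** 6


def relative_rate(k_DA_per_ns: float, k_D_per_ns: float) -> float:
    """Relative rate γ = k_D→A / k_D (dimensionless)."""
    if k_D_per_ns <= 0:
        raise ValueError("k_D must be > 0")
    if k_DA_per_ns < 0:
        raise ValueError("k_DA must be >= 0")
    return k_DA_per_ns / k_D_per_ns


def efficiency_from_relative_rate(gamma: float) -> float:
    """E = γ/(1+γ), identical to k_DA/(k_D + k_DA)."""
    if gamma < 0:
        raise ValueError("relative rate must be >= 0")
    return gamma / (1.0 + gamma)
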