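"""Multi-exponential TCSPC decay fitting and amplitude-weighted lifetimes.

Photon-arrival histograms are fit to

.. math:: I(t) = C\\sum_i \\gamma_i\\,e^{-t/\\tau_i} + b,
          \\qquad \\sum_i \\gamma_i = 1,

by weighted nonlinear least squares (Neyman weights ``1/max(count, 1)``)
over a tail window starting after the excitation peak. The optimization
uses variable projection: the nonlinear search runs over log-lifetimes
only, while amplitudes and the constant background are obtained at each
step by non-negative linear least squares — this keeps the fit insensitive
to amplitude initialisation and makes multistart cheap. At least five
seeded initialisations with log-spaced lifetime ladders are tried and the
best-loss solution kept.

The amplitude-weighted mean lifetime ``τ̄ = Σ γᵢτᵢ`` is the quantity
entering intensity-based FRET efficiency relations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

__all__ = [
    "DecayCurve",
    "DecayFit",
    "FitConvergenceError",
    "fit_decay",
    "amplitude_weighted_lifetime",
    "select_component_count",
]

MAX_COMPONENTS = 4
#: Fitted components below this amplitude fraction are pruned.
PRUNE_FRACTION = 0.005


class FitConvergenceError(RuntimeError):
    """Raised when the decay fit fails to converge to a meaningful model."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class DecayCurve:
    """A TCSPC histogram: uniform time bins (ns) and photon counts."""

    time_ns: np.ndarray
    counts: np.ndarray
    repetition_period_ns: float | None = None
    background_per_bin: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ns, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "time_ns", t)
        object.__setattr__(self, "counts", c)
        if t.ndim != 1 or t.shape != c.shape or t.size < 4:
            raise ValueError("time_ns and counts must be equal-length 1-D arrays (>= 4 bins)")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time bins must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9):
            raise ValueError("time bins must be uniformly spaced")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")
        if c.sum() <= 0:
            raise ValueError("histogram contains no photons")

    @property
    def bin_width_ns(self) -> float:
        return float(self.time_ns[1] - self.time_ns[0])

    @property
    def peak_time_ns(self) -> float:
        return float(self.time_ns[int(np.argmax(self.counts))])


@dataclass(frozen=True)
class DecayFit:
    """Result of a multi-exponential decay fit.

    ``amplitude_fractions`` sum to 1; ``lifetimes_ns`` are ascending;
    ``tau_mean_ns`` is the amplitude-weighted mean Σ γᵢτᵢ.
    """

    total_amplitude: float
    amplitude_fractions: np.ndarray
    lifetimes_ns: np.ndarray
    background_per_bin: float
    chi2_reduced: float
    window_ns: tuple[float, float]
    n_components: int = field(default=0)

    def __post_init__(self) -> None:
        g = np.asarray(self.amplitude_fractions, dtype=float)
        tau = np.asarray(self.lifetimes_ns, dtype=float)
        object.__setattr__(self, "amplitude_fractions", g)
        object.__setattr__(self, "lifetimes_ns", tau)
        if self.n_components == 0:
            object.__setattr__(self, "n_components", g.size)
        if g.size != tau.size or g.size < 1:
            raise ValueError("fractions and lifetimes must have equal length >= 1")
        if not np.isclose(g.sum(), 1.0, atol=1e-9):
            raise ValueError(f"amplitude fractions sum to {g.sum()}, not 1")
        if np.any(tau <= 0):
            raise ValueError("lifetimes must be > 0")
        if np.any(np.diff(tau) < 0):
            raise ValueError("lifetimes must be sorted ascending")

    @property
    def tau_mean_ns(self) -> float:
        """Amplitude-weighted mean lifetime Σ γᵢτᵢ."""
        return float(np.dot(self.amplitude_fractions, self.lifetimes_ns))


def amplitude_weighted_lifetime(fit: DecayFit) -> float:
    """Σ γᵢτᵢ of a fitted decay (ns)."""
    return fit.tau_mean_ns


def _resolve_window(
    curve: DecayCurve, fit_window_ns: tuple[float, float] | None
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Select the tail-fit window; default starts 2 bins past the peak."""
    if fit_window_ns is None:
        start = curve.peak_time_ns + 2 * curve.bin_width_ns
        stop = float(curve.time_ns[-1])
    else:
        start, stop = fit_window_ns
    mask = (curve.time_ns >= start) & (curve.time_ns <= stop)
    if mask.sum() < 4:
        raise ValueError(f"fit window [{start}, {stop}] ns covers fewer than 4 bins")
    return curve.time_ns[mask], curve.counts[mask], (float(start), float(stop))


def _varpro_solve(
    log_taus: np.ndarray, t: np.ndarray, counts: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitudes+background by weighted NNLS for fixed lifetimes.

    Returns (coeffs, weighted residual vector); coeffs[:-1] are
    per-component amplitudes, coeffs[-1] the constant background.
    """
    taus = np.exp(log_taus)
    design = np.exp(-(t[:, None] - t[0]) / taus[None, :])
    design = np.column_stack([design, np.ones(t.size)])
    coeffs, _ = nnls(design * w[:, None], counts * w)
    resid = (design @ coeffs - counts) * w
    return coeffs, resid


def fit_decay(
    curve: DecayCurve,
    n_components: int,
    fit_window_ns: tuple[float, float] | None = None,
    seed: int = 0,
    n_starts: int = 5,
) -> DecayFit:
    """Fit an n-component exponential decay to a TCSPC histogram.

    Parameters
    ----------
    curve : DecayCurve
    n_components : int in 1..4
    fit_window_ns : (start, stop) or None
        Tail window; default starts two bins after the histogram peak.
    seed : int
        Seeds the multistart lifetime initialisations.
    n_starts : int
        Number of initialisations (>= 5 recommended).

    Raises
    ------
    FitConvergenceError
        When no start converges to a model in which the exponential part
        carries a meaningful share of the signal (e.g. a flat,
        background-only histogram).
    """
    if not (1 <= n_components <= MAX_COMPONENTS):
        raise ValueError(f"n_components must be in 1..{MAX_COMPONENTS}")
    t, counts, window = _resolve_window(curve, fit_window_ns)
    n_params = 2 * n_components + 1
    if counts.sum() <= 10 * n_params:
        raise ValueError(
            f"window holds {counts.sum():.0f} counts; need > {10 * n_params} "
            f"for {n_params} parameters"
        )
    w = 1.0 / np.sqrt(np.maximum(counts, 1.0))  # Neyman weighting

    rng = np.random.default_rng(seed)
    span = t[-1] - t[0]
    tau_lo = max(curve.bin_width_ns, 1e-3)
    tau_hi = curve.repetition_period_ns or (2.0 * span)
    best = None
    for start_idx in range(max(n_starts, 5)):
        # log-spaced ladder across the window, jittered per start
        base = np.logspace(
            np.log10(tau_lo * 2), np.log10(tau_hi / 2), n_components + 2
        )[1:-1]
        jitter = rng.uniform(0.5, 2.0, size=n_components) if start_idx else 1.0
        x0 = np.log(base * jitter)
        try:
            sol = least_squares(
                lambda lt: _varpro_solve(lt, t, counts, w)[1],
                x0,
                bounds=(np.log(tau_lo / 10), np.log(tau_hi * 10)),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:
            continue
        loss = float(np.sum(sol.fun**2))
        if best is None or loss < best[0]:
            best = (loss, sol.x)
    if best is None:
        raise FitConvergenceError("no multistart initialisation converged")

    loss, log_taus = best
    coeffs, resid = _varpro_solve(log_taus, t, counts, w)
    amps, background = coeffs[:-1], coeffs[-1]
    taus = np.exp(log_taus)

    decay_counts = float(
        np.sum(amps[None, :] * np.exp(-(t[:, None] - t[0]) / taus[None, :]))
    )
    total_window = float(counts.sum())
    if amps.sum() <= 0 or decay_counts < 0.01 * total_window:
        raise FitConvergenceError(
            "fit converged to a background-only model: no exponential decay "
            "detected in the window",
            best_residual=loss,
        )

    # refer amplitudes back to t = 0 (the excitation pulse) so the
    # fractions match the decay-model convention, then sort and prune
    amps = amps * np.exp(t[0] / taus)
    order = np.argsort(taus)
    taus, amps = taus[order], amps[order]
    fractions = amps / amps.sum()
    keep = fractions >= PRUNE_FRACTION
    if not np.all(keep):
        warnings.warn(
            f"pruned {np.count_nonzero(~keep)} component(s) with amplitude "
            f"fraction < {PRUNE_FRACTION:.1%}",
            stacklevel=2,
        )
        taus, amps = taus[keep], amps[keep]
        fractions = amps / amps.sum()

    dof = max(t.size - (2 * taus.size + 1), 1)
    chi2_red = float(np.sum(resid**2) / dof)
    return DecayFit(
        total_amplitude=float(amps.sum()),
        amplitude_fractions=fractions,
        lifetimes_ns=taus,
        background_per_bin=float(background),
        chi2_reduced=chi2_red,
        window_ns=window,
    )


def select_component_count(
    curve: DecayCurve,
    max_components: int = MAX_COMPONENTS,
    improvement_threshold: float = 0.05,
    fit_window_ns: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[int, list[float]]:
    """Pick the number of exponential components by chi-square improvement.

    Fits n = 1, 2, ... and returns the smallest n for which adding a
    component improves reduced chi-square by less than
    ``improvement_threshold`` (relative). Returns ``(n, chi2_trace)``
    where the trace records reduced chi-square per candidate n.
    """
    chi2_trace: list[float] = []
    prev = None
    for n in range(1, max_components + 1):
        try:
            fit = fit_decay(curve, n, fit_window_ns=fit_window_ns, seed=seed)
        except FitConvergenceError:
            if prev is None:
                raise
            return n - 1, chi2_trace
        chi2_trace.append(fit.chi2_reduced)
        if prev is not None:
            improvement = (prev - fit.chi2_reduced) / prev if prev > 0 else 0.0
            if improvement < improvement_threshold:
                return n - 1, chi2_trace
        prev = fit.chi2_reduced
    warnings.warn(
        f"chi-square still improving at the cap of {max_components} components",
        stacklevel=2,
    )
    return max_components, chi2_trace
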