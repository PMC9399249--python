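# Methods

This note records the models implemented in `geofret`, the defaults and
why they hold, the numerical choices, and what the synthetic-data tests
do and do not demonstrate about real measurements.

## Förster theory layer

The overlap integral J = ∫ Ī_D(λ) ε_A(λ) λ⁴ dλ is evaluated by the
trapezoidal rule on the union of the two input wavelength grids after
linear interpolation, restricted to the interval where both spectra have
support; outside its own support a spectrum contributes zero (no
extrapolation). With λ in nm and ε_A in M⁻¹ cm⁻¹, J carries units of
M⁻¹ cm⁻¹ nm⁴ and the prefactor 0.0211 in
R₀ = 0.0211 (κ² Φ_D n⁻⁴ J)^(1/6) yields R₀ in nm. No fixed wavelength
step is imposed — the integration grid is whatever the inputs provide,
and it is returned in the result metadata so a run is auditable.
Against a 2×10⁶-point quadrature of analytic Gaussian bands the
union-grid trapezoid agrees to better than 0.1% at 0.5 nm input spacing.

Defaults: κ² = 2/3, appropriate when both dipoles reorient fast relative
to the transfer time (flexibly tethered dyes, isotropic QD emission);
n = 1.35 for aqueous buffer. Both are overridable per call and per CLI
config.

Absorbance unmixing solves measured(λ) = Σᵢ cᵢ εᵢ(λ) l by non-negative
least squares (`scipy.optimize.nnls`) on the union grid, with an
optional constant-baseline column for unstructured scattering
background; the baseline is off by default because the provenance of
such a term in any given measurement is instrument-specific. A
rank-deficient component matrix is rejected by name rather than
producing an arbitrary split between collinear spectra. The relative
quantum-yield method uses the standard single-point formula
Φ = Φ_s (I/I_s)(A_s/A)(n²/n_s²) with rhodamine 101 in ethanol
(Φ_s = 0.92) as the default standard; absorbances above 0.2 trigger an
inner-filter warning rather than an error.

## FRET engine and network

Efficiency routes (intensity, lifetime, geometry, rates) are closed
forms; the engine's job is consistency and inversion. Negative
efficiencies (I_DA > I_D or τ_DA > τ_D) are reported with a warning
instead of raised, because emission enhancement is a real observation
the pipeline must surface. The acceptor-count inversion
n = E R⁶ / ((1−E) R₀⁶) reports both the real value and its
round-half-to-even integer, since a physical dye count is an integer but
the uncertainty band is not.

The multi-step network is fixed at three nodes (initial donor, relay,
terminal acceptor) — the topology the quench formulas are written for —
rather than generalized to N nodes, keeping every output verifiable
against an independent kinetic Monte-Carlo branching simulation (the
test suite runs 10⁶-trial simulations over random rate triples and
requires agreement within 0.005 absolute). Assumptions: no back-transfer
from acceptor to relay, no homo-FRET, negligible direct excitation of
the relay (excitation is chosen on the QD absorption side), and only
relative rates matter, so the radiative/non-radiative split of the donor
decay is not modeled. Distances are center-to-center. When an edge is
given both a direct γ and an (R₀, R) pair, the direct γ wins with a
warning.

## TCSPC decay analysis

Decays are tail-fit: the window starts two bins after the histogram peak
by default (configurable), avoiding the instrument-response region
without requiring a measured IRF, which tail fitting does not need for
lifetimes well above the bin width. The model is
I(t) = C Σ γᵢ e^(−t/τᵢ) + b with Neyman weights 1/max(count, 1). The
optimizer uses variable projection: the nonlinear search runs over
log-lifetimes only and the amplitudes plus constant background are
solved by weighted NNLS at every step. This reduces a 2k+1-parameter
problem to k nonlinear dimensions and makes multistart cheap; five
seeded initialisations with jittered log-spaced lifetime ladders are
tried and the best loss kept. Fitted amplitudes are extrapolated from
the window start back to t = 0 so the reported fractions γᵢ follow the
decay-model convention (Σγᵢ = 1 at the excitation pulse) and the
amplitude-weighted mean τ̄ = Σγᵢτᵢ is directly comparable across
windows. Components with fraction < 0.5% are pruned with a warning. A
fit in which the exponential part carries under 1% of the windowed
counts raises a convergence error rather than returning a
background-only "fit". Component count selection adds components until
the reduced chi-square improves by less than 5% (threshold
configurable) and logs the chi-square trace.

A Poisson maximum-likelihood loss was considered as an alternative to
Neyman weighting; at the count levels the pipeline targets (≥10⁵ photons
per curve) the two are practically indistinguishable, so the weighted
least-squares route with its variable-projection structure was kept.

## Scaffold geometry and polymer statistics

Scaffolds are idealized regular solids — tetrahedron and equilateral
pentagonal pyramid (apex edges equal to base edges) — with centroid at
the origin and edge length edge_bp × 0.34 nm (B-DNA rise). Real origami
edges are helix bundles with finite cross-section and specific overhang
geometry; the idealization reproduces designed edge lengths (52 bp →
17.68 ≈ 18 nm; 63 bp → 21.42 ≈ 21 nm) and inter-site distances at the
nanometre level, and radial site offsets let a user match
independently-known distances (e.g. particle radius + spacer) exactly.
A site anchored at the centroid has no defined radial direction; a
nonzero offset there is applied along +z by convention. Bond angles are
interior angles in [0°, 180°] via the clipped normalized dot product.
Angle ensembles get a Gaussian maximum-likelihood summary (sample mean
and sd) plus the empirical fraction inside a stated angular window —
matching how particle-trimer TEM statistics are reported.

The ssDNA mapping solves R_ee = b (L/b)^ν for the Kuhn length b, with
R_ee = √6.25 × Rg, contour L = n_nt × 0.63 nm and Flory exponent
ν = 0.588. The Rg→R_ee prefactor for a self-avoiding walk is not
universal across conventions, so it is an explicit parameter (√6
recovers the ideal-chain closed form b = 6Rg²/L at ν = 1/2). Persistence
length is reported as b/2, the wormlike-chain convention; literature
usage occasionally swaps the two quantities, so the returned model
echoes every convention it used. For Rg = 6.2 nm at 51 nt the defaults
give b ≈ 5.5 nm (l_p ≈ 2.7 nm); the inversion round-trips to 1e-9.

## Synthetic data: what it does and does not show

Generators produce Gaussian emission bands, absorptivity bands with an
optional power-law UV tail (the qualitative shape of QD absorption; the
exponent is a free knob because real tail shapes vary), additive
absorbance mixtures with Gaussian noise, multi-exponential decay
histograms with Poisson counting noise, uniform background and periodic
wrap-around at the 400 ns repetition period (2.5 MHz excitation —
wrap-around matters because QD lifetimes of tens of ns leave residual
intensity between pulses), lognormally-noised intensity/lifetime
replicate pairs, and Gaussian bond-angle draws reflected at 0°/180°
(reflection avoids the truncation bias that clipping would put at the
boundaries). One global seed fans out to fixed per-generator substreams,
so every dataset is bitwise reproducible and adding a generator never
shifts existing streams. Each generator returns its ground truth beside
the data.

Closed-loop tests (generate → analyze → recover) therefore demonstrate
correctness of the estimators under the generating model: exact model
class, ideal baselines, no instrument response, no detector afterpulsing
or pile-up, no spectral calibration error, no dye photophysics
(blinking, bleaching). Passing them shows the analysis is right, not
that real data meet these assumptions.

Problem sizes used in the routine suite: 10⁶-count decay histograms
(single fits and a 50-seed recovery study), 10⁶-trial Monte-Carlo
network simulations over 20 random rate triples, 100-replicate unmixing
noise studies, and 10³–10⁴-draw angle ensembles. The full suite runs in
well under a minute on one core.

## Known limitations

- The overlap integral inherits the input grid; severely undersampled
  spectra degrade J silently (the returned grid metadata is the check).
- Tail fitting cannot resolve lifetimes comparable to the bin width or
  to the pre-window cut; those need IRF reconvolution, which is out of
  scope.
- The network model omits back-transfer and homo-FRET; for spectrally
  close relay/acceptor pairs the sequential component would be
  overestimated.
- Scaffold models are rigid; thermal fluctuations of origami edges and
  tether flexibility enter only through user-supplied site offsets or
  the angle-ensemble width.
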