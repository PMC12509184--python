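# Methods

This note documents the models behind `qsuppress`, the defaults and the
reasoning for them, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Single-spin model of the suppression element

Each event in a pulse train is an SU(2) rotation on an uncoupled
spin-1/2 at resonance offset ν (Hz), tracked by Cayley–Klein parameters
(α, β) with |α|² + |β|² = 1:

- a hard pulse of flip angle θ, phase φ and duration t_p is a rotation
  by 2π·ν_eff·t_p about the effective field
  (ν₁cosφ, ν₁sinφ, ν)/ν_eff with ν_eff = √(ν₁² + ν²) and
  ν₁ = (θ/360)/t_p the RF amplitude;
- the idealized (zero-duration) limit is the offset-independent rotation
  by θ about the in-plane axis at φ;
- free precession during a delay τ is a z-rotation by 2πντ;
- shaped pulses are propagated as piecewise-constant segments.

Phase 0° rotates about +x and positive offsets precess counterclockwise.
Only internal consistency matters: every reported profile is a
magnitude.  A test cross-checks the Cayley–Klein composition against an
independent 3×3 rotation-matrix propagation (conjugation map
R_ij = ½Tr(σ_i U σ_j U†)) to 1e−8.

**Excitation sculpting.**  Crusher gradients are treated as ideal: each
crushed echo keeps only the refocused coherence pathway, so the retained
transverse fraction is |β²| per echo and |β|⁴ for the double echo.
Gradient amplitudes/timing are carried as metadata and never enter the
computation.  Relaxation and radiation damping during the element are
neglected; deviations from measured profiles are expected near notch
edges, where real spectrometers also suffer B1 inhomogeneity.  The
perfect-echo flag (quadrature 90° between the echoes) refocuses
J evolution in coupled systems; it does not change the single-spin
profile and is documentation only.  Coupled-spin simulation is out of
scope.

**Nominal delay convention.**  τ = 1/ν_null, not the 1/(2ν) convention
some vendor binomial sequences use.  It is the unique choice that
simultaneously reproduces a first off-center null at exactly ν_null
(verified by simulation in the test suite) and the familiar element
durations (≈5.0 ms nominal for a 10-pulse W5 at 1800 Hz; ≈3.9 ms for an
8-pulse train).

**W5 flip angles.**  7.8°, 18.5°, 37.2°, 70.0°, 134.2°, mirrored with
inverted phase — the standard W5 constants, exposed as
`W5_FLIP_ANGLES` and overridable per call.  JRS-family coefficients are
deliberately not shipped: they come from a genetic-algorithm
optimization published elsewhere, so `build_jrs` stays generic and takes
them from the caller.

**Time correction.**  Chemical-shift evolution during finite pulses
lengthens each effective evolution interval and drags the off-center
nulls inward (e.g. at 2.5 kHz RF the simulated 1800 Hz null of an
uncorrected W5 sits near 1776 Hz).  The correction shortens delay i by
c·(2/π)·(t_p,i + t_p,i+1)/2 and calibrates the scale c numerically:
the first off-center null position is located by a coarse scan plus
bounded scalar minimization of |β|, and c is root-found (Brent) so the
null returns to ν_null.  The (2/π) first-order rule only seeds the
search; the null-position-vs-c curve is not monotone at low RF, so the
scan prefers the last (stable, increasing) sign-change bracket.  After
root-finding the result is verified — the restored minimum must lie
within 2 % of ν_null with residual |β| < 0.05 — otherwise the
correction is declared infeasible (as it is when pulse durations are
comparable to the delays).  An analytic correction formula exists in
the literature; the numerical calibration reproduces its effect without
assuming its form.

**Presaturation.**  Continuous-wave irradiation is modeled by the Bloch
steady state, Mz/M0 = (1 + (2πνT2)²)/(1 + (2πνT2)² + (2πν₁)²T1T2),
checked in tests against a linear solve of the full Bloch system.
Phase-cycled presaturation sequence internals, saturation transfer and
radiation damping are out of scope.

## Notch analysis and robust statistics

The default analysis grid is 25 Hz steps over ±2.5 kHz (201 points) —
25 Hz is a 0.05 ppm carrier-sweep step at 500 MHz, and 200-odd points
matches a realistic sweep series.  Profiles are plateau-normalized
(divide by the maximum; a Huber-based robust mode exists for noisy
sweeps).  A notch is a maximal run of grid points below the efficiency
threshold (default 0.97, the level at which usable regions are
conventionally anchored; configurable).  Its width is the distance
between the first grid offsets on either side at or above the
threshold; endpoints are reported at grid resolution, mirroring how
sweep data are read, with no sub-grid interpolation.  Usable ranges are
the maximal at-or-above-threshold intervals.  The threshold-crossing
rule is this package's operationalization of the visual
"inflection before the notch" selection used with experimental sweeps.

Excitation scatter inside the usable ranges is summarized robustly:

- **Huber-M location**, tuning constant c = 1.345 (the standard
  95 %-efficiency choice), iteratively reweighted with a fixed
  normalized-MAD scale (1.4826·MAD); if the MAD is zero the median is
  returned.  On a symmetric sample with no point beyond c·s the
  estimate equals the mean.
- **Qn scale**, the first-quartile order statistic of the n(n−1)/2
  pairwise absolute differences times 2.2219 (normal consistency), by
  explicit enumeration — exact, O(n²), and entirely adequate for the
  few hundred points of a profile.  No finite-sample correction is
  applied; that keeps the estimator identical to its defining order
  statistic (an approximate cross-check against statsmodels'
  corrected implementation is in the tests).
- **relative excitation uncertainty** = 100·Qn/location (percent), the
  allowance a suppression scheme adds per suppressed signal used in the
  measurement model.

A Shapiro–Wilk p-value is reported for transparency, but the robust
path is unconditional: excitation values over a usable range are
bounded above and rippled, and their distribution is generally
non-normal (the simulated W5 plateau fails the test decisively).

## Relaxometry

Inversion recovery uses the three-parameter model
M(vd) = M₀(1 − 2f·e^(−vd/T1)).  Freeing the inversion efficiency f
matters when a suppression block follows the excitation pulse: partial
inversion would otherwise bias T1.  Whether one fixes f = 1 cannot be
decided from fitted T1 values alone, so both forms are available
(`fix_f=1.0` gives the textbook two-parameter fit).  Fits are
Levenberg–Marquardt (lmfit) with multi-start T1 initialization — the
zero-crossing estimate t_null/ln 2 plus a log-spaced ladder across the
delay range — keeping the fit out of local minima for all-positive
(weak-inversion) series, which are additionally flagged when
f < 0.5.  Standard errors come from the scaled covariance; a
parameter-recovery study in the tests (200 seeded replicates, SNR 1000,
T1 ∈ [0.5, 5.4] s on a 12-point log-spaced 0.01–30 s delay design)
keeps the median relative T1 error under 0.5 %.

CPMG decays are fitted as M(t) = M₀e^(−t/T2), initialized from a
log-linear regression; a non-decaying series raises a fit failure
("T2 unbounded") rather than returning a divergent estimate.  Relaxation
loss during the suppression block itself is not corrected — published
correction schemes exist but are out of scope — and signals inside the
suppression band must be excluded upstream (they cannot be measured).

The repetition-time helper returns factor × max(T1), default factor 10,
leaving < 0.005 % residual saturation.

## Quantitation

Integration is plain trapezoidal on the frequency grid, with no
baseline or lineshape model — synthetic spectra are baseline-free and
experimental baseline handling is deliberately left to the caller.
Finite integration windows clip Lorentzian tails; the closed-form
capture fraction (2/π)·arctan(2·half-width/FWHM) is available
(`lorentzian_area_in`) and used in the recovery tests (a ±20 FWHM
window captures 98.4 % of the area).  Integration limits per signal are
configurable; no defaults are imposed.  Molar-mass bookkeeping
(monohydrate vs anhydrous) is the caller's responsibility; the default
fixture uses the monohydrate value for kainic acid (231.25 g/mol),
consistent with its fixture concentration.

## Uncertainty budgets

Components are named relative uncertainties in percent, each tied to a
factor of the measurement model; internal-standard-area components
divide the simulated measurand, all others multiply it.  Normal
components are sampled as 1 + u·z/100; rectangular components are
quoted as half-widths and sampled uniformly (their standard uncertainty
is half-width/√3, and the quadrature cross-check applies the same
convention).  The default 10 000 draws reproduce a two-component
3 %/4 % quadrature to within Monte Carlo error (≈0.035 % standard error
of the combined value) in well under a second.  The excitation
allowance enters once per suppressed signal (analyte and internal
standard), treated as independent — the profile value at two different
offsets fluctuates independently through shimming and carrier drift.
The package ships only a documented example budget (a 0.89 % base plus
two 1.03 % excitation allowances, combining to ≈1.71 %); full
laboratory budgets are inputs, not constants.

## Synthetic data: what it emulates, what it does not

`gen_spectrum` builds frequency-domain sums of Lorentzians: area
proportional to proton count × molar amount, FWHM = 1/(πT2), a solvent
line whose height is a configurable multiple (default 100×, usable to
10⁴ and beyond) of the tallest analyte line, optional pointwise
multiplication by a suppression transfer function, and seeded Gaussian
noise.  Spectra are generated directly in the frequency domain — every
consumer operates on spectra, so FID synthesis would add nothing.  The
default mixture emulates a kainic acid (17.3 µmol, eight signals at
1.64–4.93 ppm with their measured D2O T1 constants) plus maleic acid
(38.3 µmol, singlet) sample in water at 500.13 MHz; the maleic shift
(6.27 ppm), per-signal proton counts and T2 values are fixture choices.

Two deliberate idealizations bound what passing tests demonstrate:

1. **Pointwise transfer.**  Multiplying the spectrum by the transfer
   function conflates a signal's position with its spectral support.
   Real suppression removes the whole solvent *magnetization* — tails
   included — whereas the pointwise model leaves solvent tails that lie
   in usable ranges untouched.
2. **Sharp solvent line.**  The default solvent T2 of 1 s (≈0.3 Hz
   linewidth, a well-shimmed water line) keeps those residual tails
   below ≈0.05 % of the default quantitation integrals.  Real no-D
   water lines can be broader, asymmetric and radiation-damped, with
   baseline consequences the generator does not model.

Consequently the end-to-end recovery tests (bias < 0.5 %) demonstrate
the correctness of the integration/quantitation chain, not robustness
to real solvent lineshapes, receiver-gain clipping or phase errors —
all explicitly outside the generator's scope.  Every generator is a
pure function of its seed.

## Problem sizes and numerical defaults

- Profile grids: 201 points (25 Hz over ±2.5 kHz) for analysis; 2 501
  points (1 Hz over 0–2.5 kHz) for null localization; both run in
  milliseconds.
- Null localization in `time_correct`: 400-point coarse scan over
  0.45–1.6× the null spacing, then bounded minimization (xatol 1e−4 Hz);
  correction-scale root-finding to xtol 1e−6.
- Huber-M iteration: relative tolerance 1e−12, max 200 iterations.
- Monte Carlo: 10 000 draws default (minimum 1 000), numpy PCG64
  streams, fully reproducible from the seed.
- T1 recovery study: 200 replicates × 12-point series (seconds total).
- Degenerate inputs raise typed exceptions (invalid parameter,
  infeasible correction, no usable range, insufficient data, fit
  failure) rather than returning sentinel values.
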