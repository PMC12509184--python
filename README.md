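# qsuppress

A quantitative-NMR (qNMR) solvent-suppression toolkit for analysts who
quantify compounds in protonated ("no-D") solvents, where the solvent
resonance can be orders of magnitude more intense than any analyte
signal.  The package answers the practical questions such a measurement
raises:

- *How do I build the selective suppression element?*  W5 binomial-like
  trains, generic jump-and-return-sandwich (JRS) trains and user-supplied
  shaped pulses, parameterized by a single null-spacing constant
  (the distance in Hz from the central suppression to the next null).
- *What does the element do across the spectrum?*  A single-spin
  simulator propagates Cayley–Klein rotation parameters through the
  pulse train and returns the excitation-sculpting transfer function
  |β(ν)|⁴ of the double crushed gradient echo.
- *Which signals can I trust?*  Notch detection, suppression widths and
  usable spectral ranges at a 97 % efficiency threshold, with robust
  excitation statistics (Huber-M location on a MAD scale, Qn scale)
  summarizing the plateau scatter.
- *What is my result and its uncertainty?*  Internal-standard
  quantitation by the area-ratio measurement model, inversion-recovery
  T1 / CPMG T2 fitting with multi-start nonlinear least squares, and a
  seeded Monte Carlo uncertainty engine that folds the
  excitation-profile allowance into the budget.

## The models in brief

**Suppression element.**  A W5 element is ten hard pulses
(7.8°, 18.5°, 37.2°, 70.0°, 134.2° at phase 0°, then the mirror image at
phase 180°) separated by uniform delays τ = 1/ν_null.  On resonance the
two halves cancel; between nulls the train acts as an effective 180°
pulse.  Wrapped in a double crushed spin echo (excitation sculpting),
the retained transverse fraction at offset ν is |β(ν)|⁴, zero at
multiples of ν_null.  With finite pulse durations the nulls creep
inward; `time_correct` root-finds the uniform delay reduction that
restores them.

**Quantitation.**  The internal-standard measurement model

    m_a = (I_a / I_IS) · (N_IS / N_a) · (MM_a / MM_IS) · m_IS · P_IS

with signal areas I, equivalent-proton counts N, molar masses MM, the
internal-standard mass m_IS (mg) and purity P_IS (g/g); trueness is the
relative bias b% = (m_a − m_a,theor)/m_a,theor × 100.

**Relaxometry.**  Inversion recovery
M(vd) = M₀(1 − 2f·e^(−vd/T1)) with an explicit inversion efficiency f
(suppression blocks make f < 1 plausible), CPMG decay
M(t) = M₀·e^(−t/T2).  `statsmodels`-style model objects
(`InversionRecoveryModel(...).fit()` → results with `summary()`).

**Uncertainty.**  Relative components perturb the factors of the
measurement model multiplicatively; 10 000 seeded Monte Carlo draws give
the combined relative standard uncertainty and the expanded (k = 2)
value, with a root-sum-of-squares (GUM-style) quadrature as the analytic
cross-check.  The excitation allowance applies once per suppressed
signal used in the ratio — analyte and internal standard each.

## Worked example

```python
import numpy as np
import qsuppress as q

train = q.build_w5(1800.0)                      # idealized W5, cnst-style 1800 Hz
spec = q.SequenceSpec(train, echo_count=2)      # excitation sculpting
profile = q.sculpting_profile(spec, q.default_offset_grid()).normalized()
report = q.find_notches(profile, threshold=0.97)
report = q.robust_excitation_stats(profile, report.usable_ranges, report)
print("suppression width:", report.suppression_width, "Hz")
print("usable ranges:", report.usable_ranges)
print(f"relative excitation uncertainty: {report.relative_excitation_uncertainty:.2f} %")
```

prints

```
suppression width: 600.0 Hz
usable ranges: [(-2500.0, -2100.0), (-1500.0, -300.0), (300.0, 1500.0), (2100.0, 2500.0)]
relative excitation uncertainty: 0.46 %
```

The central notch is 600 Hz wide at the 97 % threshold — signals beyond
±300 Hz (±0.6 ppm at 500 MHz) from the solvent are quantifiable — and
the usable range runs out to 1500 Hz, where the secondary notch at
1800 Hz begins to bite.  The 0.46 % is the Qn/Huber-M scatter of the
simulated plateau; experimental sweeps add acquisition noise on top.

Fitting a seeded synthetic inversion-recovery series and combining an
example uncertainty budget:

```python
series = q.gen_ir_series(T1=5.4, noise_sigma=1e-3, seed=42)
print(q.fit_inversion_recovery(series).summary())

comps = [
    q.BudgetComponent("base budget (no suppression)", 0.89),
    q.BudgetComponent("excitation allowance (analyte)", 1.03, applies_to="excitation"),
    q.BudgetComponent("excitation allowance (IS)", 1.03, applies_to="excitation"),
]
print(q.mc_combine(comps, draws=10_000, seed=1).report())
```

```
inversion-recovery fit
==============================================
parameter         estimate       std err
----------------------------------------------
m0                 1.00098     0.0008422
f                 0.999627    0.00048993
t1                 5.40653     0.0068971
----------------------------------------------
n = 12, residual norm = 0.002872

Uncertainty budget (Monte Carlo)
============================================
component                    u_rel (%)
--------------------------------------------
base budget (no suppression)       0.890
excitation allowance (analyte)       1.030
excitation allowance (IS)        1.030
--------------------------------------------
combined u_rel                   1.705
expanded U (k=2)                 3.410
draws = 10000, seed = 1
```

The fitted T1 recovers the generating 5.4 s within one standard error,
and adding the two excitation allowances to a 0.89 % base budget roughly
doubles the combined uncertainty to ≈1.7 %.

A command-line interface mirrors these pipelines
(`qsuppress simulate-profile | analyze-profile | fit-t1 | fit-t2 |
quantify | budget | gen-synthetic`); every run logs its parameters and
seed.

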