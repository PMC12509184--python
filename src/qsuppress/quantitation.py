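"""Internal-standard qNMR quantitation.

The measurement model relates the analyte mass in the tube to the ratio
of normalized signal areas against a gravimetrically known internal
standard:

    m_a = (I_a / I_IS) * (N_IS / N_a) * (MM_a / MM_IS) * m_IS * P_IS

with I the signal areas, N the equivalent-proton counts, MM the molar
masses (g/mol), m_IS the internal-standard mass (mg) and P_IS its purity
(g/g).  Trueness is summarized by the relative bias
``b% = (m_a - m_a,theor) / m_a,theor * 100`` against a gravimetric
reference value.

Integration is plain trapezoidal on the frequency grid with no baseline
model (synthetic spectra are baseline-free; experimental baselines are
the caller's responsibility).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "QuantInput",
    "QuantResult",
    "quantify_mass",
    "relative_bias",
    "integrate_region",
    "concentration_from_mass",
]


@dataclass(frozen=True)
class QuantInput:
    """Inputs of the internal-standard measurement model.

    Areas are in arbitrary (but common) units; N are equivalent-proton
    counts; MM in g/mol; m_IS in mg; P_IS in g/g.
    """

    I_a: float
    I_IS: float
    N_a: float
    N_IS: float
    MM_a: float
    MM_IS: float
    m_IS: float
    P_IS: float

    def __post_init__(self) -> None:
        for name in ("I_a", "I_IS", "N_a", "N_IS", "MM_a", "MM_IS", "m_IS", "P_IS"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.P_IS > 1.0:
            raise InvalidParameterError("P_IS is a mass fraction, must be <= 1")


@dataclass(frozen=True)
class QuantResult:
    """Analyte mass (mg), optional purity (g/g) and relative bias (%)."""

    m_a: float
    purity: float | None = None
    bias_percent: float | None = None


def quantify_mass(q: QuantInput) -> float:
    """Analyte mass (mg) from the internal-standard area ratio."""
    return (
        (q.I_a / q.I_IS)
        * (q.N_IS / q.N_a)
        * (q.MM_a / q.MM_IS)
        * q.m_IS
        * q.P_IS
    )


def quantify(
    q: QuantInput,
    m_theor: float | None = None,
    m_weighed: float | None = None,
) -> QuantResult:
    """Full quantitation record: mass, bias vs a gravimetric reference,
    and purity when the weighed analyte mass is supplied."""
    m_a = quantify_mass(q)
    bias = relative_bias(m_a, m_theor) if m_theor is not None else None
    purity = (m_a / m_weighed) if m_weighed else None
    return QuantResult(m_a=m_a, purity=purity, bias_percent=bias)


def relative_bias(m_a: float, m_theor: float) -> float:
    """Signed relative bias in percent against the reference mass."""
    if m_theor <= 0:
        raise InvalidParameterError("reference mass must be > 0")
    return (m_a - m_theor) / m_theor * 100.0


def integrate_region(spectrum, region: tuple[float, float]) -> float:
    """Trapezoidal integral of the real intensity over a ppm interval.

    ``spectrum`` is anything with ``ppm`` and ``intensity`` attributes
    (e.g. :class:`qsuppress.io.Spectrum`) or an ``(x, y)`` pair of
    arrays.  The region is inclusive of grid points at its edges; an
    interval that contains fewer than two grid points is an error.
    """
    if hasattr(spectrum, "ppm"):
        x = np.asarray(spectrum.ppm, dtype=float)
        y = np.asarray(spectrum.intensity)
    else:
        x, y = (np.asarray(a) for a in spectrum)
    lo, hi = sorted(float(r) for r in region)
    if lo == hi:
        raise InvalidParameterError("integration region is empty")
    order = np.argsort(x)
    x, y = x[order], np.real(y[order])
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 2:
        raise InvalidParameterError(
            f"region [{lo}, {hi}] contains fewer than 2 grid points"
        )
    return float(np.trapezoid(y[mask], x[mask]))


def concentration_from_mass(
    mass_mg: float, molar_mass: float, volume_ml: float
) -> float:
    """Concentration in mM from mass (mg), molar mass (g/mol), volume (mL).

    mg / (g/mol) = mmol; mmol / mL = mol/L; x1000 gives mmol/L (mM).
    """
    if mass_mg <= 0 or molar_mass <= 0 or volume_ml <= 0:
        raise InvalidParameterError("mass, molar mass and volume must be > 0")
    return mass_mg / molar_mass / volume_ml * 1000.0
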