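"""Synthetic spectra and relaxation series for pipeline testing.

Emulates the statistical structure the analyses assume: Lorentzian-peak
frequency-domain spectra with a dominant solvent resonance (a
protonated-solvent "no-D" sample of an analyte plus an internal
standard), optional pointwise multiplication by a suppression transfer
function, seeded additive Gaussian noise; and exponential
inversion-recovery / CPMG relaxation series.

Spectra are generated directly in the frequency domain (every consumer
in the package operates on spectra, not FIDs).  Each Lorentzian's area
is proportional to the proton count times the molar amount of its
compound, its full width at half maximum follows from the transverse
relaxation time as ``1/(pi*T2)``, and the solvent line is scaled so its
peak height is a configurable multiple of the tallest analyte line —
two or more orders of magnitude emulates no-D conditions.  Every
generator is a pure function of its seed.

The default mixture emulates a kainic acid + maleic acid sample in
water: maleic acid singlet (2H) at 6.27 ppm, kainic acid signals at
1.64/2.36/2.98/3.33/3.54/4.15/4.65/4.93 ppm with their measured
D2O T1 constants, solvent at 4.70 ppm, 500.13 MHz.  The proton counts
per kainic signal and the maleic shift are fixture choices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError
from .io import Spectrum
from .relaxometry import RelaxationSeries
from .simulate import ExcitationProfile

__all__ = [
    "SyntheticPeak",
    "SyntheticMixtureSpec",
    "default_kainic_maleic_spec",
    "gen_spectrum",
    "gen_ir_series",
    "gen_cpmg_series",
    "lorentzian_area_in",
]

#: molar masses used by the default fixture (g/mol); kainic acid as the
#: monohydrate, consistent with the fixture concentrations.
MM_KAINIC_MONOHYDRATE = 231.25
MM_MALEIC = 116.07


@dataclass(frozen=True)
class SyntheticPeak:
    """One resonance: position, proton count, relaxation, molar amount."""

    center_ppm: float
    protons: int
    T1: float
    T2: float
    label: str = ""
    amount_mmol: float = 1.0

    def __post_init__(self) -> None:
        if not (self.T1 >= self.T2 > 0):
            raise InvalidParameterError(
                f"need T1 >= T2 > 0, got T1={self.T1}, T2={self.T2}"
            )
        if self.protons <= 0 or self.amount_mmol <= 0:
            raise InvalidParameterError("protons and amount must be > 0")


@dataclass(frozen=True)
class SyntheticMixtureSpec:
    """A synthetic mixture: analyte peaks plus a dominant solvent line."""

    peaks: tuple[SyntheticPeak, ...]
    solvent_ppm: float = 4.70
    solvent_relative_intensity: float = 100.0
    solvent_T2: float = 1.0
    spectrometer_frequency: float = 500.13
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.solvent_relative_intensity < 1.0:
            raise InvalidParameterError(
                "solvent must be at least as intense as the analytes"
            )
        if self.spectrometer_frequency <= 0:
            raise InvalidParameterError("spectrometer frequency must be > 0")

    def to_manifest(self) -> dict:
        return {
            "peaks": [
                {
                    "center_ppm": p.center_ppm,
                    "protons": p.protons,
                    "T1_s": p.T1,
                    "T2_s": p.T2,
                    "label": p.label,
                    "amount_mmol": p.amount_mmol,
                }
                for p in self.peaks
            ],
            "solvent_ppm": self.solvent_ppm,
            "solvent_relative_intensity": self.solvent_relative_intensity,
            "solvent_T2_s": self.solvent_T2,
            "spectrometer_frequency_MHz": self.spectrometer_frequency,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    def write_manifest(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_manifest(), indent=2))


def default_kainic_maleic_spec(
    solvent_relative_intensity: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SyntheticMixtureSpec:
    """The default no-D fixture: kainic acid + maleic acid in water.

    Amounts reflect ~4 mg of each compound in 1 mL (17.3 umol kainic
    monohydrate, 38.3 umol maleic acid); T2 values are fixture choices
    giving linewidths of a fraction of a Hz to a few Hz.
    """
    kainic = [
        # (ppm, protons, T1 in D2O)
        (1.64, 3, 1.16),
        (2.36, 1, 0.66),
        (2.98, 1, 1.30),
        (3.33, 1, 0.54),
        (3.54, 1, 0.64),
        (4.15, 1, 2.49),
        (4.65, 1, 0.71),
        (4.93, 1, 0.92),
    ]
    peaks = [
        SyntheticPeak(
            center_ppm=ppm,
            protons=n,
            T1=t1,
            T2=min(0.4, t1 / 2),
            label=f"kainic {ppm:.2f} ppm",
            amount_mmol=0.0173,
        )
        for ppm, n, t1 in kainic
    ]
    peaks.append(
        SyntheticPeak(
            center_ppm=6.27,
            protons=2,
            T1=5.4,
            T2=1.0,
            label="maleic 6.27 ppm",
            amount_mmol=0.0383,
        )
    )
    return SyntheticMixtureSpec(
        peaks=tuple(peaks),
        solvent_relative_intensity=solvent_relative_intensity,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _lorentzian(x: np.ndarray, x0: float, area: float, fwhm: float) -> np.ndarray:
    hw = fwhm / 2.0
    return (area / np.pi) * hw / ((x - x0) ** 2 + hw**2)


def lorentzian_area_in(fwhm: float, half_span: float) -> float:
    """Closed-form fraction of a Lorentzian's area within +-half_span of
    its center: (2/pi) * arctan(2 * half_span / fwhm)."""
    return (2.0 / np.pi) * np.arctan(2.0 * half_span / fwhm)


def gen_spectrum(
    spec: SyntheticMixtureSpec,
    transfer: ExcitationProfile | None = None,
    ppm_range: tuple[float, float] = (-1.0, 11.0),
    npoints: int = 2**16,
) -> Spectrum:
    """Generate a frequency-domain spectrum of the synthetic mixture.

    Peak areas (before noise) are ``protons * amount_mmol`` in arbitrary
    units; linewidths are ``1/(pi*T2)`` Hz.  When ``transfer`` is given,
    the spectrum is multiplied pointwise by the suppression transfer
    function, with offsets measured from the solvent position (the
    carrier); the transfer grid must cover the whole spectral window.
    Noise is i.i.d. Gaussian with the spec's sigma and seed.
    """
    sf = spec.spectrometer_frequency
    ppm = np.linspace(ppm_range[0], ppm_range[1], npoints)
    y = np.zeros_like(ppm)
    heights = []
    for p in spec.peaks:
        area = p.protons * p.amount_mmol
        fwhm_ppm = (1.0 / (np.pi * p.T2)) / sf
        y += _lorentzian(ppm, p.center_ppm, area, fwhm_ppm)
        heights.append(2.0 * area / (np.pi * fwhm_ppm))
    solvent_fwhm_ppm = (1.0 / (np.pi * spec.solvent_T2)) / sf
    solvent_height = spec.solvent_relative_intensity * max(heights)
    solvent_area = solvent_height * np.pi * solvent_fwhm_ppm / 2.0
    y += _lorentzian(ppm, spec.solvent_ppm, solvent_area, solvent_fwhm_ppm)

    if transfer is not None:
        offsets_hz = (ppm - spec.solvent_ppm) * sf
        if (
            offsets_hz.min() < transfer.offsets[0]
            or offsets_hz.max() > transfer.offsets[-1]
        ):
            raise InvalidParameterError(
                "transfer grid does not cover the spectral window: "
                f"need {offsets_hz.min():.0f}..{offsets_hz.max():.0f} Hz, "
                f"have {transfer.offsets[0]:.0f}..{transfer.offsets[-1]:.0f} Hz"
            )
        y = y * np.interp(offsets_hz, transfer.offsets, transfer.retained_fraction)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sigma, npoints)

    label = "synthetic kainic+maleic" if spec.peaks else "synthetic"
    return Spectrum(ppm=ppm, intensity=y, sf_mhz=sf, label=label)


def gen_ir_series(
    T1: float,
    M0: float = 1.0,
    f: float = 1.0,
    delays: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    signal_label: str = "",
) -> RelaxationSeries:
    """Inversion-recovery series M(vd) = M0 (1 - 2 f exp(-vd/T1)) + noise.

    The default delay design is 12 points log-spaced from 10 ms to 30 s,
    bracketing the T1 range met in small-molecule qNMR.
    """
    if T1 <= 0:
        raise InvalidParameterError("T1 must be > 0")
    if delays is None:
        delays = np.geomspace(0.01, 30.0, 12)
    delays = np.asarray(delays, dtype=float)
    y = M0 * (1.0 - 2.0 * f * np.exp(-delays / T1))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, delays.size)
    return RelaxationSeries.from_arrays(delays, y, signal_label)


def gen_cpmg_series(
    T2: float,
    M0: float = 1.0,
    durations: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    signal_label: str = "",
) -> RelaxationSeries:
    """CPMG decay series M(t) = M0 exp(-t/T2) + noise."""
    if T2 <= 0:
        raise InvalidParameterError("T2 must be > 0")
    if durations is None:
        durations = np.geomspace(0.01, 5.0 * T2, 12)
    durations = np.asarray(durations, dtype=float)
    y = M0 * np.exp(-durations / T2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, durations.size)
    return RelaxationSeries.from_arrays(durations, y, signal_label)
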