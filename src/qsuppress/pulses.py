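"""Construction of binomial-like solvent-suppression pulse elements.

This module builds the selective inversion elements used in
excitation-sculpting solvent suppression: the W5 binomial-like train,
generic jump-and-return-sandwich (JRS) trains, and user-supplied shaped
pulses.  The single user-facing timing parameter is the *null spacing*
(the ``cnst10``-style constant): the distance in Hz from the central
suppression notch to the next null of the excitation profile.  For an
idealized train of zero-duration pulses the uniform interpulse delay is
``tau = 1 / null_spacing``.

With finite-duration pulses, chemical-shift evolution during the pulses
adds to the evolution during the delays and drags the off-center nulls
inward.  :func:`time_correct` shortens the delays to compensate, using a
numerical calibration: the uniform delay reduction is root-found so that
the simulated first off-center null returns to the nominal spacing.  The
first-order rule (subtract ``2/pi`` times half the durations of the two
flanking pulses) only seeds the search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import InfeasibleCorrectionError, InvalidParameterError

__all__ = [
    "W5_FLIP_ANGLES",
    "HardPulse",
    "ShapedPulse",
    "PulseTrain",
    "SequenceSpec",
    "delay_from_null_spacing",
    "build_w5",
    "build_jrs",
    "time_correct",
    "read_shaped_pulse",
]

#: Flip angles (degrees) of the first half of the W5 element; the second
#: half repeats them in reverse order with inverted phase.  Configurable:
#: :func:`build_w5` accepts an override.
W5_FLIP_ANGLES: tuple[float, ...] = (7.8, 18.5, 37.2, 70.0, 134.2)


@dataclass(frozen=True)
class HardPulse:
    """A rectangular pulse: flip angle and phase in degrees, duration in s.

    ``duration = 0`` marks the idealized (infinite-RF) limit; otherwise
    ``duration = (flip_angle / 360) / rf_amplitude``.
    """

    flip_angle: float
    phase: float = 0.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.flip_angle <= 0:
            raise InvalidParameterError(
                f"flip_angle must be > 0, got {self.flip_angle}"
            )
        if self.duration < 0:
            raise InvalidParameterError("duration must be >= 0")

    @property
    def rf_amplitude(self) -> float:
        """Equivalent RF field strength in Hz (inf for idealized pulses)."""
        if self.duration == 0:
            return float("inf")
        return (self.flip_angle / 360.0) / self.duration

    @classmethod
    def from_rf(
        cls, flip_angle: float, phase: float = 0.0, rf_amplitude: float | None = None
    ) -> "HardPulse":
        """Build a pulse whose duration follows from the RF amplitude.

        ``rf_amplitude=None`` (or inf) gives the idealized zero-duration
        pulse.
        """
        if rf_amplitude is None or np.isinf(rf_amplitude):
            return cls(flip_angle, phase, 0.0)
        if rf_amplitude <= 0:
            raise InvalidParameterError("rf_amplitude must be > 0")
        return cls(flip_angle, phase, (flip_angle / 360.0) / rf_amplitude)


@dataclass(frozen=True)
class ShapedPulse:
    """A shaped pulse as (relative amplitude, phase deg) samples.

    The carrier for externally optimized selective pulses (e.g. WADE-style
    shapes); the shape itself is an input, not something this package
    designs.
    """

    samples: tuple[tuple[float, float], ...]
    total_duration: float
    peak_rf: float
    label: str = "shaped"

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise InvalidParameterError("shaped pulse needs >= 2 samples")
        if self.total_duration <= 0:
            raise InvalidParameterError("total_duration must be > 0")
        if self.peak_rf <= 0:
            raise InvalidParameterError("peak_rf must be > 0")


@dataclass(frozen=True)
class PulseTrain:
    """An ordered train of pulses with interpulse delays.

    ``delays`` has one entry fewer than ``elements``; ``null_spacing`` is
    the cnst10-style parameter the train was built for.
    """

    elements: tuple[HardPulse, ...]
    delays: tuple[float, ...]
    null_spacing: float
    time_corrected: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.delays) != len(self.elements) - 1:
            raise InvalidParameterError(
                "need exactly one delay between consecutive pulses: "
                f"{len(self.elements)} pulses, {len(self.delays)} delays"
            )
        if any(d < 0 for d in self.delays):
            raise InvalidParameterError("delays must be >= 0")

    @property
    def total_duration(self) -> float:
        """Element length: pulse durations plus interpulse delays (s)."""
        return sum(p.duration for p in self.elements) + sum(self.delays)

    @property
    def idealized(self) -> bool:
        return all(p.duration == 0 for p in self.elements)


@dataclass(frozen=True)
class SequenceSpec:
    """A full excitation-sculpting suppression scheme.

    ``echo_count`` is the number of crushed gradient echoes wrapped around
    the selective element (2 = excitation sculpting / double echo).  The
    ``perfect_echo`` flag records whether a quadrature 90-degree pulse sits
    between the echoes to refocus J evolution; it does not change the
    single-spin profile and is documentation for coupled-spin behavior.
    Gradient amplitudes and timing are carried as free-form metadata only:
    the simulator treats the crushers as ideal.
    """

    selective_element: PulseTrain | ShapedPulse
    echo_count: int = 2
    perfect_echo: bool = False
    gradient_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.echo_count not in (1, 2):
            raise InvalidParameterError("echo_count must be 1 or 2")


def delay_from_null_spacing(null_spacing: float) -> float:
    """Nominal uniform interpulse delay (s) for a given null spacing (Hz).

    For an idealized antisymmetric train the excitation nulls are
    separated by exactly ``null_spacing`` when the delay is
    ``1 / null_spacing``: during each delay a spin at offset
    ``null_spacing`` precesses through a full turn, so the train acts as
    it does on resonance.
    """
    if null_spacing <= 0:
        raise InvalidParameterError(
            f"null_spacing must be > 0 Hz, got {null_spacing}"
        )
    return 1.0 / null_spacing


def _uniform_train(
    angles: Sequence[float],
    phases: Sequence[float],
    null_spacing: float,
    rf_amplitude: float | None,
    label: str,
) -> PulseTrain:
    tau = delay_from_null_spacing(null_spacing)
    pulses = []
    for ang, ph in zip(angles, phases):
        # a negative flip angle is the same rotation with the phase inverted
        if ang < 0:
            ang, ph = -ang, ph + 180.0
        pulses.append(HardPulse.from_rf(ang, ph % 360.0, rf_amplitude))
    return PulseTrain(
        elements=tuple(pulses),
        delays=(tau,) * (len(pulses) - 1),
        null_spacing=null_spacing,
        time_corrected=False,
        label=label,
    )


def build_w5(
    null_spacing: float,
    rf_amplitude: float | None = None,
    time_corrected: bool = False,
    flip_angles: Sequence[float] = W5_FLIP_ANGLES,
) -> PulseTrain:
    """Build the 10-pulse W5 selective inversion element.

    Five pulses of increasing flip angle at phase 0 followed by the same
    five in reverse order at phase 180, separated by uniform delays of
    ``1/null_spacing``.  On resonance the two halves cancel pairwise and
    the composite rotation is the identity; between nulls the train acts
    as an effective 180-degree pulse.

    Parameters
    ----------
    null_spacing : float
        Distance (Hz) from the central suppression to the next null.
    rf_amplitude : float, optional
        RF field strength in Hz; ``None`` gives idealized zero-duration
        pulses.
    time_corrected : bool
        Shorten the delays to compensate shift evolution during finite
        pulses (no-op for idealized pulses).
    flip_angles : sequence of float
        First-half flip angles; defaults to the standard W5 constants.
    """
    angles = list(flip_angles) + list(flip_angles[::-1])
    phases = [0.0] * len(flip_angles) + [180.0] * len(flip_angles)
    train = _uniform_train(angles, phases, null_spacing, rf_amplitude, "W5")
    if time_corrected:
        train = time_correct(train)
    return train


def build_jrs(
    flip_angles: Sequence[float],
    phases: Sequence[float],
    null_spacing: float,
    rf_amplitude: float | None = None,
    time_corrected: bool = False,
) -> PulseTrain:
    """Build a generic jump-and-return-sandwich style train.

    The JRS family's optimized flip angles and phases are supplied by the
    caller (they come from the genetic-algorithm optimization literature,
    not from this package); this constructor only lays out the uniform
    delay structure and optional time correction.
    """
    if len(flip_angles) != len(phases):
        raise InvalidParameterError(
            f"flip_angles ({len(flip_angles)}) and phases ({len(phases)}) "
            "must have equal length"
        )
    if len(flip_angles) < 2:
        raise InvalidParameterError("a train needs at least 2 pulses")
    train = _uniform_train(
        flip_angles, phases, null_spacing, rf_amplitude, f"JRS{len(flip_angles)}"
    )
    if time_corrected:
        train = time_correct(train)
    return train


def _first_order_reductions(train: PulseTrain) -> np.ndarray:
    """First-order delay reductions: (2/pi) x half the flanking durations."""
    tp = np.array([p.duration for p in train.elements])
    return (2.0 / np.pi) * (tp[:-1] + tp[1:]) / 2.0


def _null_position(train: PulseTrain) -> float:
    """Locate the first off-center null of the single-echo profile (Hz)."""
    from .simulate import _propagate  # local import: simulate imports pulses

    nu = train.null_spacing
    coarse = np.linspace(0.45 * nu, 1.6 * nu, 400)
    _, b = _propagate(train, coarse)
    mag = np.abs(b)
    i = int(np.argmin(mag))
    lo = coarse[max(i - 1, 0)]
    hi = coarse[min(i + 1, len(coarse) - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda o: float(np.abs(_propagate(train, np.array([o]))[1][0])),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x)


def time_correct(train: PulseTrain) -> PulseTrain:
    """Shorten delays so the first off-center null sits at ``null_spacing``.

    Chemical-shift evolution during finite pulses effectively lengthens
    each evolution interval, pulling the off-center nulls inward from the
    nominal spacing.  The correction scales the first-order reductions by
    a factor found numerically: the scale is root-found so the simulated
    null returns to the nominal position.  Idealized trains are returned
    unchanged (flag set).

    Raises
    ------
    InfeasibleCorrectionError
        If the required reduction would make any delay negative (pulses
        too long for the requested spacing).
    """
    if train.idealized:
        return replace(train, time_corrected=True)

    red = _first_order_reductions(train)
    delays0 = np.array(train.delays, dtype=float)
    nu = train.null_spacing
    # largest admissible scale before a delay goes negative
    c_max = float(np.min(delays0 / red))
    if c_max <= 0:
        raise InfeasibleCorrectionError(
            "pulses too long for the requested null spacing"
        )

    def corrected(c: float) -> PulseTrain:
        new = delays0 - c * red
        if np.any(new < 0):
            raise InfeasibleCorrectionError(
                f"correction scale {c:.3f} drives a delay negative"
            )
        return replace(train, delays=tuple(new), time_corrected=True)

    def offset_error(c: float) -> float:
        return _null_position(corrected(c)) - nu

    # The null position is not monotone in the scale at low RF, so scan
    # for a sign-change bracket before root-finding.
    grid = np.linspace(0.0, min(c_max, 4.0), 33)
    errs = [offset_error(c) for c in grid]
    bracket = None
    for j in range(len(grid) - 1):
        if errs[j] == 0.0:
            bracket = (grid[j], grid[j])
            break
        if errs[j] * errs[j + 1] < 0:
            bracket = (grid[j], grid[j + 1])
            # keep scanning: prefer the last (stable, increasing) branch
    if bracket is None:
        raise InfeasibleCorrectionError(
            "no delay reduction within feasible range restores the null"
        )
    if bracket[0] == bracket[1]:
        c_star = bracket[0]
    else:
        from scipy.optimize import brentq

        c_star = brentq(offset_error, bracket[0], bracket[1], xtol=1e-6)
    result = corrected(float(c_star))
    # guard against spurious crossings of the (non-monotone) null-position
    # curve: the restored minimum must be a genuine null at the nominal
    # spacing, or the correction is declared infeasible
    from .simulate import _propagate

    null = _null_position(result)
    residual = float(np.abs(_propagate(result, np.array([null]))[1][0]))
    if abs(null - nu) > 0.02 * nu or residual > 0.05:
        raise InfeasibleCorrectionError(
            "no feasible delay reduction restores a clean null at "
            f"{nu:.0f} Hz (best: {null:.0f} Hz, residual |beta| {residual:.3f})"
        )
    return result


# ---------------------------------------------------------------------------
# serialization

def _pulse_to_dict(p: HardPulse) -> dict:
    return {"flip_angle": p.flip_angle, "phase": p.phase, "duration": p.duration}


def train_to_dict(train: PulseTrain) -> dict:
    return {
        "type": "pulse_train",
        "elements": [_pulse_to_dict(p) for p in train.elements],
        "delays": list(train.delays),
        "null_spacing": train.null_spacing,
        "time_corrected": train.time_corrected,
        "label": train.label,
    }


def train_from_dict(d: dict) -> PulseTrain:
    return PulseTrain(
        elements=tuple(HardPulse(**p) for p in d["elements"]),
        delays=tuple(d["delays"]),
        null_spacing=d["null_spacing"],
        time_corrected=d.get("time_corrected", False),
        label=d.get("label", ""),
    )


def shaped_to_dict(p: ShapedPulse) -> dict:
    return {
        "type": "shaped_pulse",
        "samples": [list(s) for s in p.samples],
        "total_duration": p.total_duration,
        "peak_rf": p.peak_rf,
        "label": p.label,
    }


def shaped_from_dict(d: dict) -> ShapedPulse:
    return ShapedPulse(
        samples=tuple((float(a), float(ph)) for a, ph in d["samples"]),
        total_duration=d["total_duration"],
        peak_rf=d["peak_rf"],
        label=d.get("label", "shaped"),
    )


def spec_to_dict(spec: SequenceSpec) -> dict:
    elem = spec.selective_element
    return {
        "selective_element": train_to_dict(elem)
        if isinstance(elem, PulseTrain)
        else shaped_to_dict(elem),
        "echo_count": spec.echo_count,
        "perfect_echo": spec.perfect_echo,
        "gradient_metadata": spec.gradient_metadata,
    }


def spec_from_dict(d: dict) -> SequenceSpec:
    ed = d["selective_element"]
    elem = (
        train_from_dict(ed) if ed.get("type") == "pulse_train" else shaped_from_dict(ed)
    )
    return SequenceSpec(
        selective_element=elem,
        echo_count=d.get("echo_count", 2),
        perfect_echo=d.get("perfect_echo", False),
        gradient_metadata=d.get("gradient_metadata", {}),
    )


def write_sequence_json(spec: SequenceSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec_to_dict(spec), indent=2))


def read_sequence_json(path: str | Path) -> SequenceSpec:
    return spec_from_dict(json.loads(Path(path).read_text()))


def read_shaped_pulse(
    path: str | Path,
    total_duration: float,
    peak_rf: float,
    label: str | None = None,
) -> ShapedPulse:
    """Read a shaped pulse from two-column (amplitude %, phase deg) text.

    Vendor-style shape files list relative amplitudes 0-100; they are
    rescaled to 0-1.  Lines starting with ``#`` or ``##`` are ignored.
    """
    rows = np.loadtxt(path, comments=["#", "##"], ndmin=2)
    if rows.shape[1] < 2:
        raise InvalidParameterError("shape file needs two columns (amp %, phase)")
    samples = tuple((float(a) / 100.0, float(ph)) for a, ph in rows[:, :2])
    return ShapedPulse(
        samples=samples,
        total_duration=total_duration,
        peak_rf=peak_rf,
        label=label or Path(path).stem,
    )
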