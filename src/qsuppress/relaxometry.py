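"""Inversion-recovery T1 and CPMG T2 fitting.

Models follow a statsmodels-like pattern: a model object is built from a
delay/intensity series (or a DataFrame), ``fit()`` returns a results
object carrying estimates, standard errors, diagnostics and a
``summary()`` table.

Inversion recovery uses the three-parameter model

    M(vd) = M0 * (1 - 2 * f * exp(-vd / T1))

where ``f`` is the inversion efficiency.  The third parameter matters in
suppression-embedded pseudo-2D schemes: the selective suppression block
after the excitation pulse, finite-pulse imperfections, or radiation
damping can leave the inversion partial (f < 1), and forcing f = 1 would
bias T1.  CPMG decays are fitted with ``M(t) = M0 * exp(-t / T2)``.

Fits are nonlinear least squares (lmfit / Levenberg-Marquardt) with
multi-start initialization over candidate time constants to avoid local
minima.  Signals inside the suppression band cannot be measured and must
be excluded upstream; these fitters see only one signal's series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model as LmModel

from .exceptions import FitFailureError, InvalidParameterError

__all__ = [
    "RelaxationSeries",
    "RelaxationResults",
    "InversionRecoveryModel",
    "CPMGModel",
    "fit_inversion_recovery",
    "fit_cpmg",
    "min_repetition_time",
]


@dataclass(frozen=True)
class RelaxationSeries:
    """A delay/intensity series for one signal.

    ``delays`` is the variable delay (s) for inversion recovery or the
    echo-train duration for CPMG; ``signal_label`` typically carries the
    chemical shift.
    """

    delays: tuple[float, ...]
    intensities: tuple[float, ...]
    signal_label: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, dtype=float)
        if d.size < 4:
            raise InvalidParameterError("need at least 4 points")
        if len(self.intensities) != d.size:
            raise InvalidParameterError("delays and intensities differ in length")
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise InvalidParameterError(
                "delays must be non-negative and strictly increasing"
            )

    @classmethod
    def from_arrays(cls, delays, intensities, signal_label=""):
        return cls(
            tuple(float(x) for x in delays),
            tuple(float(y) for y in intensities),
            signal_label,
        )


def _ir_model(vd, m0, f, t1):
    return m0 * (1.0 - 2.0 * f * np.exp(-vd / t1))


def _cpmg_model(t, m0, t2):
    return m0 * np.exp(-t / t2)


@dataclass
class RelaxationResults:
    """Estimates, uncertainties and diagnostics of a relaxation fit."""

    model_name: str
    params: dict[str, float]
    bse: dict[str, float]
    residual_norm: float
    nobs: int
    signal_label: str = ""
    diagnostics: list[str] = field(default_factory=list)

    @property
    def T_estimate(self) -> float:
        return self.params["t1"] if "t1" in self.params else self.params["t2"]

    @property
    def amplitude(self) -> float:
        return self.params["m0"]

    @property
    def inversion_efficiency(self) -> float | None:
        return self.params.get("f")

    def stderr(self, name: str) -> float:
        return self.bse[name]

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "signal": self.signal_label,
            "params": self.params,
            "stderr": self.bse,
            "residual_norm": self.residual_norm,
            "nobs": self.nobs,
            "diagnostics": self.diagnostics,
        }

    def summary(self) -> str:
        lines = [
            f"{self.model_name} fit" + (f" [{self.signal_label}]" if self.signal_label else ""),
            "=" * 46,
            f"{'parameter':<12}{'estimate':>14}{'std err':>14}",
            "-" * 46,
        ]
        for k, v in self.params.items():
            se = self.bse.get(k)
            se_s = f"{se:>14.5g}" if se is not None and np.isfinite(se) else f"{'--':>14}"
            lines.append(f"{k:<12}{v:>14.6g}{se_s}")
        lines.append("-" * 46)
        lines.append(f"n = {self.nobs}, residual norm = {self.residual_norm:.4g}")
        for d in self.diagnostics:
            lines.append(f"note: {d}")
        return "\n".join(lines)

    def plot(self, series: RelaxationSeries | None = None, ax=None):
        """Plot the fitted curve (and the data when a series is given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if series is not None:
            ax.plot(series.delays, series.intensities, "o", label="data")
            tmax = max(series.delays)
        else:
            tmax = 5 * self.T_estimate
        t = np.linspace(0, tmax, 300)
        if "f" in self.params:
            y = _ir_model(t, self.params["m0"], self.params["f"], self.params["t1"])
        else:
            y = _cpmg_model(t, self.params["m0"], self.params["t2"])
        ax.plot(t, y, "-", label="fit")
        ax.set_xlabel("delay (s)")
        ax.set_ylabel("intensity (a.u.)")
        ax.legend()
        return ax


class _SeriesModel:
    """Shared constructor plumbing for the relaxation models."""

    def __init__(self, series: RelaxationSeries):
        self.series = series
        self.delays = np.asarray(series.delays, dtype=float)
        self.intensities = np.asarray(series.intensities, dtype=float)

    @classmethod
    def from_arrays(cls, delays, intensities, signal_label=""):
        return cls(RelaxationSeries.from_arrays(delays, intensities, signal_label))

    @classmethod
    def from_dataframe(cls, df, delay_col="delay", intensity_col="intensity",
                       signal_label=""):
        return cls(
            RelaxationSeries.from_arrays(
                df[delay_col].to_numpy(), df[intensity_col].to_numpy(), signal_label
            )
        )


class InversionRecoveryModel(_SeriesModel):
    """Three-parameter inversion-recovery model for one signal's series."""

    def fit(self, fix_f: float | None = None) -> RelaxationResults:
        """Fit ``M0 (1 - 2 f exp(-vd/T1))`` by multi-start least squares.

        ``fix_f`` pins the inversion efficiency (e.g. 1.0 for the
        textbook two-parameter form).  Candidate T1 starting values come
        from the zero-crossing estimate (T1 ~ t_null / ln 2) plus a
        log-spaced ladder across the delay range; the best converged
        start wins.
        """
        vd, y = self.delays, self.intensities
        scale = float(np.max(np.abs(y))) or 1.0

        t1_starts = set()
        sign_change = np.flatnonzero(np.diff(np.signbit(y)))
        if sign_change.size:
            t_null = 0.5 * (vd[sign_change[0]] + vd[sign_change[0] + 1])
            if t_null > 0:
                t1_starts.add(t_null / np.log(2.0))
        lo = max(vd[1], 1e-6)
        t1_starts.update(np.geomspace(lo / 2, max(vd[-1], 2 * lo), 6))

        lm = LmModel(_ir_model, independent_vars=["vd"])
        best = None
        for t1_0 in sorted(t1_starts):
            p = lm.make_params(
                m0=dict(value=scale, min=0.0),
                f=dict(value=1.0 if fix_f is None else fix_f,
                       min=0.0, max=1.5, vary=fix_f is None),
                t1=dict(value=float(t1_0), min=1e-9),
            )
            try:
                res = lm.fit(y, p, vd=vd)
            except Exception:
                continue
            if not res.success:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise FitFailureError(
                "inversion-recovery fit did not converge from any start",
                {"n_starts": len(t1_starts), "signal": self.series.signal_label},
            )
        params = {k: float(best.params[k].value) for k in ("m0", "f", "t1")}
        bse = {
            k: (float(best.params[k].stderr)
                if best.params[k].stderr is not None else np.nan)
            for k in ("m0", "f", "t1")
        }
        diags = []
        if fix_f is None and params["f"] < 0.5:
            diags.append(
                f"partial inversion: fitted efficiency f = {params['f']:.3f} < 0.5"
            )
        if not sign_change.size and np.all(y > 0):
            diags.append("all intensities positive (no inversion zero-crossing)")
        return RelaxationResults(
            model_name="inversion-recovery",
            params=params,
            bse=bse,
            residual_norm=float(np.sqrt(best.chisqr)),
            nobs=int(vd.size),
            signal_label=self.series.signal_label,
            diagnostics=diags,
        )


class CPMGModel(_SeriesModel):
    """Monoexponential CPMG T2 decay model for one signal's series."""

    def fit(self) -> RelaxationResults:
        """Fit ``M0 exp(-t/T2)``, initialized from a log-linear regression."""
        t, y = self.delays, self.intensities
        if np.any(y <= 0):
            raise InvalidParameterError("CPMG intensities must be positive")
        slope, logm0 = np.polyfit(t, np.log(y), 1)
        if slope >= -1e-12:
            raise FitFailureError(
                "series does not decay: T2 is unbounded",
                {"log_slope": float(slope)},
            )
        lm = LmModel(_cpmg_model, independent_vars=["t"])
        p = lm.make_params(
            m0=dict(value=float(np.exp(logm0)), min=0.0),
            t2=dict(value=float(-1.0 / slope), min=1e-9),
        )
        res = lm.fit(y, p, t=t)
        if not res.success:
            raise FitFailureError("CPMG fit did not converge", res.message)
        params = {k: float(res.params[k].value) for k in ("m0", "t2")}
        bse = {
            k: (float(res.params[k].stderr)
                if res.params[k].stderr is not None else np.nan)
            for k in ("m0", "t2")
        }
        return RelaxationResults(
            model_name="CPMG",
            params=params,
            bse=bse,
            residual_norm=float(np.sqrt(res.chisqr)),
            nobs=int(t.size),
            signal_label=self.series.signal_label,
        )


def fit_inversion_recovery(
    series: RelaxationSeries, fix_f: float | None = None
) -> RelaxationResults:
    """Convenience wrapper: fit an inversion-recovery series."""
    return InversionRecoveryModel(series).fit(fix_f=fix_f)


def fit_cpmg(series: RelaxationSeries) -> RelaxationResults:
    """Convenience wrapper: fit a CPMG decay series."""
    return CPMGModel(series).fit()


def min_repetition_time(t1_values, factor: float = 10.0) -> float:
    """Minimum repetition time for quantitative work: factor x max(T1).

    The slowest-relaxing signal dictates the repetition time; the default
    factor of 10 keeps the residual saturation of a fully relaxed signal
    below 0.005%.
    """
    t1s = list(t1_values)
    if not t1s:
        raise InvalidParameterError("T1 list is empty")
    if any(t <= 0 for t in t1s):
        raise InvalidParameterError("all T1 values must be > 0")
    if factor <= 0:
        raise InvalidParameterError("factor must be > 0")
    return factor * max(t1s)
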