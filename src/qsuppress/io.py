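"""Readers and writers shared by all modules.

Formats are deliberately plain text: delimited two-column tables for
profiles and relaxation series, JCAMP-DX (AFFN, ``(X++(Y..Y))``) for
spectra, JSON for sequence specifications and reports, and a delimited
table for uncertainty-budget components.  The JCAMP writer emits
uncompressed AFFN data with unit factors so round-trips preserve values
to full printed precision; the reader handles the AFFN subset this
package writes plus ``(XY..XY)`` point lists.

Offset axes are Hz relative to the carrier; conversion to and from ppm
always requires an explicit spectrometer frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "Spectrum",
    "ppm_to_hz",
    "hz_to_ppm",
    "read_profile_table",
    "write_profile_table",
    "read_series_table",
    "write_series_table",
    "read_jcampdx",
    "write_jcampdx",
    "read_budget_components",
    "write_budget_components",
]


@dataclass
class Spectrum:
    """A 1D frequency-domain spectrum on a ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    sf_mhz: float
    label: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.size != self.intensity.size:
            raise InvalidParameterError("ppm and intensity differ in length")
        if self.sf_mhz <= 0:
            raise InvalidParameterError("spectrometer frequency must be > 0")

    def offsets_hz(self, reference_ppm: float) -> np.ndarray:
        """Offsets in Hz relative to a carrier position in ppm."""
        return (self.ppm - reference_ppm) * self.sf_mhz

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ppm, self.intensity, **kwargs)
        ax.set_xlabel("chemical shift (ppm)")
        ax.set_ylabel("intensity (a.u.)")
        ax.invert_xaxis()
        if self.label:
            ax.set_title(self.label)
        return ax


def ppm_to_hz(ppm, sf_mhz: float, reference_ppm: float = 0.0):
    """ppm to Hz offset from a reference, at spectrometer frequency sf (MHz)."""
    if sf_mhz <= 0:
        raise InvalidParameterError("spectrometer frequency must be > 0")
    return (np.asarray(ppm, dtype=float) - reference_ppm) * sf_mhz


def hz_to_ppm(hz, sf_mhz: float, reference_ppm: float = 0.0):
    """Hz offset from a reference to ppm, at spectrometer frequency sf (MHz)."""
    if sf_mhz <= 0:
        raise InvalidParameterError("spectrometer frequency must be > 0")
    return np.asarray(hz, dtype=float) / sf_mhz + reference_ppm


# ---------------------------------------------------------------------------
# profiles


def write_profile_table(profile, path: str | Path) -> None:
    """Two-column (offset Hz, retained fraction) with a comment header."""
    header = (
        f"sequence: {profile.sequence_label}\n"
        f"normalization: {profile.normalization}\n"
        f"npoints: {profile.offsets.size}\n"
        "columns: offset_hz retained_fraction"
    )
    np.savetxt(
        path,
        np.column_stack([profile.offsets, profile.retained_fraction]),
        header=header,
        fmt="%.12e",
    )


def read_profile_table(path: str | Path):
    """Read a profile table written by :func:`write_profile_table`
    (or any two-column offset/intensity text file)."""
    from .simulate import ExcitationProfile

    label, norm = "", "raw"
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if body.startswith("sequence:"):
                label = body.split(":", 1)[1].strip()
            elif body.startswith("normalization:"):
                norm = body.split(":", 1)[1].strip()
        else:
            break
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise InvalidParameterError("profile table needs two columns")
    order = np.argsort(data[:, 0])
    return ExcitationProfile(
        offsets=data[order, 0],
        retained_fraction=data[order, 1],
        normalization=norm,
        sequence_label=label,
    )


# ---------------------------------------------------------------------------
# relaxation series


def write_series_table(series, path: str | Path) -> None:
    header = f"signal: {series.signal_label}\ncolumns: delay_s intensity"
    np.savetxt(
        path,
        np.column_stack([series.delays, series.intensities]),
        header=header,
        fmt="%.12e",
    )


def read_series_table(path: str | Path):
    from .relaxometry import RelaxationSeries

    label = ""
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if body.startswith("signal:"):
                label = body.split(":", 1)[1].strip()
        else:
            break
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise InvalidParameterError("series table needs two columns")
    return RelaxationSeries.from_arrays(data[:, 0], data[:, 1], label)


# ---------------------------------------------------------------------------
# JCAMP-DX


def write_jcampdx(spectrum: Spectrum, path: str | Path, title: str | None = None) -> None:
    """Write a spectrum as uncompressed AFFN JCAMP-DX ``(X++(Y..Y))``.

    The ppm grid must be evenly spaced (generated spectra are).  Unit
    X/Y factors and 12-significant-digit AFFN values keep write/read
    round-trips lossless at working precision.
    """
    x, y = spectrum.ppm, spectrum.intensity
    if x.size < 2:
        raise InvalidParameterError("spectrum too short for JCAMP-DX")
    dx = np.diff(x)
    if not np.allclose(dx, dx[0], rtol=1e-9, atol=0):
        raise InvalidParameterError("JCAMP-DX (X++(Y..Y)) needs an even grid")
    lines = [
        f"##TITLE={title or spectrum.label or 'qsuppress spectrum'}",
        "##JCAMP-DX=5.00",
        "##DATA TYPE=NMR SPECTRUM",
        "##DATA CLASS=XYDATA",
        f"##OBSERVE FREQUENCY={float(spectrum.sf_mhz)!r}",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={float(x[0])!r}",
        f"##LASTX={float(x[-1])!r}",
        f"##NPOINTS={x.size}",
        f"##FIRSTY={float(y[0])!r}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 4
    for i in range(0, x.size, per_line):
        ys = " ".join(f"{v:.12e}" for v in y[i : i + per_line])
        lines.append(f"{x[i]:.12e} {ys}")
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read the AFFN JCAMP-DX subset written by :func:`write_jcampdx`
    (``(X++(Y..Y))``) plus simple ``(XY..XY)`` point lists."""
    meta: dict[str, str] = {}
    ydata: list[float] = []
    xydata: list[tuple[float, float]] = []
    mode = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            meta[key] = val.strip()
            if key == "XYDATA" and "X++" in val:
                mode = "xyy"
            elif key in ("XYDATA", "XYPOINTS", "PEAK TABLE") and "XY" in val:
                mode = "xy"
            elif key == "END":
                mode = None
            continue
        if mode == "xyy":
            vals = [float(t) for t in line.replace(",", " ").split()]
            ydata.extend(vals[1:])  # first token is the line's X value
        elif mode == "xy":
            toks = [float(t) for t in line.replace(";", " ").replace(",", " ").split()]
            xydata.extend(zip(toks[0::2], toks[1::2]))
    sf = float(meta.get("OBSERVE FREQUENCY", "0") or 0) or 1.0
    title = meta.get("TITLE", "")
    yfac = float(meta.get("YFACTOR", "1") or 1)
    xfac = float(meta.get("XFACTOR", "1") or 1)
    if ydata:
        n = int(meta["NPOINTS"])
        first = float(meta["FIRSTX"]) * xfac
        last = float(meta["LASTX"]) * xfac
        if len(ydata) != n:
            raise InvalidParameterError(
                f"JCAMP-DX NPOINTS={n} but {len(ydata)} Y values read"
            )
        x = np.linspace(first, last, n)
        y = np.asarray(ydata) * yfac
    elif xydata:
        arr = np.asarray(xydata, dtype=float)
        x = arr[:, 0] * xfac
        y = arr[:, 1] * yfac
    else:
        raise InvalidParameterError("no XYDATA block found in JCAMP-DX file")
    if x.size > 1 and x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return Spectrum(ppm=x, intensity=y, sf_mhz=sf, label=title)


# ---------------------------------------------------------------------------
# budget components


def write_budget_components(components, path: str | Path) -> None:
    """Delimited table: name, value %, distribution, applies_to."""
    df = pd.DataFrame(
        {
            "name": [c.name for c in components],
            "relative_std_uncertainty_percent": [
                c.relative_std_uncertainty for c in components
            ],
            "distribution": [c.distribution for c in components],
            "applies_to": [c.applies_to for c in components],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_budget_components(path: str | Path):
    from .budget import BudgetComponent

    df = pd.read_csv(path, sep="\t")
    required = {
        "name",
        "relative_std_uncertainty_percent",
        "distribution",
        "applies_to",
    }
    if not required.issubset(df.columns):
        raise InvalidParameterError(
            f"budget table must have columns {sorted(required)}"
        )
    return [
        BudgetComponent(
            name=row["name"],
            relative_std_uncertainty=float(row["relative_std_uncertainty_percent"]),
            distribution=row["distribution"],
            applies_to=row["applies_to"],
        )
        for _, row in df.iterrows()
    ]
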