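"""Photophysical calibration of the dual-activatable molecular rotor.

A fluorescent molecular rotor's emission grows with solvent viscosity
because viscous media restrict the intramolecular rotation that otherwise
quenches it non-radiatively.  The intensity–viscosity relation follows the
empirical Förster–Hoffmann power law

    log10(I_f) = c + x * log10(eta)

with intensity ``I_f`` (arbitrary units), viscosity ``eta`` (cP) and probe
constants ``x`` (slope) and ``c`` (intercept).  The same probe also responds
linearly to nitroreductase concentration over the assay's working range,
which yields a conventional 3-sigma limit of detection

    LOD = 3 * sigma / k

from the blank standard deviation ``sigma`` and calibration slope ``k``.

This module fits both laws by ordinary least squares, inverts the viscosity
law, and computes the LOD.  Logarithms are base 10 throughout, matching the
lg I vs lg eta convention of spectroscopic calibration plots.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EmissionSeries", "CalibrationFit", "LinearFit", "LodResult",
    "fit_forster_hoffmann", "invert_viscosity", "fit_titration",
    "blank_sigma", "compute_lod", "fold_enhancement",
    "read_emission_csv", "write_emission_csv",
]

SeriesKind = Literal["viscosity", "titration"]


@dataclass(frozen=True)
class EmissionSeries:
    """A set of (condition, intensity) pairs from a spectrometer.

    ``condition`` is viscosity in cP for ``kind="viscosity"`` or enzyme
    concentration in μg/mL for ``kind="titration"``; ``intensity`` is the
    emission intensity in arbitrary units at ``wavelength_nm``.
    """

    kind: SeriesKind
    points: tuple[tuple[float, float], ...]
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("viscosity", "titration"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        pts = tuple((float(c), float(i)) for c, i in self.points)
        object.__setattr__(self, "points", pts)
        if self.kind == "viscosity" and any(c <= 0 for c, _ in pts):
            raise ValueError("viscosity conditions must be strictly positive")
        if self.kind == "titration" and any(c < 0 for c, _ in pts):
            raise ValueError("titration concentrations must be non-negative")

    @property
    def conditions(self) -> np.ndarray:
        return np.array([c for c, _ in self.points], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.points], dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CalibrationFit:
    """Förster–Hoffmann fit: log10 I = intercept_c + slope_x * log10 eta."""

    slope_x: float
    intercept_c: float
    pearson_r: float
    n: int

    def predict_intensity(self, viscosity_cp: float | np.ndarray) -> np.ndarray:
        eta = np.asarray(viscosity_cp, dtype=float)
        if np.any(eta <= 0):
            raise ValueError("viscosity must be strictly positive")
        return 10.0 ** (self.intercept_c + self.slope_x * np.log10(eta))


@dataclass(frozen=True)
class LinearFit:
    """Linear titration fit: I = slope_k * concentration + intercept."""

    slope_k: float
    intercept: float
    pearson_r: float
    n: int

    def predict_intensity(self, conc: float | np.ndarray) -> np.ndarray:
        return self.slope_k * np.asarray(conc, dtype=float) + self.intercept


@dataclass(frozen=True)
class LodResult:
    """3σ/k detection limit, in both μg/mL and ng/mL views."""

    sigma: float
    slope_k: float
    lod_ug_per_ml: float
    lod_ng_per_ml: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.lod_ng_per_ml is None:
            object.__setattr__(self, "lod_ng_per_ml", 1000.0 * self.lod_ug_per_ml)

    def display_ng_per_ml(self) -> str:
        """Render the detection limit at the conventional 1-decimal precision."""
        return f"{self.lod_ng_per_ml:.1f}"


def fit_forster_hoffmann(series: EmissionSeries) -> CalibrationFit:
    """Fit log10 I = c + x log10 eta by ordinary least squares.

    Parameters
    ----------
    series
        A ``kind="viscosity"`` emission series with at least two points,
        all viscosities and intensities strictly positive.

    Returns
    -------
    CalibrationFit
        Slope ``x``, intercept ``c`` and the Pearson correlation of the
        log-log pairs.
    """
    if series.kind != "viscosity":
        raise ValueError("fit_forster_hoffmann requires a viscosity series")
    if len(series) < 2:
        raise ValueError("need at least 2 points to fit")
    eta = series.conditions
    inten = series.intensities
    if np.any(inten <= 0):
        raise ValueError("intensities must be strictly positive for log-log fit")
    x = np.log10(eta)
    y = np.log10(inten)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: zero variance in log viscosity")
    res = stats.linregress(x, y)
    # linregress reports r = 1 exactly for a perfect 2-point line; for
    # zero-variance y it returns r = 0, which is the correct degenerate value.
    return CalibrationFit(slope_x=float(res.slope), intercept_c=float(res.intercept),
                          pearson_r=float(res.rvalue), n=len(series))


def invert_viscosity(fit: CalibrationFit, intensity: float) -> float:
    """Viscosity (cP) implied by an intensity, inverting the power law."""
    if fit.slope_x == 0:
        raise ValueError("fit is non-invertible: slope is zero")
    if intensity <= 0:
        raise ValueError("intensity must be strictly positive")
    return float(10.0 ** ((np.log10(intensity) - fit.intercept_c) / fit.slope_x))


def fit_titration(series: EmissionSeries) -> LinearFit:
    """Fit I = k*conc + b by ordinary least squares on the linear scale."""
    if series.kind != "titration":
        raise ValueError("fit_titration requires a titration series")
    if len(series) < 2:
        raise ValueError("need at least 2 points to fit")
    x = series.conditions
    y = series.intensities
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: zero variance in concentration")
    res = stats.linregress(x, y)
    return LinearFit(slope_k=float(res.slope), intercept=float(res.intercept),
                     pearson_r=float(res.rvalue), n=len(series))


def blank_sigma(blanks: Sequence[float]) -> float:
    """Sample standard deviation (n−1 denominator) of blank replicates."""
    arr = np.asarray(list(blanks), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 blank values")
    return float(np.std(arr, ddof=1))


def compute_lod(slope_k: float, sigma: float) -> LodResult:
    """Limit of detection LOD = 3σ/k on the concentration axis of the fit.

    ``slope_k`` must be positive (intensity per μg/mL); ``sigma`` is the
    blank (or residual) standard deviation in intensity units.  The result
    carries both μg/mL and ng/mL views; rounding happens only at display.
    """
    if slope_k <= 0:
        raise ValueError("slope_k must be strictly positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    lod = 3.0 * sigma / slope_k
    return LodResult(sigma=float(sigma), slope_k=float(slope_k), lod_ug_per_ml=float(lod))


def fold_enhancement(series: EmissionSeries) -> float:
    """Intensity ratio between the most and least viscous conditions.

    For an ethanol→glycerol series this is the probe's viscosity contrast
    (about 18-fold for the rotor modelled here).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 points")
    cond = series.conditions
    inten = series.intensities
    lo = inten[int(np.argmin(cond))]
    hi = inten[int(np.argmax(cond))]
    if lo == 0:
        raise ValueError("zero intensity at the minimum condition")
    return float(hi / lo)


# ---------------------------------------------------------------------------
# CSV round-trip: two columns (condition, intensity) preceded by one metadata
# comment line carrying the series kind and wavelength.

def write_emission_csv(series: EmissionSeries, path: str | Path) -> None:
    path = Path(path)
    buf = io.StringIO()
    wl = "" if series.wavelength_nm is None else f" wavelength_nm={series.wavelength_nm:g}"
    buf.write(f"# kind={series.kind}{wl}\n")
    buf.write("condition,intensity\n")
    for c, i in series.points:
        buf.write(f"{c!r},{i!r}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_emission_csv(path: str | Path) -> EmissionSeries:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing metadata header line")
    meta: dict[str, str] = {}
    for tok in lines[0].lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    kind = meta.get("kind")
    if kind not in ("viscosity", "titration"):
        raise ValueError(f"{path}: unknown or missing series kind {kind!r}")
    wl = float(meta["wavelength_nm"]) if "wavelength_nm" in meta else None
    points = []
    for ln in lines[2:]:
        if not ln.strip():
            continue
        c, i = ln.split(",")
        points.append((float(c), float(i)))
    return EmissionSeries(kind=kind, points=tuple(points), wavelength_nm=wl)
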