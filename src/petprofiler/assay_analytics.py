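"""Quantitative reductions of PET-hydrolase assay data.

Covers the standard measurements around an enzymatic PET-depolymerization
campaign:

* **Tm from thermal-shift curves** — the melting temperature is read as the
  maximum of the first derivative of the dye-fluorescence melt curve
  (25-99 degC scans are typical), with light smoothing and parabolic sub-grid
  refinement of the peak.
* **DSC crystallinity** — crystallinity(%) = (dHm - dHc) / dHf * 100, with
  dHf = 140.1 J/g the fusion enthalpy of fully crystalline PET.
* **HPLC calibration/quantification** — per-analyte straight-line standard
  curves (TPA, MHET, BHET) and sample concentrations with a dilution factor.
* **Depolymerization extent** — released TPA + MHET moles (optionally BHET)
  converted to the mass fraction of the PET charge via the 192.17 g/mol
  repeat-unit mass.
* **pH-stat accounting** — cumulative NaOH volume times molarity gives acid
  equivalents; each released TPA carries 2 carboxyl groups, MHET 1, BHET 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "MeltCurve", "TmEstimate", "DSCRecord", "ProductTimeCourse",
    "TitrationTrace", "fit_tm", "crystallinity", "calibrate_and_quantify",
    "depolymerization_extent", "base_to_acid_equivalents",
    "expected_acid_equivalents", "AmbiguousPeakError",
    "PET_REPEAT_UNIT_MASS", "FULLY_CRYSTALLINE_PET_DHF",
]

#: one TPA-ethylene-glycol ester repeat unit (g/mol) — the PET mass released
#: per mole of aromatic product
PET_REPEAT_UNIT_MASS = 192.17

#: fusion enthalpy of fully crystalline PET (J/g)
FULLY_CRYSTALLINE_PET_DHF = 140.1

#: carboxyl groups released per product molecule at the pH-stat setpoint
CARBOXYLS_PER_PRODUCT = {"TPA": 2, "MHET": 1, "BHET": 0}


class AmbiguousPeakError(ValueError):
    """The derivative of a melt curve has no unambiguous maximum."""


@dataclass
class MeltCurve:
    """A thermal-shift fluorescence melt curve on a strictly increasing grid."""

    temperatures: np.ndarray   # degC
    signal: np.ndarray         # arbitrary fluorescence units

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures.shape != self.signal.shape or self.temperatures.ndim != 1:
            raise ValueError("temperatures and signal must be matching 1-D arrays")
        if len(self.temperatures) < 5:
            raise ValueError("melt curve needs at least 5 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


@dataclass
class TmEstimate:
    tm: float                    # degC
    derivative_peak_value: float  # signal per degC
    window: int                   # smoothing width used (points)


@dataclass
class DSCRecord:
    """DSC enthalpies (J/g): fusion dHm, cold crystallization dHc, and the
    fully-crystalline reference dHf."""

    dHm: float
    dHc: float
    dHf: float = FULLY_CRYSTALLINE_PET_DHF

    def __post_init__(self) -> None:
        if self.dHf <= 0:
            raise ValueError("dHf must be positive")
        if self.dHm < 0 or self.dHc < 0:
            raise ValueError("enthalpies must be nonnegative")


@dataclass
class ProductTimeCourse:
    """Moles of soluble hydrolysis products over time for one reaction."""

    times: np.ndarray            # hours
    tpa: np.ndarray              # mol
    mhet: np.ndarray             # mol
    bhet: np.ndarray             # mol
    volume: float                # L
    pet_load: float              # g

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("times", "tpa", "mhet", "bhet"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arrays[name])
        n = len(arrays["times"])
        if any(len(a) != n for a in arrays.values()):
            raise ValueError("time and product arrays must have equal length")
        if np.any(np.diff(arrays["times"]) < 0):
            raise ValueError("times must be nondecreasing")
        for name in ("tpa", "mhet", "bhet"):
            if np.any(arrays[name] < 0):
                raise ValueError(f"{name} amounts must be nonnegative")
        if self.pet_load <= 0:
            raise ValueError("pet_load must be positive")


@dataclass
class TitrationTrace:
    """Cumulative titrant volume over time for a pH-stat reactor."""

    times: np.ndarray            # hours
    cumulative_volume: np.ndarray  # L
    molarity: float = 0.3575     # mol/L, concentrated NaOH feed

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_volume = np.asarray(self.cumulative_volume, dtype=float)
        if self.times.shape != self.cumulative_volume.shape:
            raise ValueError("times and volumes must have equal length")
        if np.any(np.diff(self.cumulative_volume) < 0):
            raise ValueError("cumulative titrant volume must be nondecreasing")
        if self.molarity <= 0:
            raise ValueError("titrant molarity must be positive")


def fit_tm(curve: MeltCurve, window: int = 5) -> TmEstimate:
    """Melting temperature from the first-derivative maximum of a melt curve.

    The signal is smoothed by a centered moving average (``window`` points,
    odd), differentiated by central differences on the temperature grid, and
    the derivative maximum — excluding the outermost ``window // 2`` points,
    where the moving average is truncated — is refined to sub-grid precision
    by a parabola through the peak and its neighbours.

    Raises :class:`AmbiguousPeakError` when the derivative has no peak that
    stands above the noise floor (flat or purely linear signals).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    t = curve.temperatures
    y = curve.signal
    if window > len(t):
        raise ValueError("window exceeds curve length")

    half = window // 2
    smooth = uniform_filter1d(y, size=window, mode="nearest")

    deriv = np.gradient(smooth, t)

    lo, hi = half, len(t) - half
    inner = deriv[lo:hi]
    spread = inner.max() - np.median(inner)
    noise = 1.4826 * np.median(np.abs(inner - np.median(inner)))
    if spread <= max(1e-12, 3.0 * noise) or inner.max() - inner.min() <= 1e-12:
        raise AmbiguousPeakError("no unambiguous derivative maximum (flat curve?)")

    ipk = lo + int(np.argmax(inner))
    tm = t[ipk]
    peak = deriv[ipk]
    if 0 < ipk < len(t) - 1:
        y0, y1, y2 = deriv[ipk - 1], deriv[ipk], deriv[ipk + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # proper maximum
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            # local grid spacing (uniform grids expected, but be safe)
            step = (t[ipk + 1] - t[ipk - 1]) / 2.0
            tm = t[ipk] + delta * step
            peak = y1 - 0.25 * (y0 - y2) * delta
    if not (t[0] < tm < t[-1]):
        raise AmbiguousPeakError("derivative maximum at the scan boundary")
    return TmEstimate(tm=float(tm), derivative_peak_value=float(peak), window=window)


def crystallinity(r: DSCRecord) -> float:
    """Percent crystallinity from DSC enthalpies: (dHm - dHc)/dHf * 100.

    A negative value (cold crystallization exceeding fusion) is physically
    odd but reported as-is, with a warning.
    """
    value = (r.dHm - r.dHc) / r.dHf * 100.0
    if value < 0:
        warnings.warn("crystallinity is negative (dHc > dHm); reporting as-is",
                      stacklevel=2)
    return value


def calibrate_and_quantify(
    standards: Mapping[str, Sequence[tuple[float, float]]],
    samples: Mapping[str, Sequence[float] | float],
    dilution_factor: float = 1.0,
) -> dict[str, np.ndarray]:
    """Concentrations from peak areas via per-analyte standard curves.

    ``standards[analyte]`` is a list of ``(known_concentration, peak_area)``
    points (at least two, distinct concentrations); an ordinary least-squares
    line with intercept is fitted per analyte and sample concentrations are
    ``(area - intercept) / slope * dilution_factor``. Negative estimates are
    clipped to zero with a warning.
    """
    out: dict[str, np.ndarray] = {}
    for analyte, pts in standards.items():
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise ValueError(f"{analyte}: need at least 2 standards")
        conc, area = pts[:, 0], pts[:, 1]
        if np.unique(conc).size < 2:
            raise ValueError(f"{analyte}: standard concentrations must be distinct")
        slope, intercept = np.polyfit(conc, area, 1)
        if abs(slope) < 1e-300 or np.ptp(area) == 0:
            raise ValueError(f"{analyte}: singular calibration (flat response)")
        if analyte not in samples:
            continue
        areas = np.atleast_1d(np.asarray(samples[analyte], dtype=float))
        est = (areas - intercept) / slope * dilution_factor
        if np.any(est < 0):
            warnings.warn(f"{analyte}: negative concentration estimate clipped to 0",
                          stacklevel=2)
            est = np.clip(est, 0.0, None)
        out[analyte] = est
    return out


def depolymerization_extent(
    tc: ProductTimeCourse,
    include_bhet: bool = False,
) -> np.ndarray:
    """Percent of the PET charge depolymerized at each time point.

    extent(t) = 100 * (mol TPA + mol MHET [+ mol BHET]) * M_unit / pet_load
    with M_unit = 192.17 g/mol per released aromatic unit. By convention the
    extent counts TPA and MHET (the terminal soluble hydrolysis products);
    BHET is included only on request. Values above 100 % are reported as-is
    with a warning (calibration or weighing error upstream).
    """
    total = tc.tpa + tc.mhet + (tc.bhet if include_bhet else 0.0)
    extent = 100.0 * total * PET_REPEAT_UNIT_MASS / tc.pet_load
    if np.any(extent > 100.0 + 1e-9):
        warnings.warn("depolymerization extent exceeds 100%", stacklevel=2)
    return extent


def base_to_acid_equivalents(tt: TitrationTrace) -> np.ndarray:
    """Moles of acid equivalents neutralized at each time point."""
    return tt.molarity * tt.cumulative_volume


def expected_acid_equivalents(
    tpa: float | np.ndarray,
    mhet: float | np.ndarray,
    bhet: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Acid equivalents implied by product amounts (mol): TPA 2, MHET 1, BHET 0."""
    return (CARBOXYLS_PER_PRODUCT["TPA"] * np.asarray(tpa, dtype=float)
            + CARBOXYLS_PER_PRODUCT["MHET"] * np.asarray(mhet, dtype=float)
            + CARBOXYLS_PER_PRODUCT["BHET"] * np.asarray(bhet, dtype=float))
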