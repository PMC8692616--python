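"""Per-modality pre-treatment of measurement curves.

The recipes mirror standard chemometric practice for the six modalities:

* NMR / FT-IR profiles: cubic-spline axis alignment, third-order polynomial
  Savitzky-Golay second differentiation, truncation to the informative window
  (or exclusion of ATR-crystal interference regions), then total-area
  normalization.
* DTG curves: 1 degC binning over 44-497 degC, division by sample weight
  (giving %/min), then Savitzky-Golay second differentiation.
* TD-NMR decays: normalization by the fitted model amplitude at t = 0.

Order matters and is recorded in each spectrum's lineage:
differentiate -> truncate/exclude -> normalize for NMR/FT-IR, and
bin(1 degC) -> weight-normalize -> differentiate for DTG.
"""

from __future__ import annotations

from typing import Sequence, TYPE_CHECKING

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .spectra import AGGREGATE_REPLICATE, Spectrum

if TYPE_CHECKING:  # pragma: no cover
    from .deconv import TDFit

#: Truncation windows keeping the informative spectral regions, per modality.
TRUNCATION_WINDOWS = {
    "h1_wideline": (-102.0, 102.0),   # ppm
    "h1_mas": (-8.0, 14.2),           # ppm
    "c13_cpmas": (2.8, 185.2),        # ppm
}

#: ATR diamond-crystal interference regions excluded from FT-IR spectra (cm-1).
FTIR_EXCLUDED_REGIONS = ((1711.0, 2669.0), (3400.0, 4000.0))

#: DTG working range (degC) and bin width for the 1-degree pre-binning.
DTG_RANGE = (44.0, 497.0)

#: Default Savitzky-Golay window (points); polynomial order is fixed at 3.
DEFAULT_SG_WINDOW = 11


def interpolate_to_axis(spectrum: Spectrum, target_axis) -> Spectrum:
    """Cubic-spline resampling onto ``target_axis`` (no extrapolation)."""
    sp = spectrum.ascending()
    target = np.asarray(target_axis, dtype=float)
    if sp.n_points < 4:
        raise ValueError("need at least 4 points for cubic interpolation")
    if target.min() < sp.axis[0] or target.max() > sp.axis[-1]:
        raise ValueError("target axis extends beyond the measured span")
    spline = CubicSpline(sp.axis, sp.intensity)
    return sp.evolve("cubic_spline_align", axis=target,
                     intensity=spline(target))


def sg_second_derivative(spectrum: Spectrum,
                         window_pts: int = DEFAULT_SG_WINDOW) -> Spectrum:
    """Savitzky-Golay second derivative (polynomial order 3).

    The derivative is taken with respect to the axis units (the uniform axis
    step is honored).  The ``(window_pts - 1) / 2`` points at each edge are
    dropped: the polynomial edge fits are artifact-prone and would otherwise
    feed into edge bins downstream.
    """
    if window_pts % 2 == 0 or window_pts < 5:
        raise ValueError("window_pts must be odd and >= 5")
    sp = spectrum.ascending()
    if window_pts >= sp.n_points:
        raise ValueError("window_pts must be smaller than the axis length")
    steps = np.diff(sp.axis)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
        raise ValueError("Savitzky-Golay differentiation needs a uniform axis")
    deriv = savgol_filter(sp.intensity, window_pts, polyorder=3, deriv=2,
                          delta=float(steps[0]))
    half = (window_pts - 1) // 2
    return sp.evolve(f"sg2der(w={window_pts})",
                     axis=sp.axis[half:-half].copy(),
                     intensity=deriv[half:-half],
                     derivative_order=2)


def truncate(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep only points with ``lo <= axis <= hi``."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    sp = spectrum.ascending()
    mask = (sp.axis >= lo) & (sp.axis <= hi)
    if not mask.any():
        raise ValueError(f"truncation to [{lo}, {hi}] leaves no points")
    return sp.evolve(f"truncate({lo},{hi})", axis=sp.axis[mask],
                     intensity=sp.intensity[mask])


def exclude_regions(spectrum: Spectrum,
                    regions: Sequence[tuple[float, float]]) -> Spectrum:
    """Remove points falling inside any (lo, hi) region (gaps allowed)."""
    sp = spectrum.ascending()
    if not regions:
        return sp
    mask = np.ones(sp.n_points, dtype=bool)
    for lo, hi in regions:
        if not lo < hi:
            raise ValueError(f"malformed region ({lo}, {hi})")
        mask &= ~((sp.axis >= lo) & (sp.axis <= hi))
    if not mask.any():
        raise ValueError("exclusion regions removed every point")
    token = "exclude(" + ";".join(f"{lo}-{hi}" for lo, hi in regions) + ")"
    return sp.evolve(token, axis=sp.axis[mask], intensity=sp.intensity[mask])


def _abs_trapz_area(axis: np.ndarray, intensity: np.ndarray) -> float:
    return float(np.trapezoid(np.abs(intensity), axis))


def normalize_total_area(spectrum: Spectrum, signed: bool = False) -> Spectrum:
    """Scale so the total trapezoidal area equals one.

    By default the absolute-value area is used: second-derivative profiles
    are signed and their signed area is ~0, which would be ill-conditioned.
    ``signed=True`` preserves the plain-integral alternative for
    nonnegative profiles.
    """
    sp = spectrum.ascending()
    if signed:
        area = float(np.trapezoid(sp.intensity, sp.axis))
    else:
        area = _abs_trapz_area(sp.axis, sp.intensity)
    if area <= 0.0 or not np.isfinite(area):
        raise ValueError("cannot area-normalize a zero-area spectrum")
    return sp.evolve("normalize_area" + ("(signed)" if signed else ""),
                     intensity=sp.intensity / area)


def subtract_baseline(spectrum: Spectrum, degree: int = 2) -> Spectrum:
    """Optional low-order polynomial baseline subtraction (off by default
    in the pipeline: instrument-corrected or synthetic profiles are
    baseline-clean).

    The baseline is the least-squares polynomial of the given degree
    (<= 2) fitted to the whole profile.
    """
    if not 0 <= degree <= 2:
        raise ValueError("baseline degree must be 0, 1 or 2")
    sp = spectrum.ascending()
    coefs = np.polynomial.polynomial.polyfit(sp.axis, sp.intensity, degree)
    baseline = np.polynomial.polynomial.polyval(sp.axis, coefs)
    return sp.evolve(f"baseline(deg={degree})",
                     intensity=sp.intensity - baseline)


def dtg_prepare(spectrum: Spectrum) -> Spectrum:
    """1-degC binning over 44-497 degC plus sample-weight normalization.

    Bins are left-closed, ``[T, T+1)`` for integer T = 44..497 (454 bins,
    labeled by their left edge); the bin value is the mean raw intensity of
    the points falling in the bin.  Intensities (g/min) are divided by the
    sample weight (mg, converted to g) and multiplied by 100, yielding %/min.
    """
    if spectrum.modality != "dtg":
        raise ValueError("dtg_prepare expects a DTG curve")
    if spectrum.sample_weight is None or spectrum.sample_weight <= 0:
        raise ValueError("DTG weight normalization needs a sample weight")
    sp = spectrum.ascending()
    lo, hi = DTG_RANGE
    if sp.axis[0] > lo or sp.axis[-1] < hi:
        raise ValueError(f"DTG axis must cover [{lo}, {hi}] degC")
    edges = np.arange(lo, hi + 2.0)          # 44, 45, ..., 498
    idx = np.digitize(sp.axis, edges) - 1    # left-closed bins
    valid = (idx >= 0) & (idx < edges.size - 1)
    counts = np.bincount(idx[valid], minlength=edges.size - 1)
    if (counts == 0).any():
        raise ValueError("raw DTG sampling too coarse for 1 degC bins")
    sums = np.bincount(idx[valid], weights=sp.intensity[valid],
                       minlength=edges.size - 1)
    weight_g = spectrum.sample_weight / 1000.0
    return sp.evolve("dtg_bin1C+weight_norm",
                     axis=edges[:-1].copy(),
                     intensity=100.0 * (sums / counts) / weight_g)


def td_normalize(decay: Spectrum, fit: "TDFit") -> Spectrum:
    """Normalize a TD-NMR decay by the fitted model amplitude at t = 0.

    Every component shape equals one at the origin, so the model value at
    t = 0 is the sum of the fitted component amplitudes.
    """
    if decay.modality != "tdnmr":
        raise ValueError("td_normalize expects a TD-NMR decay")
    total = fit.total_amplitude
    if total <= 0:
        raise ValueError("fitted amplitude sum is zero; cannot normalize")
    return decay.evolve("td_normalize", intensity=decay.intensity / total)


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate curves from one sample (shared axis)."""
    if not spectra:
        raise ValueError("no spectra to average")
    first = spectra[0]
    for sp in spectra[1:]:
        if sp.modality != first.modality or sp.sample_id != first.sample_id:
            raise ValueError("replicates must share modality and sample")
        if sp.axis.shape != first.axis.shape or not np.allclose(
                sp.axis, first.axis, rtol=0.0, atol=1e-9):
            raise ValueError("replicate axes differ; align them first")
    mean = np.mean([sp.intensity for sp in spectra], axis=0)
    return first.evolve(f"avg_replicates(n={len(spectra)})",
                        intensity=mean, replicate=AGGREGATE_REPLICATE)
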