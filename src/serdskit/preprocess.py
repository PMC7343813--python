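"""Spectrum-level corrections applied before SERDS subtraction.

Cosmic-spike removal, pixel-to-wavenumber calibration against a reference
substance, white-light intensity calibration, and SNIP baseline estimation
(decreasing-window variant with the log-log-square-root compression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.ndimage import uniform_filter1d

__all__ = [
    "CalibrationError",
    "CalibrationModel",
    "SnipParams",
    "ACETAMINOPHEN_SHIFTS_CM1",
    "remove_cosmic_spikes",
    "fit_wavelength_calibration",
    "calibrate_intensity",
    "snip_baseline",
    "snip_correct",
]

# 4-acetaminophen (paracetamol) Raman shift standard (ASTM E1840 class
# values, cm^-1) -- the usual wavelength-calibration reference around 785 nm.
# Any user-supplied peak table is equally accepted by the calibration fit.
ACETAMINOPHEN_SHIFTS_CM1 = (
    329.2, 390.9, 465.1, 504.0, 651.6, 710.8, 797.2, 834.5, 857.9,
    968.7, 1105.5, 1168.5, 1236.8, 1278.5, 1323.9, 1371.5, 1561.5,
    1648.4, 2931.1, 3064.6,
)


class CalibrationError(ValueError):
    pass


def _values_of(spectrum):
    """Accept a spectrum object (``.values``) or a bare array."""
    if hasattr(spectrum, "values") and not isinstance(spectrum, np.ndarray):
        return np.asarray(spectrum.values, dtype=float), spectrum
    return np.asarray(spectrum, dtype=float), None


def _rebuild(template, values: np.ndarray):
    if template is None:
        return values
    if hasattr(template, "with_intensity"):
        return template.with_intensity(values)
    return template.with_value(values)


# ---------------------------------------------------------------------------
# Cosmic spikes


def remove_cosmic_spikes(spectrum, z_threshold: float = 8.0):
    """Flag and repair single-pixel cosmic spikes.

    The detector is the modified z-score of the (negated) second difference
    D_i = 2 y_i - y_{i-1} - y_{i+1}, which is large and positive at a
    spike and negative at its neighbours; flagging is one-sided
    (z > z_threshold) so spike neighbours are not dragged in.  Flagged
    pixels are replaced by the median of a 5-pixel neighbourhood that
    excludes other flagged pixels.  Returns (corrected spectrum, list of
    corrected pixel indices).  A zero-variance spectrum yields no flags.
    """
    y, template = _values_of(spectrum)
    n = y.size
    if n < 5:
        raise ValueError("spectrum must have at least 5 points")
    d = np.zeros(n)
    d[1:-1] = 2.0 * y[1:-1] - y[:-2] - y[2:]
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0.0:
        # degenerate scale (constant curvature); fall back to the mean
        # absolute deviation so an isolated spike is still detectable
        mad = np.mean(np.abs(d - med)) * 1.4826 * 0.6745
        if mad == 0.0:
            return _rebuild(template, y.copy()), []
    z = 0.6745 * (d - med) / mad
    flagged = np.flatnonzero(z > z_threshold)
    if flagged.size == 0:
        return _rebuild(template, y.copy()), []
    flagged_set = set(int(i) for i in flagged)
    out = y.copy()
    for i in sorted(flagged_set):
        for half in (2, 4, 8):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            neighbours = [y[j] for j in range(lo, hi) if j not in flagged_set]
            if neighbours:
                out[i] = float(np.median(neighbours))
                break
    return _rebuild(template, out), sorted(flagged_set)


# ---------------------------------------------------------------------------
# Wavelength calibration


@dataclass
class CalibrationModel:
    """Pixel -> Raman shift polynomial fitted on reference peaks."""

    coefficients: np.ndarray  # ascending powers
    residuals_cm1: np.ndarray
    reference: str = "4-acetaminophen"

    @property
    def max_abs_residual_cm1(self) -> float:
        return float(np.max(np.abs(self.residuals_cm1)))

    def apply(self, pixels) -> np.ndarray:
        return npoly.polyval(np.asarray(pixels, dtype=float), self.coefficients)


def fit_wavelength_calibration(observed_peak_pixels: Sequence[float],
                               reference_shifts_cm1: Sequence[float],
                               degree: int = 2,
                               reference: str = "4-acetaminophen") -> CalibrationModel:
    """Least-squares pixel->shift polynomial from reference-peak positions.

    Requires at least degree+1 peaks and a strictly monotone fitted mapping
    over the observed pixel span (a non-monotone fit would fold the axis).
    """
    px = np.asarray(observed_peak_pixels, dtype=float)
    ref = np.asarray(reference_shifts_cm1, dtype=float)
    if degree not in (1, 2, 3):
        raise CalibrationError(f"degree must be 1, 2 or 3, got {degree}")
    if px.size != ref.size:
        raise CalibrationError("pixel and reference lists differ in length")
    if px.size < degree + 1:
        raise CalibrationError(
            f"need at least {degree + 1} peaks for degree {degree}, got {px.size}")
    coeffs = npoly.polyfit(px, ref, degree)
    dense = np.linspace(px.min(), px.max(), max(512, px.size * 16))
    deriv = npoly.polyval(dense, npoly.polyder(coeffs))
    if np.any(deriv <= 0):
        raise CalibrationError("fitted pixel->shift mapping is not strictly increasing")
    residuals = npoly.polyval(px, coeffs) - ref
    return CalibrationModel(coefficients=coeffs, residuals_cm1=residuals, reference=reference)


# ---------------------------------------------------------------------------
# Intensity calibration


def calibrate_intensity(spectrum, measured_white_light, known_lamp_emission,
                        smoothing_halfwidth: int = 7):
    """Correct the detector/system spectral response with a white-light lamp.

    The gain is known_lamp_emission / smoothed(measured_white_light),
    normalized to unit mean so only the spectral shape of the response is
    corrected, not the absolute scale.  Commutes with positive scaling of
    the spectrum.
    """
    y, template = _values_of(spectrum)
    white = np.asarray(measured_white_light, dtype=float)
    lamp = np.asarray(known_lamp_emission, dtype=float)
    if white.shape != y.shape or lamp.shape != y.shape:
        raise ValueError("white-light and lamp arrays must match the spectrum's axis")
    if np.any(white <= 0):
        bad = int(np.flatnonzero(white <= 0)[0])
        raise ValueError(f"non-positive white-light intensity at pixel {bad}")
    smooth = uniform_filter1d(white, size=2 * smoothing_halfwidth + 1, mode="nearest")
    gain = lamp / smooth
    gain = gain / gain.mean()
    return _rebuild(template, y * gain)


# ---------------------------------------------------------------------------
# SNIP baseline


@dataclass
class SnipParams:
    """Decreasing-window SNIP settings.

    ``m`` is the maximal clipping half-width in pixels; iterations run with
    window m, m-1, ..., 1.  m should exceed the half-width of the widest
    Raman band (default 24 px on the default 1024-point grid) so bands are
    clipped away while the broad background survives.  ``split_at_cm1``
    optionally runs the estimate separately below/above a wavenumber (e.g.
    to decouple fingerprint and CH-stretch regions).
    """

    m: int = 24
    use_lls_transform: bool = True
    split_at_cm1: Optional[float] = None

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("SNIP half-width m must be >= 1")


def _lls(y: np.ndarray) -> np.ndarray:
    return np.log(np.log(np.sqrt(y + 1.0) + 1.0) + 1.0)


def _inv_lls(v: np.ndarray) -> np.ndarray:
    return (np.exp(np.exp(v) - 1.0) - 1.0) ** 2 - 1.0


def _snip_1d(y: np.ndarray, m: int, use_lls: bool) -> np.ndarray:
    if use_lls:
        if np.any(y < 0):
            warnings.warn("negative intensities clipped to 0 for the LLS transform")
            y = np.maximum(y, 0.0)
        v = _lls(y)
    else:
        v = y.copy()
    n = v.size
    for w in range(min(m, (n - 1) // 2), 0, -1):
        clipped = 0.5 * (v[: n - 2 * w] + v[2 * w:])
        v[w: n - w] = np.minimum(v[w: n - w], clipped)
    baseline = _inv_lls(v) if use_lls else v
    return np.minimum(baseline, y if not use_lls else np.maximum(np.asarray(y, dtype=float), 0.0))


def snip_baseline(spectrum, params: Optional[SnipParams] = None) -> np.ndarray:
    """SNIP baseline estimate (array on the spectrum's axis).

    Iterative peak clipping y_i <- min(y_i, (y_{i-w} + y_{i+w})/2) with the
    window decreasing from params.m to 1, in log-log-sqrt space when
    enabled.  The estimate never exceeds the input; the background-corrected
    spectrum is input - baseline.
    """
    params = SnipParams() if params is None else params
    y, template = _values_of(spectrum)
    if params.split_at_cm1 is not None and template is not None:
        axis = template.axis
        left = axis < params.split_at_cm1
        baseline = np.empty_like(y)
        for mask in (left, ~left):
            if mask.sum() >= 3:
                baseline[mask] = _snip_1d(y[mask].copy(), params.m, params.use_lls_transform)
            else:
                baseline[mask] = y[mask]
        return baseline
    return _snip_1d(y.copy(), params.m, params.use_lls_transform)


def snip_correct(spectrum, params: Optional[SnipParams] = None):
    """Background-corrected spectrum: input minus its SNIP baseline."""
    y, template = _values_of(spectrum)
    baseline = snip_baseline(spectrum, params)
    return _rebuild(template, y - baseline)
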