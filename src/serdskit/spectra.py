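"""Domain types and axis conversions for SERDS spectra.

All calibrated spectra live on a Raman-shift axis referenced to 785 nm
excitation, regardless of the wavelength actually used for the acquisition.
On that common axis the Raman bands of the 784 nm and 786 nm acquisitions
appear displaced against each other (by roughly 16 cm^-1 per nm of
excitation offset) while wavelength-fixed contributions -- fluorescence,
ambient light, detector etaloning -- stay put.  That displacement is what
makes pixel-wise subtraction of a shifted-excitation pair meaningful.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

REFERENCE_EXCITATION_NM = 785.0

__all__ = [
    "REFERENCE_EXCITATION_NM",
    "RawSpectrum",
    "CalibratedSpectrum",
    "DifferenceSpectrum",
    "SpectrumCollection",
    "wavelength_to_raman_shift",
    "raman_shift_to_wavelength",
    "resample",
]


def wavelength_to_raman_shift(lambda_nm, lambda_ref_nm):
    """Raman shift (cm^-1) of wavelength ``lambda_nm`` relative to an
    excitation at ``lambda_ref_nm``.

    Implements nu = 1e7 * (1/lambda_ref - 1/lambda) with wavelengths in nm.
    Positive on the Stokes side (lambda_nm > lambda_ref_nm).  Accepts
    scalars or arrays.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    ref = np.asarray(lambda_ref_nm, dtype=float)
    if np.any(lam <= 0) or np.any(ref <= 0):
        raise ValueError("wavelengths must be positive")
    out = 1e7 * (1.0 / ref - 1.0 / lam)
    return out.item() if np.isscalar(lambda_nm) and np.isscalar(lambda_ref_nm) else out


def raman_shift_to_wavelength(shift_cm1, lambda_ref_nm):
    """Absolute wavelength (nm) of a Raman shift for a given excitation.

    Exact inverse of :func:`wavelength_to_raman_shift`; raises for shifts at
    or beyond the 1e7/lambda_ref singularity (non-physical wavelength).
    """
    shift = np.asarray(shift_cm1, dtype=float)
    ref = np.asarray(lambda_ref_nm, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference wavelength must be positive")
    inv = 1.0 / ref - shift * 1e-7
    if np.any(inv <= 0):
        raise ValueError("Raman shift out of range for this excitation (shift >= 1e7/lambda_ref)")
    out = 1.0 / inv
    return out.item() if np.isscalar(shift_cm1) and np.isscalar(lambda_ref_nm) else out


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class RawSpectrum:
    """Detector counts over pixels, with acquisition metadata."""

    pixel_index: np.ndarray
    counts: np.ndarray
    excitation_nm: float
    power_mw: float
    acquisition_order: int = 1
    sample_id: str = ""
    genus_label: Optional[str] = None
    habit_label: Optional[str] = None

    def __post_init__(self):
        self.pixel_index = np.asarray(self.pixel_index, dtype=int)
        self.counts = _as_float_array(self.counts, "counts")
        if self.pixel_index.shape != self.counts.shape:
            raise ValueError("pixel_index and counts must have the same length")
        if np.any(np.diff(self.pixel_index) <= 0):
            raise ValueError("pixel_index must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("detector counts must be non-negative")
        if self.power_mw <= 0:
            raise ValueError("power_mw must be positive")
        if self.acquisition_order < 1:
            raise ValueError("acquisition_order starts at 1")

    @property
    def axis(self) -> np.ndarray:
        return self.pixel_index

    @property
    def values(self) -> np.ndarray:
        return self.counts


@dataclass
class CalibratedSpectrum:
    """Intensity over a Raman-shift axis referenced to 785 nm excitation."""

    wavenumber_cm1: np.ndarray
    intensity: np.ndarray
    excitation_nm: float
    power_mw: float
    acquisition_order: int = 1
    sample_id: str = ""
    genus_label: Optional[str] = None
    habit_label: Optional[str] = None

    def __post_init__(self):
        self.wavenumber_cm1 = _as_float_array(self.wavenumber_cm1, "wavenumber_cm1")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.wavenumber_cm1.shape != self.intensity.shape:
            raise ValueError("axis and intensity must have the same length")
        if np.any(np.diff(self.wavenumber_cm1) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    @property
    def axis(self) -> np.ndarray:
        return self.wavenumber_cm1

    @property
    def values(self) -> np.ndarray:
        return self.intensity

    def with_intensity(self, intensity: np.ndarray) -> "CalibratedSpectrum":
        return dataclasses.replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass
class DifferenceSpectrum:
    """Optimized difference of two calibrated spectra: minuend - k * subtrahend.

    ``k`` is the background optimization factor, ``lambda_pair_nm`` records
    (minuend excitation, subtrahend excitation) and ``delta_lambda_nm`` their
    signed offset (e.g. 784 - 786 = -2 nm for the headline 2 nm pair).
    """

    wavenumber_cm1: np.ndarray
    value: np.ndarray
    k: float
    lambda_pair_nm: tuple
    normalized: bool = False
    sample_id: str = ""
    genus_label: Optional[str] = None
    habit_label: Optional[str] = None

    def __post_init__(self):
        self.wavenumber_cm1 = _as_float_array(self.wavenumber_cm1, "wavenumber_cm1")
        self.value = _as_float_array(self.value, "value")
        if self.wavenumber_cm1.shape != self.value.shape:
            raise ValueError("axis and value must have the same length")
        if np.any(np.diff(self.wavenumber_cm1) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if self.k <= 0:
            raise ValueError("optimization factor k must be positive")
        self.lambda_pair_nm = (float(self.lambda_pair_nm[0]), float(self.lambda_pair_nm[1]))
        if self.normalized:
            nrm = float(np.linalg.norm(self.value))
            if not np.isclose(nrm, 1.0, rtol=1e-9, atol=0.0):
                raise ValueError("normalized difference must have unit Euclidean norm")

    @property
    def delta_lambda_nm(self) -> float:
        return self.lambda_pair_nm[0] - self.lambda_pair_nm[1]

    @property
    def axis(self) -> np.ndarray:
        return self.wavenumber_cm1

    @property
    def values(self) -> np.ndarray:
        return self.value

    def with_value(self, value: np.ndarray, normalized: Optional[bool] = None) -> "DifferenceSpectrum":
        norm_flag = self.normalized if normalized is None else normalized
        return dataclasses.replace(self, value=np.asarray(value, dtype=float), normalized=norm_flag)


@dataclass
class SpectrumCollection:
    """Homogeneous list of spectra on a bitwise-identical axis."""

    spectra: list
    notes: list = field(default_factory=list)

    def __post_init__(self):
        if self.spectra:
            first = self.spectra[0]
            ref_axis = first.axis
            for s in self.spectra:
                if type(s) is not type(first):
                    raise TypeError("collection members must share one concrete spectrum type")
                if s.axis.shape != ref_axis.shape or not np.array_equal(s.axis, ref_axis):
                    raise ValueError(
                        f"spectrum {s.sample_id!r} is not on the collection's common axis"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return SpectrumCollection(self.spectra[i], notes=list(self.notes))
        return self.spectra[i]

    @property
    def axis(self) -> np.ndarray:
        if not self.spectra:
            raise ValueError("empty collection has no axis")
        return self.spectra[0].axis

    def matrix(self) -> np.ndarray:
        """Stack intensities as an (n_spectra, n_points) array."""
        return np.vstack([s.values for s in self.spectra])

    def labels(self, field_name: str) -> list:
        return [getattr(s, field_name) for s in self.spectra]

    def subset(self, indices: Sequence[int]) -> "SpectrumCollection":
        return SpectrumCollection([self.spectra[i] for i in indices], notes=list(self.notes))


def resample(spectrum: CalibratedSpectrum, new_axis: np.ndarray) -> CalibratedSpectrum:
    """Linear interpolation onto ``new_axis``.

    Subtraction itself refuses mismatched grids; this is the explicit escape
    hatch for spectra recorded on different grids.
    """
    new_axis = _as_float_array(new_axis, "new_axis")
    if np.any(np.diff(new_axis) <= 0):
        raise ValueError("new_axis must be strictly increasing")
    lo, hi = spectrum.wavenumber_cm1[0], spectrum.wavenumber_cm1[-1]
    if new_axis[0] < lo - 1e-9 or new_axis[-1] > hi + 1e-9:
        raise ValueError("new_axis extends beyond the spectrum's support; refusing to extrapolate")
    vals = np.interp(new_axis, spectrum.wavenumber_cm1, spectrum.intensity)
    return dataclasses.replace(spectrum, wavenumber_cm1=new_axis, intensity=vals)
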