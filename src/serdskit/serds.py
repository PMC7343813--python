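"""Shifted-excitation difference processing.

The heart of the method: two Raman spectra of one particle acquired at
slightly different excitation wavelengths share the same wavelength-fixed
background (fluorescence, ambient light, etaloning) but carry Raman bands
displaced by the excitation offset.  Because the background bleaches
between the consecutive acquisitions and the laser powers differ, the
backgrounds do not match in amplitude; the subtrahend is therefore scaled
by an optimization factor k chosen to null the broadband residual before
subtraction.  In the bleaching regime (second acquisition has the weaker
background) k comes out larger than 1.

Pipeline order: optimize k -> subtract -> quality-control the optimized
differences against their class mean -> L2-normalize the survivors.
Reconstruction (cumulative sum plus SNIP) recovers a conventional-looking
Raman spectrum from a difference at the cost of effective resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import minimize_scalar

from .preprocess import SnipParams, snip_baseline
from .spectra import CalibratedSpectrum, DifferenceSpectrum, SpectrumCollection

__all__ = [
    "QcReport",
    "optimize_factor",
    "grid_search_factor",
    "subtract",
    "difference_collection",
    "pair_spectra",
    "qc_filter",
    "l2_normalize",
    "reconstruct",
]


def _check_shared_axis(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or not np.array_equal(a, b):
        raise ValueError(
            "spectra are not on a bitwise-identical axis; resample explicitly first")


def _broadband_residual(diff: np.ndarray, halfwidth: int) -> float:
    """L1 norm of the wide moving-median of a difference.

    The moving median annihilates the narrow derivative-like Raman
    difference features, leaving the broadband background residual; its L1
    norm is therefore a band-leakage-resistant measure of how much
    background survives the subtraction.
    """
    smooth = median_filter(diff, size=2 * halfwidth + 1, mode="nearest")
    return float(np.sum(np.abs(smooth)))


def optimize_factor(minuend: CalibratedSpectrum, subtrahend: CalibratedSpectrum,
                    k_bounds: Tuple[float, float] = (0.2, 5.0),
                    smoothing_halfwidth: int = 50) -> float:
    """Background-matching factor k for minuend - k * subtrahend.

    Bounded scalar minimization (tolerance 1e-6 in k) of the broadband
    residual objective.  Warns when the optimum sits at a bound, which
    usually means the pair's backgrounds differ more than the bounds allow.
    """
    _check_shared_axis(minuend.wavenumber_cm1, subtrahend.wavenumber_cm1)
    s = subtrahend.intensity
    if not np.any(s):
        raise ValueError("subtrahend is identically zero; no factor can match backgrounds")
    m = minuend.intensity

    res = minimize_scalar(
        lambda k: _broadband_residual(m - k * s, smoothing_halfwidth),
        bounds=k_bounds, method="bounded", options={"xatol": 1e-6},
    )
    k = float(res.x)
    span = k_bounds[1] - k_bounds[0]
    if min(k - k_bounds[0], k_bounds[1] - k) < 1e-4 * span:
        warnings.warn(f"optimization factor k={k:.4f} is at a search bound {k_bounds}")
    return k


def grid_search_factor(minuend: CalibratedSpectrum, subtrahend: CalibratedSpectrum,
                       k_bounds: Tuple[float, float] = (0.2, 5.0),
                       step: float = 1e-3,
                       smoothing_halfwidth: int = 50) -> float:
    """Brute-force k search on a uniform grid; independent slow oracle for
    the bounded minimization."""
    _check_shared_axis(minuend.wavenumber_cm1, subtrahend.wavenumber_cm1)
    grid = np.arange(k_bounds[0], k_bounds[1] + step / 2, step)
    objective = [
        _broadband_residual(minuend.intensity - k * subtrahend.intensity, smoothing_halfwidth)
        for k in grid
    ]
    return float(grid[int(np.argmin(objective))])


def subtract(minuend: CalibratedSpectrum, subtrahend: CalibratedSpectrum,
             k: float) -> DifferenceSpectrum:
    """Pixel-wise difference minuend - k * subtrahend on the shared axis.

    Refuses mismatched grids (no silent interpolation) and does not alter
    the spectral resolution.  The particle id (sample_id prefix before
    '#') and labels are carried over from the minuend.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    _check_shared_axis(minuend.wavenumber_cm1, subtrahend.wavenumber_cm1)
    base_id = minuend.sample_id.rsplit("#", 1)[0]
    return DifferenceSpectrum(
        wavenumber_cm1=minuend.wavenumber_cm1,
        value=minuend.intensity - k * subtrahend.intensity,
        k=k,
        lambda_pair_nm=(minuend.excitation_nm, subtrahend.excitation_nm),
        normalized=False,
        sample_id=base_id,
        genus_label=minuend.genus_label,
        habit_label=minuend.habit_label,
    )


def pair_spectra(collection: SpectrumCollection, minuend_nm: float,
                 subtrahend_nm: float) -> List[Tuple[CalibratedSpectrum, CalibratedSpectrum]]:
    """Group a collection into (minuend, subtrahend) pairs per particle.

    Particles are identified by the sample_id prefix before '#'; each
    particle must have exactly one acquisition at each requested
    excitation.  Default pairing convention is minuend at the shorter
    wavelength (e.g. 784) and subtrahend at the longer (786).
    """
    groups: Dict[str, Dict[float, CalibratedSpectrum]] = {}
    order: List[str] = []
    for s in collection:
        base = s.sample_id.rsplit("#", 1)[0]
        if base not in groups:
            groups[base] = {}
            order.append(base)
        if s.excitation_nm in groups[base]:
            raise ValueError(f"particle {base!r} has duplicate acquisition at {s.excitation_nm} nm")
        groups[base][s.excitation_nm] = s
    pairs = []
    for base in order:
        grp = groups[base]
        if minuend_nm not in grp or subtrahend_nm not in grp:
            raise ValueError(
                f"particle {base!r} lacks an acquisition at "
                f"{minuend_nm if minuend_nm not in grp else subtrahend_nm} nm")
        pairs.append((grp[minuend_nm], grp[subtrahend_nm]))
    return pairs


def difference_collection(collection: SpectrumCollection, minuend_nm: float = 784.0,
                          subtrahend_nm: float = 786.0,
                          k_bounds: Tuple[float, float] = (0.2, 5.0),
                          smoothing_halfwidth: int = 50) -> SpectrumCollection:
    """Optimize and subtract every particle's pair; returns unnormalized
    optimized differences (the input the quality control expects)."""
    diffs = []
    for minuend, subtrahend in pair_spectra(collection, minuend_nm, subtrahend_nm):
        k = optimize_factor(minuend, subtrahend, k_bounds, smoothing_halfwidth)
        diffs.append(subtract(minuend, subtrahend, k))
    return SpectrumCollection(diffs)


# ---------------------------------------------------------------------------
# Quality control


@dataclass
class QcReport:
    """Per-spectrum Pearson correlation to its class-mean difference."""

    threshold: float
    sample_ids: List[str]
    class_labels: List[str]
    r_values: np.ndarray
    kept: np.ndarray  # boolean

    def per_class_discard_fraction(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        labels = np.asarray(self.class_labels, dtype=object)
        for cls in sorted(set(self.class_labels)):
            mask = labels == cls
            out[cls] = float(np.mean(~self.kept[mask]))
        return out

    def to_records(self) -> List[dict]:
        return [
            {"sample_id": sid, "class": cls, "pearson_r": float(r), "kept": bool(k)}
            for sid, cls, r, k in zip(self.sample_ids, self.class_labels,
                                      self.r_values, self.kept)
        ]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0.0:
        return 0.0
    return float(np.dot(xc, yc) / denom)


def qc_filter(differences: SpectrumCollection, threshold: float = 0.52,
              label_field: str = "genus_label"):
    """Discard incoherent difference spectra.

    For each class the mean optimized (pre-normalization) difference is
    computed once over all members; every member whose Pearson correlation
    to that mean falls below the threshold is discarded.  This removes
    debris, out-of-focus and background-only acquisitions whose difference
    carries no reproducible band structure.  Returns (kept collection,
    discarded collection, QcReport).
    """
    if len(differences) == 0:
        raise ValueError("empty collection")
    labels = [getattr(s, label_field) for s in differences]
    if any(lab is None for lab in labels):
        raise ValueError(f"qc_filter requires {label_field} on every spectrum")
    mat = differences.matrix()
    labels_arr = np.asarray(labels, dtype=object)
    r = np.full(len(differences), np.nan)
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels_arr == cls)
        if idx.size == 1:
            warnings.warn(f"class {cls!r} has a single spectrum; kept with undefined r")
            continue
        mean = mat[idx].mean(axis=0)
        for i in idx:
            r[i] = _pearson(mat[i], mean)
    kept_mask = ~(r < threshold)  # NaN (singleton class) is kept
    report = QcReport(
        threshold=threshold,
        sample_ids=[s.sample_id for s in differences],
        class_labels=list(labels),
        r_values=r,
        kept=kept_mask,
    )
    kept = differences.subset(np.flatnonzero(kept_mask))
    discarded = differences.subset(np.flatnonzero(~kept_mask))
    return kept, discarded, report


def l2_normalize(difference: DifferenceSpectrum) -> DifferenceSpectrum:
    """Euclidean (unit L2 norm) normalization of a difference spectrum.

    Scale information is removed so classification sees spectral shape
    only.  Idempotent; a zero vector cannot be normalized.
    """
    nrm = float(np.linalg.norm(difference.value))
    if nrm == 0.0:
        raise ValueError("cannot normalize an identically-zero difference spectrum")
    return difference.with_value(difference.value / nrm, normalized=True)


def reconstruct(difference: DifferenceSpectrum,
                snip: Optional[SnipParams] = SnipParams()) -> CalibratedSpectrum:
    """Recover a conventional-looking Raman spectrum from a difference.

    Cumulative sum of the difference over pixels in axis order
    (S(n) = sum_{x<=n} S(x)), shifted to be non-negative, followed by SNIP
    baseline subtraction to remove the integration ramp and residual
    background.  The summation acts as a low-pass filter, so the
    reconstruction has reduced effective resolution; no deconvolution is
    attempted.  Pass ``snip=None`` to get the raw cumulative sum.
    """
    cum = np.cumsum(difference.value)
    if snip is not None:
        cum = cum - cum.min()
        cum = cum - snip_baseline(cum, snip)
    return CalibratedSpectrum(
        wavenumber_cm1=difference.wavenumber_cm1,
        intensity=cum,
        excitation_nm=difference.lambda_pair_nm[0],
        power_mw=1.0,  # reconstruction has no physical power; placeholder
        sample_id=difference.sample_id,
        genus_label=difference.genus_label,
        habit_label=difference.habit_label,
    )
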