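"""Forward simulator for shifted-excitation Raman acquisitions.

The generator reproduces the statistical structure a SERDS pipeline relies
on, so every downstream stage is testable without deposited data:

* Raman bands are fixed in Raman-shift coordinates **relative to their own
  excitation**; on the common 785 nm-referenced axis a band therefore
  appears displaced by the excitation offset (about 16 cm^-1 per nm).
* The fluorescence background is fixed in **absolute wavelength** (a broad
  Gaussian over the detector), so it lands on identical axis positions for
  every excitation; its amplitude decays geometrically between consecutive
  acquisitions of one particle (photobleaching) and scales with laser power.
* Ambient-light lines and detector etaloning ripple are wavelength/pixel
  fixed and independent of the laser, so they are identical across the
  acquisitions of a particle.
* Noise is additive Gaussian with a Poisson-like variance,
  sigma = scale * sqrt(max(signal, floor)); cosmic spikes are single-pixel
  positive excursions with recorded positions.

Defaults emulate the pollen case study: three excitations 784/785/786 nm at
130/180/200 mW acquired in that order, sporopollenin bands shared across
genera (1007, 1454, 1614 cm^-1), habit- and genus-specific marker bands,
and a bleaching rate strong enough that total intensity decreases across
the triplet despite the rising laser power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .spectra import (
    REFERENCE_EXCITATION_NM,
    CalibratedSpectrum,
    SpectrumCollection,
    raman_shift_to_wavelength,
    wavelength_to_raman_shift,
)

__all__ = [
    "BandSpec",
    "BackgroundSpec",
    "NoiseModel",
    "EtalonSpec",
    "AmbientLine",
    "AxisSpec",
    "SerdsSimConfig",
    "default_pollen_profiles",
    "default_config",
    "generate_acquisition",
    "generate_serds_triplet",
    "generate_dataset",
    "inject_cosmic_spikes",
]


@dataclass(frozen=True)
class BandSpec:
    """One Raman band: center in cm^-1 relative to its own excitation,
    full width at half maximum, and peak amplitude.  Lorentzian by default
    (the typical Raman lineshape); Gaussian available per band."""

    center_cm1: float
    fwhm_cm1: float
    amplitude: float
    shape: str = "lorentzian"

    def __post_init__(self):
        if self.fwhm_cm1 <= 0:
            raise ValueError("fwhm_cm1 must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, axis_cm1: np.ndarray, center: Optional[float] = None) -> np.ndarray:
        c = self.center_cm1 if center is None else center
        if self.shape == "lorentzian":
            hw = self.fwhm_cm1 / 2.0
            return self.amplitude * hw**2 / ((axis_cm1 - c) ** 2 + hw**2)
        sigma = self.fwhm_cm1 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return self.amplitude * np.exp(-0.5 * ((axis_cm1 - c) / sigma) ** 2)


@dataclass(frozen=True)
class BackgroundSpec:
    """Broad fluorescence profile, Gaussian in absolute wavelength (nm)."""

    center_nm: float = 830.0
    width_nm: float = 70.0
    amplitude: float = 1200.0


@dataclass(frozen=True)
class NoiseModel:
    """sigma = scale * sqrt(max(signal, floor)); floor avoids zero variance."""

    scale: float = 1.0
    floor: float = 10.0


@dataclass(frozen=True)
class EtalonSpec:
    """Pixel-fixed interference ripple of a back-illuminated CCD."""

    amplitude: float = 0.0
    period_px: float = 80.0
    phase: float = 0.0


@dataclass(frozen=True)
class AmbientLine:
    """Narrow wavelength-fixed line (e.g. room lighting)."""

    center_nm: float
    fwhm_nm: float = 0.3
    amplitude: float = 200.0


@dataclass(frozen=True)
class AxisSpec:
    """Common Raman-shift grid (785 nm referenced). 300-3100 cm^-1 covers
    the fingerprint and CH-stretch regions."""

    min_cm1: float = 300.0
    max_cm1: float = 3100.0
    n_points: int = 1024

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("axis needs at least 2 points")
        if self.max_cm1 <= self.min_cm1:
            raise ValueError("max_cm1 must exceed min_cm1")

    def grid(self) -> np.ndarray:
        return np.linspace(self.min_cm1, self.max_cm1, self.n_points)


def default_pollen_profiles() -> Tuple[Dict[str, List[BandSpec]], Dict[str, str]]:
    """Band profiles for eight genera grouped into tree / non_tree habits.

    All genera share the sporopollenin bands (1007, 1454, 1614 cm^-1) and
    amide features (1310, 1650 cm^-1); each habit carries a marker band
    (CH2 stretch for trees, carbonyl for non-trees) and each genus one
    distinctive fingerprint band, so habit and genus classification are
    both solvable but only from spectral shape.
    """
    shared = [
        BandSpec(1007.0, 12.0, 160.0),
        BandSpec(1310.0, 18.0, 90.0),
        BandSpec(1454.0, 16.0, 140.0),
        BandSpec(1650.0, 20.0, 110.0),
        BandSpec(2930.0, 45.0, 130.0),
    ]
    band_1614 = {
        "alder": 170.0, "birch": 180.0, "hazel": 175.0, "larch": 150.0,
        "cyclamen": 165.0, "rumex": 160.0, "mugwort": 170.0, "moor_grass": 60.0,
    }
    tree_marker = BandSpec(2850.0, 30.0, 150.0)
    nontree_marker = BandSpec(1735.0, 16.0, 140.0)
    unique = {
        "alder": 524.0, "birch": 655.0, "hazel": 742.0, "larch": 872.0,
        "cyclamen": 566.0, "rumex": 701.0, "mugwort": 832.0, "moor_grass": 948.0,
    }
    habits = {
        "alder": "tree", "birch": "tree", "hazel": "tree", "larch": "tree",
        "cyclamen": "non_tree", "rumex": "non_tree",
        "mugwort": "non_tree", "moor_grass": "non_tree",
    }
    profiles: Dict[str, List[BandSpec]] = {}
    for genus, habit in habits.items():
        bands = list(shared)
        bands.append(BandSpec(1614.0, 14.0, band_1614[genus]))
        bands.append(tree_marker if habit == "tree" else nontree_marker)
        bands.append(BandSpec(unique[genus], 12.0, 120.0))
        if genus == "larch":  # conifer essential oils: extra lipid CH2 signal
            bands.append(BandSpec(2885.0, 28.0, 90.0))
        profiles[genus] = bands
    return profiles, habits


@dataclass
class SerdsSimConfig:
    """Generative parameters for synthetic SERDS triplets."""

    class_profiles: Dict[str, List[BandSpec]] = field(default_factory=dict)
    class_habits: Dict[str, str] = field(default_factory=dict)
    excitations_nm: Tuple[float, ...] = (784.0, 785.0, 786.0)
    powers_mw: Tuple[float, ...] = (130.0, 180.0, 200.0)
    reference_power_mw: float = 180.0
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    bleach_factor: float = 0.6
    noise: NoiseModel = field(default_factory=NoiseModel)
    spike_rate: float = 0.0
    spike_amplitude_range: Tuple[float, float] = (500.0, 3000.0)
    ambient_lines: Tuple[AmbientLine, ...] = ()
    etalon: EtalonSpec = field(default_factory=EtalonSpec)
    axis: AxisSpec = field(default_factory=AxisSpec)
    amplitude_jitter_sd: float = 0.10
    intensity_jitter_sd: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if not self.class_profiles:
            profiles, habits = default_pollen_profiles()
            self.class_profiles = profiles
            if not self.class_habits:
                self.class_habits = habits
        self.excitations_nm = tuple(float(x) for x in self.excitations_nm)
        self.powers_mw = tuple(float(x) for x in self.powers_mw)
        if len(self.excitations_nm) != len(self.powers_mw):
            raise ValueError("excitations_nm and powers_mw must have the same length")
        if not (0.0 < self.bleach_factor <= 1.0):
            raise ValueError("bleach_factor must lie in (0, 1]")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be non-negative")

    # -- JSON round trip (unknown keys rejected) ---------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SerdsSimConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "class_profiles" in d:
            d["class_profiles"] = {
                cls_name: [BandSpec(**b) for b in bands]
                for cls_name, bands in d["class_profiles"].items()
            }
        for key, typ in (("background", BackgroundSpec), ("noise", NoiseModel),
                         ("etalon", EtalonSpec), ("axis", AxisSpec)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "ambient_lines" in d:
            d["ambient_lines"] = tuple(
                AmbientLine(**a) if isinstance(a, dict) else a for a in d["ambient_lines"]
            )
        for key in ("excitations_nm", "powers_mw", "spike_amplitude_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SerdsSimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_config(**overrides) -> SerdsSimConfig:
    return SerdsSimConfig(**overrides)


# ---------------------------------------------------------------------------
# Forward model components


def band_component(profile: Sequence[BandSpec], axis_cm1: np.ndarray,
                   excitation_nm: float) -> np.ndarray:
    """Band term on the common 785 nm-referenced axis.

    A band at shift c relative to its own excitation sits at absolute
    wavelength 1/lambda = 1/lambda_ex - c*1e-7; re-expressed against the
    785 nm reference that is c + 1e7*(1/785 - 1/lambda_ex).
    """
    offset = wavelength_to_raman_shift(excitation_nm, REFERENCE_EXCITATION_NM)
    out = np.zeros_like(axis_cm1)
    for band in profile:
        out += band.profile(axis_cm1, center=band.center_cm1 + offset)
    return out


def background_component(background: BackgroundSpec, axis_cm1: np.ndarray) -> np.ndarray:
    """Fluorescence term; fixed in absolute wavelength, hence identical on
    the common axis for every excitation."""
    lam = raman_shift_to_wavelength(axis_cm1, REFERENCE_EXCITATION_NM)
    return background.amplitude * np.exp(-0.5 * ((lam - background.center_nm) / background.width_nm) ** 2)


def ambient_component(lines: Sequence[AmbientLine], axis_cm1: np.ndarray) -> np.ndarray:
    lam = raman_shift_to_wavelength(axis_cm1, REFERENCE_EXCITATION_NM)
    out = np.zeros_like(axis_cm1)
    for line in lines:
        sigma = line.fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        out += line.amplitude * np.exp(-0.5 * ((lam - line.center_nm) / sigma) ** 2)
    return out


def etalon_component(etalon: EtalonSpec, n_points: int) -> np.ndarray:
    if etalon.amplitude == 0.0:
        return np.zeros(n_points)
    px = np.arange(n_points)
    # offset so the ripple stays non-negative (a transfer-function modulation)
    return etalon.amplitude * 0.5 * (1.0 + np.sin(2.0 * np.pi * px / etalon.period_px + etalon.phase))


def generate_acquisition(profile: Sequence[BandSpec], config: SerdsSimConfig,
                         excitation_nm: float, power_mw: float,
                         acquisition_index: int,
                         rng: Optional[np.random.Generator] = None,
                         sample_id: str = "", genus_label: Optional[str] = None,
                         habit_label: Optional[str] = None) -> CalibratedSpectrum:
    """One synthetic acquisition on the common axis.

    intensity = power_scale * [bands + background * bleach^index]
                + ambient + etalon + noise
    with power_scale = power_mw / reference_power_mw.  All terms are
    non-negative before noise; noise is only drawn when an rng is given.
    """
    if excitation_nm not in config.excitations_nm:
        raise ValueError(f"excitation {excitation_nm} nm not in config {config.excitations_nm}")
    if acquisition_index < 0:
        raise ValueError("acquisition_index must be >= 0")
    axis = config.axis.grid()
    power_scale = power_mw / config.reference_power_mw
    signal = power_scale * (
        band_component(profile, axis, excitation_nm)
        + background_component(config.background, axis) * config.bleach_factor**acquisition_index
    )
    signal = signal + ambient_component(config.ambient_lines, axis)
    signal = signal + etalon_component(config.etalon, axis.size)
    intensity = signal
    if rng is not None and config.noise.scale > 0:
        sigma = config.noise.scale * np.sqrt(np.maximum(signal, config.noise.floor))
        intensity = signal + rng.normal(0.0, 1.0, axis.size) * sigma
    return CalibratedSpectrum(
        wavenumber_cm1=axis,
        intensity=intensity,
        excitation_nm=excitation_nm,
        power_mw=power_mw,
        acquisition_order=acquisition_index + 1,
        sample_id=sample_id,
        genus_label=genus_label,
        habit_label=habit_label,
    )


def generate_serds_triplet(profile: Sequence[BandSpec], config: SerdsSimConfig,
                           rng: Optional[np.random.Generator] = None,
                           particle_id: str = "p0000",
                           genus_label: Optional[str] = None,
                           habit_label: Optional[str] = None) -> List[CalibratedSpectrum]:
    """One particle measured at each configured excitation, in order.

    Acquisition index runs 0,1,2 along config.excitations_nm (784 then 785
    then 786 by default), so the background bleaches across the triplet.
    sample_ids follow the ``<particle>#<excitation>`` convention.
    """
    out = []
    for idx, (exc, pw) in enumerate(zip(config.excitations_nm, config.powers_mw)):
        out.append(
            generate_acquisition(
                profile, config, exc, pw, idx, rng,
                sample_id=f"{particle_id}#{int(round(exc))}",
                genus_label=genus_label, habit_label=habit_label,
            )
        )
    return out


def _jitter_profile(profile: Sequence[BandSpec], rng: np.random.Generator,
                    band_sd: float, scale_sd: float) -> List[BandSpec]:
    scale = float(np.exp(rng.normal(0.0, scale_sd))) if scale_sd > 0 else 1.0
    out = []
    for band in profile:
        amp = band.amplitude * scale
        if band_sd > 0:
            amp *= float(np.exp(rng.normal(0.0, band_sd)))
        out.append(BandSpec(band.center_cm1, band.fwhm_cm1, amp, band.shape))
    return out


def generate_dataset(config: SerdsSimConfig, n_per_class: int,
                     seed: Optional[int] = None) -> SpectrumCollection:
    """Labeled synthetic dataset: ``n_per_class`` particles per class, three
    acquisitions each.  Per-particle band-amplitude jitter (lognormal) and a
    global intensity jitter emulate biological and focus variability.
    Deterministic under the seed."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if len(config.class_profiles) < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    spectra: List[CalibratedSpectrum] = []
    notes: List[str] = []
    for cls_name in sorted(config.class_profiles):
        profile = config.class_profiles[cls_name]
        habit = config.class_habits.get(cls_name)
        for i in range(n_per_class):
            jittered = _jitter_profile(profile, rng,
                                       config.amplitude_jitter_sd, config.intensity_jitter_sd)
            triplet = generate_serds_triplet(
                jittered, config, rng,
                particle_id=f"{cls_name}-{i:04d}",
                genus_label=cls_name, habit_label=habit,
            )
            if config.spike_rate > 0:
                spiked = []
                for s in triplet:
                    s2, positions = inject_cosmic_spikes(
                        s, config.spike_rate, config.spike_amplitude_range, rng)
                    if positions:
                        notes.append(f"spikes {s.sample_id}: {positions}")
                    spiked.append(s2)
                triplet = spiked
            spectra.extend(triplet)
    return SpectrumCollection(spectra, notes=notes)


def inject_cosmic_spikes(spectrum: CalibratedSpectrum, rate: float,
                         amplitude_range: Tuple[float, float],
                         rng: np.random.Generator):
    """Add Poisson(rate) single-pixel positive excursions; returns the
    spiked spectrum and the injected pixel positions (test oracle)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    n = int(rng.poisson(rate))
    if n == 0:
        return spectrum, []
    n = min(n, spectrum.intensity.size)
    positions = sorted(int(p) for p in rng.choice(spectrum.intensity.size, size=n, replace=False))
    values = spectrum.intensity.copy()
    lo, hi = amplitude_range
    for p in positions:
        values[p] += float(rng.uniform(lo, hi))
    return spectrum.with_intensity(values), positions
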