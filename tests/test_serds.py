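"""Difference optimization, subtraction, QC, normalization, reconstruction."""

import numpy as np
import pytest

import serdskit as sk
from serdskit.preprocess import SnipParams, snip_correct
from serdskit.serds import (
    difference_collection, grid_search_factor, l2_normalize, optimize_factor,
    pair_spectra, qc_filter, reconstruct, subtract,
)
from serdskit.simulate import BandSpec, band_component, generate_serds_triplet


def _spectrum(axis, y, exc=784.0, power=130.0, sid="s#784", **labels):
    return sk.CalibratedSpectrum(wavenumber_cm1=axis, intensity=y,
                                 excitation_nm=exc, power_mw=power,
                                 sample_id=sid, **labels)


class TestOptimizeFactor:
    def test_proportional_pair_recovers_ratio(self):
        axis = np.linspace(300.0, 3100.0, 512)
        m = 100.0 * np.exp(-0.5 * ((axis - 1200.0) / 600.0) ** 2) + 20.0
        minuend = _spectrum(axis, m)
        subtrahend = _spectrum(axis, 0.8 * m, exc=786.0, power=200.0, sid="s#786")
        k = optimize_factor(minuend, subtrahend)
        assert k == pytest.approx(1.25, abs=1e-4)

    def test_recovers_true_background_ratio_on_synthetic_pair(self, noise_free_config):
        cfg = noise_free_config
        t = generate_serds_triplet(cfg.class_profiles["birch"], cfg)
        true_ratio = (130.0 / 180.0) / ((200.0 / 180.0) * cfg.bleach_factor**2)
        k = optimize_factor(t[0], t[2])
        assert abs(k - true_ratio) / true_ratio < 0.02

    def test_agrees_with_grid_search_oracle(self, noise_free_config):
        t = generate_serds_triplet(noise_free_config.class_profiles["alder"],
                                   noise_free_config)
        k_opt = optimize_factor(t[0], t[2])
        k_grid = grid_search_factor(t[0], t[2], step=1e-3)
        assert abs(k_opt - k_grid) <= 2e-3

    def test_bleaching_regime_gives_k_above_one(self):
        """786 nm is measured last, so its background has bleached most and
        the optimization factor exceeds 1."""
        cfg = sk.SerdsSimConfig(seed=21)
        rng = np.random.default_rng(21)
        for genus in ("birch", "rumex"):
            t = generate_serds_triplet(cfg.class_profiles[genus], cfg, rng)
            assert optimize_factor(t[0], t[2]) > 1.0

    def test_zero_subtrahend_rejected(self):
        axis = np.linspace(300.0, 900.0, 64)
        with pytest.raises(ValueError, match="identically zero"):
            optimize_factor(_spectrum(axis, np.ones(64)),
                            _spectrum(axis, np.zeros(64), exc=786.0, sid="s#786"))

    def test_bound_hit_warns(self):
        axis = np.linspace(300.0, 900.0, 64)
        base = np.exp(-0.5 * ((axis - 600.0) / 200.0) ** 2)
        minuend = _spectrum(axis, 100.0 * base)
        subtrahend = _spectrum(axis, 5.0 * base, exc=786.0, sid="s#786")
        with pytest.warns(UserWarning, match="bound"):
            optimize_factor(minuend, subtrahend, k_bounds=(0.2, 5.0))


class TestSubtract:
    def test_identical_spectra_cancel_at_k_one(self):
        axis = np.linspace(300.0, 900.0, 64)
        y = np.linspace(5.0, 50.0, 64)
        d = subtract(_spectrum(axis, y), _spectrum(axis, y, exc=786.0, sid="s#786"), 1.0)
        np.testing.assert_array_equal(d.value, np.zeros(64))
        assert d.lambda_pair_nm == (784.0, 786.0)
        assert d.delta_lambda_nm == pytest.approx(-2.0)

    def test_shifted_lorentzian_pair_gives_s_shape(self):
        """Classic derivative-like difference: one positive and one negative
        lobe, with signed integral (1 - k) * band area."""
        cfg = sk.SerdsSimConfig(noise=sk.NoiseModel(scale=0.0),
                                background=sk.BackgroundSpec(amplitude=0.0),
                                bleach_factor=1.0, powers_mw=(180.0, 180.0, 180.0))
        band = BandSpec(1007.0, 14.0, 200.0)
        t = generate_serds_triplet([band], cfg)
        k = 1.3
        d = subtract(t[0], t[2], k)
        assert d.value.max() > 0 and d.value.min() < 0
        peak_pos = d.wavenumber_cm1[int(np.argmax(d.value))]
        trough_pos = d.wavenumber_cm1[int(np.argmin(d.value))]
        assert peak_pos < trough_pos  # minuend band sits at lower wavenumber
        step = d.wavenumber_cm1[1] - d.wavenumber_cm1[0]
        area = band.amplitude * np.pi * band.fwhm_cm1 / 2.0
        assert d.value.sum() * step == pytest.approx((1.0 - k) * area, rel=0.01)

    def test_axis_mismatch_rejected(self):
        a = _spectrum(np.linspace(300.0, 900.0, 64), np.ones(64))
        b = _spectrum(np.linspace(301.0, 901.0, 64), np.ones(64), exc=786.0, sid="s#786")
        with pytest.raises(ValueError, match="axis"):
            subtract(a, b, 1.0)

    def test_wavelength_fixed_perturbations_cancel(self):
        """Ambient line and etaloning ripple identical in both acquisitions
        survive at < 1% of their amplitude in the optimized difference of a
        matched-background pair."""
        kwargs = dict(noise=sk.NoiseModel(scale=0.0), bleach_factor=1.0,
                      powers_mw=(180.0, 180.0, 180.0))
        clean_cfg = sk.SerdsSimConfig(**kwargs)
        pert_cfg = sk.SerdsSimConfig(
            **kwargs,
            ambient_lines=(sk.AmbientLine(852.1, 0.4, 300.0),),
            etalon=sk.EtalonSpec(amplitude=60.0, period_px=80.0),
        )
        prof = clean_cfg.class_profiles["birch"]
        d_clean = _optimized_difference(prof, clean_cfg)
        d_pert = _optimized_difference(prof, pert_cfg)
        leak = np.max(np.abs(d_pert.value - d_clean.value))
        assert leak < 0.01 * 300.0


def _optimized_difference(profile, config, rng=None):
    t = generate_serds_triplet(profile, config, rng)
    k = optimize_factor(t[0], t[2])
    return subtract(t[0], t[2], k)


class TestPairing:
    def test_pairs_by_particle_prefix(self, noise_free_config):
        ds = sk.generate_dataset(noise_free_config, n_per_class=2, seed=0)
        pairs = pair_spectra(ds, 784.0, 786.0)
        assert len(pairs) == len(ds) // 3
        for m, s in pairs:
            assert (m.excitation_nm, s.excitation_nm) == (784.0, 786.0)
            assert m.sample_id.rsplit("#", 1)[0] == s.sample_id.rsplit("#", 1)[0]

    def test_missing_excitation_is_error(self, small_collection):
        with pytest.raises(ValueError, match="lacks an acquisition"):
            pair_spectra(small_collection, 784.0, 786.0)


class TestQcFilter:
    def test_identical_members_all_kept_with_r_one(self):
        axis = np.linspace(300.0, 900.0, 64)
        value = np.sin(axis / 40.0)
        diffs = sk.SpectrumCollection([
            sk.DifferenceSpectrum(wavenumber_cm1=axis, value=value.copy(), k=1.2,
                                  lambda_pair_nm=(784.0, 786.0), sample_id=f"d{i}",
                                  genus_label="birch")
            for i in range(5)
        ])
        kept, discarded, report = qc_filter(diffs, 0.52)
        assert len(kept) == 5 and len(discarded) == 0
        np.testing.assert_allclose(report.r_values, 1.0, atol=1e-12)

    def test_injected_noise_spectra_discarded_exactly(self):
        """20 coherent synthetic differences plus 3 band-free noise spectra:
        the QC threshold 0.52 discards exactly the 3 noise spectra."""
        cfg = sk.SerdsSimConfig(seed=7)
        rng = np.random.default_rng(5)
        diffs = []
        for i in range(20):
            d = _optimized_difference(cfg.class_profiles["birch"], cfg, rng)
            diffs.append(d.with_value(d.value))
        for i in range(3):
            d = _optimized_difference([], cfg, rng)  # band amplitude 0
            diffs.append(d.with_value(d.value))
        for i, d in enumerate(diffs):
            d.sample_id = f"{'coh' if i < 20 else 'noise'}{i}"
            d.genus_label = "birch"
        kept, discarded, report = qc_filter(sk.SpectrumCollection(diffs), 0.52)
        assert sorted(s.sample_id for s in discarded) == ["noise20", "noise21", "noise22"]
        assert report.per_class_discard_fraction() == {"birch": pytest.approx(3 / 23)}

    def test_threshold_boundaries(self, rng):
        axis = np.linspace(300.0, 900.0, 64)
        diffs = sk.SpectrumCollection([
            sk.DifferenceSpectrum(wavenumber_cm1=axis,
                                  value=np.sin(axis / 40.0) + rng.normal(0, 0.1, 64),
                                  k=1.2, lambda_pair_nm=(784.0, 786.0),
                                  sample_id=f"d{i}", genus_label="x")
            for i in range(6)
        ])
        kept_all, _, _ = qc_filter(diffs, -1.0)
        assert len(kept_all) == 6
        kept_none, _, _ = qc_filter(diffs, 1.0)
        assert len(kept_none) == 0

    def test_singleton_class_kept_with_warning(self):
        axis = np.linspace(300.0, 900.0, 16)
        diffs = sk.SpectrumCollection([
            sk.DifferenceSpectrum(wavenumber_cm1=axis, value=np.arange(16.0) + i,
                                  k=1.0, lambda_pair_nm=(784.0, 786.0),
                                  sample_id=f"d{i}", genus_label=g)
            for i, g in enumerate(["solo", "pair", "pair"])
        ])
        with pytest.warns(UserWarning, match="solo"):
            kept, _, report = qc_filter(diffs, 0.52)
        assert "d0" in [s.sample_id for s in kept]
        assert np.isnan(report.r_values[0])


class TestL2Normalize:
    def test_three_four_vector(self):
        axis = np.arange(6, dtype=float)
        value = np.array([3.0, 4.0, 0.0, 0.0, 0.0, 0.0])
        d = sk.DifferenceSpectrum(wavenumber_cm1=axis, value=value, k=1.0,
                                  lambda_pair_nm=(784.0, 786.0))
        out = l2_normalize(d)
        np.testing.assert_allclose(out.value, [0.6, 0.8, 0, 0, 0, 0], atol=1e-15)
        assert out.normalized

    def test_unit_norm_and_idempotence(self, rng):
        axis = np.linspace(300.0, 900.0, 128)
        d = sk.DifferenceSpectrum(wavenumber_cm1=axis, value=rng.normal(size=128),
                                  k=1.1, lambda_pair_nm=(784.0, 786.0))
        once = l2_normalize(d)
        assert np.linalg.norm(once.value) == pytest.approx(1.0, abs=1e-12)
        twice = l2_normalize(once)
        np.testing.assert_allclose(twice.value, once.value, atol=1e-15)

    def test_zero_vector_rejected(self):
        d = sk.DifferenceSpectrum(wavenumber_cm1=np.arange(4.0), value=np.zeros(4),
                                  k=1.0, lambda_pair_nm=(784.0, 786.0))
        with pytest.raises(ValueError):
            l2_normalize(d)

    def test_classification_input_invariant_to_common_scaling(self, noise_free_config):
        """Pre-scaling a raw pair by any positive constant leaves the
        normalized difference unchanged."""
        t = generate_serds_triplet(noise_free_config.class_profiles["hazel"],
                                   noise_free_config)
        k = optimize_factor(t[0], t[2])
        d1 = l2_normalize(subtract(t[0], t[2], k))
        scaled = [s.with_intensity(7.3 * s.intensity) for s in t]
        k2 = optimize_factor(scaled[0], scaled[2])
        d2 = l2_normalize(subtract(scaled[0], scaled[2], k2))
        assert k2 == pytest.approx(k, abs=1e-4)
        np.testing.assert_allclose(d2.value, d1.value, atol=1e-7)


class TestReconstruct:
    def test_zero_difference_reconstructs_to_zero(self):
        d = sk.DifferenceSpectrum(wavenumber_cm1=np.arange(32.0), value=np.zeros(32),
                                  k=1.0, lambda_pair_nm=(784.0, 786.0))
        r = reconstruct(d, None)
        np.testing.assert_array_equal(r.intensity, np.zeros(32))

    def test_unit_impulse_integrates_to_step(self):
        value = np.zeros(32)
        value[10] = 1.0
        d = sk.DifferenceSpectrum(wavenumber_cm1=np.arange(32.0), value=value,
                                  k=1.0, lambda_pair_nm=(784.0, 786.0))
        r = reconstruct(d, None)
        expected = np.concatenate([np.zeros(10), np.ones(22)])
        np.testing.assert_array_equal(r.intensity, expected)

    def test_single_band_recovered_near_true_center(self):
        """Reconstruction of a displaced band pair peaks within the
        excitation displacement (~16 cm^-1) of the true center and
        correlates >= 0.9 with the true band-only spectrum."""
        cfg = sk.SerdsSimConfig(noise=sk.NoiseModel(scale=0.0), bleach_factor=1.0,
                                powers_mw=(180.0, 180.0, 180.0),
                                background=sk.BackgroundSpec(amplitude=0.0))
        band = BandSpec(1007.0, 14.0, 200.0)
        t = generate_serds_triplet([band], cfg)
        d = subtract(t[0], t[2], 1.0)  # k at truth for a matched pair
        r = reconstruct(d, SnipParams(m=24))
        center = r.wavenumber_cm1[int(np.argmax(r.intensity))]
        assert abs(center - band.center_cm1) < 16.5
        truth = band.profile(r.wavenumber_cm1)
        assert np.corrcoef(r.intensity, truth)[0, 1] >= 0.9


def test_noise_variance_adds_in_quadrature():
    """Variance of minuend - k*subtrahend for independent equal-noise
    acquisitions is (1 + k^2) times the single-spectrum variance."""
    cfg = sk.SerdsSimConfig(background=sk.BackgroundSpec(amplitude=0.0),
                            noise=sk.NoiseModel(scale=1.0, floor=400.0))
    rng = np.random.default_rng(11)
    k = 1.4
    singles, diffs = [], []
    for i in range(150):
        t = generate_serds_triplet([], cfg, rng)
        singles.append(np.var(t[0].intensity))
        diffs.append(np.var(t[0].intensity - k * t[2].intensity))
    ratio = np.mean(diffs) / np.mean(singles)
    assert ratio == pytest.approx(1.0 + k**2, rel=0.05)


def test_difference_collection_runs_optimize_and_subtract(noise_free_config):
    ds = sk.generate_dataset(noise_free_config, n_per_class=2, seed=0)
    diffs = difference_collection(ds, 784.0, 786.0)
    assert len(diffs) == len(ds) // 3
    true_ratio = (130.0 / 180.0) / ((200.0 / 180.0) * noise_free_config.bleach_factor**2)
    for d in diffs:
        assert d.k == pytest.approx(true_ratio, rel=0.05)
        assert d.genus_label is not None
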