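import numpy as np
import pytest

import serdskit as sk


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_free_config():
    """Default pollen simulator with the noise switched off."""
    return sk.SerdsSimConfig(noise=sk.NoiseModel(scale=0.0))


@pytest.fixture
def matched_background_config():
    """No bleaching, equal powers, no noise: the two acquisitions of a pair
    share an identical background (k should come out at 1)."""
    return sk.SerdsSimConfig(
        noise=sk.NoiseModel(scale=0.0), bleach_factor=1.0,
        powers_mw=(180.0, 180.0, 180.0),
    )


@pytest.fixture
def small_collection():
    """Three calibrated spectra on a shared axis with mixed labels."""
    axis = np.linspace(400.0, 1800.0, 64)
    rng = np.random.default_rng(7)
    spectra = [
        sk.CalibratedSpectrum(
            wavenumber_cm1=axis,
            intensity=rng.uniform(0, 100, axis.size),
            excitation_nm=exc, power_mw=pw, acquisition_order=order,
            sample_id=sid, genus_label=genus, habit_label=habit,
        )
        for sid, exc, pw, order, genus, habit in [
            ("p0#784", 784.0, 130.0, 1, "birch", "tree"),
            ("p0#786", 786.0, 200.0, 3, "birch", "tree"),
            ("p1#784", 784.0, 130.0, 1, None, None),
        ]
    ]
    return sk.SpectrumCollection(spectra)
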