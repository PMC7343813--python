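"""Reconstruct a conventional-looking Raman spectrum from a difference.

The cumulative sum of the difference spectrum re-integrates the
derivative-like features into bands; SNIP baseline correction then removes
the integration ramp. The price is reduced effective resolution.
"""

import numpy as np

import serdskit as sk
from serdskit.preprocess import SnipParams
from serdskit.serds import reconstruct, subtract
from serdskit.simulate import BandSpec, generate_serds_triplet

cfg = sk.SerdsSimConfig(noise=sk.NoiseModel(scale=0.0), bleach_factor=1.0,
                        powers_mw=(180.0, 180.0, 180.0),
                        background=sk.BackgroundSpec(amplitude=0.0))
band = BandSpec(1007.0, 14.0, 200.0)
t = generate_serds_triplet([band], cfg)

d = subtract(t[0], t[2], 1.0)
r = reconstruct(d, SnipParams(m=24))

center = r.wavenumber_cm1[np.argmax(r.intensity)]
corr = np.corrcoef(r.intensity, band.profile(r.wavenumber_cm1))[0, 1]
print(f"true band center: {band.center_cm1:.1f} cm^-1")
print(f"reconstructed maximum: {center:.1f} cm^-1 (error {center - 1007.0:+.1f})")
print(f"correlation with the band-only truth: {corr:.3f}")
print("-> the band is recovered near its true position (well within the")
print("   ~32 cm^-1 excitation displacement) but broadened by the summation.")
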