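"""Show the adaptive local window filter rejecting impulse noise.

Builds a two-region image (dark/bright halves) with 1% salt noise at 255,
filters it, and prints how far the noise pixels moved back toward their
neighborhoods while flat interiors stayed untouched.  Unreliable
neighbors -- pixels deviating from the robust window reference by more
than the window RMS deviation -- carry zero weight, which is what makes
the filter edge-preserving and outlier-proof.
"""

import numpy as np

from pupilfcm import filter_image

rng = np.random.default_rng(0)
img = np.full((60, 60), 40, dtype=np.uint8)
img[:, 30:] = 200
noisy = img.copy()
salt = rng.choice(img.size, size=36, replace=False)
noisy.ravel()[salt] = 255

out = filter_image(noisy, lambda_g=3.0)

moved = np.abs(out.ravel()[salt].astype(int) - img.ravel()[salt].astype(int))
untouched = (out == img)[5:-5, 5:25].mean()
print(f"salt pixels injected        : {salt.size} at intensity 255")
print(f"after filtering, |residual| : median {np.median(moved):.0f} gray levels "
      f"(vs 215/55 before)")
print(f"dark-interior pixels intact : {100 * untouched:.1f}%")
print(f"edge column means           : {out[:, 28:32].mean(axis=0).round(1)}")
print("The 40/200 step survives (no blur across the edge) while the salt "
      "pixels are pulled back into their local intensity population.")
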