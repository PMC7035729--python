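"""Level-1 3D wavelet decomposition of a synthetic texture volume.

Builds one 32^3 volume, decomposes it with the db2 wavelet and prints each
subband's label, shape and share of the total energy.  The approximation
(LLL) holds the smooth content; the seven detail subbands hold oriented
micro-edges (H marks the high-pass axis).
"""

import numpy as np

from voxtex import Volume3D, decompose_level1

rng = np.random.default_rng(0)
vol = Volume3D(rng.standard_normal((32, 32, 32)))

sb = decompose_level1(vol, wavelet_name="db2", extension_mode="periodization")
total = sum(np.sum(b.data**2) for b in [sb.approx] + sb.details)

print(f"input dims {vol.dims}, wavelet {sb.wavelet_name}, mode {sb.extension_mode}")
print(f"{'subband':>8} {'dims':>14} {'energy %':>9}")
for label, band in [("LLL", sb.approx)] + list(zip(sb.orientation_labels, sb.details)):
    frac = 100 * np.sum(band.data**2) / total
    print(f"{label:>8} {str(band.dims):>14} {frac:9.2f}")
print("White noise spreads energy ~evenly over the 8 subbands (~12.5% each);")
print("a smooth volume would concentrate it in LLL.")
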