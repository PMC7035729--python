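"""The 140-feature combined descriptor of a single volume.

Pipeline: level-1 db2 wavelet decomposition -> riu LBP histogram (20 bins)
on each of the seven detail subbands -> concatenation in subband order.
Each 20-bin block sums to 1, so the descriptor is a set of seven pattern
distributions describing oriented micro-structure.
"""

import numpy as np

from voxtex import extract_dwt_lbp20
from voxtex.synthdata import SynthParams, generate_volume

params = SynthParams(seed=7)
rough = generate_volume(0, params, 0)    # correlation scale 1 voxel
smooth = generate_volume(1, params, 0)   # correlation scale 2 voxels

for name, vol in [("rough (class A)", rough), ("smooth (class B)", smooth)]:
    vec = extract_dwt_lbp20(vol)
    blocks = vec.values.reshape(7, 20)
    print(f"{name}: descriptor length {len(vec)}")
    print(f"  block sums: {np.round(blocks.sum(axis=1), 12)}")
    print(f"  non-uniform (bin 19) share per subband: {np.round(blocks[:, 19], 3)}")
print("The two classes differ visibly in how much non-uniform pattern mass")
print("each detail subband carries - that difference is what the classifier uses.")
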