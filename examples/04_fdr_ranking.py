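"""Fisher-discriminant-ratio feature ranking on a toy two-class matrix.

FDR(i) = (m1 - m2)^2 / (s1^2 + s2^2) per feature; larger = more
discriminative.  Here features 0 and 1 carry a real class difference of
different strengths and the rest are noise.
"""

import numpy as np

from voxtex import FeatureMatrix, rank_by_fdr

rng = np.random.default_rng(2)
x = rng.standard_normal((40, 8))
x[20:, 0] += 3.0   # strong effect
x[20:, 1] += 1.0   # weak effect
fm = FeatureMatrix(values=x, labels=["A"] * 20 + ["B"] * 20)

ranking = rank_by_fdr(fm)
print("feature  FDR score")
for idx in ranking.order:
    print(f"{idx:7d}  {ranking.scores[idx]:.4f}")
print("\nFeature 0 (3-SD shift) ranks first, feature 1 (1-SD) second;")
print("pure-noise features trail with scores near 0.")
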