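"""Generate synthetic fundus pairs and expand them with the fixed recipes.

The generator grows random-walk vessel trees on a dark circular field of
view (vessel fraction held in the 5-15% band that brackets the ~9:1
background:vessel ratio of real fundus masks).  The three-stage expansion
is fully deterministic: n source pairs always become 96n training pairs
(20 -> 1920), whatever the image content.
"""

import numpy as np

from vessnet import SynthParams, augment_dataset, generate_dataset
from vessnet.augment import stage1_flips, stage2_recursive, stage3_nonrecursive

pairs = generate_dataset(20, SynthParams(image_size=64, seed=1))
fractions = [p.mask.mean() for p in pairs]
print(f"generated {len(pairs)} pairs, vessel fraction "
      f"{np.min(fractions):.3f}-{np.max(fractions):.3f} "
      f"(background:vessel ~ {np.mean([(1 - f) / f for f in fractions]):.1f}:1)")

s1 = stage1_flips(pairs)
s2 = stage2_recursive(s1)
s3 = stage3_nonrecursive(s2)
full = augment_dataset(pairs)
print(f"stage 1 (flips)           : {len(pairs)} -> {len(s1)}")
print(f"stage 2 (recursive)       : {len(s1)} -> {len(s2)}")
print(f"stage 3 (non-recursive)   : {len(s2)} -> {len(s3)} new")
print(f"training set (s2 + s3)    : {len(full)}")
print(f"example lineage           : {full[-1].provenance}")
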