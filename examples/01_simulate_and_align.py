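"""Generate a phantom view pair and recover its pose from the masks.

Builds a synthetic dorsal/palmar boundary pair with a known mirror +
rigid displacement, runs the full mask -> landmarks -> pose -> fusion
pipeline, and compares the recovered transform with the generator's
ground truth.
"""

import numpy as np

from pocusalign import AlignmentConfig, align_masks
from pocusalign.phantom import PhantomConfig, generate_pair

pair = generate_pair(PhantomConfig(seed=7))
cfg = AlignmentConfig(d=pair.config.bone_width, w=pair.config.bone_width)
res = align_masks(pair.fixed_mask, pair.moving_mask, cfg)

rec = pair.moving_landmarks.transformed(res.transform).as_array()
tru = pair.moving_landmarks.transformed(pair.true_transform).as_array()
err = np.linalg.norm(rec - tru, axis=1)

print(f"recovered pose: theta={res.transform.theta:+.4f} rad, "
      f"t=({res.transform.tx:+.2f}, {res.transform.ty:+.2f}) mm, flip={res.transform.pre_flip}")
print(f"final energy: {res.final_energy:.4f}  (weighted mm of residual constraint violation)")
print(f"landmark placement error vs ground truth: "
      f"{err.mean():.3f} mm mean, {err.max():.3f} mm max")
print("A sub-millimetre error means the two views land on the two cortices")
print("of one bone, i.e. the fused view is anatomically consistent.")
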