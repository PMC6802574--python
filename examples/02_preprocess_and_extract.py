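"""Preprocess one image and extract per-block backbone features.

Shows the two resize protocols and the block geometry: after block ck of
the five-block backbone the spatial side is S / 2^k, with filter depths
64, 128, 256, 512, 512.
"""

import numpy as np

import taxofeat as tf

rng = np.random.default_rng(0)
image = rng.integers(0, 256, (300, 180, 3), dtype=np.uint8)  # a tall "photo"

spec = tf.ResizeSpec(target_side=224, mode="preserve_aspect", pad_seed=0)
frame = tf.preprocess_image(image, spec)
print(f"input {image.shape[:2]} -> frame {frame.shape[:2]} (aspect preserved, random padding)")

backbone = tf.make_fixture_backbone(seed=0)
features = tf.extract_features(backbone, frame, ("c3", "c4", "c5"), {"c5": "pre_pool"})
for block, fm in features.items():
    print(f"{block} ({fm.tap_point}): {fm.values.shape}")
# c3 post-pool is 28x28x256 at S=224, c4 is 14x14x512 and c5 tapped before
# its final max-pool keeps 14x14x512 — the common grid of the intermediate
# pooling scheme.
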