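"""Build descriptor variants from one image's block features.

Global pooling collapses a block to one value per filter; the intermediate
scheme pools to an N x N grid on the padded common grid; fusion
concatenates blocks; signed square root compresses the dynamic range.
"""

import numpy as np

import taxofeat as tf

backbone = tf.make_fixture_backbone(seed=0)
frame = np.random.default_rng(1).integers(0, 256, (416, 416, 3), dtype=np.uint8)
fmats = tf.extract_features(backbone, frame, ("c3", "c4", "c5"), {"c5": "pre_pool"})

g3 = tf.global_pool(fmats["c3"], "average")
print(f"c3 global average: {g3.shape[0]} features")  # 256

flat4 = tf.flatten_features(fmats["c4"].values)
print(f"c4 fully flattened: {flat4.shape[0]:,} features")  # 346,112

v7 = tf.intermediate_vector(fmats["c4"], reference_side=26, level=7)
print(f"c4 at N=7: {v7.shape[0]:,} features")  # 7*7*512 = 25,088

fused = tf.fuse([
    tf.FeatureVector(tf.intermediate_vector(fmats[b], 26, 2), "img", (b,))
    for b in ("c3", "c4", "c5")
])
normalized = tf.signed_sqrt(fused.values)
print(f"c3+c4+c5 fused at N=2: {len(fused):,} features, blocks {fused.blocks}")
print(f"signed sqrt keeps signs: {np.array_equal(np.sign(normalized), np.sign(fused.values))}")
# The descriptor length trades off spatial detail (N) against classifier cost.
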