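"""Encode a slice with PCFAN, fuse the pyramid, and pretrain briefly.

The encoder yields 32/64/128-channel maps at full/half/quarter resolution;
PCFA combines them through four channel-attention blocks and two upsamplings;
a single convolution reconstructs a [0,1] image.
"""

import numpy as np

from pdfuse import pcfan, phantoms

cfg = pcfan.PCFANConfig(stage_channels=(8, 16, 24), attention_reduction=4)
model = pcfan.PCFAN(cfg)

img = phantoms.generate_phantom(phantoms.PhantomSpec(image_size=64, seed=3))
pyr = model.encode(img[None, None])
print("pyramid shapes:", pyr.f1.shape, pyr.f2.shape, pyr.f3.shape)
print("channel-attention blocks in PCFA:", len(model.attention_blocks))

X = np.stack([phantoms.generate_phantom(
    phantoms.PhantomSpec(image_size=32, class_label=i % 3, seed=i))
    for i in range(16)])
trained, history = pcfan.pretrain_pcfan(X, cfg, epochs=5, seed=0)
print(history.to_string(index=False))
# Self-supervised reconstruction: the loss is the MSE between each input
# slice and its attention-refined reconstruction; it should fall epoch over
# epoch from the randomly initialized starting point.
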