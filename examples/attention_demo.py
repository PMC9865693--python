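"""The multi-scale attention module on a toy feature map.

Shows the two defining properties of the dual attention: every row of
the spatial map S and the channel map X is a probability distribution,
and with the scale parameters alpha and beta at their zero
initialisation the whole attention block is an exact identity.
"""

import numpy as np

from laseg.autodiff import Tensor
from laseg.msa import MSA, ChannelAttention, PositionAttention

rng = np.random.default_rng(0)
feature_map = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))

pos = PositionAttention(8, rng=rng)
chan = ChannelAttention()

s = pos.attention_map(feature_map).data      # (1, 36, 36): pixel-to-pixel
x = chan.attention_map(feature_map).data     # (1, 8, 8): channel-to-channel
print(f"spatial attention S: shape {s.shape[1:]}, "
      f"row sums in [{s.sum(axis=2).min():.6f}, {s.sum(axis=2).max():.6f}]")
print(f"channel attention X: shape {x.shape[1:]}, "
      f"row sums in [{x.sum(axis=2).min():.6f}, {x.sum(axis=2).max():.6f}]")

out = pos(feature_map).data
print(f"max |output - input| with alpha = 0: {np.abs(out - feature_map.data).max():.2e} "
      "(attention starts as identity and grows in during training)")

msa = MSA(8, max_grid=8, rng=rng)
fused = msa.pool(feature_map)
print(f"pyramid pooling: {feature_map.shape[1]} -> {fused.shape[1]} channels "
      "(avg+max pyramids at grids 1, 2, 4, 6, fused with the input)")
print(f"full MSA restores the skip width: output {msa(feature_map).shape}")
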