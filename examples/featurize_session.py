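"""Turn one subject's raw IMU session into the model input tensor.

Shows the 1530-feature registry at work: preprocessing, joint angles, 2 s /
50% windows, and per-window statistics, packed as [7 motions, WL, 1530].
"""

import numpy as np

from fmaue import ImpairmentProfile, simulate_subject
from fmaue.features import feature_index, feature_meaning
from fmaue.pipeline import PipelineConfig, session_to_tensor

subject = simulate_subject(
    ImpairmentProfile(np.array([0.3, 0.6, 0.2, 0.8])), seed=42)
tensor = session_to_tensor(subject, PipelineConfig())

print("tensor shape:", tensor.values.shape)          # (7, 9, 1530)
print("real window slots per motion:", tensor.mask.sum(axis=1))

i = feature_index("hand.gyro_x", "std")
print(f"feature {i} = {feature_meaning(i)}")
print("  WC-motion values over windows:",
      np.round(tensor.values[4, :, i], 2))
# Larger wrist-severity subjects show larger hand-gyro variability in the
# wrist-circumduction (WC) rows; the mask marks padded slots for motions
# whose trial yielded fewer than WL windows.
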