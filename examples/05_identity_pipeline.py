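"""Identity-aware social decoding and temporal identity correction.

Uses exact (oracle) head maps for two-animal scenes to walk through the
bidirectional identity procedure — BAF votes for centers, LRSS labels the
centers, heatmap peaks inherit the identity map's labels — then injects a
single-frame identity swap into a video track and removes it with the
temporal pass.
"""

import adpt
from adpt.experiments import (
    identity_pipeline_accuracy,
    swap_correction_change_rates,
)

acc = identity_pipeline_accuracy(n_scenes=50, seed=0)
print(f"two-animal scenes fully recovered from exact head maps: "
      f"{100 * acc:.0f}% (correct identities, keypoints exact)")

before, after = swap_correction_change_rates(seed=0)
print(f"identity change rate at alpha=75 px with one injected swap: "
      f"{before:.4f} before temporal correction, {after:.4f} after")
print("(a single-frame swap makes each identity's center jump out and "
      "back: 2 jumps / 100 frames = 0.02; motion-continuity relabeling "
      "plus majority smoothing removes it)")
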